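"""Molecular structures, trajectories and force-field parameter tables.

Internal units are Å for length and kcal mol⁻¹ for energy everywhere in the
package; GRO files (nm) are converted at the I/O boundary.  A *dimer* is a
:class:`Structure` whose atoms carry chain labels ``A`` and ``B`` — the
partition every downstream binding-energy and interface calculation consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ForceField",
    "CoreSelection",
    "DEFAULT_CORE",
    "StructureError",
    "ParseError",
    "MissingParameterError",
    "read_gro",
    "write_gro",
    "read_gro_trajectory",
    "write_gro_trajectory",
    "read_pdb",
    "write_pdb",
    "partition_dimer",
    "merge",
    "load_forcefield",
]


class StructureError(ValueError):
    """Inconsistent molecular structure or partition."""


class ParseError(ValueError):
    """Malformed coordinate or parameter file."""


class MissingParameterError(KeyError):
    """An atom could not be resolved against the force-field tables."""


@dataclass
class Atom:
    """One atom: identity, residue membership and position (Å)."""

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = _guess_element(self.name)


def _guess_element(name: str) -> str:
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    return ""


class Structure:
    """An ordered collection of atoms with an optional periodic box (Å).

    Array-backed for vectorised access: ``coords`` is an (N, 3) float array,
    ``names``/``resnames``/``chains`` are object arrays, ``resseqs``/``serials``
    integer arrays.  :meth:`atoms` materialises :class:`Atom` objects on demand.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        resnames: Sequence[str],
        resseqs: Sequence[int],
        chains: Sequence[str],
        coords: np.ndarray,
        box: np.ndarray | None = None,
    ) -> None:
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resseqs = np.asarray(resseqs, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.box = None if box is None else np.asarray(box, dtype=float)
        n = len(self.serials)
        if not all(len(a) == n for a in (self.names, self.resnames, self.resseqs, self.chains)) or len(self.coords) != n:
            raise StructureError("structure fields must have identical length")
        if len(set(self.serials.tolist())) != n:
            raise StructureError("atom serials must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    # -- construction -------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: Iterable[Atom], box: np.ndarray | None = None) -> "Structure":
        atoms = list(atoms)
        return cls(
            [a.serial for a in atoms],
            [a.name for a in atoms],
            [a.residue_name for a in atoms],
            [a.residue_seq for a in atoms],
            [a.chain_id for a in atoms],
            np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3),
            box=box,
        )

    # -- basic views --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(int(s), str(n), str(rn), int(rs), str(c), xyz)
            for s, n, rn, rs, c, xyz in zip(
                self.serials, self.names, self.resnames, self.resseqs, self.chains, self.coords
            )
        ]

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.serials[mask], self.names[mask], self.resnames[mask],
            self.resseqs[mask], self.chains[mask], self.coords[mask], box=self.box,
        )

    def chain(self, label: str) -> "Structure":
        return self.subset(self.chains == label)

    def chain_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(str(c), None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, resseq, resname) triples in order of appearance."""
        out: dict[tuple[str, int], str] = {}
        for c, rs, rn in zip(self.chains, self.resseqs, self.resnames):
            out.setdefault((str(c), int(rs)), str(rn))
        return [(c, rs, rn) for (c, rs), rn in out.items()]

    # -- geometry -----------------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.serials, self.names, self.resnames, self.resseqs,
                         self.chains, coords, box=self.box)

    def with_chain(self, label: str) -> "Structure":
        return Structure(self.serials, self.names, self.resnames, self.resseqs,
                         np.full(self.n_atoms, label, dtype=object), self.coords, box=self.box)

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "Structure":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return self.with_coords(xyz)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def ca_mask(self) -> np.ndarray:
        return np.array([str(n).strip() == "CA" for n in self.names], dtype=bool)


@dataclass
class Trajectory:
    """Frames sharing one topology; ``time_per_frame`` in ps."""

    frames: list[Structure]
    time_per_frame: float = 100.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        names0 = self.frames[0].names
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n0 or not np.array_equal(fr.names, names0):
                raise StructureError(f"frame {i} does not share the common topology")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.time_per_frame


# ---------------------------------------------------------------------------
# GRO I/O (fixed column, nm in file, Å in memory)
# ---------------------------------------------------------------------------

def _parse_gro_frame(lines: list[str], lineno0: int, chain: str = "") -> Structure:
    if len(lines) < 3:
        raise ParseError(f"line {lineno0 + 1}: truncated GRO frame")
    try:
        n_atoms = int(lines[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {lineno0 + 2}: cannot read GRO atom count") from exc
    if len(lines) != n_atoms + 3:
        raise ParseError(
            f"line {lineno0 + 2}: header declares {n_atoms} atoms but frame has {len(lines) - 3}"
        )
    serials, names, resnames, resseqs, coords = [], [], [], [], []
    for k, line in enumerate(lines[2:2 + n_atoms]):
        ln = lineno0 + 3 + k
        if len(line.rstrip("\n")) < 44:
            raise ParseError(f"line {ln}: GRO atom line too short")
        try:
            resseqs.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            serials.append(int(line[15:20]))
            coords.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
            # velocity columns (44:68), if present, are parsed and discarded
        except ValueError as exc:
            raise ParseError(f"line {ln}: malformed GRO atom record") from exc
    try:
        box = np.array([float(x) for x in lines[2 + n_atoms].split()[:3]]) * NM_TO_ANGSTROM
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {lineno0 + 3 + n_atoms}: malformed GRO box line") from exc
    # GRO atom numbering wraps at 100000; renumber sequentially if duplicated
    if len(set(serials)) != len(serials):
        serials = list(range(1, n_atoms + 1))
    return Structure(
        serials, names, resnames, resseqs, [chain] * n_atoms,
        np.asarray(coords) * NM_TO_ANGSTROM, box=box,
    )


def read_gro(path: str | Path) -> Structure:
    """Read a single-frame GRO file.  Coordinates converted nm → Å."""
    lines = Path(path).read_text().splitlines()
    try:
        n_atoms = int(lines[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError("line 2: cannot read GRO atom count") from exc
    return _parse_gro_frame(lines[: n_atoms + 3] if len(lines) >= n_atoms + 3 else lines, 0)


def read_gro_trajectory(path: str | Path, time_per_frame: float = 100.0) -> Trajectory:
    """Read concatenated GRO frames as a trajectory."""
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        try:
            n_atoms = int(lines[i + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {i + 2}: cannot read GRO atom count") from exc
        frames.append(_parse_gro_frame(lines[i: i + n_atoms + 3], i))
        i += n_atoms + 3
    return Trajectory(frames, time_per_frame=time_per_frame)


def _format_gro_frame(structure: Structure, title: str) -> str:
    out = [title, f"{structure.n_atoms:5d}"]
    for s, n, rn, rs, xyz in zip(
        structure.serials, structure.names, structure.resnames, structure.resseqs, structure.coords
    ):
        x, y, z = xyz / NM_TO_ANGSTROM
        out.append(f"{int(rs) % 100000:5d}{str(rn):<5.5s}{str(n):>5.5s}{int(s) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    box = structure.box if structure.box is not None else np.zeros(3)
    out.append("".join(f"{v / NM_TO_ANGSTROM:10.5f}" for v in box))
    return "\n".join(out) + "\n"


def write_gro(structure: Structure, path: str | Path, title: str = "bindmodes") -> None:
    Path(path).write_text(_format_gro_frame(structure, title))


def write_gro_trajectory(trajectory: Trajectory, path: str | Path, title: str = "bindmodes") -> None:
    with open(path, "w") as fh:
        for i, fr in enumerate(trajectory.frames):
            fh.write(_format_gro_frame(fr, f"{title} t= {i * trajectory.time_per_frame:.1f} ps"))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records (Å).  Insertion codes are rejected; other
    record types are skipped with a log entry."""
    serials, names, resnames, resseqs, chains, coords = [], [], [], [], [], []
    skipped: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {ln}: ATOM record too short")
            if line[26].strip():
                raise ParseError(f"line {ln}: insertion codes are not supported")
            try:
                serials.append(int(line[6:11]))
                names.append(line[12:16].strip())
                resnames.append(line[17:20].strip())
                chains.append(line[21].strip())
                resseqs.append(int(line[22:26]))
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise ParseError(f"line {ln}: malformed ATOM record") from exc
        elif rec and rec not in ("TER", "END", "ENDMDL", "MODEL", "REMARK", "CRYST1", "TITLE"):
            skipped.add(rec)
    if skipped:
        log.info("read_pdb: skipped record types %s", sorted(skipped))
    if len(set(serials)) != len(serials):
        raise ParseError("duplicate atom serials in PDB file")
    return Structure(serials, names, resnames, resseqs, chains, np.asarray(coords, dtype=float))


def write_pdb(structure: Structure, path: str | Path) -> None:
    out = []
    for s, n, rn, rs, c, xyz in zip(
        structure.serials, structure.names, structure.resnames,
        structure.resseqs, structure.chains, structure.coords,
    ):
        name = str(n)
        name_f = f" {name:<3.3s}" if len(name) < 4 else name[:4]
        out.append(
            f"ATOM  {int(s) % 100000:5d} {name_f} {str(rn):<3.3s} {str(c)[:1] or 'A'}"
            f"{int(rs) % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}"
        )
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Dimer partition
# ---------------------------------------------------------------------------

def partition_dimer(
    structure: Structure,
    rule: str | int = "chain",
    labels: tuple[str, str] | None = None,
) -> tuple[Structure, Structure]:
    """Split a complex into its two monomers.

    ``rule='chain'`` splits on the existing chain labels (optionally named
    explicitly via ``labels``); an integer rule splits at that atom index.
    The two halves are relabeled ``A`` and ``B``.
    """
    if rule == "chain":
        present = structure.chain_labels()
        if labels is None:
            if len(present) != 2:
                raise StructureError(f"chain partition needs exactly 2 chains, found {present}")
            labels = (present[0], present[1])
        for lab in labels:
            if lab not in present:
                raise StructureError(f"chain {lab!r} not present in structure (chains: {present})")
        a = structure.chain(labels[0])
        b = structure.chain(labels[1])
        if a.n_atoms + b.n_atoms != structure.n_atoms:
            raise StructureError("chain partition does not cover the whole structure")
    elif isinstance(rule, int):
        if not 0 < rule < structure.n_atoms:
            raise StructureError(f"index split {rule} outside (0, {structure.n_atoms})")
        idx = np.arange(structure.n_atoms)
        a, b = structure.subset(idx < rule), structure.subset(idx >= rule)
    else:
        raise StructureError(f"unknown partition rule {rule!r}")
    return a.with_chain("A"), b.with_chain("B")


def merge(a: Structure, b: Structure) -> Structure:
    """Concatenate two monomers back into one complex (order preserved)."""
    return Structure(
        np.concatenate([a.serials, b.serials]),
        np.concatenate([a.names, b.names]),
        np.concatenate([a.resnames, b.resnames]),
        np.concatenate([a.resseqs, b.resseqs]),
        np.concatenate([a.chains, b.chains]),
        np.vstack([a.coords, b.coords]),
        box=a.box,
    )


# ---------------------------------------------------------------------------
# Force field
# ---------------------------------------------------------------------------

WILDCARD = "*"


@dataclass
class ForceField:
    """Nonbonded parameters: partial charges (e), PB radii (Å) and
    intermolecular 12–6 Lennard-Jones pair coefficients
    (C6: kcal mol⁻¹ Å⁶, C12: kcal mol⁻¹ Å¹²).

    Charges and radii are keyed by ``(residue_name, atom_name)`` with a
    wildcard-residue fallback; first match wins.  LJ pairs are keyed by atom
    type, where an atom's type defaults to its atom name unless remapped in
    ``atom_types``.
    """

    charges: dict[tuple[str, str], float]
    radii: dict[tuple[str, str], float]
    lj_pairs: dict[tuple[str, str], tuple[float, float]]
    atom_types: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"radius for {key} must be positive")

    def _lookup(self, table: dict, resname: str, name: str, what: str):
        for key in ((resname, name), (WILDCARD, name)):
            if key in table:
                return table[key]
        raise MissingParameterError(f"no {what} for atom {name!r} in residue {resname!r}")

    def charge_of(self, resname: str, name: str) -> float:
        return self._lookup(self.charges, resname, name, "charge")

    def radius_of(self, resname: str, name: str) -> float:
        return self._lookup(self.radii, resname, name, "radius")

    def type_of(self, resname: str, name: str) -> str:
        for key in ((resname, name), (WILDCARD, name)):
            if key in self.atom_types:
                return self.atom_types[key]
        return name

    def lj_of(self, type_i: str, type_j: str) -> tuple[float, float]:
        for key in ((type_i, type_j), (type_j, type_i)):
            if key in self.lj_pairs:
                return self.lj_pairs[key]
        raise MissingParameterError(f"no Lennard-Jones coefficients for type pair ({type_i}, {type_j})")

    # vectorised assignment ------------------------------------------
    def assign_charges(self, structure: Structure) -> np.ndarray:
        return np.array([self.charge_of(rn, n) for rn, n in zip(structure.resnames, structure.names)])

    def assign_radii(self, structure: Structure) -> np.ndarray:
        return np.array([self.radius_of(rn, n) for rn, n in zip(structure.resnames, structure.names)])

    def assign_types(self, structure: Structure) -> np.ndarray:
        return np.array([self.type_of(rn, n) for rn, n in zip(structure.resnames, structure.names)], dtype=object)


def _read_table(path: str | Path, ncols: int) -> list[list[str]]:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < ncols:
            raise ParseError(f"{path}: line {ln}: expected {ncols} columns, got {len(parts)}")
        rows.append(parts[:ncols])
    return rows


def load_forcefield(charges_path: str | Path, radii_path: str | Path, lj_path: str | Path) -> ForceField:
    """Load plain-text parameter tables.

    ``charges.tsv``: resname atomname charge; ``radii.tsv``: resname atomname
    radius_Å; ``lj.tsv``: type_i type_j C6 C12.  Conflicting duplicate keys
    raise; identical duplicates are tolerated.
    """
    charges: dict[tuple[str, str], float] = {}
    for rn, an, q in _read_table(charges_path, 3):
        key = (rn, an)
        val = float(q)
        if key in charges and charges[key] != val:
            raise ParseError(f"{charges_path}: conflicting duplicate charge for {key}")
        charges[key] = val
    radii: dict[tuple[str, str], float] = {}
    for rn, an, r in _read_table(radii_path, 3):
        key = (rn, an)
        val = float(r)
        if key in radii and radii[key] != val:
            raise ParseError(f"{radii_path}: conflicting duplicate radius for {key}")
        radii[key] = val
    lj: dict[tuple[str, str], tuple[float, float]] = {}
    for t1, t2, c6, c12 in _read_table(lj_path, 4):
        val = (float(c6), float(c12))
        for key in ((t1, t2), (t2, t1)):
            if key in lj and lj[key] != val:
                raise ParseError(f"{lj_path}: conflicting duplicate LJ coefficients for {key}")
        lj[(t1, t2)] = val
        lj[(t2, t1)] = val
    return ForceField(charges=charges, radii=radii, lj_pairs=lj)


# ---------------------------------------------------------------------------
# Core selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreSelection:
    """Residue ranges (inclusive) defining the structured core used for
    fitting and RMSD; applied identically to both monomers."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("core selection must contain at least one range")
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"invalid core range ({lo}, {hi})")

    def contains(self, resseq: int) -> bool:
        return any(lo <= resseq <= hi for lo, hi in self.ranges)

    def ca_coords(self, structure: Structure, chain: str | None = None) -> np.ndarray:
        """Core Cα coordinates of one chain (or the whole structure), in
        residue order."""
        mask = structure.ca_mask()
        if chain is not None:
            mask &= structure.chains == chain
        mask &= np.array([self.contains(int(r)) for r in structure.resseqs])
        sub = structure.subset(mask)
        expected = [rs for lo, hi in self.ranges for rs in range(lo, hi + 1)]
        got = sorted(int(r) for r in sub.resseqs)
        missing = sorted(set(expected) - set(got))
        if missing:
            raise StructureError(f"core Cα atoms missing for residues {missing}"
                                 + (f" in chain {chain}" if chain else ""))
        order = np.argsort(sub.resseqs, kind="stable")
        return sub.coords[order]


#: β-sheet core of the β2-microglobulin fold: the residue ranges whose Cα
#: atoms are used for structural fitting and RMSD.
DEFAULT_CORE = CoreSelection(((23, 27), (36, 39), (51, 55), (62, 66), (78, 82)))
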