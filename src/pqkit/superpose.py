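"""Rigid-body superposition and RMSD between two models of one entry.

A deposited model and its re-refined counterpart share chain and residue
numbering, so atoms are paired by identity keys (chain, residue number,
insertion code, residue name, atom name) rather than by sequence
alignment -- this sidesteps the cross-program misalignment artifacts that
produce absurd RMSD values (tens of Angstroms) when whole-model
alignments go wrong. Two atom selections are supported: ``calpha`` (CA
atoms of the standard amino acids) and ``heavy`` (all non-hydrogen,
non-water atoms). Superposition is the Kabsch algorithm: the
least-squares optimal proper rotation via SVD of the coordinate
cross-covariance, with the reflection corrected so the returned rotation
always has determinant +1.

Alternate locations: altloc 'A' or blank is kept, others discarded;
occupancy is ignored. Waters are residues named HOH/WAT/DOD; hydrogens
are elements H/D.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "AtomSet",
    "MatchReport",
    "Superposition",
    "PairRMSD",
    "read_structure",
    "write_pdb",
    "match_atoms",
    "kabsch_superpose",
    "model_pair_rmsd",
]

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})
HYDROGEN_ELEMENTS = frozenset({"H", "D"})
STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


class Atom(NamedTuple):
    chain: str
    resseq: int
    icode: str
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chain, self.resseq, self.icode, self.resname, self.name)


@dataclass(frozen=True)
class AtomSet:
    """Labelled coordinates of one model (one altloc-resolved atom per key)."""

    entry_id: str
    atoms: tuple[Atom, ...]
    source_format: str = "memory"

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(keys) != len(set(keys)):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate atom key {dup} in {self.entry_id}")
        for a in self.atoms:
            if not all(np.isfinite([a.x, a.y, a.z])):
                raise ValueError(f"non-finite coordinates on {a.key}")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)


def read_structure(path: str | Path, entry_id: Optional[str] = None) -> AtomSet:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomSet`.

    The first model is used; altloc 'A'/blank kept, others dropped.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    fmt = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                atoms.append(Atom(
                    chain=chain.name,
                    resseq=residue.seqid.num,
                    icode=(residue.seqid.icode or "").strip(),
                    resname=residue.name.strip().upper(),
                    name=atom.name.strip().upper(),
                    element=atom.element.name.strip().upper(),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                ))
    return AtomSet(entry_id=(entry_id or st.name or path.stem).lower(),
                   atoms=tuple(atoms), source_format=fmt)


def write_pdb(atom_set: AtomSet, path: str | Path) -> None:
    """Write an AtomSet as a minimal PDB-format file (deterministic)."""
    lines = []
    for i, a in enumerate(atom_set.atoms, start=1):
        hetatm = a.resname in WATER_RESIDUES or a.resname not in STANDARD_AMINO_ACIDS
        record = "HETATM" if hetatm else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name}{'':1s}{a.resname:>3s} {a.chain[:1]}"
            f"{a.resseq:4d}{a.icode:1s}   {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class MatchReport:
    n_matched: int
    unmatched_a: tuple[tuple, ...]
    unmatched_b: tuple[tuple, ...]

    @property
    def matched_fraction(self) -> float:
        total = self.n_matched + max(len(self.unmatched_a), len(self.unmatched_b))
        return self.n_matched / total if total else 0.0


def _select(atom_set: AtomSet, mode: Literal["calpha", "heavy"]) -> list[Atom]:
    out = []
    for a in atom_set.atoms:
        if a.resname in WATER_RESIDUES:
            continue
        if mode == "calpha":
            if a.name == "CA" and a.resname in STANDARD_AMINO_ACIDS:
                out.append(a)
        elif mode == "heavy":
            if a.element not in HYDROGEN_ELEMENTS:
                out.append(a)
        else:
            raise ValueError(f"mode must be 'calpha' or 'heavy', got {mode!r}")
    return out


def match_atoms(
    a: AtomSet, b: AtomSet, mode: Literal["calpha", "heavy"]
) -> tuple[np.ndarray, np.ndarray, MatchReport]:
    """Pair atoms of two models by identity keys under a selection mode.

    Returns paired Nx3 coordinate arrays (same key order on both sides,
    sorted for order-invariance) and a report of unmatched atoms per side.
    Zero matched pairs is an error -- it signals mismatched models.
    """
    if not a.atoms or not b.atoms:
        raise ValueError("empty atom set")
    sel_a = {atom.key: atom for atom in _select(a, mode)}
    sel_b = {atom.key: atom for atom in _select(b, mode)}
    shared = sorted(sel_a.keys() & sel_b.keys())
    if not shared:
        raise ValueError(
            f"no atoms matched between {a.entry_id} and {b.entry_id} in mode {mode!r}"
        )
    coords_a = np.array([(sel_a[k].x, sel_a[k].y, sel_a[k].z) for k in shared])
    coords_b = np.array([(sel_b[k].x, sel_b[k].y, sel_b[k].z) for k in shared])
    report = MatchReport(
        n_matched=len(shared),
        unmatched_a=tuple(sorted(sel_a.keys() - sel_b.keys())),
        unmatched_b=tuple(sorted(sel_b.keys() - sel_a.keys())),
    )
    return coords_a, coords_b, report


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # applied as R @ x + t, mapping a onto b
    rmsd: float


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of paired point sets.

    SVD-based Kabsch with reflection correction: the returned rotation is
    always proper (det = +1). Requires at least 3 non-collinear pairs;
    collinear configurations leave the rotation underdetermined and are
    rejected.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coords must be matching Nx3 arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atom pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv = np.linalg.svd(A0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate configuration")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A0 @ R.T) - B0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


@dataclass(frozen=True)
class PairRMSD:
    calpha_rmsd: float
    heavy_rmsd: float
    calpha_report: MatchReport
    heavy_report: MatchReport
    warnings: tuple[str, ...]


def model_pair_rmsd(
    a: AtomSet,
    b: AtomSet,
    warn_rmsd: float = 10.0,
    warn_min_matched_fraction: float = 0.5,
) -> PairRMSD:
    """CA-only and all-heavy-atom RMSD between two models of one entry.

    Waters are always excluded. A warning is emitted when an RMSD exceeds
    ``warn_rmsd`` (default 10 A, the scale of known misalignment
    artifacts) or when fewer than half the atoms matched.
    """
    warnings: list[str] = []
    results = {}
    reports = {}
    for mode in ("calpha", "heavy"):
        ca, cb, report = match_atoms(a, b, mode)
        sup = kabsch_superpose(ca, cb)
        results[mode] = sup.rmsd
        reports[mode] = report
        if sup.rmsd > warn_rmsd:
            warnings.append(
                f"{mode} RMSD {sup.rmsd:.1f} A exceeds {warn_rmsd} A -- likely misalignment"
            )
        if report.matched_fraction < warn_min_matched_fraction:
            warnings.append(
                f"{mode} matched fraction {report.matched_fraction:.2f} below "
                f"{warn_min_matched_fraction}"
            )
    return PairRMSD(
        calpha_rmsd=results["calpha"],
        heavy_rmsd=results["heavy"],
        calpha_report=reports["calpha"],
        heavy_report=reports["heavy"],
        warnings=tuple(warnings),
    )
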