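"""Structural-ensemble superposition, coordinate precision and restraint tallies.

An NMR ensemble is a set of models sharing one atom inventory.  Precision
is reported as the mean RMSD of the models to their iteratively refined
mean structure over a stated atom selection (backbone = N, CA, C by
default), the convention used for "coordinate precision" statistics of
NMR structure tables; a pairwise-RMSD alternative is available behind a
flag.  Superposition is the closed-form least-squares (Kabsch) rotation
with reflections excluded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureEnsemble", "Selection", "RestraintTable", "kabsch_superpose",
    "ensemble_precision", "per_residue_rmsd", "tally_restraints",
    "BACKBONE_ATOMS",
]

#: Backbone atom names used for precision statistics (carbonyl O excluded).
BACKBONE_ATOMS = ("N", "CA", "C")

# A model is a plain mapping: residue_id -> {atom_name: (x, y, z)}.
Model = dict[int, dict[str, np.ndarray]]


@dataclass
class StructureEnsemble:
    """Multi-model coordinates with a shared atom inventory."""

    models: list[Model]
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        inv0 = self._inventory(self.models[0])
        for k, m in enumerate(self.models[1:], start=2):
            if self._inventory(m) != inv0:
                raise ValueError(
                    f"model {k} atom inventory differs from model 1")

    @staticmethod
    def _inventory(model: Model) -> list[tuple[int, str]]:
        return sorted((rid, a) for rid, atoms in model.items() for a in atoms)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self.models[0])

    def coordinates(self, sel: "Selection | None" = None) -> np.ndarray:
        """Stacked coordinates, shape (n_models, n_atoms, 3), atoms in a
        fixed (residue_id, atom_name) order under the selection."""
        keys = self.atom_keys(sel)
        out = np.empty((self.n_models, len(keys), 3))
        for i, m in enumerate(self.models):
            for j, (rid, a) in enumerate(keys):
                out[i, j] = m[rid][a]
        return out

    def atom_keys(self, sel: "Selection | None" = None) -> list[tuple[int, str]]:
        keys = self._inventory(self.models[0])
        if sel is None:
            return keys
        return [k for k in keys if sel.contains(*k)]


@dataclass(frozen=True)
class Selection:
    """Residue ranges (1-based, inclusive) and atom names.

    Parsed from strings like ``"2-13,16-19:N,CA,C"``; an empty range list
    means all residues, an empty atom list all atoms.
    """

    ranges: tuple[tuple[int, int], ...] = ()
    atoms: tuple[str, ...] = ()

    @classmethod
    def parse(cls, spec: str) -> "Selection":
        spec = spec.strip()
        if not spec:
            return cls()
        res_part, _, atom_part = spec.partition(":")
        ranges = []
        for token in filter(None, (t.strip() for t in res_part.split(","))):
            m = re.fullmatch(r"(\d+)(?:-(\d+))?", token)
            if not m:
                raise ValueError(f"bad residue range {token!r}")
            lo = int(m.group(1))
            hi = int(m.group(2) or lo)
            if hi < lo:
                raise ValueError(f"inverted range {token!r}")
            ranges.append((lo, hi))
        atoms = tuple(filter(None, (a.strip() for a in atom_part.split(","))))
        return cls(tuple(ranges), atoms)

    def contains(self, residue_id: int, atom_name: str) -> bool:
        if self.ranges and not any(lo <= residue_id <= hi for lo, hi in self.ranges):
            return False
        if self.atoms and atom_name not in self.atoms:
            return False
        return True


@dataclass(frozen=True)
class RestraintTable:
    """Restraint counts by class for structure-statistics accounting.

    Hydrogen-bond restraints are counted as supplied; note that some
    protocols enter two distance restraints per hydrogen bond, so the
    count convention must match the source table.
    """

    noe_count: int = 0
    dihedral_phi: int = 0
    dihedral_psi: int = 0
    dihedral_chi: int = 0
    hbond_count: int = 0
    rdc_count: int = 0
    n_residues: int = 1

    def __post_init__(self) -> None:
        for name in ("noe_count", "dihedral_phi", "dihedral_psi",
                     "dihedral_chi", "hbond_count", "rdc_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_residues <= 0:
            raise ValueError("n_residues must be positive")


def kabsch_superpose(reference: Model, mobile: Model,
                     sel: Selection | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits the reference over
    the selected atoms.  The rotation is proper (det = +1); reflections
    are excluded by the standard sign correction.  Requires >= 3
    non-collinear atoms in common under the selection.
    """
    keys = sorted(set(StructureEnsemble._inventory(reference))
                  & set(StructureEnsemble._inventory(mobile)))
    if sel is not None:
        keys = [k for k in keys if sel.contains(*k)]
    if len(keys) < 3:
        raise ValueError(f"selection yields {len(keys)} common atoms; >= 3 required")
    p = np.array([reference[r][a] for r, a in keys], dtype=float)
    q = np.array([mobile[r][a] for r, a in keys], dtype=float)
    rot, t, rmsd = _kabsch(p, q)
    return rot, t, rmsd


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(q0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    h = q0.T @ p0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = pc - rot @ qc
    fitted = q0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - p0) ** 2, axis=1))))
    return rot, t, rmsd


def _superpose_to_mean(coords: np.ndarray, tol: float = 1e-6,
                       max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all models onto their mean until the mean
    structure shifts by less than `tol` Angstrom.  Returns (aligned
    coords, mean structure)."""
    aligned = coords.copy()
    # seed: superpose everything on model 1
    for i in range(1, len(aligned)):
        rot, t, _ = _kabsch(aligned[0], aligned[i])
        aligned[i] = aligned[i] @ rot.T + t
    mean = aligned.mean(axis=0)
    for _ in range(max_iter):
        for i in range(len(aligned)):
            rot, t, _ = _kabsch(mean, aligned[i])
            aligned[i] = aligned[i] @ rot.T + t
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return aligned, mean


def ensemble_precision(ens: StructureEnsemble, sel: Selection | None = None,
                       metric: str = "to_mean") -> tuple[float, float]:
    """Coordinate precision of an ensemble over a selection.

    metric="to_mean" (default): mean +/- sd of per-model RMSDs to the
    iteratively refined mean structure.  metric="pairwise": mean +/- sd
    over all distinct model pairs after superposition to the mean.
    """
    if ens.n_models < 2:
        raise ValueError("precision needs >= 2 models")
    coords = ens.coordinates(sel)
    aligned, mean = _superpose_to_mean(coords)
    if metric == "to_mean":
        rmsds = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
    elif metric == "pairwise":
        pairs = [
            math.sqrt(np.mean(np.sum((aligned[i] - aligned[j]) ** 2, axis=1)))
            for i in range(len(aligned)) for j in range(i + 1, len(aligned))]
        rmsds = np.array(pairs)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sd = float(np.std(rmsds, ddof=1)) if len(rmsds) > 1 else 0.0
    return float(np.mean(rmsds)), sd


def per_residue_rmsd(ens: StructureEnsemble,
                     atoms: tuple[str, ...] = BACKBONE_ATOMS,
                     fit_sel: Selection | None = None) -> dict[int, float]:
    """Per-residue mean RMSD to the mean structure after one global
    superposition (over fit_sel, or all selected atoms).

    The global fit is done once, then per-residue deviations are read off
    without refitting, so flexible segments show up against the common
    core rather than being individually zeroed.
    """
    sel_atoms = Selection(atoms=atoms)
    keys = ens.atom_keys(sel_atoms)
    coords = ens.coordinates(sel_atoms)
    # global superposition over fit_sel (default: all backbone atoms)
    if fit_sel is not None:
        fit_idx = [j for j, k in enumerate(keys) if fit_sel.contains(*k)]
        if len(fit_idx) < 3:
            raise ValueError("fit selection too small")
        fit_coords = coords[:, fit_idx]
        aligned_fit, _ = _superpose_to_mean(fit_coords)
        aligned = coords.copy()
        for i in range(len(coords)):
            rot, t, _ = _kabsch(aligned_fit[i], fit_coords[i])
            aligned[i] = coords[i] @ rot.T + t
    else:
        aligned, _ = _superpose_to_mean(coords)
    mean = aligned.mean(axis=0)
    sq = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # per atom
    out: dict[int, float] = {}
    for rid in ens.residue_ids:
        idx = [j for j, (r, _) in enumerate(keys) if r == rid]
        if idx:
            out[rid] = float(np.sqrt(np.mean(sq[idx])))
    return out


def tally_restraints(t: RestraintTable) -> tuple[int, float]:
    """Total restraint count and the per-residue density.

    total = NOE + (phi + psi + chi) + H-bond + RDC; the density is
    total/n_residues (round to 1 decimal at report time only).
    """
    total = (t.noe_count + t.dihedral_phi + t.dihedral_psi + t.dihedral_chi
             + t.hbond_count + t.rdc_count)
    return total, total / t.n_residues
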