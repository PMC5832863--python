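"""Residual dipolar coupling analysis: alignment-tensor fitting by SVD.

A weakly aligned molecule acquires residual one-bond 1D_NH couplings

    D_i = sum_jk  S_jk  v_ij v_ik            (molecular frame)
        = Da [ (3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2phi ]
                                             (tensor principal frame)

where S is the traceless symmetric order (Saupe) tensor scaled to coupling
units (Hz), v_i the unit N-H bond vector, Da the axial magnitude and
R = Dr/Da the rhombicity (0 <= R <= 2/3).  With >= 5 independent bond
orientations, S is the solution of an ordinary linear least-squares
problem; the fit quality is summarised by the RDC R-factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BondVectorSet", "RdcRecord", "AlignmentTensor", "extract_vectors",
    "svd_fit", "back_calculate", "rdc_rfactor", "tensor_from_da_rhombicity",
]

_UNIT_TOL = 1e-6


@dataclass
class BondVectorSet:
    """Unit N-H bond vectors in the molecular frame, one per residue."""

    residue_ids: np.ndarray   # (n,)
    vectors: np.ndarray       # (n, 3), each |v| = 1

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must be an (n, 3) array")
        if len(self.residue_ids) != len(self.vectors):
            raise ValueError("residue_ids and vectors length mismatch")
        norms = np.linalg.norm(self.vectors, axis=1)
        bad = np.abs(norms - 1.0) > _UNIT_TOL
        if np.any(bad):
            raise ValueError(
                f"non-unit bond vectors for residues {self.residue_ids[bad].tolist()}")

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class RdcRecord:
    residue_id: int
    d_obs: float            # Hz
    d_err: float = 0.0      # Hz
    d_calc: float = math.nan  # filled after fitting

    def __post_init__(self) -> None:
        if self.d_err < 0:
            raise ValueError("d_err must be >= 0")


@dataclass
class AlignmentTensor:
    """Traceless symmetric order tensor in coupling units (Hz).

    saupe holds the full 3x3 matrix.  Derived quantities follow the
    |Szz| >= |Syy| >= |Sxx| eigenvalue convention: Da = Szz/2,
    rhombicity R = (Sxx - Syy)/(1.5*Szz) = Dr/Da taken non-negative by
    relabelling the x/y axes, and Euler angles (ZYZ, degrees) rotate the
    molecular frame onto the principal frame.
    """

    saupe: np.ndarray

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (3, 3):
            raise ValueError("saupe must be 3x3")
        if not np.allclose(self.saupe, self.saupe.T, atol=1e-9):
            raise ValueError("saupe must be symmetric")
        if abs(np.trace(self.saupe)) > 1e-9 * max(1.0, np.abs(self.saupe).max()):
            raise ValueError("saupe must be traceless")

    def _principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues ordered (Sxx, Syy, Szz) by |Szz| >= |Syy| >= |Sxx|,
        with Sxx - Syy >= 0 (non-negative rhombicity) by x/y relabelling."""
        w, v = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(w))          # |Sxx| <= |Syy| <= |Szz|
        w, v = w[order], v[:, order]
        if (w[0] - w[1]) * w[2] < 0:           # x/y relabel so R >= 0
            w = w[[1, 0, 2]]
            v = v[:, [1, 0, 2]]
        if np.linalg.det(v) < 0:               # right-handed principal frame
            v[:, 0] = -v[:, 0]
        return w, v

    @property
    def da(self) -> float:
        """Axial magnitude Da = Szz/2, Hz (signed)."""
        w, _ = self._principal()
        return 0.5 * w[2]

    @property
    def rhombicity(self) -> float:
        """R = Dr/Da with Dr = (Sxx - Syy)/3; in [0, 2/3]."""
        w, _ = self._principal()
        if w[2] == 0:
            return 0.0
        return float((w[0] - w[1]) / (1.5 * w[2]))

    @property
    def euler_angles(self) -> tuple[float, float, float]:
        """ZYZ Euler angles (alpha, beta, gamma) in degrees of the rotation
        taking molecular-frame coordinates into the principal frame."""
        _, v = self._principal()
        rot = v.T  # rows are principal axes expressed in the molecular frame
        beta = math.degrees(math.acos(np.clip(rot[2, 2], -1.0, 1.0)))
        if abs(rot[2, 2]) < 1.0 - 1e-12:
            alpha = math.degrees(math.atan2(rot[2, 1], rot[2, 0]))
            gamma = math.degrees(math.atan2(rot[1, 2], -rot[0, 2]))
        else:  # beta ~ 0/180: only alpha+gamma defined; put it all in alpha
            alpha = math.degrees(math.atan2(rot[1, 0], rot[0, 0]))
            gamma = 0.0
        return alpha, beta, gamma


def tensor_from_da_rhombicity(da: float, rhombicity: float,
                              euler_deg: tuple[float, float, float] = (0, 0, 0),
                              ) -> AlignmentTensor:
    """Construct an alignment tensor from its axial magnitude (Hz),
    rhombicity and principal-frame orientation (ZYZ Euler angles, deg).

    Principal values: Szz = 2 Da, Sxx = -Da (1 - 1.5 R), Syy = -Da (1 + 1.5 R).
    """
    if not 0.0 <= rhombicity <= 2.0 / 3.0 + 1e-12:
        raise ValueError("rhombicity must be in [0, 2/3]")
    szz = 2.0 * da
    sxx = -da * (1.0 - 1.5 * rhombicity)
    syy = -da * (1.0 + 1.5 * rhombicity)
    diag = np.diag([sxx, syy, szz])
    a, b, g = (math.radians(x) for x in euler_deg)

    def rz(t: float) -> np.ndarray:
        return np.array([[math.cos(t), -math.sin(t), 0],
                         [math.sin(t), math.cos(t), 0], [0, 0, 1]])

    def ry(t: float) -> np.ndarray:
        return np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0],
                         [-math.sin(t), 0, math.cos(t)]])

    rot = rz(a) @ ry(b) @ rz(g)  # principal -> molecular
    return AlignmentTensor(rot @ diag @ rot.T)


def extract_vectors(models, pairs: tuple[str, str] = ("N", "H"),
                    model_index: int = 0) -> BondVectorSet:
    """Normalised inter-atom bond vectors from a structure.

    Accepts a StructureEnsemble (first model used by default) or a single
    model, where a model is a mapping residue_id -> {atom_name: xyz}.
    Residues missing either atom are skipped (commonly the amide proton
    in X-ray-derived or proline-containing models).
    """
    from .ensemble import StructureEnsemble  # local import avoids a cycle
    if isinstance(models, StructureEnsemble):
        model = models.models[model_index]
    else:
        model = models
    a1, a2 = pairs
    ids, vecs = [], []
    for rid in sorted(model):
        atoms = model[rid]
        if a1 not in atoms or a2 not in atoms:
            continue
        v = np.asarray(atoms[a2], dtype=float) - np.asarray(atoms[a1], dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"residue {rid}: coincident {a1}/{a2} atoms")
        ids.append(rid)
        vecs.append(v / norm)
    return BondVectorSet(np.array(ids, dtype=int), np.array(vecs))


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    """Rows map the 5 independent Saupe components
    (Syy, Szz, Sxy, Sxz, Syz), with Sxx = -Syy - Szz, onto couplings."""
    x, y, z = vectors[:, 0], vectors[:, 1], vectors[:, 2]
    return np.column_stack([y * y - x * x, z * z - x * x,
                            2 * x * y, 2 * x * z, 2 * y * z])


def svd_fit(vectors: BondVectorSet, records: list[RdcRecord],
            bootstrap: int = 0, seed: int = 0,
            ) -> AlignmentTensor | tuple[AlignmentTensor, dict]:
    """Least-squares alignment tensor from observed couplings.

    Solves the linear system A s = d for the five independent tensor
    components by SVD (numpy lstsq); fills each record's d_calc.  With
    bootstrap > 0, a nonparametric bootstrap over records gives standard
    errors on Da and rhombicity, returned as a second dict.

    Requires >= 5 records with non-degenerate bond geometry; a
    rank-deficient design matrix (e.g. all vectors coplanar in a way that
    hides a tensor component) raises with the rank found.
    """
    rec_ids = {r.residue_id: r for r in records}
    mask = np.array([rid in rec_ids for rid in vectors.residue_ids])
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 residues with both a bond vector and an observed "
            f"coupling; got {int(mask.sum())}")
    v = vectors.vectors[mask]
    ids = vectors.residue_ids[mask]
    d = np.array([rec_ids[rid].d_obs for rid in ids])

    a = _design_matrix(v)
    rank = np.linalg.matrix_rank(a, tol=1e-8)
    if rank < 5:
        raise ValueError(
            f"degenerate bond-vector geometry: design matrix rank {rank} < 5")
    s, *_ = np.linalg.lstsq(a, d, rcond=None)
    tensor = _tensor_from_components(s)

    d_calc = a @ s
    for rid, dc in zip(ids, d_calc):
        rec_ids[rid].d_calc = float(dc)

    if bootstrap <= 0:
        return tensor
    rng = np.random.default_rng(seed)
    das, rhs = np.empty(bootstrap), np.empty(bootstrap)
    n = len(ids)
    for k in range(bootstrap):
        idx = rng.integers(0, n, n)
        while np.linalg.matrix_rank(_design_matrix(v[idx]), tol=1e-8) < 5:
            idx = rng.integers(0, n, n)
        sb, *_ = np.linalg.lstsq(_design_matrix(v[idx]), d[idx], rcond=None)
        tb = _tensor_from_components(sb)
        das[k], rhs[k] = tb.da, tb.rhombicity
    errors = {"da_sd": float(np.std(das, ddof=1)),
              "rhombicity_sd": float(np.std(rhs, ddof=1))}
    return tensor, errors


def _tensor_from_components(s: np.ndarray) -> AlignmentTensor:
    syy, szz, sxy, sxz, syz = s
    sxx = -syy - szz
    return AlignmentTensor(np.array([[sxx, sxy, sxz],
                                     [sxy, syy, syz],
                                     [sxz, syz, szz]]))


def back_calculate(tensor: AlignmentTensor, vectors: BondVectorSet) -> np.ndarray:
    """Couplings predicted by a tensor for a set of bond vectors:
    D_i = v_i^T S v_i (quadratic form in the molecular frame)."""
    v = vectors.vectors
    return np.einsum("ij,jk,ik->i", v, tensor.saupe, v)


def rdc_rfactor(records: list[RdcRecord]) -> float:
    """RDC quality factor in percent:

        R = 100 * sqrt( <(d_obs - d_calc)^2> / (2 <d_obs^2>) )

    normalised by twice the mean-square observed coupling, so that an
    uninformative fit (d_calc = 0) scores sqrt(1/2) ~ 70.7%.
    """
    obs = np.array([r.d_obs for r in records])
    calc = np.array([r.d_calc for r in records])
    if np.any(np.isnan(calc)):
        raise ValueError("records carry no d_calc; run svd_fit first")
    denom = 2.0 * np.mean(obs**2)
    if denom == 0:
        raise ValueError("all observed couplings are zero; R-factor undefined")
    return float(100.0 * math.sqrt(np.mean((obs - calc) ** 2) / denom))
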