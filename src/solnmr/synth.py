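"""Synthetic-data generators for every pipeline input.

Each generator produces data with the statistical structure the analysis
assumes — monoexponential intensity decays from model-free rates, RDCs
from a known alignment tensor over bond vectors, one-site thermograms at
a stated injection schedule, and multi-model coordinate ensembles with a
controlled per-residue scatter profile — so the full pipeline is
exercisable and testable without any external download.  Noise is i.i.d.
Gaussian everywhere, and every generator takes an explicit seed; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import StructureEnsemble
from .itc import InjectionSchedule, ItcExperiment, wiseman_isotherm
from .modelfree import SpinParams, modelfree_rates
from .rdc import AlignmentTensor, BondVectorSet, RdcRecord, back_calculate
from .relax import RelaxationSeries

__all__ = [
    "EnsembleSpec", "R1_DELAYS", "R1RHO_DELAYS", "simulate_decay",
    "simulate_rdc", "simulate_itc", "simulate_ensemble", "random_unit_vectors",
]

#: Longitudinal relaxation delay list, s (10-1500 ms).
R1_DELAYS = np.array([0.010, 0.050, 0.100, 0.400, 0.800, 1.200, 1.500])

#: Rotating-frame relaxation delay list, s (0-96 ms).
R1RHO_DELAYS = np.array([0.0, 0.004, 0.012, 0.024, 0.040, 0.060, 0.080, 0.096])


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic coordinate ensemble.

    scatter_profile gives the per-residue positional standard deviation
    (Angstrom) applied isotropically to every atom of that residue.
    """

    n_models: int
    n_residues: int
    scatter_profile: tuple[float, ...]
    seed: int = 0
    sidechain_scale: float = 1.0  # extra scatter multiplier for non-backbone atoms

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need >= 2 models")
        if len(self.scatter_profile) != self.n_residues:
            raise ValueError("scatter_profile length must equal n_residues")
        if any(s < 0 for s in self.scatter_profile):
            raise ValueError("scatter values must be >= 0")
        if self.sidechain_scale < 0:
            raise ValueError("sidechain_scale must be >= 0")


def simulate_decay(rate: float, i0: float, delays: np.ndarray,
                   noise_sd: float = 0.0, seed: int = 0,
                   residue_id: int = 1) -> RelaxationSeries:
    """Monoexponential intensity decay I0 exp(-rate t) with Gaussian noise."""
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delay list is empty")
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = i0 * np.exp(-rate * delays)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, delays.size)
    return RelaxationSeries(residue_id=residue_id, delays=delays,
                            intensities=clean, noise_sd=noise_sd)


def random_unit_vectors(n: int, seed: int = 0) -> np.ndarray:
    """n unit vectors drawn uniformly on the sphere."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_rdc(tensor: AlignmentTensor, vectors: BondVectorSet,
                 noise_sd: float = 0.0, seed: int = 0) -> list[RdcRecord]:
    """Couplings back-calculated from a known tensor plus Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    d = back_calculate(tensor, vectors)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, d.size)
    return [RdcRecord(int(rid), float(di), d_err=noise_sd)
            for rid, di in zip(vectors.residue_ids, d)]


def simulate_itc(n: float, kd: float, dh: float, sched: InjectionSchedule,
                 noise_sd: float = 0.0, seed: int = 0) -> ItcExperiment:
    """One-site thermogram (ucal per injection) plus Gaussian noise."""
    if kd <= 0:
        raise ValueError("kd must be positive (M)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heats = wiseman_isotherm(n, kd, dh, sched)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, heats.size)
    return ItcExperiment(sched, heats)


#: Idealised residue template: backbone + one sidechain atom, Angstrom.
_TEMPLATE_ATOMS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([0.0, -0.94, -0.40]),
    "CA": np.array([1.46, 0.0, 0.0]),
    "C": np.array([2.10, 1.35, 0.0]),
    "CB": np.array([1.98, -0.77, 1.20]),
}


def simulate_ensemble(spec: EnsembleSpec) -> StructureEnsemble:
    """Multi-model ensemble around a common mean conformation.

    The mean conformation is an extended chain of idealised residues
    (N, H, CA, C plus a CB sidechain atom) laid along a gentle helix so
    the geometry is non-degenerate.  Each model displaces every atom
    isotropically by the residue's scatter_profile sd (sidechain atoms
    scaled by sidechain_scale), then applies a random rigid motion so
    the analysis must actually superpose the models.
    """
    rng = np.random.default_rng(spec.seed)
    mean_model: dict[int, dict[str, np.ndarray]] = {}
    for i in range(spec.n_residues):
        rid = i + 1
        # place successive residues along a loose helix
        angle = 0.6 * i
        origin = np.array([10.0 * np.cos(angle), 10.0 * np.sin(angle), 1.5 * i])
        rot = _rotation_z(angle)
        mean_model[rid] = {a: origin + rot @ xyz
                           for a, xyz in _TEMPLATE_ATOMS.items()}

    models = []
    for _ in range(spec.n_models):
        model: dict[int, dict[str, np.ndarray]] = {}
        for i in range(spec.n_residues):
            rid = i + 1
            sd = spec.scatter_profile[i]
            model[rid] = {}
            for a, xyz in mean_model[rid].items():
                s = sd if a in ("N", "H", "CA", "C") else sd * spec.sidechain_scale
                model[rid][a] = xyz + (rng.normal(0.0, s, 3) if s > 0 else 0.0)
        # random rigid motion of the whole model
        rot = _random_rotation(rng)
        shift = rng.uniform(-20, 20, 3)
        for rid in model:
            for a in model[rid]:
                model[rid][a] = rot @ model[rid][a] + shift
        models.append(model)
    return StructureEnsemble(models)


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
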