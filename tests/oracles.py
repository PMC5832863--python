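"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the library
(grid search instead of gradient fitting, quaternions instead of SVD
rotation, numeric equilibrium root instead of the closed-form binding
quadratic, explicit mole bookkeeping instead of the Origin dilution
convention) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def grid_search_rate(delays: np.ndarray, intensities: np.ndarray,
                     lo: float = 0.01, hi: float = 20.0,
                     step: float = 1e-4) -> float:
    """Least-squares decay rate by brute-force grid search.

    For each candidate R the amplitude has the closed form
    I0 = sum(y e^{-Rt}) / sum(e^{-2Rt}); the grid minimiser of the SSE
    is returned.  O(n_grid * n_points) but exact to the grid resolution.
    """
    rates = np.arange(lo, hi + step, step)
    e = np.exp(-np.outer(rates, delays))           # (n_grid, n_points)
    i0 = (e @ intensities) / np.sum(e * e, axis=1)
    sse = np.sum((intensities[None, :] - i0[:, None] * e) ** 2, axis=1)
    return float(rates[np.argmin(sse)])


def quaternion_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimal RMSD superposing q onto p by Horn's quaternion method.

    Builds the 4x4 key matrix from the correlation of centred
    coordinates; the largest eigenvalue gives the residual directly.
    """
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    m = q0.T @ p0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = (np.sum(p0 ** 2) + np.sum(q0 ** 2) - 2.0 * lam) / len(p)
    return float(np.sqrt(max(sq, 0.0)))


def itc_equilibrium_heats(n: float, kd_m: float, dh: float, sched) -> np.ndarray:
    """Per-injection heats by numerically solving the binding equilibrium
    (root of the mass-action equation in free-ligand concentration) after
    each injection, on the same total-concentration convention as the
    library, with the same displacement-heat term.
    """
    mt, xt = sched.total_concentrations()
    kd_um = kd_m * 1e6
    v0 = sched.cell_volume
    v = sched.volumes()
    q = np.empty(len(mt))
    for i, (m_t, x_t) in enumerate(zip(mt, xt)):
        def excess(x_free: float) -> float:
            bound = n * m_t * x_free / (kd_um + x_free)
            return x_free + bound - x_t
        x_free = brentq(excess, 0.0, x_t + 1e-12, xtol=1e-15, rtol=1e-15)
        bound_um = x_t - x_free
        q[i] = dh * bound_um * 1e-12 * v0 * 1e9  # ucal
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (v / v0) * (q + q_prev) / 2.0


def itc_mass_balance(n: float, kd_m: float, dh: float, sched
                     ) -> tuple[np.ndarray, float]:
    """Exact sequential mole bookkeeping of a titration.

    Each injection first expels volume v of the pre-injection mixture
    from the constant active volume V0 (tracking complex that leaves),
    then adds v of titrant and re-equilibrates; the heat is dH times the
    complex newly formed.  Returns (per-injection heats in ucal, total
    moles of complex formed = in-cell + displaced).  Independent of the
    Origin dilution convention.
    """
    kd_um = kd_m * 1e6
    v0 = sched.cell_volume
    m_mol = sched.cell_conc * 1e-12 * v0          # mol (uM * uL * 1e-12)
    x_mol = 0.0
    complex_prev = 0.0
    displaced = 0.0
    heats = np.empty(sched.n_injections)
    for i, v in enumerate(sched.volumes()):
        keep = (v0 - v) / v0
        displaced += complex_prev * (1.0 - keep)
        m_mol *= keep
        x_mol *= keep
        complex_prev *= keep
        x_mol += sched.syringe_conc * 1e-12 * v
        m_t = m_mol / (v0 * 1e-6) * 1e6           # uM back at V0
        x_t = x_mol / (v0 * 1e-6) * 1e6

        def excess(x_free: float) -> float:
            bound = n * m_t * x_free / (kd_um + x_free)
            return x_free + bound - x_t

        x_free = brentq(excess, 0.0, x_t + 1e-12, xtol=1e-15, rtol=1e-15)
        complex_mol = (x_t - x_free) * 1e-12 * v0
        heats[i] = dh * (complex_mol - complex_prev) * 1e9
        complex_prev = complex_mol
    total_formed = complex_prev + displaced
    return heats, total_formed


def brute_force_precision(coords: np.ndarray) -> float:
    """Ensemble precision without iterative refinement: superpose every
    model onto the first, form the explicit mean structure, report the
    mean per-model RMSD to it (quaternion superposition throughout)."""
    aligned = coords.copy()
    ref = aligned[0]
    for i in range(1, len(aligned)):
        aligned[i] = _quat_fit(ref, aligned[i])
    mean = aligned.mean(axis=0)
    for i in range(len(aligned)):
        aligned[i] = _quat_fit(mean, aligned[i])
    mean = aligned.mean(axis=0)
    rmsds = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
    return float(np.mean(rmsds))


def _quat_fit(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Return q superposed onto p using the quaternion rotation."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    m = q0.T @ p0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    w, vec = np.linalg.eigh(k)
    qw, qx, qy, qz = vec[:, -1]
    rot = np.array([
        [qw*qw + qx*qx - qy*qy - qz*qz, 2*(qx*qy - qw*qz), 2*(qx*qz + qw*qy)],
        [2*(qx*qy + qw*qz), qw*qw - qx*qx + qy*qy - qz*qz, 2*(qy*qz - qw*qx)],
        [2*(qx*qz - qw*qy), 2*(qy*qz + qw*qx), qw*qw - qx*qx - qy*qy + qz*qz]])
    return q0 @ rot.T + pc
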