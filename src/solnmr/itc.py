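"""One-site ITC binding analysis: forward isotherm, fitting, thermodynamics.

An isothermal titration calorimetry experiment titrates a syringe ligand X
into a cell macromolecule M and integrates the heat of each injection.
For a single class of n identical sites with dissociation constant KD and
molar enthalpy dH, the cumulative heat content of the cell after the i-th
injection is

    Q_i = n [M]_i dH V0 / 2 * ( 1 + r + 1/(n c_i)
            - sqrt( (1 + r + 1/(n c_i))^2 - 4 r / n ) ),
    r = [X]_i / (n [M]_i),  c_i = [M]_i / KD

(the root of the binding quadratic), and the measured differential heat is
dQ_i = Q_i - Q_{i-1} plus a displacement-volume correction for the complex
pushed out of the active volume during the injection.  Total cell and
titrant concentrations follow the Origin-compatible dilution convention,
so fitted parameters are comparable to instrument-software results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, T_STANDARD

__all__ = [
    "InjectionSchedule", "ItcExperiment", "BindingFit", "wiseman_isotherm",
    "subtract_dilution", "fit_one_site", "thermodynamics", "enhancement_factor",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """Titration layout: injections, volumes and concentrations.

    cell_conc / syringe_conc in uM, volumes in uL, temperature in K.
    cell_volume is the calorimeter's active cell volume V0 (iTC200
    nominal 200 uL).
    """

    n_injections: int = 20
    injection_volume: float = 2.0
    cell_volume: float = 200.0
    cell_conc: float = 50.0
    syringe_conc: float = 500.0
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.n_injections < 2:
            raise ValueError("need at least 2 injections")
        for name in ("injection_volume", "cell_volume", "cell_conc",
                     "syringe_conc", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def volumes(self) -> np.ndarray:
        return np.full(self.n_injections, self.injection_volume)

    def total_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Origin-convention total concentrations (uM) in the active
        volume after each injection.

        With cumulative injected volume dV_i, the cell species is diluted
        by (1 - dV/2V0)/(1 + dV/2V0) and the titrant accumulates to
        X0 * (dV/V0) * (1 - dV/2V0); both are second-order-accurate
        treatments of displacement from a constant active volume.
        """
        dv = np.cumsum(self.volumes())
        half = dv / (2.0 * self.cell_volume)
        mt = self.cell_conc * (1.0 - half) / (1.0 + half)
        xt = self.syringe_conc * (dv / self.cell_volume) * (1.0 - half)
        return mt, xt


@dataclass
class ItcExperiment:
    """Integrated injection heats (ucal) with their schedule."""

    schedule: InjectionSchedule
    heats: np.ndarray
    blank_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ValueError(
                f"{len(self.heats)} heats for {self.schedule.n_injections} injections")
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if len(self.blank_heats) != len(self.heats):
                raise ValueError("blank heat list length mismatch")


@dataclass
class BindingFit:
    """One-site fit result with the thermodynamic decomposition.

    kd in M; dh, dg, tds_neg in kcal/mol; the identities
    dg = R T ln(kd) and tds_neg = dg - dh hold exactly (asserted at
    construction); round only at report time.
    """

    n: float
    kd: float
    dh: float
    dg: float
    tds_neg: float
    temperature: float = T_STANDARD
    n_sd: float = math.nan
    kd_sd: float = math.nan
    dh_sd: float = math.nan
    c_value: float = math.nan
    ill_conditioned: bool = False

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if abs(self.dg - R_KCAL * self.temperature * math.log(self.kd)) > 1e-6:
            raise ValueError("dg inconsistent with R T ln(kd)")
        if abs(self.tds_neg - (self.dg - self.dh)) > 1e-6:
            raise ValueError("tds_neg inconsistent with dg - dh")


def _q_total(n: float, kd_m: float, dh: float, mt_um: np.ndarray,
             xt_um: np.ndarray, v0_ul: float) -> np.ndarray:
    """Cumulative heat content (ucal) after each injection from the
    closed-form root of the one-site binding quadratic.

    dh in kcal/mol; concentrations uM; volume uL.
    """
    kd_um = kd_m * 1e6
    nm = n * mt_um
    term = 1.0 + xt_um / nm + kd_um / nm
    bound_um = 0.5 * nm * (term - np.sqrt(term * term - 4.0 * xt_um / nm))
    # complex in the active volume: uM * 1e-6 mol/L * (V0 uL * 1e-6 L) = mol
    moles = bound_um * 1e-12 * v0_ul
    return dh * moles * 1e9  # kcal -> ucal


def wiseman_isotherm(n: float, kd: float, dh: float,
                     sched: InjectionSchedule) -> np.ndarray:
    """Per-injection heats (ucal) of a one-site titration.

    Parameters: stoichiometry n, dissociation constant kd (M), molar
    enthalpy dh (kcal/mol).  The differential heat of injection i is
    Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1})/2, the last term replacing
    the heat content displaced from the active volume by the injection.
    """
    if kd <= 0:
        raise ValueError("kd must be positive (M)")
    mt, xt = sched.total_concentrations()
    q = _q_total(n, kd, dh, mt, xt, sched.cell_volume)
    v = sched.volumes()
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (v / sched.cell_volume) * (q + q_prev) / 2.0


def subtract_dilution(exp: ItcExperiment) -> ItcExperiment:
    """Subtract blank (titrant-into-buffer) heats from the measured heats.

    Without a blank the experiment is returned unchanged with a warning —
    dilution heats then remain in the data.
    """
    if exp.blank_heats is None:
        warnings.warn("no blank heats supplied; dilution not subtracted",
                      stacklevel=2)
        return exp
    return ItcExperiment(exp.schedule, exp.heats - exp.blank_heats, None)


def thermodynamics(kd: float, dh: float,
                   temperature: float = T_STANDARD) -> tuple[float, float]:
    """Free energy and entropic term from KD and enthalpy:
    dG = R T ln(KD), -T dS = dG - dH (kcal/mol; KD in M)."""
    if kd <= 0:
        raise ValueError("kd must be positive (M)")
    dg = R_KCAL * temperature * math.log(kd)
    return dg, dg - dh


def enhancement_factor(kd_weak: float, kd_tight: float) -> float:
    """Affinity-enhancement fold between two binding modes, KD_weak/KD_tight."""
    if kd_weak <= 0 or kd_tight <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_weak / kd_tight


def _initial_guesses(exp: ItcExperiment) -> tuple[float, float, float]:
    """Heuristic (n, kd, dh) start: dh from the early plateau, n from the
    inflection molar ratio, kd from the slope there."""
    sched = exp.schedule
    mt, xt = sched.total_concentrations()
    molar_ratio = xt / mt
    v = sched.volumes()
    inj_moles = sched.syringe_conc * 1e-12 * v  # mol per injection
    ndh = exp.heats / (inj_moles * 1e9)  # per-mole normalised heats, kcal/mol
    dh0 = float(np.mean(ndh[:2]))
    # inflection: steepest descent of the normalised heat curve
    d1 = np.gradient(ndh, molar_ratio)
    i_inf = int(np.argmax(np.abs(d1)))
    n0 = float(np.clip(molar_ratio[i_inf], 0.2, 5.0))
    # slope at inflection ~ -n dh c / 4 for moderately sharp isotherms
    slope = d1[i_inf]
    c0 = abs(4.0 * slope / dh0) if dh0 != 0 else 10.0
    c0 = float(np.clip(c0, 0.5, 1e4))
    kd0 = sched.cell_conc * 1e-6 / c0
    if dh0 == 0:
        dh0 = -1.0
    return n0, kd0, dh0


def fit_one_site(exp: ItcExperiment, n_restarts: int = 5, seed: int = 0,
                 temperature: float | None = None) -> BindingFit:
    """Nonlinear least-squares fit of (n, KD, dH) to injection heats.

    Multi-start: heuristic initial guesses plus jittered restarts; the
    solution with the lowest residual sum of squares is kept.  Parameter
    uncertainties come from the Jacobian at the optimum.  Fits outside
    the reliably fittable c-value window (c = cell_conc/KD in [1, 1e5])
    are returned flagged ill_conditioned rather than suppressed.
    """
    if exp.blank_heats is not None:
        exp = subtract_dilution(exp)
    heats = exp.heats
    sched = exp.schedule
    if temperature is None:
        temperature = sched.temperature
    if np.allclose(heats, 0.0):
        raise ValueError("all injection heats are zero: no binding signal to fit")
    informative = np.sum(np.abs(heats) > 0.02 * np.max(np.abs(heats)))
    if informative < 5:
        raise ValueError(f"only {informative} informative injections; >= 5 required")

    def residuals(p: np.ndarray) -> np.ndarray:
        n, log_kd, dh = p
        return wiseman_isotherm(n, math.exp(log_kd), dh, sched) - heats

    n0, kd0, dh0 = _initial_guesses(exp)
    rng = np.random.default_rng(seed)
    starts = [(n0, math.log(kd0), dh0)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append((n0 * rng.uniform(0.5, 2.0),
                       math.log(kd0) + rng.uniform(-2.3, 2.3),
                       dh0 * rng.uniform(0.5, 2.0)))

    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0,
                                bounds=([1e-3, math.log(1e-15), -1e4],
                                        [1e2, math.log(1.0), 1e4]))
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("one-site fit failed to converge from any start")

    n_fit, log_kd, dh_fit = best.x
    kd_fit = math.exp(log_kd)
    dg, tds = thermodynamics(kd_fit, dh_fit, temperature)

    # asymptotic standard errors from J^T J at the optimum
    dof = max(1, len(heats) - 3)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        n_sd = math.sqrt(max(cov[0, 0], 0.0))
        kd_sd = math.sqrt(max(cov[1, 1], 0.0)) * kd_fit  # delta method off log
        dh_sd = math.sqrt(max(cov[2, 2], 0.0))
    except np.linalg.LinAlgError:
        n_sd = kd_sd = dh_sd = math.nan

    c_value = sched.cell_conc * 1e-6 / kd_fit
    ill = not (1.0 <= c_value <= 1e5)
    if ill:
        warnings.warn(
            f"c-value {c_value:.3g} outside the reliably fittable range "
            "[1, 1e5]; parameters may be poorly determined", stacklevel=2)
    return BindingFit(n=float(n_fit), kd=kd_fit, dh=float(dh_fit), dg=dg,
                      tds_neg=tds, temperature=temperature, n_sd=n_sd,
                      kd_sd=kd_sd, dh_sd=dh_sd, c_value=c_value,
                      ill_conditioned=ill)
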