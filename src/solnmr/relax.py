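"""Backbone 15N relaxation analysis.

Converts per-residue peak-intensity decays into R1 and R1rho rates,
applies the rotating-frame offset correction to obtain R2, forms the
heteronuclear NOE from saturated/reference intensity pairs, estimates the
global rotational correlation time from the trimmed R2/R1 ratio of rigid
residues, and classifies per-residue dynamics into fast (ps-ns),
exchange (us-ms), both, rigid, or broadened/missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .constants import larmor_omega
from .modelfree import rigid_r2_over_r1

__all__ = [
    "RelaxationSeries", "SpectrometerConfig", "RelaxationRates",
    "TumblingEstimate", "DynamicsLabel", "fit_exponential", "r2_from_r1rho",
    "het_noe", "estimate_tauc", "classify_dynamics", "intensity_ratio",
]


@dataclass
class RelaxationSeries:
    """Peak intensities of one residue over a set of relaxation delays."""

    residue_id: int
    delays: np.ndarray  # s
    intensities: np.ndarray
    noise_sd: float = 0.0
    residue_name: str = "UNK"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have equal length")
        if np.any(self.delays < 0):
            raise ValueError("relaxation delays must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        order = np.argsort(self.delays)
        self.delays = self.delays[order]
        self.intensities = self.intensities[order]
        if np.any(np.diff(self.delays) == 0):
            raise ValueError(
                f"residue {self.residue_id}: duplicate relaxation delays")


@dataclass(frozen=True)
class SpectrometerConfig:
    """Spectrometer settings needed by the offset correction and the
    tumbling-time estimator.

    offset is the 15N resonance offset Omega_N from the spin-lock carrier
    (Hz); spinlock the field strength gamma_N*B1 (Hz).  The tilt angle is
    theta = arctan(offset/spinlock).
    """

    field_h1: float = 800.0   # MHz
    spinlock: float = 1500.0  # Hz
    offset: float = 0.0       # Hz; per-residue values are passed explicitly

    def __post_init__(self) -> None:
        if self.spinlock <= 0:
            raise ValueError("spin-lock field strength must be positive")
        if self.field_h1 <= 0:
            raise ValueError("field_h1 must be positive (MHz)")


@dataclass
class RelaxationRates:
    """Per-residue relaxation observables with 1-sigma uncertainties.

    Fields left as NaN mean the observable is unavailable for that residue
    (e.g. exchange-broadened amide).
    """

    residue_id: int
    r1: float = math.nan
    r1_sd: float = math.nan
    r1rho: float = math.nan
    r1rho_sd: float = math.nan
    r2: float = math.nan
    r2_sd: float = math.nan
    noe: float = math.nan
    noe_sd: float = math.nan

    @property
    def missing(self) -> bool:
        return math.isnan(self.r1) and math.isnan(self.r2) and math.isnan(self.noe)


@dataclass(frozen=True)
class TumblingEstimate:
    tau_c: float                 # ns
    n_residues_used: int
    trimmed_ids: tuple[int, ...]
    ratio: float                 # trimmed-mean R2/R1 that was inverted

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")


@dataclass(frozen=True)
class DynamicsLabel:
    residue_id: int
    label: str  # rigid | fast | exchange | both | broadened/missing


def _exp_model(t: np.ndarray, i0: float, rate: float) -> np.ndarray:
    return i0 * np.exp(-rate * t)


def fit_exponential(series: RelaxationSeries, n_mc: int = 200,
                    seed: int | None = 0) -> tuple[float, float, float]:
    """Fit I(t) = I0 exp(-R t) to one intensity series.

    Returns (rate, i0, rate_sd).  The rate uncertainty comes from Monte
    Carlo resampling: n_mc synthetic series with Gaussian noise of the
    stated noise_sd are refit and the sd of the refit rates reported.
    With noise_sd == 0 the sd is 0 and no resampling is done.

    Raises ValueError for fewer than 3 points or an all-zero series;
    RuntimeError if the fit does not converge.
    """
    t, y = series.delays, series.intensities
    if len(t) < 3:
        raise ValueError(
            f"residue {series.residue_id}: need >= 3 delay points, got {len(t)}")
    if np.all(y == 0):
        raise ValueError(f"residue {series.residue_id}: all intensities zero")

    def _single_fit(yy: np.ndarray) -> tuple[float, float]:
        i0_guess = yy[np.argmin(t)]
        # log-linear slope as a rate guess, guarded against non-positive y
        pos = yy > 0
        if pos.sum() >= 2 and i0_guess > 0:
            slope = np.polyfit(t[pos], np.log(yy[pos]), 1)[0]
            r_guess = max(-slope, 1e-3)
        else:
            r_guess = 1.0
        popt, _ = curve_fit(_exp_model, t, yy, p0=[i0_guess, r_guess],
                            maxfev=10000)
        return popt[1], popt[0]

    try:
        rate, i0 = _single_fit(y)
    except RuntimeError as exc:  # pragma: no cover - curve_fit rarely fails here
        raise RuntimeError(
            f"residue {series.residue_id}: exponential fit did not converge") from exc

    if series.noise_sd == 0 or n_mc <= 0:
        return rate, i0, 0.0

    rng = np.random.default_rng(seed)
    clean = _exp_model(t, i0, rate)
    rates = np.empty(n_mc)
    for k in range(n_mc):
        try:
            rates[k], _ = _single_fit(clean + rng.normal(0.0, series.noise_sd, t.size))
        except RuntimeError:
            rates[k] = np.nan
    return rate, i0, float(np.nanstd(rates, ddof=1))


def r2_from_r1rho(r1rho: float, r1: float, cfg: SpectrometerConfig,
                  offset: float | None = None,
                  r1rho_sd: float = 0.0, r1_sd: float = 0.0,
                  ) -> tuple[float, float]:
    """Offset-correct a rotating-frame rate:
    R2 = (R1rho - R1 sin^2 theta) / cos^2 theta, theta = arctan(Omega_N / gammaN B1).

    Returns (r2, r2_sd) with the uncertainty propagated in quadrature.
    At zero offset the correction is the identity.
    """
    if offset is None:
        offset = cfg.offset
    theta = math.atan2(offset, cfg.spinlock)
    cos2 = math.cos(theta) ** 2
    if cos2 < 1e-6:
        raise ValueError(
            f"offset {offset} Hz too large for spin-lock {cfg.spinlock} Hz "
            "(tilt angle ~90 deg; offset correction ill-conditioned)")
    sin2 = math.sin(theta) ** 2
    r2 = (r1rho - r1 * sin2) / cos2
    r2_sd = math.hypot(r1rho_sd, r1_sd * sin2) / cos2
    return r2, r2_sd


def het_noe(i_sat: float, i_ref: float, noise_sd: float = 0.0,
            ) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat / I_ref with quadrature error propagation.

    The reference intensity must stand clear of the noise floor; a ratio
    against near-zero reference is meaningless and rejected.
    """
    if i_ref == 0 or abs(i_ref) <= 3.0 * noise_sd:
        raise ValueError("reference intensity within noise of zero; NOE undefined")
    noe = i_sat / i_ref
    sd = abs(noe) * math.hypot(noise_sd / i_sat if i_sat != 0 else 0.0,
                               noise_sd / i_ref)
    return noe, sd


def _ordered_region_trim(rates: list[RelaxationRates], noe_cut: float,
                         iqr_k: float) -> tuple[list[RelaxationRates], list[int]]:
    """Keep residues that look rigid: NOE >= noe_cut and R2 within
    median +/- iqr_k * IQR.  Residues with missing R1/R2 are dropped."""
    usable = [r for r in rates
              if not (math.isnan(r.r1) or math.isnan(r.r2)) and r.r1 > 0]
    with_noe = [r for r in usable if not math.isnan(r.noe)]
    kept = [r for r in with_noe if r.noe >= noe_cut] if with_noe else usable
    if kept:
        r2s = np.array([r.r2 for r in kept])
        med = np.median(r2s)
        q1, q3 = np.percentile(r2s, [25, 75])
        iqr = q3 - q1
        lo, hi = med - iqr_k * iqr, med + iqr_k * iqr
        kept = [r for r in kept if lo <= r.r2 <= hi]
    kept_ids = {r.residue_id for r in kept}
    trimmed = [r.residue_id for r in rates if r.residue_id not in kept_ids]
    return kept, trimmed


def estimate_tauc(rates: list[RelaxationRates], cfg: SpectrometerConfig,
                  noe_cut: float = 0.8, iqr_k: float = 1.5,
                  method: str = "invert",
                  tau_bracket: tuple[float, float] = (0.2, 100.0),
                  ) -> TumblingEstimate:
    """Estimate the global rotational correlation time from the trimmed
    mean R2/R1 ratio of ordered-region residues.

    method="invert" (default) numerically inverts the rigid isotropic
    model-free ratio R2/R1 as a function of tau_c at the configured field
    (monotone root-finding), so a forward-simulated rigid residue
    round-trips exactly.  method="approx" uses the closed-form
    tau_c ~ sqrt(6 R2/R1 - 7) / (2 omega_N) cross-check.

    Trimming (the "ordered region"): residues with NOE < noe_cut or with
    R2 outside median +/- iqr_k * IQR are excluded, which removes
    flexible and exchange-affected amides before averaging.
    """
    kept, trimmed = _ordered_region_trim(rates, noe_cut, iqr_k)
    if len(kept) < 5:
        raise ValueError(
            f"only {len(kept)} residues survive ordered-region trimming; >= 5 required")
    ratio = float(np.mean([r.r2 / r.r1 for r in kept]))

    if method == "approx":
        _, omega_n = larmor_omega(cfg.field_h1)
        arg = 6.0 * ratio - 7.0
        if arg <= 0:
            raise ValueError(f"R2/R1 = {ratio:.3f} below the approximate formula's range")
        tau_c = math.sqrt(arg) / (2.0 * abs(omega_n)) * 1e9
        return TumblingEstimate(tau_c, len(kept), tuple(trimmed), ratio)
    if method != "invert":
        raise ValueError(f"unknown method {method!r}")

    lo, hi = tau_bracket
    f = lambda t: rigid_r2_over_r1(t, cfg.field_h1) - ratio
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"trimmed R2/R1 = {ratio:.3f} outside the invertible range for "
            f"tau_c in [{lo}, {hi}] ns at {cfg.field_h1} MHz")
    tau_c = brentq(f, lo, hi, xtol=1e-10)
    return TumblingEstimate(float(tau_c), len(kept), tuple(trimmed), ratio)


def classify_dynamics(rates: list[RelaxationRates], noe_cut: float = 0.8,
                      exchange_k: float = 1.5, iqr_k: float = 1.5,
                      ) -> list[DynamicsLabel]:
    """Label each residue's dynamics regime.

    fast      NOE < noe_cut (ps-ns internal motion)
    exchange  R2 > trimmed mean + exchange_k * sd (us-ms exchange)
    both      both criteria met
    broadened/missing   no observables (amide not detected)
    rigid     otherwise

    The R2 reference distribution is the ordered-region trimmed set, so a
    handful of exchange-broadened residues cannot drag the threshold up.
    Every residue receives exactly one label.
    """
    kept, _ = _ordered_region_trim(rates, noe_cut, iqr_k)
    if kept:
        r2_ref = np.array([r.r2 for r in kept])
        r2_mean = float(np.mean(r2_ref))
        r2_sd = float(np.std(r2_ref, ddof=1)) if len(r2_ref) > 1 else 0.0
    else:  # degenerate: no rigid reference; fall back to all finite R2
        finite = [r.r2 for r in rates if not math.isnan(r.r2)]
        r2_mean = float(np.mean(finite)) if finite else math.nan
        r2_sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0

    labels = []
    for r in rates:
        if r.missing:
            labels.append(DynamicsLabel(r.residue_id, "broadened/missing"))
            continue
        fast = (not math.isnan(r.noe)) and r.noe < noe_cut
        exch = (not math.isnan(r.r2)) and not math.isnan(r2_mean) \
            and r.r2 > r2_mean + exchange_k * r2_sd
        if fast and exch:
            label = "both"
        elif fast:
            label = "fast"
        elif exch:
            label = "exchange"
        else:
            label = "rigid"
        labels.append(DynamicsLabel(r.residue_id, label))
    return labels


def intensity_ratio(bound: dict[int, float], free: dict[int, float],
                    ) -> dict[int, float]:
    """Per-residue I_bound/I_free titration attenuation profile.

    Residues present in the free spectrum but absent from the bound one
    are reported as ratio 0 (fully broadened on binding).  A zero free
    intensity makes the ratio undefined and is rejected.
    """
    out: dict[int, float] = {}
    for rid, i_free in free.items():
        if i_free == 0:
            raise ValueError(f"residue {rid}: free-state intensity is zero")
        out[rid] = bound.get(rid, 0.0) / i_free
    return out
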