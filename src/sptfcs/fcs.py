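"""Fluorescence-correlation-spectroscopy analysis.

The fluctuation autocorrelation of a photon trace,

    G(τ) = ⟨δF(t) δF(t+τ)⟩ / ⟨F⟩²,

is computed with a multi-tau scheme (linear channels within each octave, bin
width doubling per octave, symmetric normalization) and fitted with the
Gaussian-beam diffusion models

    normal:     G(τ) = (1/N) · 1/(1+τ/τ_D) · 1/√(1 + (w0²/z0²)(τ/τ_D))
    anomalous:  G(τ) = (1/N) · 1/(1+(τ/τ_D)^α) · 1/√(1 + (w0²/z0²)(τ/τ_D)^α)

by trust-region-reflective least squares. The amplitude gives the molecule
number N = 1/G(0); a calibration dye of known diffusion coefficient and
concentration fixes the focal geometry (w0 = √(4 D τ_D), z0 from the
structure parameter) and the effective volume V_eff = 1/(G(0)·N_A·c).

No triplet/blinking term is included: the model set deliberately matches the
two diffusion-only equations above, and the first correlator channels (the
afterpulsing regime) are excluded from fits instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.constants import Avogadro

from .simulate import IntensityTrace

__all__ = [
    "ACFCurve",
    "FCSModelFit",
    "BleachCheck",
    "CalibrationResult",
    "multitau_acf",
    "exclude_photobleaching",
    "acf_model_normal",
    "acf_model_anomalous",
    "fit_acf_normal",
    "fit_acf_anomalous",
    "number_of_molecules",
    "effective_volume",
    "calibrate_focal_volume",
    "concentration_from_fit",
]

LITER_IN_UM3 = 1e15


@dataclass
class ACFCurve:
    """Normalized fluctuation autocorrelation on a quasi-logarithmic lag grid."""

    lags: np.ndarray
    g: np.ndarray
    uncertainties: np.ndarray | None = None
    duration: float | None = None


@dataclass
class FCSModelFit:
    model: str  # "normal" | "anomalous"
    n_molecules: float
    tau_d: float
    alpha: float
    structure: float  # (w0/z0)² as it appears in the model
    residual_ss: float
    converged: bool
    d_coefficient: float | None = None  # µm²/s^α, set when w0 is known

    @property
    def g0(self) -> float:
        return 1.0 / self.n_molecules


def _sym_corr(x: np.ndarray, lag: int) -> float:
    """Symmetrically normalized fluctuation correlation at an integer lag."""
    a = x[:-lag]
    b = x[lag:]
    ma, mb = a.mean(), b.mean()
    if ma == 0.0 or mb == 0.0:
        return 0.0
    return float(np.mean(a * b) / (ma * mb) - 1.0)


def multitau_acf(trace: IntensityTrace, channels_per_octave: int = 16) -> ACFCurve:
    """Multi-tau autocorrelation of a photon trace.

    The first octave holds ``channels_per_octave`` linearly spaced lags at the
    native bin width; each further octave doubles the bin width (pairwise
    averaging of the trace) and contributes the upper half of the channels.
    Symmetric normalization (separate means of the leading and trailing
    segments) keeps the estimate unbiased for drifting intensities. A
    constant trace yields G ≡ 0.
    """
    x = np.asarray(trace.counts, dtype=float)
    if x.size < 1000:
        raise ValueError("trace too short for a meaningful ACF (need >= 1000 bins)")
    m = int(channels_per_octave)
    if m < 4 or m % 2:
        raise ValueError("channels_per_octave must be an even number >= 4")
    lags: list[float] = []
    g: list[float] = []
    width = trace.bin_width
    level = 0
    while True:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        if x.size <= m + 1:
            break
        for k in ks:
            lags.append(k * width)
            g.append(_sym_corr(x, k))
        if x.size < 2 * (m + 1):
            break
        n_even = (x.size // 2) * 2
        x = 0.5 * (x[0:n_even:2] + x[1:n_even:2])
        width *= 2.0
        level += 1
    return ACFCurve(
        lags=np.asarray(lags), g=np.asarray(g), uncertainties=None, duration=trace.duration
    )


@dataclass
class BleachCheck:
    accepted: bool
    slope: float  # counts/s per second, from the 1 s-binned trend
    decay_fraction: float  # fitted fractional intensity loss over the trace
    p_value: float


def exclude_photobleaching(
    trace: IntensityTrace,
    max_decay_fraction: float = 0.20,
    p_threshold: float = 0.01,
) -> BleachCheck:
    """Reject traces whose intensity decays linearly — the photobleaching signature.

    The trace is binned to 1 s, a linear trend is fitted, and the trace is
    rejected when the fitted fractional decay exceeds ``max_decay_fraction``
    with a significantly negative slope (two-sided t-test p < ``p_threshold``).
    """
    if trace.duration < 5.0:
        raise ValueError("bleach assessment needs at least 5 s of trace")
    per_bin = max(1, int(round(1.0 / trace.bin_width)))
    n_sec = trace.counts.size // per_bin
    coarse = trace.counts[: n_sec * per_bin].reshape(n_sec, per_bin).sum(axis=1).astype(float)
    t = np.arange(n_sec) + 0.5
    res = stats.linregress(t, coarse)
    start = res.intercept
    end = res.intercept + res.slope * n_sec
    decay = (start - end) / start if start > 0 else 0.0
    reject = decay > max_decay_fraction and res.slope < 0 and res.pvalue < p_threshold
    return BleachCheck(
        accepted=not reject,
        slope=float(res.slope),
        decay_fraction=float(decay),
        p_value=float(res.pvalue),
    )


def acf_model_normal(tau, n: float, tau_d: float, structure: float):
    """Free 3D diffusion through a Gaussian volume; ``structure`` = (w0/z0)²."""
    r = np.asarray(tau, dtype=float) / tau_d
    return (1.0 / n) / (1.0 + r) / np.sqrt(1.0 + structure * r)


def acf_model_anomalous(tau, n: float, tau_d: float, alpha: float, structure: float):
    """Anomalous diffusion (MSD ∝ t^α): identical to the normal model at α = 1."""
    r = (np.asarray(tau, dtype=float) / tau_d) ** alpha
    return (1.0 / n) / (1.0 + r) / np.sqrt(1.0 + structure * r)


#: Default (w0/z0)² for a confocal spot with axial elongation z0/w0 = 5.
DEFAULT_STRUCTURE = 1.0 / 25.0


def _fit_window(acf: ACFCurve, lag_min: float, lag_max: float | None):
    if lag_max is None:
        lag_max = acf.duration / 100.0 if acf.duration else acf.lags[-1]
    keep = np.ones(acf.lags.size, dtype=bool)
    keep[:2] = False  # afterpulsing-dominated first two channels
    keep &= (acf.lags >= lag_min) & (acf.lags <= lag_max)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 usable lags in the fit window")
    w = None
    if acf.uncertainties is not None:
        w = np.where(acf.uncertainties[keep] > 0, 1.0 / acf.uncertainties[keep], 0.0)
    return acf.lags[keep], acf.g[keep], w


def _initial_guess(lags: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    g0 = max(np.median(g[:3]), 1e-6)
    half = g < 0.5 * g0
    tau0 = lags[np.argmax(half)] if half.any() else lags[lags.size // 2]
    return 1.0 / g0, float(tau0)


def _run_fit(model, x0, bounds, lags, g, weights):
    def residuals(p):
        r = model(lags, *p) - g
        return r * weights if weights is not None else r

    res = optimize.least_squares(residuals, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
    return res


def fit_acf_normal(
    acf: ACFCurve,
    structure: float = DEFAULT_STRUCTURE,
    fit_structure: bool = False,
    lag_min: float = 1e-5,
    lag_max: float | None = None,
    w0: float | None = None,
) -> FCSModelFit:
    """Fit the normal-diffusion model; N and τ_D free, structure fixed by default."""
    lags, g, wts = _fit_window(acf, lag_min, lag_max)
    n0, tau0 = _initial_guess(lags, g)
    if fit_structure:
        res = _run_fit(
            lambda t, n, td, s: acf_model_normal(t, n, td, s),
            [n0, tau0, structure],
            ([1e-6, 1e-9, 1e-6], [np.inf, np.inf, 1.0]),
            lags, g, wts,
        )
        n, tau_d, structure = res.x
    else:
        res = _run_fit(
            lambda t, n, td: acf_model_normal(t, n, td, structure),
            [n0, tau0],
            ([1e-6, 1e-9], [np.inf, np.inf]),
            lags, g, wts,
        )
        n, tau_d = res.x
    d = w0**2 / (4.0 * tau_d) if w0 is not None else None
    return FCSModelFit(
        model="normal",
        n_molecules=float(n),
        tau_d=float(tau_d),
        alpha=1.0,
        structure=float(structure),
        residual_ss=float(2.0 * res.cost),
        converged=bool(res.success),
        d_coefficient=d,
    )


def fit_acf_anomalous(
    acf: ACFCurve,
    structure: float = DEFAULT_STRUCTURE,
    alpha_fixed: float | None = None,
    lag_min: float = 1e-5,
    lag_max: float | None = None,
    w0: float | None = None,
) -> FCSModelFit:
    """Fit the anomalous model with N, τ_D and α free (α bounded to (0.1, 2]).

    With ``alpha_fixed`` = 1 the fit reduces exactly to the normal model.
    ``d_coefficient`` = w0²/(4 τ_D^α) is reported when w0 is given.
    """
    lags, g, wts = _fit_window(acf, lag_min, lag_max)
    n0, tau0 = _initial_guess(lags, g)
    if alpha_fixed is not None:
        res = _run_fit(
            lambda t, n, td: acf_model_anomalous(t, n, td, alpha_fixed, structure),
            [n0, tau0],
            ([1e-6, 1e-9], [np.inf, np.inf]),
            lags, g, wts,
        )
        n, tau_d = res.x
        alpha = alpha_fixed
    else:
        res = _run_fit(
            lambda t, n, td, a: acf_model_anomalous(t, n, td, a, structure),
            [n0, tau0, 1.0],
            ([1e-6, 1e-9, 0.1], [np.inf, np.inf, 2.0]),
            lags, g, wts,
        )
        n, tau_d, alpha = res.x
    d = w0**2 / (4.0 * tau_d**alpha) if w0 is not None else None
    return FCSModelFit(
        model="anomalous",
        n_molecules=float(n),
        tau_d=float(tau_d),
        alpha=float(alpha),
        structure=float(structure),
        residual_ss=float(2.0 * res.cost),
        converged=bool(res.success),
        d_coefficient=d,
    )


def number_of_molecules(fit: FCSModelFit) -> float:
    """N = 1/G(0) from the fitted amplitude."""
    if fit.g0 <= 0:
        raise ValueError("amplitude must be positive to define a molecule number")
    return 1.0 / fit.g0


def effective_volume(g0: float, concentration_mol_l: float) -> float:
    """V_eff = 1/(G(0)·N_A·c) in µm³ for a calibration dye at molar concentration c."""
    if g0 <= 0 or concentration_mol_l <= 0:
        raise ValueError("g0 and concentration must be positive")
    per_um3 = Avogadro * concentration_mol_l / LITER_IN_UM3
    return 1.0 / (g0 * per_um3)


@dataclass
class CalibrationResult:
    w0: float
    z0: float
    v_eff: float
    reference_d: float
    reference_concentration: float


#: Reference diffusion coefficient of the Atto 488 calibration dye in water
#: near 36 °C (µm²/s), and the calibration concentration (mol/L).
ATTO488_D = 536.0
ATTO488_CONCENTRATION = 10e-9


def calibrate_focal_volume(
    fit: FCSModelFit,
    reference_d: float = ATTO488_D,
    concentration_mol_l: float = ATTO488_CONCENTRATION,
) -> CalibrationResult:
    """Focal geometry from a reference-dye fit: w0 = √(4 D τ_D), z0 = w0/√structure.

    The dye diffuses freely, so an anomalous fit should return α ≈ 1; a
    calibration performed on a visibly anomalous fit is flagged with a warning.
    """
    if not fit.converged:
        raise ValueError("calibration requires a converged reference fit")
    if abs(fit.alpha - 1.0) > 0.10:
        warnings.warn(
            f"reference-dye fit has alpha={fit.alpha:.3f}; calibration assumes free diffusion",
            stacklevel=2,
        )
    w0 = float(np.sqrt(4.0 * reference_d * fit.tau_d))
    z0 = float(w0 / np.sqrt(fit.structure))
    v_eff = effective_volume(fit.g0, concentration_mol_l)
    return CalibrationResult(
        w0=w0,
        z0=z0,
        v_eff=v_eff,
        reference_d=reference_d,
        reference_concentration=concentration_mol_l,
    )


def concentration_from_fit(fit: FCSModelFit, v_eff: float) -> tuple[float, float]:
    """Molecule density (per µm³) and molar concentration from N and V_eff."""
    if v_eff <= 0:
        raise ValueError("v_eff must be positive")
    per_um3 = fit.n_molecules / v_eff
    mol_l = per_um3 * LITER_IN_UM3 / Avogadro
    return per_um3, mol_l
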