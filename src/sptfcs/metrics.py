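"""Cross-method unification of SPT and FCS outputs.

Diffusion coefficients fitted with an anomalous model carry α-dependent units
(µm²/s^α) and cannot be compared across α directly. Both methods are therefore
mapped to a *transit time* Tt (s/µm³): the time for an isotropic 3D walker
with MSD(τ) = 6 D τ^α to first span the edge L = V_ref^(1/3) of a reference
volume, normalized by that volume:

    τ = (L² / 6D)^(1/α),    Tt = τ / V_ref        (V_ref = 1 µm³ by default).

This convention is dimensionally consistent and strictly monotone in D; it is
used for cross-method comparison only, not as a physical first-passage time.

The molecule-budget bookkeeping combines an FCS-measured total concentration
with SPT class fractions: of a total density, an FCS-detected fraction is fast
enough to correlate, and the SPT-observable remainder splits into the mobility
classes, each reported as a density (molecules/µm³) and a percent of total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TransitTime", "MoleculeBudget", "ComparisonReport", "transit_time", "compare_fcs_spt", "molecule_budget"]


@dataclass
class TransitTime:
    tt: float  # s/µm³
    tau: float  # s, residence time over the reference length
    d: float
    alpha: float
    reference_volume: float
    source: str  # "SPT" | "FCS"


def transit_time(d: float, alpha: float, reference_volume: float = 1.0, source: str = "SPT") -> TransitTime:
    """Normalized transit time of a (D, α) estimate within a reference volume."""
    if d <= 0:
        raise ValueError("transit time undefined for d <= 0 (stationary class)")
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (0, 2]")
    if reference_volume <= 0:
        raise ValueError("reference_volume must be positive")
    edge = reference_volume ** (1.0 / 3.0)
    tau = (edge**2 / (6.0 * d)) ** (1.0 / alpha)
    return TransitTime(
        tt=tau / reference_volume,
        tau=tau,
        d=d,
        alpha=alpha,
        reference_volume=reference_volume,
        source=source,
    )


@dataclass
class ComparisonReport:
    spt_min: float
    spt_max: float
    spt_median: float
    fcs_min: float
    fcs_max: float
    fcs_median: float
    gap_ratio: float  # min(SPT Tt) / max(FCS Tt)
    overlap: bool


def compare_fcs_spt(spt_tts: list[TransitTime], fcs_tts: list[TransitTime]) -> ComparisonReport:
    """Compare the transit-time ranges seen by the two methods.

    SPT reaches the slow end of the mobility spectrum and FCS the fast end; a
    gap ratio min(SPT)/max(FCS) > 1 means the two windows do not overlap (the
    slowest FCS-detected motion is still faster than anything SPT resolved).
    """
    if not spt_tts or not fcs_tts:
        raise ValueError("both SPT and FCS transit-time lists must be non-empty")
    spt = np.array([t.tt for t in spt_tts])
    fcs = np.array([t.tt for t in fcs_tts])
    gap = float(spt.min() / fcs.max())
    return ComparisonReport(
        spt_min=float(spt.min()),
        spt_max=float(spt.max()),
        spt_median=float(np.median(spt)),
        fcs_min=float(fcs.min()),
        fcs_max=float(fcs.max()),
        fcs_median=float(np.median(fcs)),
        gap_ratio=gap,
        overlap=gap <= 1.0,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class MoleculeBudget:
    total_density: float  # molecules/µm³
    fcs_fraction: float
    spt_fraction: float
    class_fractions: dict[str, float]  # of SPT-observable trajectories
    class_densities: dict[str, float]  # molecules/µm³, exact
    class_densities_rounded: dict[str, int]
    class_percent_of_total: dict[str, float]  # exact
    class_percent_rounded: dict[str, int]
    spt_density: float
    spt_density_rounded: int


def molecule_budget(
    total_density: float,
    fcs_fraction: float,
    spt_class_fractions: dict[str, float],
) -> MoleculeBudget:
    """Split a total molecule density between FCS-detected and SPT classes.

    Per class: percent of total = class_fraction · (1 − fcs_fraction) · 100 and
    density = class_fraction · (1 − fcs_fraction) · total_density; rounded
    values (half away from zero) are reported alongside the exact ones.
    """
    if total_density < 0:
        raise ValueError("total_density must be nonnegative")
    if not 0.0 <= fcs_fraction <= 1.0:
        raise ValueError("fcs_fraction must lie in [0, 1]")
    fr = np.array(list(spt_class_fractions.values()), dtype=float)
    if np.any(fr < 0) or np.any(fr > 1) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("class fractions must lie in [0, 1] and sum to 1")
    spt_fraction = 1.0 - fcs_fraction
    densities = {k: f * spt_fraction * total_density for k, f in spt_class_fractions.items()}
    percents = {k: f * spt_fraction * 100.0 for k, f in spt_class_fractions.items()}
    spt_density = spt_fraction * total_density
    return MoleculeBudget(
        total_density=total_density,
        fcs_fraction=fcs_fraction,
        spt_fraction=spt_fraction,
        class_fractions=dict(spt_class_fractions),
        class_densities=densities,
        class_densities_rounded={k: _round_half_away(v) for k, v in densities.items()},
        class_percent_of_total=percents,
        class_percent_rounded={k: _round_half_away(v) for k, v in percents.items()},
        spt_density=spt_density,
        spt_density_rounded=_round_half_away(spt_density),
    )
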