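"""Subpopulation discrimination on per-track (log10 D, α) features.

The per-trajectory diffusion estimates are pooled into a 2D feature table and
decomposed with Gaussian mixture models fitted by EM for k = 1..k_max. The
number of populations is chosen from the joint inflection of the BIC and AIC
curves as a function of k, preferring the smallest supported k; mixture
weights, centers (back-transformed to D in µm²/s) and marginal spreads are
then reported per population. Immobile or unfittable tracks never enter the
mixture; they are counted and reported as a separate fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

__all__ = [
    "FeatureTable",
    "MixtureModel",
    "ModelSelectionCurve",
    "build_feature_table",
    "fit_gmm_k",
    "model_selection_curves",
    "summarize_populations",
    "population_pdf_grid",
]


@dataclass
class FeatureTable:
    """(track_id, log10_d, alpha) rows entering the mixture, plus exclusion tallies."""

    table: pd.DataFrame
    n_excluded: int
    n_immobile: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        return self.table[["log10_d", "alpha"]].to_numpy()


@dataclass
class MixtureModel:
    k: int
    weights: np.ndarray  # EM mixture weights (mean posterior responsibilities)
    means: np.ndarray
    covariances: np.ndarray
    bic: float
    aic: float
    log_likelihood: float
    seed: int
    converged: bool
    assigned_fractions: np.ndarray | None = None  # hard max-posterior cluster shares


@dataclass
class ModelSelectionCurve:
    k_values: np.ndarray
    bic_values: np.ndarray
    aic_values: np.ndarray
    selected_k: int  # number of distinguishable populations
    inflection_k: int = 1  # raw BIC/AIC inflection before merging
    component_groups: list[list[int]] = field(default_factory=list)
    models: list[MixtureModel] = field(default_factory=list)


def build_feature_table(
    estimates: pd.DataFrame,
    d_field: str = "d60",
    exclude_immobile: bool = True,
) -> FeatureTable:
    """Feature rows (track_id, log10 D, α) from fitted diffusion estimates.

    Tracks with nonpositive or non-finite D, non-finite α, or (by default) an
    immobile classification are excluded and counted rather than silently
    dropped: the immobile fraction is reported alongside the mixture, not
    inside it.
    """
    if d_field not in estimates.columns:
        raise ValueError(f"unknown d_field {d_field!r}")
    d = estimates[d_field].to_numpy(dtype=float)
    alpha = estimates["alpha"].to_numpy(dtype=float)
    usable = np.isfinite(d) & (d > 0) & np.isfinite(alpha)
    immobile = np.zeros(len(estimates), dtype=bool)
    if exclude_immobile and "mobility_class" in estimates.columns:
        immobile = (estimates["mobility_class"] == "immobile").to_numpy()
    keep = usable & ~immobile
    if not keep.any():
        raise ValueError("no usable tracks remain for the feature table")
    table = pd.DataFrame(
        {
            "track_id": estimates.loc[keep, "track_id"].to_numpy(),
            "log10_d": np.log10(d[keep]),
            "alpha": alpha[keep],
        }
    )
    if "truth_label" in estimates.columns:
        table["truth_label"] = estimates.loc[keep, "truth_label"].to_numpy()
    return FeatureTable(
        table=table.reset_index(drop=True),
        n_excluded=int((~keep).sum()),
        n_immobile=int((immobile & usable).sum()),
    )


def _fit_sklearn(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        tol=1e-6,
        max_iter=500,
        n_init=10,
        init_params="k-means++",
        random_state=seed,
    )
    gmm.fit(x)
    return gmm


def fit_gmm_k(table: FeatureTable, k: int, seed: int) -> MixtureModel:
    """EM-fitted k-component full-covariance Gaussian mixture on the 2D features.

    BIC = −2 lnL + p ln n and AIC = −2 lnL + 2p with p = (k−1) + 2k + 3k free
    parameters; the best of 10 k-means++ initializations is kept, all driven
    by ``seed`` (same data + same seed ⇒ identical model).
    """
    x = table.values
    if len(x) < 5 * k:
        raise ValueError(f"need at least {5 * k} rows to fit k={k} components")
    gmm = _fit_sklearn(x, k, seed)
    hard = np.bincount(gmm.predict(x), minlength=k) / len(x)
    return MixtureModel(
        k=k,
        weights=gmm.weights_.copy(),
        assigned_fractions=hard,
        means=gmm.means_.copy(),
        covariances=gmm.covariances_.copy(),
        bic=float(gmm.bic(x)),
        aic=float(gmm.aic(x)),
        log_likelihood=float(gmm.score(x) * len(x)),
        seed=seed,
        converged=bool(gmm.converged_),
    )


def _inflection_k(values: np.ndarray, k_values: np.ndarray) -> int:
    """Elbow of a criterion curve: the k of maximal positive curvature among
    k where the criterion still improved from k−1, else 1 (no structure)."""
    candidates = []
    for i in range(1, len(k_values) - 1):
        if values[i] < values[i - 1]:  # ΔBIC(k−1→k) < 0
            curvature = values[i + 1] - 2 * values[i] + values[i - 1]
            candidates.append((curvature, int(k_values[i])))
    if not candidates:
        # monotone decrease to the last k still counts as improvement at the end
        if len(values) >= 2 and values[-1] < values[-2]:
            return int(k_values[-1])
        return 1
    best = max(candidates, key=lambda c: (c[0], -c[1]))
    return best[1]


#: Two Gaussian components whose means differ by less than this many pooled
#: SDs along every feature axis produce a unimodal joint density (the classic
#: 2σ resolvability limit) and are counted as one population.
MIN_COMPONENT_SEPARATION = 2.0


def _distinguishable_groups(model: MixtureModel, min_separation: float = MIN_COMPONENT_SEPARATION):
    """Group mixture components that are mutually unresolvable.

    Heavy-tailed per-track estimates make EM split one population into
    concentric narrow/wide components; those share a center and describe
    shape, not substructure. Components are linked when their per-axis mean
    separation, scaled by the pooled SD, stays below ``min_separation`` on
    every axis; groups are the transitive closure.
    """
    k = model.k
    adj = [[False] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            pooled = np.sqrt(
                0.5 * (np.diagonal(model.covariances[i]) + np.diagonal(model.covariances[j]))
            )
            sep = np.abs(model.means[i] - model.means[j]) / pooled
            adj[i][j] = adj[j][i] = bool(np.all(sep < min_separation))
    groups, seen = [], set()
    for i in range(k):
        if i in seen:
            continue
        stack, group = [i], []
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            group.append(node)
            stack.extend(j for j in range(k) if adj[node][j] and j not in seen)
        groups.append(sorted(group))
    return groups


def model_selection_curves(
    table: FeatureTable,
    k_max: int = 10,
    seed: int = 0,
    min_separation: float = MIN_COMPONENT_SEPARATION,
) -> ModelSelectionCurve:
    """BIC/AIC curves for k = 1..k_max and the selected number of populations.

    k is capped at n/5 so no component is asked to explain fewer than five
    tracks. The BIC and AIC elbows are computed separately; when they
    disagree the smaller k is kept (populations chosen as few as possible).
    Components of the elbow model that are mutually unresolvable (closer than
    ``min_separation`` pooled SDs on every axis) are then counted as one
    population, so nearly identical conditions report a single population
    even when the criteria reward an extra component for non-Gaussian shape.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_cap = max(1, min(k_max, len(table) // 5))
    k_values = np.arange(1, k_cap + 1)
    models = [fit_gmm_k(table, int(k), seed) for k in k_values]
    bic = np.array([m.bic for m in models])
    aic = np.array([m.aic for m in models])
    if k_cap == 1:
        inflection = 1
    else:
        inflection = min(_inflection_k(bic, k_values), _inflection_k(aic, k_values))
    groups = _distinguishable_groups(models[inflection - 1], min_separation)
    return ModelSelectionCurve(
        k_values=k_values,
        bic_values=bic,
        aic_values=aic,
        selected_k=len(groups),
        inflection_k=inflection,
        component_groups=groups,
        models=models,
    )


def merge_components(model: MixtureModel, groups: list[list[int]]) -> MixtureModel:
    """Collapse component groups into single moment-matched Gaussians.

    Group weight is the sum of member weights; the merged mean and covariance
    are the mixture moments of the members, so the reduced model preserves
    each population's total mass, center and spread.
    """
    weights, means, covs, hard = [], [], [], []
    for group in groups:
        w = model.weights[group]
        total = w.sum()
        mu = (w[:, None] * model.means[group]).sum(axis=0) / total
        second = np.zeros((model.means.shape[1],) * 2)
        for g, wg in zip(group, w):
            m = model.means[g]
            second += wg * (model.covariances[g] + np.outer(m, m))
        covs.append(second / total - np.outer(mu, mu))
        weights.append(total)
        means.append(mu)
        if model.assigned_fractions is not None:
            hard.append(model.assigned_fractions[group].sum())
    return MixtureModel(
        k=len(groups),
        weights=np.array(weights),
        means=np.array(means),
        covariances=np.array(covs),
        bic=model.bic,
        aic=model.aic,
        log_likelihood=model.log_likelihood,
        seed=model.seed,
        converged=model.converged,
        assigned_fractions=np.array(hard) if hard else None,
    )


def summarize_populations(model: MixtureModel) -> pd.DataFrame:
    """Per-population weight, center (D back-transformed from log10), marginal SDs."""
    rows = []
    hard = model.assigned_fractions if model.assigned_fractions is not None else model.weights
    for w, h, mu, cov in zip(model.weights, hard, model.means, model.covariances):
        rows.append(
            {
                "weight": float(w),
                "assigned_fraction": float(h),
                "d_center": float(10.0 ** mu[0]),
                "log10_d_center": float(mu[0]),
                "alpha_center": float(mu[1]),
                "log10_d_sd": float(np.sqrt(cov[0, 0])),
                "alpha_sd": float(np.sqrt(cov[1, 1])),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("weight", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def population_pdf_grid(
    model: MixtureModel,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    resolution: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mixture density on a (log10 D, α) grid — the contour data of the
    population scatter plots. Returns (grid_x, grid_y, density)."""
    (x0, x1), (y0, y1) = bounds
    if not (np.isfinite([x0, x1, y0, y1]).all() and x1 > x0 and y1 > y0):
        raise ValueError("bounds must be finite, increasing intervals")
    gx = np.linspace(x0, x1, resolution)
    gy = np.linspace(y0, y1, resolution)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    dens = np.zeros(len(pts))
    for w, mu, cov in zip(model.weights, model.means, model.covariances):
        dens += w * multivariate_normal.pdf(pts, mean=mu, cov=cov)
    return gx, gy, dens.reshape(resolution, resolution)
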