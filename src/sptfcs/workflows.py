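"""End-to-end workflows: the bead benchmark and the polymerase-like analysis.

Both are pure functions of (configuration, seed) and return plain dict
reports; the numbered scripts under ``analysis/`` drive them and write their
tables under ``results/``.
"""

from __future__ import annotations

import numpy as np

from . import fcs, metrics, msd, populations, simulate

__all__ = ["benchmark_condition", "run_mixture_discrimination", "run_benchmark_workflow", "run_rpb1_workflow"]


def benchmark_condition(
    d_true: float, n_tracks: int, seed: int, label: str | None = None
) -> tuple[dict, "np.ndarray"]:
    """Simulate one Brownian bead condition and measure recovery of (D, α)."""
    cfg = simulate.SimulationConfig(n_tracks=n_tracks, rng_seed=seed)
    tracks = simulate.simulate_brownian_tracks(d_true, cfg, label=label)
    est = msd.analyze_tracks(tracks)
    summary = msd.summarize_tracks(est)
    summary.update(
        d_true=d_true,
        d60_median=float(est["d60"].median()),
        d60_median_rel_err=float(abs(est["d60"].median() - d_true) / d_true) if d_true > 0 else np.nan,
    )
    return summary, est


def run_mixture_discrimination(
    d_values: tuple[float, float],
    fractions: tuple[float, float] = (0.5, 0.5),
    n_tracks_per_set: int = 500,
    n_mixture: int = 1000,
    seed: int = 0,
    k_max: int = 10,
) -> dict:
    """Mix two Brownian conditions, run h-MSD + GMM, report selected k and weights.

    Ground-truth labels ride along so the recovered mixture weights can be
    scored against the realized (not just nominal) composition.
    """
    root = np.random.SeedSequence(seed)
    s1, s2, s_mix, s_gmm = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(4))
    cfg1 = simulate.SimulationConfig(n_tracks=n_tracks_per_set, rng_seed=s1)
    cfg2 = simulate.SimulationConfig(n_tracks=n_tracks_per_set, rng_seed=s2)
    set1 = simulate.simulate_brownian_tracks(d_values[0], cfg1, label=f"D={d_values[0]}")
    set2 = simulate.simulate_brownian_tracks(d_values[1], cfg2, label=f"D={d_values[1]}")
    mixture = simulate.mix_track_sets([set1, set2], list(fractions), n_mixture, seed=s_mix)
    est = msd.analyze_tracks(mixture)
    table = populations.build_feature_table(est, d_field="d60")
    curve = populations.model_selection_curves(table, k_max=k_max, seed=s_gmm)
    model2 = populations.fit_gmm_k(table, 2, seed=s_gmm) if len(table) >= 10 else None
    report = {
        "d_values": list(d_values),
        "fractions": list(fractions),
        "n_mixture": n_mixture,
        "n_features": len(table),
        "n_excluded": table.n_excluded,
        "selected_k": curve.selected_k,
        "bic": curve.bic_values.tolist(),
        "aic": curve.aic_values.tolist(),
        "k_values": curve.k_values.tolist(),
    }
    if model2 is not None:
        pops = populations.summarize_populations(model2)
        # order recovered components by center to align with the faster condition first
        pops = pops.sort_values("d_center", ascending=d_values[0] > d_values[1]).reset_index(drop=True)
        report["k2_weights"] = pops["weight"].tolist()
        report["k2_assigned_fractions"] = pops["assigned_fraction"].tolist()
        report["k2_d_centers"] = pops["d_center"].tolist()
        report["k2_alpha_centers"] = pops["alpha_center"].tolist()
        if "truth_label" in table.table.columns:
            realized = (
                table.table["truth_label"].value_counts(normalize=True).reindex(
                    [f"D={d_values[0]}", f"D={d_values[1]}"]
                )
            )
            report["realized_fractions"] = realized.tolist()
    return report


def proportion_recovery_replicates(
    d_values: tuple[float, float] = (3.6, 1.28),
    fractions: tuple[float, float] = (0.5, 0.5),
    n_tracks_per_set: int = 500,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> dict:
    """Replicate the two-population mixture and score GMM weight recovery.

    For each replicate the k = 2 mixture is fitted and the maximum relative
    error of the recovered weights against the nominal composition recorded;
    the summary quotes the median over replicates, for both the EM mixture
    weights and the hard max-posterior assignment fractions.
    """
    root = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_seeds)]
    truth = np.sort(np.asarray(fractions, dtype=float))
    errs_soft, errs_hard = [], []
    for s in seeds:
        rep = run_mixture_discrimination(
            d_values, fractions, n_tracks_per_set, 2 * n_tracks_per_set, seed=s, k_max=2
        )
        model_w = np.sort(rep["k2_weights"])
        errs_soft.append(float(np.max(np.abs(model_w - truth) / truth)))
        hard = np.sort(rep["k2_assigned_fractions"])
        errs_hard.append(float(np.max(np.abs(hard - truth) / truth)))
    return {
        "n_seeds": n_seeds,
        "max_rel_error_per_seed": errs_soft,
        "median_max_rel_error": float(np.median(errs_soft)),
        "median_max_rel_error_assigned": float(np.median(errs_hard)),
    }


def run_benchmark_workflow(
    seed: int = 0,
    n_tracks: int = 500,
    spt_conditions: dict[str, float] | None = None,
    fcs_d: float = 12.0,
    fcs_duration: float = 60.0,
    mixture_d: tuple[float, float] = (3.6, 1.28),
) -> dict:
    """Bead benchmark end to end: per-condition SPT recovery, two-condition
    mixture discrimination, and one FCS trace fitted with both models.

    Default SPT conditions are the published reference diffusion coefficients
    of 100 nm beads in the water/glycerol series; the default mixture pairs
    the 20% and 50% glycerol conditions.
    """
    if spt_conditions is None:
        spt_conditions = {
            f"glycerol_{int(frac * 100)}pct": ref[2]
            for frac, ref in simulate.BEAD_TABLE_REFERENCE.items()
        }
    root = np.random.SeedSequence(seed)
    cond_seeds = root.spawn(len(spt_conditions) + 2)
    spt_summaries = {}
    for (name, d_true), sub in zip(spt_conditions.items(), cond_seeds):
        summary, _ = benchmark_condition(
            d_true, n_tracks, int(sub.generate_state(1)[0] % 2**31), label=name
        )
        spt_summaries[name] = summary
    mix_seed = int(cond_seeds[-2].generate_state(1)[0] % 2**31)
    mixture = run_mixture_discrimination(mixture_d, n_tracks_per_set=n_tracks, n_mixture=2 * n_tracks, seed=mix_seed)
    fcs_seed = int(cond_seeds[-1].generate_state(1)[0] % 2**31)
    volume = simulate.FocalVolumeSpec(w0=0.25, z0=1.25)
    spec = simulate.FCSSimSpec(
        diffusion_coefficient=fcs_d,
        mean_molecules_in_volume=2.0,
        brightness=20_000.0,
        duration=fcs_duration,
        rng_seed=fcs_seed,
    )
    trace = simulate.simulate_fcs_trace(spec, volume)
    acf = fcs.multitau_acf(trace)
    structure = (volume.w0 / volume.z0) ** 2
    fit_n = fcs.fit_acf_normal(acf, structure=structure, w0=volume.w0)
    fit_a = fcs.fit_acf_anomalous(acf, structure=structure, w0=volume.w0)
    tau_expected = volume.w0**2 / (4.0 * fcs_d)
    return {
        "seed": seed,
        "spt_conditions": spt_summaries,
        "mixture": mixture,
        "fcs": {
            "d_true": fcs_d,
            "tau_d_expected": tau_expected,
            "normal": {"n": fit_n.n_molecules, "tau_d": fit_n.tau_d, "d": fit_n.d_coefficient},
            "anomalous": {
                "n": fit_a.n_molecules,
                "tau_d": fit_a.tau_d,
                "alpha": fit_a.alpha,
                "d": fit_a.d_coefficient,
            },
        },
    }


def run_rpb1_workflow(
    seed: int = 0,
    n_tracks: int = 1000,
    total_density: float = 37.0,
    fcs_fraction: float = 1.0 / 3.0,
    k_max: int = 10,
) -> dict:
    """Polymerase-like mixture end to end: immobile fraction, GMM populations,
    per-population transit times, and the molecule-budget bookkeeping."""
    root = np.random.SeedSequence(seed)
    s_sim, s_gmm = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))
    cfg = simulate.SimulationConfig(n_tracks=n_tracks, rng_seed=s_sim)
    mixture = simulate.simulate_rpb1_like_mixture(cfg, seed=s_sim)
    est = msd.analyze_tracks(mixture)
    immobile_fraction = float((est["mobility_class"] == "immobile").mean())
    table = populations.build_feature_table(est, d_field="d60")
    curve = populations.model_selection_curves(table, k_max=k_max, seed=s_gmm)
    model = populations.merge_components(curve.models[curve.inflection_k - 1], curve.component_groups)
    pops = populations.summarize_populations(model)
    pop_records = []
    for _, row in pops.iterrows():
        # a population with alpha near 0 is a noise-floor cluster; its power-law
        # inversion is meaningless, so no transit time is reported for it
        tt = (
            metrics.transit_time(row["d_center"], row["alpha_center"], source="SPT").tt
            if row["alpha_center"] >= 0.1 and row["d_center"] > 0
            else None
        )
        pop_records.append(
            {
                "weight": row["weight"],
                "assigned_fraction": row["assigned_fraction"],
                "d_center": row["d_center"],
                "alpha_center": row["alpha_center"],
                "transit_time_s_per_um3": tt,
            }
        )
    class_fractions = est["mobility_class"].value_counts(normalize=True).to_dict()
    mobile = est[est["mobility_class"] == "mobile"]
    mobile_split = {"immobile": class_fractions.get("immobile", 0.0)}
    # split the mobile share by fitted alpha around the midpoint of the two
    # mobile classes' exponents (0.31 vs 0.95)
    sub = float((mobile["alpha"] < 0.63).mean()) * (1 - mobile_split["immobile"])
    mobile_split["subdiffusive"] = sub
    mobile_split["mobile"] = 1.0 - mobile_split["immobile"] - sub
    budget = metrics.molecule_budget(total_density, fcs_fraction, mobile_split)
    return {
        "seed": seed,
        "n_tracks_analyzed": int(len(est)),
        "immobile_fraction": immobile_fraction,
        "selected_k": curve.selected_k,
        "populations": pop_records,
        "class_fractions": mobile_split,
        "budget": {
            "total_density": budget.total_density,
            "spt_density": budget.spt_density,
            "spt_density_rounded": budget.spt_density_rounded,
            "class_densities": budget.class_densities,
            "class_densities_rounded": budget.class_densities_rounded,
            "class_percent_of_total": budget.class_percent_of_total,
            "class_percent_rounded": budget.class_percent_rounded,
        },
    }
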