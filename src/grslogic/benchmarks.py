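"""End-to-end benchmark recipes shared by the test suite, the acceptance
script and the examples.

Each function rebuilds its inputs from scratch (catalog, panels, noisy
data) so results depend only on the seed and the stated problem sizes.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

from .enumeration import (
    GRSCatalog,
    build_panel,
    deduplicate,
    enumerate_representative_catalog,
    filter_activatable,
)
from .error_model import fit_global_error_params, posterior_variances
from .fitting import catalog_identifiability, fit_all_logics, map_to_17
from .synthetic_data import NoiseConfig, empirical_variance, generate_noisy_dataset

__all__ = [
    "reference_catalog",
    "enumeration_summary",
    "error_model_benchmark",
    "fitting_benchmark",
    "design_benchmark",
]

#: Conditions of the fixed-budget design study: WT plus three single
#: knockouts; a 13-condition knockout/knockdown ladder; all 26.
DESIGN_4 = ("HHH", "LHH", "HLH", "HHL")
DESIGN_13 = ("HHH", "LHH", "HLH", "HHL", "LLH", "LHL", "HLL",
             "MHH", "HMH", "HHM", "MMH", "MHM", "HMM")


def reference_catalog() -> GRSCatalog:
    """The filtered, deduplicated representative catalog (93 retained)."""
    return deduplicate(filter_activatable(enumerate_representative_catalog()))


def enumeration_summary() -> dict:
    cat = reference_catalog()
    retained = cat.retained()
    triple_and = [e for e in retained.entries if e.params.logic == "TF1.TF2.TF3"]
    return {
        "total": len(cat),
        "poorly_activated": len(cat.with_status("poorly_activated")),
        "redundant": len(cat.with_status("redundant")),
        "retained": len(retained),
        "triple_and_retained": len(triple_and),
        "activatability_threshold": round(cat.activatability_threshold, 2),
    }


def error_model_benchmark(
    seed: int = 0,
    n_replicates: int = 2,
    n_truth_samples: int = 1000,
    use_posterior: bool = True,
) -> dict:
    """Variance-estimation accuracy of the error models.

    Simulates the 93-GRS x 26-amplitude-condition benchmark with 2
    replicates and base-level noise, takes the per-point variance of
    ``n_truth_samples`` independent draws as ground truth, and reports
    the Pearson correlation of each model's (posterior) variance
    estimates with that truth, plus the raw 2-replicate variance
    baseline.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, truth_seed = ss.spawn(2)
    cat = reference_catalog().retained()
    panel = build_panel("amplitude26")
    ds = generate_noisy_dataset(cat, panel, n_replicates, seed=data_seed)
    truth = empirical_variance(
        generate_noisy_dataset(cat, panel, n_truth_samples, seed=truth_seed).values
    )
    out = {"n_points": int(truth.size)}
    for mode, key in (("time_value", "r_time_value"),
                      ("conventional", "r_conventional")):
        params, stats = fit_global_error_params(ds.values, ds.timepoints, mode=mode)
        if use_posterior:
            est = posterior_variances(ds.values, params, stats)
        else:
            from .error_model import total_variance
            est = np.where(stats.mu <= params.eta, params.sigma_bg2,
                           total_variance(stats.mu, stats.slope, params))
        out[key] = float(pearsonr(est.ravel(), truth.ravel())[0])
    raw = empirical_variance(ds.values)
    out["r_raw"] = float(pearsonr(raw.ravel(), truth.ravel())[0])
    return out


def fitting_benchmark(
    seed: int = 0,
    n_genes: int = 15,
    n_starts: int = 100,
    modes: tuple[str, ...] = ("time_value", "conventional", "raw"),
    noise: NoiseConfig | None = None,
) -> dict:
    """Logic-gate and Kd recovery of the fitting pipeline.

    Simulates 2-replicate amplitude26 data for ``n_genes`` GRSs sampled
    from the retained catalog, fits all 8 gates per gene with
    ``n_starts`` random starts under each error model, and reports the
    number of correctly recovered logics, the fraction of non-null Kds
    within 2-fold of truth, and the Kd mean absolute percent deviation
    (MAPD).  Recovery is judged on the 17-logic label (the mapped
    taxonomy): a reduced single/dual gate is representable by more than
    one host triple logic, so comparing raw host gates would punish
    logically identical answers.
    """
    ss = np.random.SeedSequence(seed)
    pick_seed, data_seed, fit_seed = ss.spawn(3)
    cat = reference_catalog().retained()
    panel = build_panel("amplitude26")
    levels = panel.constant_levels()
    ds = generate_noisy_dataset(cat, panel, 2, noise=noise, seed=data_seed)
    rng = np.random.default_rng(pick_seed)
    sel = np.sort(rng.choice(len(cat.entries), size=n_genes, replace=False))

    raw_var = empirical_variance(ds.values)
    fitted = {}
    mode_key = {"time_value": 0, "conventional": 1, "raw": 2}
    for mode in modes:
        if mode == "raw":
            params, stats = None, None
        else:
            params, stats = fit_global_error_params(ds.values, ds.timepoints,
                                                    mode=mode)
        n_correct = 0
        ratios = []
        gene_children = np.random.SeedSequence(
            entropy=fit_seed.entropy, spawn_key=(mode_key[mode],)
        ).spawn(n_genes)
        for gi, child in zip(sel, gene_children):
            truth = cat.entries[gi]
            if mode == "raw":
                res = fit_all_logics(ds.values[gi], levels, None,
                                     slopes=None, gene=truth.label,
                                     n_starts=n_starts, seed=child,
                                     raw_variance=raw_var[gi])
            else:
                res = fit_all_logics(ds.values[gi], levels, params,
                                     slopes=stats.slope[gi], gene=truth.label,
                                     n_starts=n_starts, seed=child)
            truth_label, _ = map_to_17(truth.params.logic, truth.params.kd)
            if res.logic17_label == truth_label:
                n_correct += 1
            for k_true, k_fit in zip(truth.params.kd, res.selected_params.kd):
                if k_true < 100.0:  # non-null regulation strengths only
                    ratios.append(k_fit / k_true)
        ratios = np.asarray(ratios)
        fitted[mode] = {
            "n_genes": n_genes,
            "n_correct_logic": n_correct,
            "frac_kd_2fold": float(np.mean((ratios >= 0.5) & (ratios <= 2.0))),
            "kd_mapd": float(np.mean(np.abs(ratios - 1.0))),
        }
    return fitted


def design_benchmark(seed: int = 0, n_seeds: int = 1) -> dict:
    """Median identifiability of the fixed-budget (52-dataset) designs.

    Evaluates WT+single-KO x 13 replicates, the 13-condition mixed ladder
    x 4, and all 26 amplitude conditions x 2; optionally pools per-GRS
    values over ``n_seeds`` independent noise draws before taking
    medians.  Also reports the deterministic minimum-distance medians of
    the four 3-condition perturbation sets (single/double KO/KD).
    """
    cat = reference_catalog()
    designs = {
        "4cond_13rep": (build_panel("custom", DESIGN_4), 13),
        "13cond_4rep": (build_panel("custom", DESIGN_13), 4),
        "26cond_2rep": (build_panel("amplitude26"), 2),
    }
    ss = np.random.SeedSequence(seed)
    out = {}
    for (name, (panel, reps)), child in zip(designs.items(), ss.spawn(len(designs))):
        vals = []
        for sub in child.spawn(n_seeds):
            vals.append(catalog_identifiability(cat, panel, reps, seed=sub).values)
        out[f"median_{name}"] = float(np.median(np.concatenate(vals)))
    for name, sigs in (("HLL", ("HLL", "LHL", "LLH")),
                       ("HHL", ("LHH", "HLH", "HHL")),
                       ("HMM", ("HMM", "MHM", "MMH")),
                       ("HHM", ("MHH", "HMH", "HHM"))):
        rep = catalog_identifiability(cat, build_panel("custom", sigs), 2,
                                      metric="min_sq_distance")
        out[f"min_dist_median_{name}"] = rep.median
    return out
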