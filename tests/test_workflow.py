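"""Measured-data workflow: scaling, gene selection, basal fitting, calls."""

import numpy as np
import pandas as pd
import pytest

from grslogic.enumeration import build_panel
from grslogic.errors import ConfigurationError, DegenerateInputError, \
    InvalidInputError
from grslogic.error_model import ErrorModelParams
from grslogic.experimental_workflow import (
    SYNERGY_LOGICS,
    call_logics,
    fit_with_basal,
    infer_mapk_activity,
    normalize_across_conditions,
    normalize_mapki,
    scale_tf_activity,
    select_induced_genes,
)
from grslogic.fitting import FitResult
from grslogic.grs_core import GRSParameters, LOGICS, gate_activity

HOMO = ErrorModelParams(sigma_bg2=0.5, alpha0=1.0, alpha1=0.0, alpha2=0.0,
                        sigma_t2=25.0, mode="time_value")


class TestTFScaling:
    def test_endpoints_map_to_1pct_and_100pct(self):
        assert scale_tf_activity(10.0, 10.0, 110.0) == pytest.approx(0.01)
        assert scale_tf_activity(110.0, 10.0, 110.0) == pytest.approx(1.0)
        assert scale_tf_activity(60.0, 10.0, 110.0) == pytest.approx(0.505)

    def test_affine_invariance(self, rng):
        raw = rng.uniform(5, 50, size=8)
        basal, peak = raw.min(), raw.max()
        a, b = 3.7, -1.2
        direct = scale_tf_activity(raw, basal, peak)
        affine = scale_tf_activity(a * raw + b, a * basal + b, a * peak + b)
        assert np.allclose(direct, affine, rtol=1e-12)

    def test_degenerate_peak_rejected(self):
        with pytest.raises(DegenerateInputError):
            scale_tf_activity(5.0, 10.0, 10.0)

    def test_cross_condition_factors(self):
        scaled = {"WT": np.array([0.01, 1.0]), "KO": np.array([0.01, 1.0])}
        peaks = {"WT": 200.0, "KO": 100.0}
        out = normalize_across_conditions(scaled, peaks, reference="WT")
        assert np.allclose(out["WT"], scaled["WT"])  # reference factor is 1
        assert np.allclose(out["KO"], 0.5 * scaled["KO"])
        with pytest.raises(ConfigurationError):
            normalize_across_conditions(scaled, {"WT": 200.0}, reference="WT")
        with pytest.raises(InvalidInputError):
            normalize_across_conditions(scaled, {"WT": 0.0, "KO": 1.0},
                                        reference="WT")


class TestMAPKInference:
    def test_identical_iegs_average_to_their_scaling(self):
        series = np.array([1.0, 5.0, 9.0, 4.0])
        iegs = {g: {"WT": series} for g in ("Egr1", "Fos", "Dusp4")}
        out = infer_mapk_activity(iegs, reference="WT")
        assert out["WT"][0] == pytest.approx(0.01)
        assert out["WT"].max() == pytest.approx(1.0)

    def test_missing_condition_averages_remaining_genes(self):
        iegs = {
            "Egr1": {"WT": np.array([1.0, 9.0]), "KO": np.array([1.0, 5.0])},
            "Fos": {"WT": np.array([2.0, 10.0])},
        }
        with pytest.warns(UserWarning, match="missing condition"):
            out = infer_mapk_activity(iegs, reference="WT")
        expected_ko = scale_tf_activity(np.array([1.0, 5.0]), 1.0, 9.0)
        assert np.allclose(out["KO"], expected_ko)

    def test_empty_ieg_set_rejected(self):
        with pytest.raises(ConfigurationError):
            infer_mapk_activity({}, reference="WT")


class TestInducedGeneSelection:
    @staticmethod
    def _table(profiles):
        rows = []
        for gene, vals in profiles.items():
            for t, v in zip((0.0, 15.0, 30.0, 60.0), vals):
                rows.append({"gene": gene, "time_min": t, "value_rpkm": v})
        return pd.DataFrame(rows)

    def test_selection_rules(self):
        expr = self._table({
            "low_peak": (0.1, 0.4, 2.9, 2.0),      # 29-fold but peak < 3
            "classic": (0.5, 2.0, 8.0, 6.0),        # 16-fold, peak 8, p ok
            "early": (1.0, 7.0, 3.5, 2.0),          # 7-fold at 15 min only
            "flat": (5.0, 6.0, 5.5, 5.0),
            "no_sig": (0.5, 2.0, 9.0, 6.0),         # would pass but p = 0.2
        })
        sig = {"low_peak": 0.001, "classic": 0.005, "early": 0.5,
               "flat": 0.001, "no_sig": 0.2}
        out = select_induced_genes(expr, sig)
        got = dict(zip(out["gene"], out["rule"]))
        assert got == {"classic": "peak_fold_p", "early": "early_fold"}

    def test_zero_baseline_uses_floor(self):
        expr = self._table({"zero_base": (0.0, 0.2, 4.0, 3.0)})
        out = select_induced_genes(expr, {"zero_base": 0.001})
        # fold = 4.0 / 0.1 floor = 40 > 10, peak 4 > 3, p < 0.01
        assert list(out["gene"]) == ["zero_base"]
        assert out["max_fold"].iloc[0] == pytest.approx(40.0)

    def test_missing_t0_rejected(self):
        expr = pd.DataFrame({"gene": ["g"], "time_min": [15.0],
                             "value_rpkm": [5.0]})
        with pytest.raises(InvalidInputError):
            select_induced_genes(expr, {"g": 0.001})


class TestMapkiNormalization:
    def test_control_equal_wt_is_identity(self, rng):
        series = rng.uniform(1, 10, 4)
        wt = rng.uniform(1, 10, 4)
        assert np.allclose(normalize_mapki(series, wt, wt), series)

    def test_double_control_halves(self):
        inh = np.array([4.0, 8.0])
        wt = np.array([2.0, 3.0])
        assert np.allclose(normalize_mapki(inh, 2 * wt, wt), inh / 2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_mapki(np.ones(3), np.ones(4), np.ones(4))

    def test_zero_control_floored_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_mapki(np.array([1.0]), np.array([0.0]),
                                  np.array([2.0]))
        assert np.isfinite(out).all()


class TestBasalFitting:
    def _simulate_with_basal(self, logic, kd, basal, levels, n_rep=2):
        from grslogic.fitting import _predict_batch
        x = np.array([*np.log10(kd), 0.0, -1.0, -6.0])[None, :]
        y = _predict_batch(logic, x, levels, [0.0, 15.0, 30.0, 60.0], True,
                           basal)[0]
        return np.repeat(y[..., None], n_rep, axis=-1)

    def test_fitted_curves_reproduce_measured_basal_at_t0(self):
        levels = build_panel("custom", ["HHH", "LHH", "HLH"]).constant_levels()
        basal = np.array([2.0, 5.0, 0.5])
        y = self._simulate_with_basal("TF1+TF2+TF3", (0.1, 1e6, 1e6), basal,
                                      levels)
        assert np.allclose(y[:, 0, :], basal[:, None], atol=1e-3)
        res = fit_with_basal(y, levels, HOMO, basal,
                             slopes=np.zeros(y.shape[:2]), gene="g",
                             n_starts=80, seed=4)
        assert res.selected_params.k0 == 0.0
        assert res.logic17_label == "TF1"

    def test_zero_basal_matches_plain_fit(self):
        from grslogic.fitting import fit_all_logics
        levels = build_panel("custom", ["HHH", "HLH"]).constant_levels()
        y = self._simulate_with_basal("TF1+(TF2.TF3)", (0.5, 1e6, 1e6),
                                      np.zeros(2), levels)
        a = fit_with_basal(y, levels, HOMO, np.zeros(2),
                           slopes=np.zeros(y.shape[:2]), n_starts=40, seed=9)
        b = fit_all_logics(y, levels, HOMO, slopes=np.zeros(y.shape[:2]),
                           n_starts=40, seed=9, fit_k0=False,
                           basal=np.zeros(2))
        assert a.selected_nll == pytest.approx(b.selected_nll, rel=1e-9)

    def test_negative_basal_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_with_basal(np.ones((2, 4, 2)),
                           np.array([[1, 1, 1], [0, 1, 1]]), HOMO,
                           np.array([-1.0, 0.0]))


def _fake_result(gene, nlls, kds=None):
    kds = kds or {}
    params = {
        logic: GRSParameters(logic=logic, kd=kds.get(logic, (1.0, 1.0, 1.0)),
                             ksyn=1.0, kproc=0.1)
        for logic in LOGICS
    }
    nll_map = dict(zip(LOGICS, nlls))
    best = min(nll_map, key=nll_map.get)
    from grslogic.fitting import map_to_17
    label, nulls = map_to_17(best, params[best].kd)
    return FitResult(gene=gene, nll_per_logic=nll_map, params_per_logic=params,
                     selected_logic=best, logic17_label=label, null_tfs=nulls,
                     n_starts=1)


class TestCallLogics:
    def test_threshold_rule(self):
        res = _fake_result("g1", [80.0, 120, 130, 140, 150, 160, 170, 180])
        table = call_logics([res], nll_threshold=100.0).table
        assert table["accepted_logics"].iloc[0] == "TF1.TF2.TF3"
        assert not table["unexplained"].iloc[0]

    def test_no_accepted_logic_is_unexplained(self):
        res = _fake_result("g1", [500.0] * 8)
        table = call_logics([res], nll_threshold=100.0).table
        assert table["unexplained"].iloc[0]
        assert table["accepted_logics"].iloc[0] == ""

    def test_single_tf_classification_requires_all_accepted_single(self):
        # triple OR maps to single TF1 (two nulls); dual AND stays dual
        kds = {"TF1+TF2+TF3": (0.5, 150.0, 150.0)}
        res = _fake_result("g1", [99.0, 150, 150, 150, 150, 150, 150, 98.0],
                           kds)
        table = call_logics([res], nll_threshold=100.0).table
        assert set(table["accepted_logics"].iloc[0].split(";")) == \
            {"TF1", "TF1.TF2.TF3"}
        assert not table["single_tf_only"].iloc[0]

    def test_synergy_flag(self):
        kds = {"TF3+(TF1.TF2)": (0.5, 0.5, 150.0)}
        res = _fake_result("g1", [150, 150, 150, 150, 150, 150, 90.0, 150],
                           kds)
        table = call_logics([res], nll_threshold=100.0).table
        # MAPK null -> NFkB AND IRF, one of the 5 synergy logics
        assert table["accepted_logics"].iloc[0] == "TF1.TF2"
        assert table["synergy"].iloc[0]
        assert "TF1.TF2" in SYNERGY_LOGICS


class TestPseudoExperiment:
    def test_compensated_synergy_gene_detected(self):
        """A 'MAPK OR (NFkB AND IRF)' gene barely responds to IRF knockout
        yet is synergy-flagged -- knockout data alone would miss it."""
        p = GRSParameters(logic="TF3+(TF1.TF2)", kd=(0.1, 0.1, 0.1),
                          ksyn=1.0, kproc=0.1)
        g_wt = gate_activity(p.logic, (1.0, 1.0, 1.0), p.kd)
        g_irf_ko = gate_activity(p.logic, (1.0, 0.0, 1.0), p.kd)
        reduction = 1.0 - g_irf_ko / g_wt
        assert reduction < 0.2  # MAPK compensates for the lost IRF arm
        assert "TF3+(TF1.TF2)" in SYNERGY_LOGICS

    def test_pipeline_recovers_generating_labels(self, retained):
        """Pseudo-experiments: basal-offset data from known GRSs get the
        right 17-logic label for the large majority of identifiable cases."""
        from grslogic.fitting import _predict_batch
        # single + double knockouts and knockdowns: without the LLx
        # conditions, e.g. single TF3 and TF3.(TF1+TF2) coincide exactly
        levels = build_panel(
            "custom", ["HHH", "LHH", "HLH", "HHL", "LLH", "LHL", "HLL",
                       "MHH", "HMH", "HHM"]
        ).constant_levels()
        rng = np.random.default_rng(20210624)
        picks = [e for e in retained.entries[::9]][:10]
        ok = 0
        for i, entry in enumerate(picks):
            basal = rng.uniform(0.0, 3.0, size=levels.shape[0])
            x = np.array([*np.log10(entry.params.kd), 0.0, -1.0, -6.0])[None, :]
            y = _predict_batch(entry.params.logic, x, levels,
                               [0.0, 15.0, 30.0, 60.0], True, basal)[0]
            y = y[..., None] * (1 + rng.normal(0, 0.05, size=y.shape + (2,)))
            y = np.maximum(y, 0.0)
            res = fit_with_basal(y, levels, HOMO, basal,
                                 slopes=np.zeros(y.shape[:2]),
                                 gene=entry.label, n_starts=80, seed=100 + i)
            want, _ = __import__("grslogic.fitting", fromlist=["map_to_17"]) \
                .map_to_17(entry.params.logic, entry.params.kd)
            ok += res.logic17_label == want
        assert ok >= 9  # >= 90 % of cases
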