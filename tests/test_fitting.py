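"""Model likelihood, multi-start fitting, selection/mapping, identifiability."""

import numpy as np
import pytest

from grslogic.enumeration import GRSCatalog, build_panel, panel_response
from grslogic.errors import ConfigurationError, InvalidInputError
from grslogic.error_model import ErrorModelParams
from grslogic.fitting import (
    catalog_identifiability,
    evaluate_design,
    fit_all_logics,
    fit_gene,
    map_to_17,
    model_nll,
    select_and_map,
    symmetric_nll_distance,
)
from grslogic.grs_core import GRSParameters, LOGICS

PARAMS = ErrorModelParams(sigma_bg2=0.5, alpha0=1.0, alpha1=0.0, alpha2=0.01,
                          sigma_t2=25.0, mode="time_value")
TP = (0.0, 15.0, 30.0, 60.0)


def _panel_levels(name="amplitude26"):
    return build_panel(name).constant_levels()


def _noiseless_obs(params, levels, n_rep=2):
    """Replicated noise-free observations of one GRS under constant levels."""
    from grslogic.fitting import _predict_batch
    x = np.array([*np.log10(params.kd), np.log10(params.ksyn),
                  np.log10(params.kproc), -6.0])[None, :]
    y = _predict_batch(params.logic, x, levels, list(TP), True, None)[0]
    return np.repeat(y[..., None], n_rep, axis=-1)


class TestModelNLL:
    def test_additive_over_conditions(self):
        levels = _panel_levels()
        truth = GRSParameters(logic="TF1+TF2+TF3", kd=(0.1, 1.0, 10.0))
        y = _noiseless_obs(truth, levels)
        slopes = np.zeros(y.shape[:2])
        total = model_nll(truth, y, levels, PARAMS, slopes=slopes)
        part_a = model_nll(truth, y[:13], levels[:13], PARAMS, slopes=slopes[:13])
        part_b = model_nll(truth, y[13:], levels[13:], PARAMS, slopes=slopes[13:])
        assert total == pytest.approx(part_a + part_b, rel=1e-9)

    def test_single_point_normal_contribution(self):
        """At the mean, a normal-branch point contributes 0.5*log(2*pi*sigma^2)."""
        p = GRSParameters(logic="TF1+TF2+TF3", kd=(1e-9, 1e-9, 1e-9),
                          ksyn=1.0, kproc=0.1)
        levels = np.array([[1.0, 1.0, 1.0]])
        y15 = 10 * (1 - np.exp(-1.5))  # model value at t = 15, above eta
        nll = model_nll(p, np.array([[[y15]]]), levels, PARAMS,
                        slopes=np.zeros((1, 1)), timepoints=[15.0])
        var = PARAMS.alpha0 + PARAMS.alpha2 * y15**2
        assert nll == pytest.approx(0.5 * np.log(2 * np.pi * var), rel=1e-6)

    def test_truth_beats_random_alternatives(self, rng):
        """The generating parameters minimize the NLL against most alternatives."""
        levels = _panel_levels()
        truth = GRSParameters(logic="TF1.(TF2+TF3)", kd=(0.1, 0.1, 1.0),
                              ksyn=1.0, kproc=0.1)
        y = _noiseless_obs(truth, levels)
        slopes = np.zeros(y.shape[:2])
        nll_truth = model_nll(truth, y, levels, PARAMS, slopes=slopes)
        wins = 0
        for _ in range(40):
            alt = GRSParameters(
                logic="TF1.(TF2+TF3)",
                kd=tuple(10 ** rng.uniform(-2, 2, 3)),
                ksyn=10 ** rng.uniform(-1, 1), kproc=10 ** rng.uniform(-2, 1),
            )
            wins += nll_truth <= model_nll(alt, y, levels, PARAMS, slopes=slopes)
        assert wins >= 38  # >= 95%


class TestFitGene:
    def test_recovers_dual_and_from_noiseless_data(self):
        """Strong/Strong dual AND: correct logic, Kd within 2-fold.

        Uses a homoscedastic error model: with the plug-in
        prediction-dependent variance, even noiseless data reward
        slightly smaller predictions (lower variance), biasing the
        optimum off the generating parameters.
        """
        homo = ErrorModelParams(sigma_bg2=0.5, alpha0=1.0, alpha1=0.0,
                                alpha2=0.0, sigma_t2=25.0, mode="time_value")
        levels = _panel_levels()
        truth = GRSParameters(logic="TF1.(TF2+TF3)", kd=(0.1, 0.1, 1e6),
                              ksyn=1.0, kproc=0.1)
        y = _noiseless_obs(truth, levels)
        slopes = np.zeros(y.shape[:2])
        res = fit_all_logics(y, levels, homo, slopes=slopes, gene="dualAND",
                             n_starts=120, seed=5)
        assert res.logic17_label == "TF1.TF2"
        for got, want in zip(res.selected_params.kd[:2], truth.kd[:2]):
            assert 0.5 * want <= got <= 2.0 * want

    def test_kd_respects_bounds(self, rng):
        levels = _panel_levels("simple7")
        y = rng.uniform(0, 50, size=(7, 4, 2))
        y[:, 0, :] = 0.0
        slopes = np.zeros((7, 4))
        res = fit_gene(y, levels, "TF1+TF2+TF3", PARAMS, slopes=slopes,
                       n_starts=40, seed=2)
        assert all(0.01 - 1e-9 <= k <= 100.0 + 1e-6 for k in res["params"].kd)

    def test_multistart_batches_agree(self):
        """Two disjoint start batches reach the same optimum (convergence)."""
        levels = _panel_levels()
        truth = GRSParameters(logic="TF1+TF2+TF3", kd=(0.1, 1.0, 0.1),
                              ksyn=1.0, kproc=0.1)
        y = _noiseless_obs(truth, levels)
        slopes = np.zeros(y.shape[:2])
        a = fit_gene(y, levels, truth.logic, PARAMS, slopes=slopes,
                     n_starts=150, seed=11)
        b = fit_gene(y, levels, truth.logic, PARAMS, slopes=slopes,
                     n_starts=150, seed=12)
        assert a["nll"] == pytest.approx(b["nll"], rel=5e-3)

    def test_more_starts_never_worse(self):
        """Best-so-far NLL is monotone when every start is refined.

        The same seed yields nested start sets, so best-of-n can only
        improve with n under the refine-all contract.
        """
        levels = _panel_levels()
        truth = GRSParameters(logic="TF3+(TF1.TF2)", kd=(0.1, 1.0, 1.0),
                              ksyn=1.0, kproc=0.1)
        y = _noiseless_obs(truth, levels)
        slopes = np.zeros(y.shape[:2])
        nlls = [fit_gene(y, levels, truth.logic, PARAMS, slopes=slopes,
                         n_starts=n, seed=3, n_refine=None)["nll"]
                for n in (5, 25, 80)]
        assert nlls[0] >= nlls[1] - 1e-9 >= nlls[2] - 2e-9


class TestSelectAndMap:
    def _fits(self, nlls, kds=None):
        kds = kds or {}
        out = {}
        for i, logic in enumerate(LOGICS):
            kd = kds.get(logic, (1.0, 1.0, 1.0))
            out[logic] = {
                "nll": nlls[i],
                "params": GRSParameters(logic=logic, kd=kd, ksyn=1.0, kproc=0.1),
                "n_starts": 1,
            }
        return out

    def test_minimal_nll_selected(self):
        nlls = [50.0, 40.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0]
        res = select_and_map(self._fits(nlls), gene="g")
        assert res.selected_logic == "TF1.(TF2+TF3)"
        assert res.selected_nll == 40.0

    def test_null_kd_maps_triple_or_to_single(self):
        label, nulls = map_to_17("TF1+TF2+TF3", (0.5, 150.0, 200.0))
        assert label == "TF1" and nulls == (2, 3)

    def test_all_kd_in_range_keeps_triple_label(self):
        label, nulls = map_to_17("TF1.(TF2+TF3)", (0.5, 2.0, 60.0))
        assert label == "TF1.(TF2+TF3)" and nulls == ()

    def test_one_null_reduces_and_or_to_dual(self):
        label, _ = map_to_17("TF1.(TF2+TF3)", (0.5, 0.3, 120.0))
        assert label == "TF1.TF2"

    def test_tie_resolves_to_fewer_effective_tfs(self):
        nlls = [30.0] * 8
        kds = {"TF1+TF2+TF3": (0.5, 100.0, 100.0)}
        res = select_and_map(self._fits(nlls, kds), gene="g")
        assert res.logic17_label == "TF1"


@pytest.fixture(scope="module")
def small_catalog():
    from grslogic.enumeration import CatalogEntry
    entries = []
    for label, logic, kd in [
        ("g_or", "TF1+TF2+TF3", (0.1, 0.1, 0.1)),
        ("g_and", "TF1.TF2.TF3", (0.1, 0.1, 0.1)),
        ("g_single", "TF1+(TF2.TF3)", (0.1, 1e6, 1e6)),
    ]:
        entries.append(CatalogEntry(
            label=label,
            params=GRSParameters(logic=logic, kd=kd, ksyn=1.0, kproc=0.1)))
    return GRSCatalog(tuple(entries), provenance="test")


class TestIdentifiability:

    def test_duplicate_truth_gives_zero_identifiability(self, small_catalog):
        from dataclasses import replace
        twin = replace(small_catalog.entries[0], label="g_or_twin")
        cat = GRSCatalog(small_catalog.entries + (twin,), provenance="test")
        rep = catalog_identifiability(cat, build_panel("custom", ["HHH", "LHH"]),
                                      4, seed=0)
        i = rep.labels.index("g_or")
        assert abs(rep.values[i]) < 30  # residual is noise-level only

    def test_distance_metric_nonnegative_and_zero_for_twins(self, small_catalog):
        from dataclasses import replace
        twin = replace(small_catalog.entries[0], label="g_or_twin")
        cat = GRSCatalog(small_catalog.entries + (twin,), provenance="test")
        rep = catalog_identifiability(cat, build_panel("amplitude26"), 2,
                                      metric="min_sq_distance")
        assert np.all(rep.values >= 0)
        assert rep.values[rep.labels.index("g_or")] == pytest.approx(0.0, abs=1e-9)

    def test_catalog_of_one_rejected(self, small_catalog):
        solo = GRSCatalog(small_catalog.entries[:1], provenance="test")
        with pytest.raises(ConfigurationError):
            catalog_identifiability(solo, build_panel("simple7"), 2)

    def test_symmetric_nll_distance_properties(self, retained, amplitude_panel):
        resp = panel_response(retained, amplitude_panel)[:6]
        d01 = symmetric_nll_distance(resp[0], resp[1], PARAMS)
        d10 = symmetric_nll_distance(resp[1], resp[0], PARAMS)
        assert d01 == pytest.approx(d10, rel=1e-12)
        d00 = symmetric_nll_distance(resp[0], resp[0], PARAMS)
        others = [symmetric_nll_distance(resp[0], resp[j], PARAMS)
                  for j in range(1, 6)]
        assert all(d00 < o for o in others)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            symmetric_nll_distance(np.zeros((3, 4)), np.zeros((2, 4)), PARAMS)


class TestEvaluateDesign:
    def test_budget_and_empty_checks(self, retained):
        with pytest.raises(ConfigurationError):
            evaluate_design(10, [], retained)
        big = [("too_big", build_panel("amplitude26"), 2)]
        with pytest.raises(ConfigurationError):
            evaluate_design(10, big, retained)

    def test_more_replicates_raise_identifiability(self, retained):
        panel = build_panel("custom", ["HHH", "LHH", "HLH", "HHL"])
        designs = [("x2", panel, 2), ("x13", panel, 13)]
        df = evaluate_design(52, designs, retained, seed=77)
        med = dict(zip(df["design"], df["median_identifiability"]))
        assert med["x13"] > med["x2"]
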