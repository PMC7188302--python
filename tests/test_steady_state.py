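"""Fold-changes, pooled t-test, BH correction, volcano calls, correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metadyn.preprocess import TimeSeries, normalize_to_protein, preprocess_panel
from metadyn.steady_state import (
    bh_adjust,
    fold_change,
    pearson_fc_matrix,
    steady_state_table,
    ttest_steady_states,
)
from metadyn.synthetic import SimConfig, generate_panel, make_metabolome

from conftest import STUDY_GRID, brute_force_bh


def _ts(mean, times=STUDY_GRID):
    mean = np.asarray(mean, dtype=float)
    return TimeSeries("m", "L", times, mean, np.zeros_like(mean), np.full(mean.size, 3))


class TestFoldChange:
    def test_identical_endpoints_unity(self):
        fc, l2 = fold_change(_ts([10, 10, 11, 12, 11, 10, 10, 10]))
        assert fc == 1.0 and l2 == 0.0

    def test_direct_ratio(self):
        fc, _ = fold_change(_ts([10, 10, 11, 12, 13, 14, 15, 15]))
        assert fc == pytest.approx(1.5)

    def test_final_value_theorem_on_generator_truth(self, clean_panel):
        # zero-noise panel: fc must equal 1 + K*M/y0 exactly
        cfg, mets, panel = clean_panel
        series, _ = preprocess_panel(panel)
        for met in mets[:5]:
            for line in cfg.cell_lines:
                p = met.line_params(line)
                # 120 min is not infinity: use the model's own value at 2 h
                from metadyn.dynamics import step_response

                expect = (
                    met.baseline(line) + float(step_response(p, cfg.step_mM[line], 120.0))
                ) / met.baseline(line)
                fc, _ = fold_change(series[(line, met.name)])
                assert fc == pytest.approx(expect, rel=1e-9)

    def test_missing_endpoint_not_evaluable(self):
        ts = _ts([np.nan, 10, 11, 12, 13, 14, 15, 15])
        assert math.isnan(fold_change(ts)[0])

    def test_invariant_to_global_rescaling(self):
        a = _ts([10, 10, 11, 12, 13, 14, 15, 15])
        b = _ts([v * 7.3 for v in [10, 10, 11, 12, 13, 14, 15, 15]])
        assert fold_change(a)[0] == pytest.approx(fold_change(b)[0])


class TestTTest:
    def test_identical_samples_p_one(self):
        assert ttest_steady_states([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1e-6, 4)
        b = 1.0 + rng.normal(0.0, 1e-6, 4)
        assert ttest_steady_states(a, b) < 1e-4

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([4.1, 5.0, 5.9])
        b = np.array([7.2, 8.1, 6.9])
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4  # pooled, 4 df
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        expect = 2 * stats.t.sf(abs(t), 4)
        assert ttest_steady_states(a, b) == pytest.approx(expect, rel=1e-12)

    def test_degenerate_zero_variance_conventions(self):
        assert ttest_steady_states([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert ttest_steady_states([0.0, 0.0], [1.0, 1.0]) == 0.0


class TestBH:
    def test_single_p(self):
        rej, q = bh_adjust([0.01])
        assert rej[0] and q[0] == pytest.approx(0.01)

    def test_all_ones_rejects_none(self):
        rej, _ = bh_adjust([1.0] * 10)
        assert not rej.any()

    def test_fixed_vector_matches_enumeration(self):
        p = np.array(
            [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216,
             0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569, 0.594, 0.696,
             0.762, 0.94, 0.942, 0.975, 0.986]
        )
        rej, _ = bh_adjust(p, fdr=0.05)
        np.testing.assert_array_equal(rej, brute_force_bh(p, 0.05))

    def test_random_vectors_match_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(1, 21)
            p = rng.random(n) ** rng.uniform(0.5, 3.0)
            rej, _ = bh_adjust(p, fdr=0.05)
            np.testing.assert_array_equal(rej, brute_force_bh(p, 0.05))

    def test_empty_input(self):
        rej, q = bh_adjust([])
        assert rej.size == 0 and q.size == 0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_rejections_equal_enumeration_property(self, pvals, fdr):
        rej, q = bh_adjust(pvals, fdr=fdr)
        np.testing.assert_array_equal(rej, brute_force_bh(np.array(pvals), fdr))
        # rejections are monotone in p
        order = np.argsort(pvals)
        assert not np.any(np.diff(rej[order].astype(int)) > 0)
        assert np.all((q >= 0) & (q <= 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestVolcanoAndCorrelation:
    @pytest.fixture(scope="class")
    def ss(self, small_panel):
        _, _, panel = small_panel
        series, reports = preprocess_panel(panel)
        return steady_state_table(series, reports["normalized"], outliers=reports["outliers"])

    def test_margin_and_test_must_both_hold(self, ss):
        # fc inside the 30% margin is never significant, whatever q
        inside = np.abs(ss["fc"] - 1.0) < 0.30
        assert not ss.loc[inside, "significant"].any()
        # significant calls all rejected by BH and outside the margin
        sig = ss["significant"]
        assert (ss.loc[sig, "q"] <= 0.05).all()
        assert (np.abs(ss.loc[sig, "fc"] - 1.0) >= 0.30).all()

    def test_direction_follows_fold_change(self, ss):
        sig = ss[ss["significant"]]
        assert (sig.loc[sig["fc"] > 1, "direction"] == "up").all()
        assert (sig.loc[sig["fc"] < 1, "direction"] == "down").all()

    def test_self_correlation_is_one(self, ss):
        mat = pearson_fc_matrix(ss)
        assert np.allclose(np.diag(mat), 1.0)

    def test_type_structured_gains_correlate_within_type(self, small_panel):
        cfg, _, panel = small_panel
        series, reports = preprocess_panel(panel)
        ss = steady_state_table(series, reports["normalized"], outliers=reports["outliers"])
        mat = pearson_fc_matrix(ss)
        within = [mat.loc["hiPSC_1", "hiPSC_2"], mat.loc["hNSC_1", "hNSC_2"]]
        between = [
            mat.loc[a, b]
            for a in ("hiPSC_1", "hiPSC_2")
            for b in ("hNSC_1", "hNSC_2")
        ]
        assert min(within) > max(between)

    def test_unchanged_metabolites_rarely_called(self):
        # flat ground truth with realistic noise: volcano calls on unchanged
        # metabolites stay within the nominal error rate
        cfg = SimConfig(seed=6)
        mets = make_metabolome(
            cfg, n_total=40, n_lod_bad=0, n_cv_bad=0, frac_flat=1.0,
            frac_all_shared=0.0, frac_type_shared=0.0,
        )
        panel = generate_panel(cfg, mets)
        series, reports = preprocess_panel(panel)
        ss = steady_state_table(series, reports["normalized"], outliers=reports["outliers"])
        flat = ss["metabolite"] != "Gln"  # glutamine itself genuinely responds
        assert ss.loc[flat, "significant"].mean() <= 0.05

    def test_zero_noise_identical_truth_perfect_correlation(self):
        # two lines sharing ground truth exactly and no noise: r = 1
        cfg = SimConfig(seed=1, noise_cv=0.0, protein_cv=0.0, lod_censoring=False)
        mets = make_metabolome(cfg, n_total=12, n_lod_bad=0, n_cv_bad=0)
        for m in mets:  # force identical kinetics/baselines in the hiPSC pair
            if isinstance(m.params, dict):
                m.params["hiPSC_2"] = m.params["hiPSC_1"]
                m.y0["hiPSC_2"] = m.y0["hiPSC_1"]
        panel = generate_panel(cfg, mets)
        series, reports = preprocess_panel(panel)
        ss = steady_state_table(series, reports["normalized"])
        mat = pearson_fc_matrix(ss)
        assert mat.loc["hiPSC_1", "hiPSC_2"] == pytest.approx(1.0, abs=1e-9)
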