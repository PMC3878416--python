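import numpy as np
import pandas as pd
import pytest

from metphase import presets
from metphase.mixed_model import fit_reml, spec_model
from metphase.ranking import (
    RankedList,
    concordance_report,
    overlap,
    scatter_frame,
    selection_index,
    top_k,
)

from conftest import make_met_dataset


def _ranked(trial, model, entries, k=None):
    df = pd.DataFrame(entries, columns=["cultivar", "value"])
    return RankedList(trial=trial, model=model, k=k or len(df), entries=df)


class TestTopK:
    def test_k_equal_count_returns_all(self, fits_abc):
        fit = fits_abc["C"]
        trial = fit.trials[0]
        m = len(fit.g_indices(trial))
        ranked = top_k(fit, trial, m)
        assert len(ranked.entries) == m

    def test_values_non_increasing(self, fits_abc):
        ranked = top_k(fits_abc["C"], fits_abc["C"].trials[0], 10)
        assert (np.diff(ranked.entries["value"]) <= 1e-12).all()

    def test_model_a_uses_raw_means(self, fits_abc):
        fit = fits_abc["A"]
        trial = fit.trials[0]
        ranked = top_k(fit, trial, 5)
        raw = fit.raw_means[fit.raw_means["trial"] == trial]
        best = raw.sort_values(["raw_mean", "cultivar"], ascending=[False, True]).head(5)
        assert ranked.cultivars == list(best["cultivar"])

    def test_ties_lexicographic_and_flagged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "trial": "t1",
                "cultivar": np.repeat(["b", "a", "c"], 4),
                "sugar": np.concatenate([[5.0] * 4, [5.0] * 4, [1.0] * 4])
                + np.tile([0.1, -0.1, 0.2, -0.2], 3),
            }
        )
        fit = fit_reml(spec_model("A", df), df)
        ranked = top_k(fit, "t1", 2)
        assert ranked.cultivars == ["a", "b"]  # equal means -> lexicographic
        assert set(ranked.tied) == {"a", "b"}

    def test_k_too_large_rejected(self, fits_abc):
        fit = fits_abc["A"]
        with pytest.raises(ValueError):
            top_k(fit, fit.trials[0], 10_000)

    def test_unknown_trial_rejected(self, fits_abc):
        with pytest.raises(KeyError):
            top_k(fits_abc["A"], "nope", 5)

    def test_spiked_cultivar_ranks_first(self):
        # +5 SD genetic spike-in recovers rank 1 in >= 95% of seeds; the
        # non-genetic variances are scaled down so measurement noise does
        # not drown a 5-SD effect at this small cultivar count
        from metphase.simulate import VarianceComponents

        vc_full = presets.default_variance_components()
        vc = VarianceComponents(
            terms={t: {k: v / 10 for k, v in m.items()} for t, m in vc_full.terms.items()},
            genetic=vc_full.genetic,
            residual={t: v / 10 for t, v in vc_full.residual.items()},
            genetic_correlation=vc_full.genetic_correlation,
        )
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table, _, _, _ = make_met_dataset(
                n_cultivars=30, n_blocks=3, dup_count=2, seed=1000 + seed,
                trials=(presets.TRIAL_2010,), vc=vc,
            )
            boost = 5 * np.sqrt(presets.GENETIC_VAR[presets.TRIAL_2010])
            mask = table["cultivar"] == "CV007"
            table.loc[mask, "sugar"] += boost
            fit = fit_reml(spec_model("A", table), table)
            if top_k(fit, presets.TRIAL_2010, 1).cultivars == ["CV007"]:
                hits += 1
        assert hits >= 95


class TestOverlap:
    def test_identical_lists(self):
        a = _ranked("t1", "A", [("x", 3.0), ("y", 2.0)])
        assert overlap(a, a) == (2, ["x", "y"])

    def test_disjoint_lists(self):
        a = _ranked("t1", "A", [("x", 3.0), ("y", 2.0)])
        b = _ranked("t2", "A", [("p", 3.0), ("q", 2.0)])
        assert overlap(a, b)[0] == 0

    def test_constructed_overlap_25(self):
        shared = [(f"s{i}", 50.0 - i) for i in range(25)]
        a = _ranked("t1", "C", shared + [(f"a{i}", 10.0 - i) for i in range(15)], k=40)
        b = _ranked("t2", "C", shared + [(f"b{i}", 10.0 - i) for i in range(15)], k=40)
        count, ids = overlap(a, b)
        assert count == 25
        assert ids == sorted(s for s, _ in shared)

    def test_differing_k_rejected(self):
        a = _ranked("t1", "A", [("x", 1.0)])
        b = _ranked("t1", "A", [("x", 1.0), ("y", 0.5)])
        with pytest.raises(ValueError):
            overlap(a, b)

    def test_symmetric_and_bounded(self, fits_abc):
        fit = fits_abc["C"]
        t1, t2 = fit.trials
        a, b = top_k(fit, t1, 15), top_k(fit, t2, 15)
        assert overlap(a, b)[0] == overlap(b, a)[0] <= 15


class TestSelectionIndex:
    def test_equal_effects_give_common_value(self, fits_abc):
        fit = fits_abc["C"]
        t1, t2 = fit.trials
        idx = selection_index(fit, {t1: 0.5, t2: 0.5}).set_index("cultivar")["index"]
        p1, p2 = fit.predictions(t1), fit.predictions(t2)
        c = p1.index[0]
        assert idx[c] == pytest.approx((p1[c] + p2[c]) / 2)

    def test_degenerate_weights(self, fits_abc):
        fit = fits_abc["C"]
        t1, t2 = fit.trials
        idx = selection_index(fit, {t1: 1.0, t2: 0.0}).set_index("cultivar")["index"]
        p1 = fit.predictions(t1)
        for c in p1.index[:5]:
            assert idx[c] == pytest.approx(p1[c])

    def test_negative_weights_rejected(self, fits_abc):
        fit = fits_abc["C"]
        t1, t2 = fit.trials
        with pytest.raises(ValueError):
            selection_index(fit, {t1: 1.5, t2: -0.5})

    def test_index_beats_single_trial_ranking(self):
        # equal-weight index correlates with the true genetic mean at least as
        # well as either single-trial ranking, averaged over seeds
        from scipy.stats import spearmanr

        from metphase.simulate import VarianceComponents

        diffs = []
        for seed in range(20):
            vc = presets.default_variance_components()
            # genetics-dominated configuration with high cross-trial correlation
            vc_strong = VarianceComponents(
                terms={t: {k: v / 10 for k, v in m.items()} for t, m in vc.terms.items()},
                genetic=vc.genetic,
                residual=vc.residual,
                genetic_correlation=0.9,
            )
            table, term_lists, _, _ = make_met_dataset(
                n_cultivars=40, n_blocks=2, dup_count=2, seed=3000 + seed, vc=vc_strong
            )
            truth = (
                table[~table["is_standard"]]
                .groupby("cultivar")["sugar"]
                .mean()
            )
            fit = fit_reml(spec_model("C", table, term_lists), table)
            t1, t2 = fit.trials
            idx = selection_index(fit, {t1: 0.5, t2: 0.5}).set_index("cultivar")["index"]
            common = truth.index.intersection(idx.index)
            r_idx = spearmanr(truth[common], idx[common]).statistic
            r_single = max(
                spearmanr(truth[common], fit.predictions(t)[common]).statistic
                for t in (t1, t2)
            )
            diffs.append(r_idx - r_single)
        assert np.mean(diffs) >= -0.01


class TestConcordance:
    def test_single_model_report(self, fits_abc):
        report = concordance_report({"C": fits_abc["C"]}, k=15)
        assert set(report["cross_trial"]) == {"C"}
        assert report["cross_model"] == {}

    def test_full_report_structure(self, fits_abc):
        report = concordance_report(fits_abc, k=15)
        assert set(report["cross_trial"]) == {"A", "B", "C"}
        for trial, pairs in report["cross_model"].items():
            assert set(pairs) == {"A-B", "A-C", "B-C"}
            for v in pairs.values():
                assert 0 <= v <= 15

    def test_ranking_shift_invariance(self, fits_abc):
        import dataclasses

        fit = fits_abc["C"]
        trial = fit.trials[0]
        shifted = dataclasses.replace(
            fit, fixed_estimates={t: v + 100.0 for t, v in fit.fixed_estimates.items()}
        )
        assert top_k(fit, trial, 10).cultivars == top_k(shifted, trial, 10).cultivars


class TestScatter:
    def test_scatter_frame_columns(self, fits_abc):
        fit = fits_abc["C"]
        df = scatter_frame(fit, k=15)
        t1, t2 = fit.trials
        assert {"cultivar", f"pred_{t1}", f"pred_{t2}", "consistent"} <= set(df.columns)
        assert df["consistent"].sum() <= 15
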