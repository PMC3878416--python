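import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from metphase import presets
from metphase.designs import generate_field_design, generate_lab_design
from metphase.simulate import (
    DEFAULT_STANDARD_MEANS,
    TrialMeans,
    VarianceComponents,
    assemble_observations,
    inject_missingness,
    simulate_met,
)

from conftest import make_met_dataset


def _zero_vc(trials=("t1", "t2"), **overrides):
    terms = {t: dict.fromkeys(presets.TERM_SETS.get(t, ()), 0.0) for t in trials}
    vc = dict(
        terms={t: {} for t in trials},
        genetic={t: 0.0 for t in trials},
        residual={t: 0.0 for t in trials},
        genetic_correlation=0.0,
    )
    vc.update(overrides)
    return VarianceComponents(**vc)


@pytest.fixture(scope="module")
def small_designs():
    cvs = [f"CV{i:03d}" for i in range(40)]
    fds, lds = {}, {}
    for trial in ("t1", "t2"):
        fds[trial] = generate_field_design(cvs, 2, 8, seed=1, trial=trial)
        lds[trial] = generate_lab_design(
            {1: cvs, 2: cvs}, dup_count=2, plates_per_day=2, seed=2, trial=trial
        )
    return fds, lds


class TestValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            VarianceComponents(
                terms={"t1": {"F_block": -1.0}}, genetic={"t1": 1.0}, residual={"t1": 1.0}
            )

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            VarianceComponents(
                terms={"t1": {"bogus": 1.0}}, genetic={"t1": 1.0}, residual={"t1": 1.0}
            )

    def test_correlation_bounds(self):
        with pytest.raises(ValueError):
            VarianceComponents(
                terms={}, genetic={"t1": 1.0}, residual={"t1": 1.0}, genetic_correlation=1.2
            )

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValueError):
            TrialMeans(means={"t1": float("nan")})


class TestSimulateMet:
    def test_zero_variance_gives_trial_means(self, small_designs):
        fds, lds = small_designs
        means = TrialMeans(means={"t1": 93.3, "t2": 54.0})
        tab = simulate_met(fds, lds, _zero_vc(), means, seed=0)
        for trial, mu in (("t1", 93.3), ("t2", 54.0)):
            vals = tab.loc[(tab["trial"] == trial) & ~tab["is_standard"], "sugar"]
            assert (vals == mu).all()

    def test_standards_get_their_fixed_means(self, small_designs):
        fds, lds = small_designs
        tab = simulate_met(fds, lds, _zero_vc(), TrialMeans(means={"t1": 0, "t2": 0}), seed=0)
        std = tab[tab["is_standard"]]
        for sid, mu in DEFAULT_STANDARD_MEANS.items():
            assert (std.loc[std["cultivar"] == sid, "sugar"] == mu).all()

    def test_tech_reps_share_all_sample_level_effects(self, small_designs):
        # wells of one plate plot share every effect except the residual and
        # the laboratory terms indexed by plate row (which vary across the
        # four wells by construction)
        vc_full = presets.default_variance_components()
        row_terms = {"L_row", "L_rowxcol", "L_platexrow"}
        vc_nores = VarianceComponents(
            terms={
                t: {k: v for k, v in m.items() if k not in row_terms}
                for t, m in vc_full.terms.items()
            },
            genetic=vc_full.genetic,
            residual={presets.TRIAL_2010: 0.0, presets.TRIAL_2011: 0.0},
            genetic_correlation=vc_full.genetic_correlation,
        )
        cvs = [f"CV{i:03d}" for i in range(40)]
        fds2 = {t: generate_field_design(cvs, 2, 8, seed=1, trial=t) for t in vc_full.genetic}
        lds2 = {
            t: generate_lab_design({1: cvs, 2: cvs}, 2, 2, seed=2, trial=t)
            for t in vc_full.genetic
        }
        tab = simulate_met(fds2, lds2, vc_nores, presets.default_trial_means(), seed=4)
        spread = tab.groupby(["trial", "plate", "plate_plot"])["sugar"].agg(np.ptp)
        assert (spread == 0).all()
        # with residual back on, replicates differ
        vc_res = VarianceComponents(
            terms=vc_nores.terms,
            genetic=vc_full.genetic,
            residual=presets.RESIDUAL_VAR,
            genetic_correlation=vc_full.genetic_correlation,
        )
        tab2 = simulate_met(fds2, lds2, vc_res, presets.default_trial_means(), seed=4)
        spread2 = tab2.groupby(["trial", "plate", "plate_plot"])["sugar"].agg(np.ptp)
        assert (spread2 > 0).all()

    def test_reproducible_from_seed(self, small_designs):
        fds, lds = small_designs
        vc = _zero_vc(genetic={"t1": 4.0, "t2": 4.0}, residual={"t1": 1.0, "t2": 1.0})
        means = TrialMeans(means={"t1": 10, "t2": 10})
        a = simulate_met(fds, lds, vc, means, seed=11)
        b = simulate_met(fds, lds, vc, means, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_random_term_draw_variance(self):
        # one draw per plate plot at variance 54; sample variance inside the
        # two-sided 99.9% chi-square bracket for the realised level count
        cvs = [f"CV{i:04d}" for i in range(640)]
        fd = generate_field_design(cvs, 5, 8, seed=0, trial="t1")
        ld = generate_lab_design({b: cvs for b in range(1, 6)}, 20, 4, seed=0, trial="t1")
        vc = VarianceComponents(
            terms={"t1": {"L_platexplot": 54.0}}, genetic={"t1": 0.0}, residual={"t1": 0.0}
        )
        tab = simulate_met({"t1": fd}, {"t1": ld}, vc, TrialMeans(means={"t1": 0.0}), seed=3)
        tab = tab[~tab["is_standard"]]
        effects = tab.groupby(["plate", "plate_plot"])["sugar"].first()
        n = len(effects)
        assert n >= 3000
        s2 = effects.var(ddof=1)
        lo = 54.0 * chi2.ppf(0.0005, n - 1) / (n - 1)
        hi = 54.0 * chi2.ppf(0.9995, n - 1) / (n - 1)
        assert lo < s2 < hi

    def test_genetic_correlation_converges(self):
        # >= 5000 shared cultivars, all other variances zero
        cvs = [f"CV{i:05d}" for i in range(5000)]
        fds, lds = {}, {}
        for trial in ("t1", "t2"):
            fds[trial] = generate_field_design(cvs, 1, 8, seed=5, trial=trial)
            lds[trial] = generate_lab_design({1: cvs}, 0, 4, seed=6, trial=trial)
        vc = _zero_vc(genetic={"t1": 13.5, "t2": 6.9}, genetic_correlation=0.66)
        tab = simulate_met(fds, lds, vc, TrialMeans(means={"t1": 0, "t2": 0}), seed=7)
        tab = tab[~tab["is_standard"]]
        g = tab.groupby(["trial", "cultivar"])["sugar"].first().unstack(level=0)
        r = g["t1"].corr(g["t2"])
        se = (1 - 0.66**2) / np.sqrt(len(g))
        assert abs(r - 0.66) < 4 * se
        assert abs(g["t1"].var(ddof=1) - 13.5) < 1.0
        assert abs(g["t2"].var(ddof=1) - 6.9) < 0.6

    def test_method_of_moments_recovery(self):
        # genetic + residual only: balanced one-way ANOVA estimators recover
        # the generating values (independent of the REML engine)
        cvs = [f"CV{i:04d}" for i in range(400)]
        fd = generate_field_design(cvs, 3, 8, seed=8, trial="t1")
        ld = generate_lab_design({b: cvs for b in (1, 2, 3)}, 0, 4, seed=9, trial="t1")
        vc = _zero_vc(trials=("t1",), genetic={"t1": 9.0}, residual={"t1": 4.0})
        tab = simulate_met({"t1": fd}, {"t1": ld}, vc, TrialMeans(means={"t1": 50}), seed=10)
        tab = tab[~tab["is_standard"]]
        r = tab.groupby("cultivar")["sugar"].count().iloc[0]
        msb = tab.groupby("cultivar")["sugar"].mean().var(ddof=1) * r
        msw = tab.groupby("cultivar")["sugar"].var(ddof=1).mean()
        assert msw == pytest.approx(4.0, rel=0.1)
        assert (msb - msw) / r == pytest.approx(9.0, rel=0.25)

    def test_mismatched_trials_rejected(self, small_designs):
        fds, lds = small_designs
        with pytest.raises(ValueError, match="same trials"):
            simulate_met({"t1": fds["t1"]}, lds, _zero_vc(), TrialMeans(means={"t1": 0}), seed=0)


class TestAssemble:
    def test_lab_sample_without_field_pot_rejected(self, small_designs):
        fds, lds = small_designs
        fd = fds["t1"]
        bad_field = generate_field_design(
            [f"CV{i:03d}" for i in range(1, 40)], 2, 8, seed=1, trial="t1"
        )  # drops CV000
        with pytest.raises(ValueError, match="CV000"):
            assemble_observations(bad_field, lds["t1"])

    def test_standards_have_no_field_position(self, small_designs):
        fds, lds = small_designs
        obs = assemble_observations(fds["t1"], lds["t1"])
        assert obs.loc[obs["is_standard"], "field_row"].isna().all()
        assert obs.loc[~obs["is_standard"], "field_row"].notna().all()


@pytest.fixture(scope="module")
def table():
    cvs = [f"CV{i:04d}" for i in range(640)]
    fd = generate_field_design(cvs, 1, 8, seed=0, trial="t1")
    ld = generate_lab_design({1: cvs}, 0, 4, seed=0, trial="t1")
    return simulate_met(
        {"t1": fd}, {"t1": ld}, _zero_vc(trials=("t1",)), TrialMeans(means={"t1": 1.0}),
        seed=0,
    )


class TestMissingness:
    def test_rate_zero_identity(self, table):
        out = inject_missingness(table, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, table)

    def test_eight_of_640_removed(self, table):
        # seed realising the expectation 640 * 0.0125 = 8 exactly
        out = inject_missingness(table, 0.0125, seed=6)
        removed = (len(table) - len(out)) // 4
        assert removed == 8

    def test_whole_samples_removed(self, table):
        out = inject_missingness(table, 0.2, seed=3)
        counts = out[~out["is_standard"]].groupby(["plate", "plate_plot"]).size()
        assert (counts == 4).all()

    def test_standards_never_removed(self, table):
        out = inject_missingness(table, 0.5, seed=4)
        assert out["is_standard"].sum() == table["is_standard"].sum()

    def test_rate_one_rejected(self, table):
        with pytest.raises(ValueError):
            inject_missingness(table, 1.0, seed=0)


def test_trial1_raw_mean_near_target():
    # single reduced-scale draw; tolerance from the analytic SD of the mean
    table, _, _, _ = make_met_dataset(n_cultivars=60, n_blocks=3, seed=17)
    sub = table[(table["trial"] == presets.TRIAL_2010) & ~table["is_standard"]]
    # block effects dominate the sampling error of the overall mean
    sd = np.sqrt(54.0 / 3 + 32.2 / 5 + 28.3 / 10)
    assert abs(sub["sugar"].mean() - 93.3) < 3 * sd
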