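import numpy as np
import pandas as pd
import pytest

from metphase import presets
from metphase.designs import generate_field_design, generate_lab_design
from metphase.simulate import VarianceComponents, simulate_met

TRIALS = (presets.TRIAL_2010, presets.TRIAL_2011)


def preset_vc() -> VarianceComponents:
    return presets.default_variance_components()


def make_met_dataset(
    n_cultivars=40,
    n_blocks=2,
    dup_count=2,
    seed=0,
    plates_per_day=2,
    vc=None,
    means=None,
    trials=TRIALS,
):
    """Two-trial dataset with the preset variance structure at small scale."""
    cvs = [f"CV{i:03d}" for i in range(n_cultivars)]
    seq = np.random.SeedSequence(seed).spawn(3)
    fds, lds = {}, {}
    for ti, trial in enumerate(trials):
        fds[trial] = generate_field_design(
            cvs, n_blocks=n_blocks, n_rows=8, seed=int(seq[0].generate_state(1)[0]) + ti,
            trial=trial,
        )
        lds[trial] = generate_lab_design(
            {b: cvs for b in range(1, n_blocks + 1)},
            dup_count=dup_count,
            plates_per_day=plates_per_day,
            seed=int(seq[1].generate_state(1)[0]) + ti,
            trial=trial,
        )
    vc = vc or preset_vc()
    means = means or presets.default_trial_means()
    table = simulate_met(fds, lds, vc, means, seed=int(seq[2].generate_state(1)[0]))
    term_lists = {t: list(presets.TERM_SETS[t]) for t in trials}
    return table, term_lists, fds, lds


def make_oneway(n_groups=20, reps=5, g_var=4.0, e_var=2.0, mean=10.0, seed=0, trial="t1"):
    """Balanced one-way dataset (groups x reps) with known components."""
    rng = np.random.default_rng(seed)
    gids = [f"g{i:03d}" for i in range(n_groups)]
    eff = rng.normal(0, np.sqrt(g_var), n_groups)
    y = mean + np.repeat(eff, reps) + rng.normal(0, np.sqrt(e_var), n_groups * reps)
    return pd.DataFrame({"trial": trial, "cultivar": np.repeat(gids, reps), "sugar": y})


@pytest.fixture(scope="session")
def met_small():
    """Shared two-trial dataset (80 cultivars x 3 blocks x 4 tech reps)."""
    table, term_lists, fds, lds = make_met_dataset(
        n_cultivars=80, n_blocks=3, dup_count=3, seed=101
    )
    return {"table": table, "term_lists": term_lists, "field": fds, "lab": lds}


@pytest.fixture(scope="session")
def fits_abc(met_small):
    """Model A/B/C fits of the shared small dataset."""
    from metphase.mixed_model import fit_reml, spec_model

    table = met_small["table"]
    fits = {}
    for kind in ("A", "B", "C"):
        spec = spec_model(kind, table, None if kind == "A" else met_small["term_lists"])
        fits[kind] = fit_reml(spec, table)
    return fits
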