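"""Simulation-based validation harnesses.

Scaled-down parameter-recovery studies: simulate the two-trial structure
at the preset variance components, fit the model variants, and collect
variance estimates, the genetic correlation, per-trial heritabilities and
cross-trial top-k overlaps across seeds.  Also a replicated estimate of
the simulated trial mean at the full first-year design size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import presets
from .designs import generate_field_design, generate_lab_design
from .mixed_model import FitOptions, fit_reml, heritability, spec_model
from .ranking import overlap, top_k
from .simulate import simulate_met

#: reduced recovery configuration: shared cultivars x blocks x 2 trials x 4 reps
RECOVERY_CULTIVARS = 100
RECOVERY_BLOCKS = 3
RECOVERY_DUPS = 4  # duplicates keep plate-level terms separable from sample terms
RECOVERY_PLATES_PER_DAY = 2  # several days per block de-confounds days from blocks


def recovery_dataset(seed: int, n_cultivars: int = RECOVERY_CULTIVARS,
                     n_blocks: int = RECOVERY_BLOCKS):
    """One simulated two-trial dataset at the preset variance components."""
    cvs = [f"CV{i:04d}" for i in range(n_cultivars)]
    seq = np.random.SeedSequence(seed).spawn(3)
    fds, lds = {}, {}
    for ti, trial in enumerate((presets.TRIAL_2010, presets.TRIAL_2011)):
        fds[trial] = generate_field_design(
            cvs, n_blocks=n_blocks, n_rows=8,
            seed=int(seq[0].generate_state(1)[0]) + ti, trial=trial,
        )
        lds[trial] = generate_lab_design(
            {b: cvs for b in range(1, n_blocks + 1)},
            dup_count=RECOVERY_DUPS,
            plates_per_day=RECOVERY_PLATES_PER_DAY,
            seed=int(seq[1].generate_state(1)[0]) + ti,
            trial=trial,
        )
    table = simulate_met(
        fds, lds, presets.default_variance_components(), presets.default_trial_means(),
        seed=int(seq[2].generate_state(1)[0]),
    )
    term_lists = {t: list(presets.TERM_SETS[t]) for t in presets.TERM_SETS}
    return table, term_lists


def recovery_trial(seed: int, models=("A", "B", "C"), k: int = 40,
                   fit_opts: FitOptions | None = None) -> dict:
    """Simulate one dataset and fit the requested models.

    Returns a record with, per model: variance estimates, heritabilities
    and the cross-trial top-k overlap; plus the model-C genetic
    correlation.  Dropped (boundary) terms enter as variance 0.
    """
    table, term_lists = recovery_dataset(seed)
    record: dict = {"seed": seed}
    for kind in models:
        spec = spec_model(kind, table, None if kind == "A" else term_lists)
        fit = fit_reml(spec, table, fit_opts)
        est = {f"genetic:{t}": fit.params.g_var[t] for t in fit.trials}
        for key in spec.random_terms:
            est[f"{key[0]}:{key[1]}"] = fit.params.term_var.get(key, 0.0)
        est.update({f"residual:{t}": fit.params.resid[t] for t in fit.trials})
        t1, t2 = fit.trials
        record[kind] = {
            "loglik": fit.loglik,
            "estimates": est,
            "heritability": {t: heritability(fit, t) for t in fit.trials},
            "overlap": overlap(top_k(fit, t1, k), top_k(fit, t2, k))[0],
        }
        if kind == "C":
            record["rho"] = fit.params.rho
    return record


def recovery_study(n_seeds: int, base_seed: int = 0, models=("A", "B", "C"),
                   k: int = 40) -> list[dict]:
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(base_seed).spawn(n_seeds)]
    return [recovery_trial(s, models=models, k=k) for s in seeds]


def generating_values() -> dict[str, float]:
    """The generating variance components keyed like the recovery estimates."""
    truth = {}
    for trial, terms in (
        (presets.TRIAL_2010, presets.VC_TERMS_2010),
        (presets.TRIAL_2011, presets.VC_TERMS_2011),
    ):
        truth[f"genetic:{trial}"] = presets.GENETIC_VAR[trial]
        for term, v in terms.items():
            truth[f"{trial}:{term}"] = v
        truth[f"residual:{trial}"] = presets.RESIDUAL_VAR[trial]
    return truth


def recovery_summary(records: list[dict], kind: str = "C") -> pd.DataFrame:
    """Mean, Monte-Carlo SE and truth per variance parameter."""
    rows = []
    truth = generating_values()
    frame = pd.DataFrame([r[kind]["estimates"] for r in records])
    for name in frame.columns:
        vals = frame[name].to_numpy(float)
        rows.append(
            {
                "parameter": name,
                "truth": truth[name],
                "mean": float(vals.mean()),
                "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            }
        )
    return pd.DataFrame(rows)


def simulated_trial_mean(n_reps: int, seed: int, trial: str = presets.TRIAL_2010) -> float:
    """Replicated raw-mean estimate of the simulated first-year trial.

    Builds the full-size first-year designs (648 cultivars, 5 blocks, 640
    available + 20 duplicated samples per block) once, then redraws all
    random effects ``n_reps`` times and averages the per-replicate raw
    means of the non-standard wells.  Replication shrinks the Monte-Carlo
    error of the mean (a single draw has an SD of several units because
    only a handful of block and day effects are averaged).
    """
    layout = presets.LAYOUT_2010 if trial == presets.TRIAL_2010 else presets.LAYOUT_2011
    cvs = [f"CV{i:04d}" for i in range(layout.n_cultivars)]
    seq = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(seq[0])
    fd = generate_field_design(
        cvs, n_blocks=layout.n_blocks, n_rows=layout.n_rows,
        seed=int(seq[1].generate_state(1)[0]), trial=trial,
    )
    available = {
        b: sorted(rng.choice(cvs, size=layout.available_per_block, replace=False))
        for b in range(1, layout.n_blocks + 1)
    }
    ld = generate_lab_design(
        available, dup_count=layout.dup_count, plates_per_day=layout.plates_per_day,
        seed=int(seq[1].generate_state(1)[0]), trial=trial,
    )
    vc = presets.default_variance_components()
    means = presets.default_trial_means()
    rep_seeds = np.random.SeedSequence(int(seq[2].generate_state(1)[0])).spawn(n_reps)
    acc = 0.0
    for rs in rep_seeds:
        tab = simulate_met({trial: fd}, {trial: ld}, vc, means,
                           seed=int(rs.generate_state(1)[0]))
        acc += float(tab.loc[~tab["is_standard"], "sugar"].mean())
    return acc / n_reps
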