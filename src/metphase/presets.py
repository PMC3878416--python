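"""Default two-trial configuration presets.

The shipped defaults reproduce the layout counts and variance magnitudes
of the original two-year barley screening campaign: trial means 93.3 and
54.0 nmol glucose/mg DM, per-trial field/laboratory variance components,
per-trial genetic variances with cross-trial genetic correlation 0.66,
and partial cultivar overlap (639 cultivars shared between the 648- and
856-entry years).
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import TrialMeans, VarianceComponents

TRIAL_2010 = "trial2010"
TRIAL_2011 = "trial2011"

#: Field/laboratory variance components with a non-zero estimate per trial.
VC_TERMS_2010: dict[str, float] = {
    "F_block": 54.0,
    "F_column": 2.1,
    "F_row": 0.4,
    "F_rowxcol": 16.8,
    "L_day": 32.2,
    "L_dayxplate": 28.3,
    "L_platexplot": 37.5,
    "L_column": 4.1,
    "L_row": 12.8,
    "L_platexrow": 32.5,
    "L_rowxcol": 1.6,
}

VC_TERMS_2011: dict[str, float] = {
    "F_block": 0.7,
    "F_column": 0.8,
    "F_rowxcol": 19.1,
    "L_day": 1.6,
    "L_dayxplate": 10.0,
    "L_platexplot": 18.3,
    "L_column": 4.8,
    "L_row": 8.5,
    "L_platexcolumn": 2.7,
    "L_platexrow": 7.4,
    "L_rowxcol": 0.7,
}

GENETIC_VAR = {TRIAL_2010: 13.5, TRIAL_2011: 6.9}
RESIDUAL_VAR = {TRIAL_2010: 27.4, TRIAL_2011: 11.5}
GENETIC_CORRELATION = 0.66

TRIAL_MEANS = {TRIAL_2010: 93.3, TRIAL_2011: 54.0}

#: Realized random-term sets per trial (terms with a non-zero estimate).
TERM_SETS = {
    TRIAL_2010: tuple(VC_TERMS_2010),
    TRIAL_2011: tuple(VC_TERMS_2011),
}


def default_variance_components() -> VarianceComponents:
    return VarianceComponents(
        terms={TRIAL_2010: dict(VC_TERMS_2010), TRIAL_2011: dict(VC_TERMS_2011)},
        genetic=dict(GENETIC_VAR),
        residual=dict(RESIDUAL_VAR),
        genetic_correlation=GENETIC_CORRELATION,
    )


def default_trial_means() -> TrialMeans:
    return TrialMeans(means=dict(TRIAL_MEANS))


@dataclass(frozen=True)
class LayoutPreset:
    """Counts describing one trial's field and laboratory layout."""

    trial: str
    n_cultivars: int
    n_blocks: int
    n_rows: int
    available_per_block: int  # cultivars with a field sample in each block
    dup_count: int
    plates_per_day: int


LAYOUT_2010 = LayoutPreset(
    trial=TRIAL_2010,
    n_cultivars=648,
    n_blocks=5,
    n_rows=8,
    available_per_block=640,
    dup_count=20,
    plates_per_day=4,
)

LAYOUT_2011 = LayoutPreset(
    trial=TRIAL_2011,
    n_cultivars=856,
    n_blocks=5,
    n_rows=8,
    available_per_block=856,
    dup_count=44,
    plates_per_day=4,
)

N_SHARED_CULTIVARS = 639


def preset_cultivars() -> tuple[list[str], list[str]]:
    """Synthetic cultivar id lists for the two trials with 639 shared ids."""
    shared = [f"CV{i:04d}" for i in range(1, N_SHARED_CULTIVARS + 1)]
    only_1 = [f"CVA{i:04d}" for i in range(1, LAYOUT_2010.n_cultivars - N_SHARED_CULTIVARS + 1)]
    only_2 = [f"CVB{i:04d}" for i in range(1, LAYOUT_2011.n_cultivars - N_SHARED_CULTIVARS + 1)]
    return shared + only_1, shared + only_2
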