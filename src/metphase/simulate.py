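"""Phenotype simulation from a declared variance-component structure.

The generating model matches the analysis model exactly: one fixed mean
per trial, a per-cultivar genetic effect drawn jointly across trials
(bivariate normal with the declared cross-trial correlation for cultivars
present in both trials, marginal normal otherwise), independent normal
draws for every field/laboratory random-term level, and an independent
residual per well.  Technical replicates of one sample share everything
except the residual.

Standard samples (plate columns 11–12) receive fixed known true means
plus laboratory effects and residual; they carry no genetic or field
effects and are excluded from model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .designs import EMPTY, FieldDesign, LabDesign
from .factors import TERM_VOCABULARY, is_field_term, term_levels

PHENOTYPE_COLUMNS = [
    "trial",
    "block",
    "field_row",
    "field_column",
    "day",
    "plate",
    "plate_plot",
    "plate_row",
    "plate_column",
    "cultivar",
    "copy",
    "is_standard",
    "sugar",
]

#: Arbitrary true concentrations for the four per-plate standards.
DEFAULT_STANDARD_MEANS = {"STD1": 40.0, "STD2": 80.0, "STD3": 120.0, "STD4": 160.0}


@dataclass(frozen=True)
class VarianceComponents:
    """Generating variances: per-trial term map, genetic structure, residual."""

    terms: Mapping[str, Mapping[str, float]]  # trial -> term -> variance
    genetic: Mapping[str, float]  # trial -> genetic variance
    residual: Mapping[str, float]  # trial -> residual variance
    genetic_correlation: float = 0.0

    def __post_init__(self) -> None:
        for trial, tmap in self.terms.items():
            for term, v in tmap.items():
                if term not in TERM_VOCABULARY:
                    raise ValueError(f"unknown term {term!r} in trial {trial!r}")
                if v < 0:
                    raise ValueError(f"negative variance for {trial}/{term}")
        for name, m in (("genetic", self.genetic), ("residual", self.residual)):
            for trial, v in m.items():
                if v < 0:
                    raise ValueError(f"negative {name} variance for trial {trial!r}")
        if abs(self.genetic_correlation) > 1:
            raise ValueError("|genetic_correlation| must be <= 1")

    def trial_terms(self, trial: str) -> dict[str, float]:
        return {t: v for t, v in self.terms.get(trial, {}).items() if v > 0}


@dataclass(frozen=True)
class TrialMeans:
    """Overall fixed mean per trial (response units)."""

    means: Mapping[str, float]

    def __post_init__(self) -> None:
        for trial, v in self.means.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite mean for trial {trial!r}")

    def __getitem__(self, trial: str) -> float:
        return float(self.means[trial])


def assemble_observations(field_design: FieldDesign, lab_design: LabDesign) -> pd.DataFrame:
    """Join the lab well table with field pot coordinates for one trial.

    Returns the phenotype-table skeleton (no ``sugar`` column).  Standards
    have missing field coordinates.
    """
    lab = lab_design.table.copy()
    fsub = field_design.table[field_design.table["cultivar"] != EMPTY]
    coords = fsub.set_index(["block", "cultivar"])[["field_row", "field_column"]]
    idx = pd.MultiIndex.from_frame(lab[["block", "cultivar"]])
    joined = coords.reindex(idx).reset_index(drop=True)
    lab["field_row"] = joined["field_row"].astype("Int64")
    lab["field_column"] = joined["field_column"].astype("Int64")
    missing = lab[~lab["is_standard"] & lab["field_row"].isna()]
    if not missing.empty:
        bad = sorted(missing["cultivar"].unique())
        raise ValueError(f"lab samples without a field pot: {bad}")
    return lab[[c for c in PHENOTYPE_COLUMNS if c != "sugar"]]


def _draw_genetic(
    tables: dict[str, pd.DataFrame],
    vc: VarianceComponents,
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """One genetic effect per (trial, cultivar); joint across shared cultivars."""
    trials = sorted(tables)
    present: dict[str, set[str]] = {
        t: set(df.loc[~df["is_standard"], "cultivar"].unique()) for t, df in tables.items()
    }
    effects: dict[str, dict[str, float]] = {t: {} for t in trials}
    if len(trials) == 2:
        t1, t2 = trials
        v1, v2 = vc.genetic.get(t1, 0.0), vc.genetic.get(t2, 0.0)
        rho = vc.genetic_correlation
        shared = sorted(present[t1] & present[t2])
        if shared:
            # explicit Cholesky construction; degenerate-safe at zero variance
            z1 = rng.normal(size=len(shared))
            z2 = rng.normal(size=len(shared))
            g1 = np.sqrt(v1) * z1
            g2 = np.sqrt(v2) * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
            for i, c in enumerate(shared):
                effects[t1][c] = g1[i]
                effects[t2][c] = g2[i]
        for t, v in ((t1, v1), (t2, v2)):
            only = sorted(present[t] - set(shared))
            draws = rng.normal(0.0, np.sqrt(v), size=len(only))
            effects[t].update(zip(only, draws))
    else:
        for t in trials:
            cvs = sorted(present[t])
            draws = rng.normal(0.0, np.sqrt(vc.genetic.get(t, 0.0)), size=len(cvs))
            effects[t].update(zip(cvs, draws))
    return effects


def simulate_met(
    field_designs: Mapping[str, FieldDesign],
    lab_designs: Mapping[str, LabDesign],
    vc: VarianceComponents,
    means: TrialMeans,
    seed: int = 0,
    standard_means: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a multi-environment phenotype table from the given designs.

    Returns one row per well with the simulated ``sugar`` response.
    Reproducible from ``seed``.
    """
    if set(field_designs) != set(lab_designs):
        raise ValueError("field and lab designs must cover the same trials")
    standard_means = dict(standard_means or DEFAULT_STANDARD_MEANS)
    rng = np.random.default_rng(seed)
    tables = {
        t: assemble_observations(field_designs[t], lab_designs[t]) for t in sorted(field_designs)
    }
    genetic = _draw_genetic(tables, vc, rng)

    out = []
    for trial in sorted(tables):
        df = tables[trial].copy()
        std_mask = df["is_standard"].to_numpy()
        y = np.where(
            std_mask,
            df["cultivar"].map(standard_means).fillna(0.0).to_numpy(float),
            means[trial],
        )
        gmap = genetic[trial]
        y = y + np.where(std_mask, 0.0, df["cultivar"].map(gmap).fillna(0.0).to_numpy(float))
        for term, var in vc.trial_terms(trial).items():
            levels = term_levels(df, term)
            if is_field_term(term):
                # standards have no field position; they take no field effect
                codes, uniques = pd.factorize(levels.where(~df["is_standard"], other="__std__"))
                draws = rng.normal(0.0, np.sqrt(var), size=len(uniques))
                draws[uniques == "__std__"] = 0.0
            else:
                codes, uniques = pd.factorize(levels)
                draws = rng.normal(0.0, np.sqrt(var), size=len(uniques))
            y = y + draws[codes]
        y = y + rng.normal(0.0, np.sqrt(vc.residual.get(trial, 0.0)), size=len(df))
        df["sugar"] = y
        out.append(df)
    return pd.concat(out, ignore_index=True)[PHENOTYPE_COLUMNS]


def inject_missingness(table: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Remove whole samples (all four technical replicates) at random.

    Each non-standard sample is dropped independently with probability
    ``rate``; standards are never removed.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    key = table["trial"].astype(str) + "|" + table["plate"].astype(str) + "|" + table[
        "plate_plot"
    ].astype(str)
    samples = key[~table["is_standard"]].unique()
    drop = set(samples[rng.random(len(samples)) < rate])
    keep = ~key.isin(drop) | table["is_standard"]
    return table[keep].reset_index(drop=True)
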