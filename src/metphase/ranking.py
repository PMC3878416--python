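"""Cultivar ranking, top-k concordance and selection indices.

The baseline model's "cultivar value" is the raw mean of all its
observations in a trial (matching common practice of simply averaging
replicates); the adjusted models use the fitted trial mean plus the
cultivar EBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mixed_model import FitResult

DEFAULT_K = 40


@dataclass(frozen=True)
class RankedList:
    """Top-k cultivars of one trial under one model, descending value."""

    trial: str
    model: str
    k: int
    entries: pd.DataFrame = field(repr=False)  # columns: cultivar, value
    tied: tuple[str, ...] = ()  # cultivars whose value ties another entry

    @property
    def cultivars(self) -> list[str]:
        return list(self.entries["cultivar"])


def _trial_values(fit: FitResult, trial: str) -> pd.Series:
    if trial not in fit.trials:
        raise KeyError(f"unknown trial {trial!r}")
    if fit.spec.kind == "A":
        sub = fit.raw_means[fit.raw_means["trial"] == trial]
        return pd.Series(sub["raw_mean"].to_numpy(), index=list(sub["cultivar"]))
    return fit.predictions(trial)


def top_k(fit: FitResult, trial: str, k: int) -> RankedList:
    """Top ``k`` cultivars by predicted value; ties broken lexicographically."""
    values = _trial_values(fit, trial)
    if k > len(values):
        raise ValueError(f"k={k} exceeds cultivar count {len(values)}")
    frame = (
        values.rename("value")
        .rename_axis("cultivar")
        .reset_index()
        .sort_values(["value", "cultivar"], ascending=[False, True], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
    )
    dup_vals = frame["value"].duplicated(keep=False)
    tied = tuple(frame.loc[dup_vals, "cultivar"])
    return RankedList(trial=trial, model=fit.spec.kind, k=k, entries=frame, tied=tied)


def overlap(a: RankedList, b: RankedList) -> tuple[int, list[str]]:
    """Size and identity of the intersection of two top-k sets."""
    if a.k != b.k:
        raise ValueError(f"k differs: {a.k} vs {b.k}")
    shared = sorted(set(a.cultivars) & set(b.cultivars))
    return len(shared), shared


def selection_index(fit: FitResult, weights: Mapping[str, float]) -> pd.DataFrame:
    """Weighted sum of per-trial predictions per cultivar.

    Weights must be non-negative and sum to 1; for cultivars absent from
    some trials the weights are renormalised over the trials present.
    """
    w = {t: float(v) for t, v in weights.items()}
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be non-negative")
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    preds = {t: fit.predictions(t) for t in fit.trials if w.get(t, 0) > 0}
    cultivars = sorted(set().union(*[set(p.index) for p in preds.values()]))
    rows = []
    for c in cultivars:
        present = {t: p[c] for t, p in preds.items() if c in p.index}
        wsum = sum(w[t] for t in present)
        idx = sum(w[t] * v for t, v in present.items()) / wsum
        rows.append({"cultivar": c, "index": idx})
    return pd.DataFrame(rows).sort_values("index", ascending=False).reset_index(drop=True)


def concordance_report(fits: Mapping[str, FitResult], k: int = DEFAULT_K) -> dict:
    """Pairwise top-k overlaps across models and trials.

    Returns a dict with ``cross_trial`` (per model: overlap count and the
    consistent top-k set across trials) and ``cross_model`` (per trial,
    model-pair overlap counts).
    """
    ranked: dict[tuple[str, str], RankedList] = {}
    for model, fit in fits.items():
        for trial in fit.trials:
            ranked[(model, trial)] = top_k(fit, trial, k)

    cross_trial: dict[str, dict] = {}
    for model, fit in fits.items():
        trials = list(fit.trials)
        if len(trials) < 2:
            continue
        consistent = set(ranked[(model, trials[0])].cultivars)
        for t in trials[1:]:
            consistent &= set(ranked[(model, t)].cultivars)
        cross_trial[model] = {"count": len(consistent), "cultivars": sorted(consistent)}

    cross_model: dict[str, dict[str, int]] = {}
    models = sorted(fits)
    trials = sorted({t for f in fits.values() for t in f.trials})
    for trial in trials:
        pairs = {}
        for i, m1 in enumerate(models):
            for m2 in models[i + 1 :]:
                if (m1, trial) in ranked and (m2, trial) in ranked:
                    pairs[f"{m1}-{m2}"] = overlap(ranked[(m1, trial)], ranked[(m2, trial)])[0]
        if pairs:
            cross_model[trial] = pairs
    return {"k": k, "cross_trial": cross_trial, "cross_model": cross_model}


def scatter_frame(fit: FitResult, k: int = DEFAULT_K) -> pd.DataFrame:
    """Per-cultivar trial-1 vs trial-2 predictions with top-k flags.

    Emits both the prediction (trial mean + EBLUP) and the centred EBLUP
    for each trial; suited to a two-trial scatter plot of consistency.
    """
    if len(fit.trials) != 2:
        raise ValueError("scatter frame needs a two-trial fit")
    t1, t2 = fit.trials
    p1, p2 = _trial_values(fit, t1), _trial_values(fit, t2)
    shared = sorted(set(p1.index) & set(p2.index))
    tops = {t: set(top_k(fit, t, k).cultivars) for t in fit.trials}
    df = pd.DataFrame(
        {
            "cultivar": shared,
            f"pred_{t1}": [p1[c] for c in shared],
            f"pred_{t2}": [p2[c] for c in shared],
            f"centred_{t1}": [p1[c] - p1.mean() for c in shared],
            f"centred_{t2}": [p2[c] - p2.mean() for c in shared],
            f"top{k}_{t1}": [c in tops[t1] for c in shared],
            f"top{k}_{t2}": [c in tops[t2] for c in shared],
        }
    )
    df["consistent"] = df[f"top{k}_{t1}"] & df[f"top{k}_{t2}"]
    return df
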