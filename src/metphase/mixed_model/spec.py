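"""Declarative model specification for the three model kinds."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ..factors import TERM_VOCABULARY


@dataclass(frozen=True)
class ModelSpec:
    """Fixed, random, genetic and residual structure of one model.

    ``random_terms`` is an ordered tuple of ``(trial, term)`` pairs, each
    carrying its own variance parameter.  ``covariance`` frees the
    cross-trial genetic covariance (model C).  Every trial always gets a
    fixed mean, a genetic variance and a residual variance.
    """

    kind: str
    trials: tuple[str, ...]
    random_terms: tuple[tuple[str, str], ...] = field(default=())
    covariance: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("A", "B", "C"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate (trial, term) entries")
        if self.covariance and len(self.trials) < 2:
            raise ValueError("genetic covariance requires at least 2 trials")

    @property
    def n_params(self) -> int:
        """Number of variance parameters (genetic + covariance + terms + residual)."""
        return (
            len(self.trials)
            + (1 if self.covariance else 0)
            + len(self.random_terms)
            + len(self.trials)
        )


def spec_model(
    kind: str,
    data: pd.DataFrame,
    term_lists: Mapping[str, Sequence[str]] | None = None,
) -> ModelSpec:
    """Build the ModelSpec of the given kind for a phenotype table.

    ``term_lists`` maps each trial to its field/laboratory random terms
    (ignored for kind A, required for B and C).  Kind C additionally
    frees the cross-trial genetic covariance and requires two trials.
    """
    trials = tuple(sorted(str(t) for t in pd.unique(data["trial"])))
    if not trials:
        raise ValueError("data contains no trials")
    if kind == "A":
        return ModelSpec(kind="A", trials=trials)
    if term_lists is None:
        raise ValueError(f"model kind {kind} requires term_lists")
    random_terms = []
    for trial in trials:
        for term in term_lists.get(trial, ()):
            if term not in TERM_VOCABULARY:
                raise ValueError(f"unknown term {term!r} for trial {trial!r}")
            random_terms.append((trial, term))
    if kind == "C" and len(trials) < 2:
        raise ValueError("model kind C requires two trials")
    return ModelSpec(
        kind=kind,
        trials=trials,
        random_terms=tuple(random_terms),
        covariance=(kind == "C"),
    )
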