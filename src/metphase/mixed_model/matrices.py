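"""Sparse incidence matrices for the mixed model."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..factors import term_levels
from .spec import ModelSpec


def _incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    """n x n_levels 0/1 incidence; rows with code -1 are all-zero."""
    n = len(codes)
    mask = codes >= 0
    rows = np.flatnonzero(mask)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, codes[mask])), shape=(n, n_levels)
    )


@dataclass(frozen=True)
class DesignMatrices:
    """Incidence matrices and level dictionaries for one model/data pair."""

    spec: ModelSpec
    X: sp.csr_matrix = field(repr=False)
    Zg: sp.csr_matrix = field(repr=False)
    Z_terms: dict[tuple[str, str], sp.csr_matrix] = field(repr=False)
    term_levels: dict[tuple[str, str], list[str]] = field(repr=False)
    g_labels: list[tuple[str, str]]  # (trial, cultivar), trial-major
    trial_of_obs: np.ndarray = field(repr=False)  # trial index per observation
    y: np.ndarray = field(repr=False)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def trials(self) -> tuple[str, ...]:
        return self.spec.trials

    def g_indices(self, trial: str) -> np.ndarray:
        return np.array([i for i, (t, _) in enumerate(self.g_labels) if t == trial])

    def shared_pairs(self) -> list[tuple[int, int]]:
        """(index in trial 1, index in trial 2) for cultivars in both trials."""
        if len(self.trials) != 2:
            return []
        t1, t2 = self.trials
        pos = {lab: i for i, lab in enumerate(self.g_labels)}
        pairs = []
        for (t, c), i in pos.items():
            if t == t1 and (t2, c) in pos:
                pairs.append((i, pos[(t2, c)]))
        pairs.sort()
        return pairs


def build_matrices(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble X, Zg and per-term Zu from a phenotype table.

    Standards must already be filtered out.  Cultivar-by-trial columns
    are ordered trial-major with cultivars lexicographic within trial; a
    term scoped to one trial has all-zero rows for other trials'
    observations.
    """
    if "is_standard" in data.columns and bool(data["is_standard"].any()):
        raise ValueError("standards must be excluded before building matrices")
    required = {"trial", "cultivar", "sugar"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    data = data.reset_index(drop=True)
    trial_str = data["trial"].astype(str)
    trials = spec.trials
    trial_idx = trial_str.map({t: i for i, t in enumerate(trials)})
    if trial_idx.isna().any():
        bad = sorted(set(trial_str) - set(trials))
        raise ValueError(f"trials absent from the spec: {bad}")
    trial_idx = trial_idx.to_numpy(int)
    n = len(data)

    X = _incidence(trial_idx, len(trials))

    g_labels: list[tuple[str, str]] = []
    g_codes = np.full(n, -1, dtype=int)
    for ti, trial in enumerate(trials):
        in_trial = trial_idx == ti
        cvs = sorted(pd.unique(data.loc[in_trial, "cultivar"].astype(str)))
        lookup = {c: len(g_labels) + j for j, c in enumerate(cvs)}
        g_codes[in_trial] = data.loc[in_trial, "cultivar"].astype(str).map(lookup).to_numpy(int)
        g_labels.extend((trial, c) for c in cvs)
    Zg = _incidence(g_codes, len(g_labels))

    Z_terms: dict[tuple[str, str], sp.csr_matrix] = {}
    lvl_dicts: dict[tuple[str, str], list[str]] = {}
    for trial, term in spec.random_terms:
        in_trial = trial_idx == trials.index(trial)
        lv = term_levels(data, term)
        codes = np.full(n, -1, dtype=int)
        sub_codes, uniques = pd.factorize(lv[in_trial], sort=True)
        codes[in_trial] = sub_codes
        Z_terms[(trial, term)] = _incidence(codes, len(uniques))
        lvl_dicts[(trial, term)] = [str(u) for u in uniques]

    y = data["sugar"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    return DesignMatrices(
        spec=spec,
        X=X,
        Zg=Zg,
        Z_terms=Z_terms,
        term_levels=lvl_dicts,
        g_labels=g_labels,
        trial_of_obs=trial_idx,
        y=y,
    )
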