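"""Fit summaries: heritability, PEV, likelihood-ratio tests, variance tables."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ..factors import is_field_term
from .fit import FitResult, RemlError


def pairwise_pev_mean(pev_block: np.ndarray) -> float:
    """Mean over pairs (i != j) of ``pev_ii + pev_jj - 2 pev_ij``.

    Uses the identity ``a = 2 (m * trace - grand_sum) / (m (m - 1))``;
    equivalent to the brute-force pair loop.
    """
    m = pev_block.shape[0]
    if m < 2:
        raise ValueError("need at least two cultivars for pairwise PEV")
    tr = float(np.trace(pev_block))
    total = float(pev_block.sum())
    return 2.0 * (m * tr - total) / (m * (m - 1))


def heritability(fit: FitResult, trial: str) -> float:
    """Generalized heritability ``1 - a / (2 * genetic_variance)``.

    ``a`` is the average pairwise prediction error variance of the
    trial's cultivar effects.
    """
    if trial not in fit.trials:
        raise KeyError(f"trial {trial!r} not in fit")
    g_var = fit.params.g_var[trial]
    if g_var <= 0:
        raise ValueError(f"genetic variance for {trial!r} is not positive")
    idx = fit.g_indices(trial)
    block = fit.pev[np.ix_(idx, idx)]
    a = pairwise_pev_mean(block)
    return float(1.0 - a / (2.0 * g_var))


def avg_pev(fit: FitResult) -> float:
    """Mean diagonal PEV across all cultivar-by-trial effects."""
    if not fit.converged:
        raise RemlError("fit did not converge", best=fit)
    return float(np.mean(np.diag(fit.pev)))


def lrt_from_loglik(
    loglik_nested: float, loglik_full: float, df: int, tol: float = 1.0e-4
) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, df and chi-square upper-tail p value.

    Note: when the restriction pins variances at the boundary of the
    parameter space, the naive chi-square reference is conservative.
    """
    stat = 2.0 * (loglik_full - loglik_nested)
    if stat < -tol:
        raise RemlError(
            f"full-model log likelihood {loglik_full} below nested {loglik_nested}; "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    if df < 0:
        raise ValueError("negative degrees of freedom")
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return float(stat), int(df), p


def _is_restriction(nested, full) -> bool:
    return (
        set(nested.random_terms) <= set(full.random_terms)
        and (not nested.covariance or full.covariance)
        and nested.trials == full.trials
    )


def lrt(nested: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of two nested REML fits on the same data."""
    if not _is_restriction(nested.spec, full.spec):
        raise ValueError("first fit is not a restriction of the second")
    df = full.spec.n_params - nested.spec.n_params
    return lrt_from_loglik(nested.loglik, full.loglik, df)


def genetic_correlation(fit: FitResult, boundary_tol: float = 1.0e-7) -> float:
    """Estimated cross-trial genetic correlation from a covariance-model fit."""
    if fit.params.rho is None:
        raise ValueError("fit has no cross-trial genetic covariance")
    for t, v in fit.params.g_var.items():
        if v <= boundary_tol:
            raise ValueError(f"genetic variance for {t!r} is at the boundary")
    return float(fit.params.rho)


def variance_table(
    components: "FitResult | Mapping[str, float]",
    trial: str | None = None,
    genetic: float | None = None,
    residual: float | None = None,
) -> pd.DataFrame:
    """Variance components with percent-of-total, plus stratum subtotals.

    Accepts either a converged fit (with ``trial``) or a plain mapping of
    term name -> variance together with ``genetic`` and ``residual``.
    Per-component percents are ``100 * v / total`` rounded to 1 decimal.
    Subtotal rows (``Field Total``, ``Laboratory Total``) carry the sum
    of their component variances, the percent of that sum (1 decimal),
    and separately the sum of the rounded component percents.
    """
    if isinstance(components, FitResult):
        fit = components
        if trial is None:
            raise ValueError("trial required when summarising a fit")
        term_map = {
            term: v for (t, term), v in fit.params.term_var.items() if t == trial
        }
        genetic = fit.params.g_var[trial]
        residual = fit.params.resid[trial]
    else:
        term_map = dict(components)
        if genetic is None or residual is None:
            raise ValueError("genetic and residual variances are required")

    total = sum(term_map.values()) + genetic + residual
    if total <= 0:
        raise ValueError("total variance must be positive")

    def pct(v: float) -> float:
        return round(100.0 * v / total, 1)

    rows = []
    for group, pred in (("Field", is_field_term), ("Laboratory", lambda t: not is_field_term(t))):
        members = {t: v for t, v in term_map.items() if pred(t)}
        for term, v in members.items():
            rows.append({"term": term, "group": group, "variance": v, "percent": pct(v)})
        if members:
            subtotal = sum(members.values())
            rows.append(
                {
                    "term": f"{group} Total",
                    "group": group,
                    "variance": subtotal,
                    "percent": pct(subtotal),
                    "percent_rounded_sum": round(sum(pct(v) for v in members.values()), 1),
                }
            )
    rows.append({"term": "Cultivar", "group": "Genetic", "variance": genetic, "percent": pct(genetic)})
    rows.append(
        {"term": "Residual", "group": "Residual", "variance": residual, "percent": pct(residual)}
    )
    return pd.DataFrame(rows)
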