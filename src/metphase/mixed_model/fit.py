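"""REML fitting, EBLUPs and prediction error variance.

Models without a cross-trial genetic covariance factor into independent
per-trial problems and are fitted trial by trial (identical likelihood,
much smaller systems).  The covariance model is warm-started from the
per-trial fits plus an empirical correlation of their EBLUPs, then
optimised jointly over the unconstrained transform with L-BFGS-B, using
the workspace's exact analytic gradient when its factorisation backend
provides one (finite differences otherwise).

A term whose estimated variance falls below ``boundary_frac`` times the
total phenotypic variance is treated as having gone to the boundary: it
is dropped and the model refitted, and the drop recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .matrices import build_matrices
from .params import VarianceParams
from .reml import NotPositiveDefiniteError, REMLWorkspace
from .spec import ModelSpec

_PENALTY = 1.0e12


class RemlError(RuntimeError):
    """REML fitting failure; carries the best state found so far."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    ftol: float = 1.0e-11
    gtol: float = 1.0e-5
    fd_step: float = 1.0e-4
    boundary_frac: float = 1.0e-8
    drop_boundary: bool = True
    #: accept an abnormal optimizer exit if the projected gradient is this small
    grad_accept: float = 1.0
    max_boundary_rounds: int = 5


@dataclass
class FitResult:
    """Converged REML fit: estimates, EBLUPs, PEV and bookkeeping."""

    spec: ModelSpec
    params: VarianceParams
    loglik: float
    converged: bool
    n_iter: int
    fixed_estimates: dict[str, float]
    g_labels: list[tuple[str, str]]
    g_eblups: np.ndarray = field(repr=False)
    pev: np.ndarray = field(repr=False)  # (m_total, m_total) block of C^-1
    raw_means: pd.DataFrame = field(repr=False)  # trial, cultivar, raw_mean, n_obs
    dropped_terms: tuple[tuple[str, str], ...] = ()

    @property
    def trials(self) -> tuple[str, ...]:
        return self.spec.trials

    def g_indices(self, trial: str) -> np.ndarray:
        idx = np.array([i for i, (t, _) in enumerate(self.g_labels) if t == trial], dtype=int)
        if len(idx) == 0:
            raise KeyError(f"trial {trial!r} not in fit")
        return idx

    def eblup_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t for t, _ in self.g_labels],
                "cultivar": [c for _, c in self.g_labels],
                "eblup": self.g_eblups,
                "pev_diag": np.diag(self.pev),
            }
        )

    def predictions(self, trial: str) -> pd.Series:
        """tau_hat + g_hat for every cultivar of a trial."""
        idx = self.g_indices(trial)
        values = self.fixed_estimates[trial] + self.g_eblups[idx]
        names = [self.g_labels[i][1] for i in idx]
        return pd.Series(values, index=names, name=trial)


def _strip_standards(data: pd.DataFrame) -> pd.DataFrame:
    if "is_standard" in data.columns:
        std = data["is_standard"]
        if std.dtype == object:
            std = std.astype(str).str.lower().isin(("true", "1"))
        return data[~std.astype(bool)].reset_index(drop=True)
    return data


def _raw_means(data: pd.DataFrame) -> pd.DataFrame:
    g = data.groupby(["trial", "cultivar"], sort=True)["sugar"]
    out = g.agg(raw_mean="mean", n_obs="count").reset_index()
    out["trial"] = out["trial"].astype(str)
    return out


def _transform_scale(params: VarianceParams) -> np.ndarray:
    """d(theta)/d(z) for the unconstrained transform, in vector order."""
    spec = params.spec
    parts = [params.g_var[t] for t in spec.trials]
    if spec.covariance:
        parts.append(1.0 - params.rho**2)
    parts += [params.term_var[k] for k in spec.random_terms]
    parts += [params.resid[t] for t in spec.trials]
    return np.array(parts)


def _optimize(
    ws: REMLWorkspace, spec: ModelSpec, x0: np.ndarray, opts: FitOptions
) -> tuple[VarianceParams, float, bool, int]:
    if ws.has_gradient:

        def objective(x: np.ndarray):
            try:
                params = VarianceParams.from_vector(spec, x)
                ll, grad = ws.loglik_grad(params)
                return -ll, -grad * _transform_scale(params)
            except (NotPositiveDefiniteError, FloatingPointError):
                return _PENALTY, np.zeros_like(x)

        jac = True
    else:

        def objective(x: np.ndarray) -> float:
            try:
                params = VarianceParams.from_vector(spec, x)
                return -ws.loglik(params)
            except (NotPositiveDefiniteError, FloatingPointError):
                return _PENALTY

        jac = None

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        jac=jac,
        options={
            "maxiter": opts.max_iter,
            "ftol": opts.ftol,
            "gtol": opts.gtol,
            "eps": opts.fd_step,
            "maxcor": 25,
        },
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm <= opts.grad_accept
    params = VarianceParams.from_vector(spec, res.x)
    return params, -float(res.fun), converged, int(res.nit)


def _fit_joint(
    spec: ModelSpec,
    data: pd.DataFrame,
    opts: FitOptions,
    start: VarianceParams | None = None,
) -> FitResult:
    mats = build_matrices(data, spec)
    ws = REMLWorkspace(mats)
    var_y = {
        t: float(np.var(mats.y[mats.trial_of_obs == ti], ddof=1))
        for ti, t in enumerate(spec.trials)
    }
    x0 = (start or VarianceParams.initial(spec, var_y)).to_vector()

    dropped: list[tuple[str, str]] = []
    cur_spec = spec
    for _round in range(opts.max_boundary_rounds):
        params, loglik, converged, n_iter = _optimize(ws, cur_spec, x0, opts)
        if not opts.drop_boundary or not cur_spec.random_terms:
            break
        thr = {t: opts.boundary_frac * var_y[t] for t in cur_spec.trials}
        at_zero = [k for k, v in params.term_var.items() if v < thr[k[0]]]
        if not at_zero:
            break
        dropped.extend(at_zero)
        params = params.drop_terms(at_zero)
        cur_spec = params.spec
        mats = build_matrices(data, cur_spec)
        ws = REMLWorkspace(mats)
        x0 = params.to_vector()

    fac = ws.factorize(params, need_pev=True)
    sol = fac.solution
    tau = {t: float(sol[i]) for i, t in enumerate(cur_spec.trials)}
    m = ws.m_total
    g_hat = np.asarray(sol[ws.g_offset : ws.g_offset + m], float)
    pev = fac.pev_gg
    result = FitResult(
        spec=cur_spec,
        params=params,
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        fixed_estimates=tau,
        g_labels=list(mats.g_labels),
        g_eblups=g_hat,
        pev=pev,
        raw_means=_raw_means(data),
        dropped_terms=tuple(dropped),
    )
    if not converged:
        raise RemlError(
            f"REML did not converge after {n_iter} iterations (kind {spec.kind})",
            best=result,
        )
    return result


def _merge_trial_fits(spec: ModelSpec, fits: list[FitResult]) -> FitResult:
    kept_terms = tuple(
        k for k in spec.random_terms if all(k not in f.dropped_terms for f in fits)
    )
    merged_spec = replace(spec, random_terms=kept_terms)
    g_var: dict[str, float] = {}
    term_var: dict[tuple[str, str], float] = {}
    resid: dict[str, float] = {}
    fixed: dict[str, float] = {}
    labels: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []
    for f in fits:
        g_var.update(f.params.g_var)
        term_var.update(f.params.term_var)
        resid.update(f.params.resid)
        fixed.update(f.fixed_estimates)
        labels.extend(f.g_labels)
        dropped.extend(f.dropped_terms)
    params = VarianceParams(
        spec=merged_spec, g_var=g_var, term_var=term_var, resid=resid, rho=None
    )
    m = len(labels)
    pev = np.zeros((m, m))
    g_hat = np.zeros(m)
    lo = 0
    for f in fits:
        k = len(f.g_labels)
        pev[lo : lo + k, lo : lo + k] = f.pev
        g_hat[lo : lo + k] = f.g_eblups
        lo += k
    return FitResult(
        spec=merged_spec,
        params=params,
        loglik=float(sum(f.loglik for f in fits)),
        converged=all(f.converged for f in fits),
        n_iter=sum(f.n_iter for f in fits),
        fixed_estimates=fixed,
        g_labels=labels,
        g_eblups=g_hat,
        pev=pev,
        raw_means=pd.concat([f.raw_means for f in fits], ignore_index=True),
        dropped_terms=tuple(dropped),
    )


def _single_trial_spec(spec: ModelSpec, trial: str) -> ModelSpec:
    return ModelSpec(
        kind="A" if spec.kind == "A" else "B",
        trials=(trial,),
        random_terms=tuple(k for k in spec.random_terms if k[0] == trial),
        covariance=False,
    )


def fit_reml(
    spec: ModelSpec,
    data: pd.DataFrame,
    opts: FitOptions | None = None,
) -> FitResult:
    """Maximise the REML log likelihood for ``spec`` on a phenotype table.

    Standards are filtered out automatically.  Returns a
    :class:`FitResult`; raises :class:`RemlError` carrying the best state
    on non-convergence.
    """
    opts = opts or FitOptions()
    data = _strip_standards(data)
    observed = set(pd.unique(data["trial"].astype(str)))
    if observed != set(spec.trials):
        raise ValueError(
            f"data trials {sorted(observed)} differ from spec trials {list(spec.trials)}"
        )

    if not spec.covariance and len(spec.trials) > 1:
        fits = []
        for trial in spec.trials:
            sub = data[data["trial"].astype(str) == trial]
            fits.append(_fit_joint(_single_trial_spec(spec, trial), sub, opts))
        return _merge_trial_fits(spec, fits)

    if spec.covariance:
        # warm start from the covariance-off restriction
        restricted = replace(spec, kind="B" if spec.random_terms else "A", covariance=False)
        base = fit_reml(restricted, data, opts)
        rho0 = _empirical_rho(base)
        start = VarianceParams(
            spec=replace(spec, random_terms=base.spec.random_terms),
            g_var=dict(base.params.g_var),
            term_var=dict(base.params.term_var),
            resid=dict(base.params.resid),
            rho=rho0,
        )
        result = _fit_joint(start.spec, data, opts, start=start)
        # keep the requested kind label on the (possibly reduced) spec
        final_spec = replace(result.spec, kind=spec.kind)
        return replace_fit_spec(result, final_spec, extra_dropped=base.dropped_terms)

    return _fit_joint(spec, data, opts)


def replace_fit_spec(
    fit: FitResult, spec: ModelSpec, extra_dropped: tuple[tuple[str, str], ...] = ()
) -> FitResult:
    params = VarianceParams(
        spec=spec,
        g_var=dict(fit.params.g_var),
        term_var=dict(fit.params.term_var),
        resid=dict(fit.params.resid),
        rho=fit.params.rho,
    )
    return FitResult(
        spec=spec,
        params=params,
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        fixed_estimates=fit.fixed_estimates,
        g_labels=fit.g_labels,
        g_eblups=fit.g_eblups,
        pev=fit.pev,
        raw_means=fit.raw_means,
        dropped_terms=tuple(dict.fromkeys(tuple(extra_dropped) + fit.dropped_terms)),
    )


def _empirical_rho(base: FitResult) -> float:
    """Correlation of per-trial EBLUPs over shared cultivars (warm start)."""
    if len(base.trials) != 2:
        return 0.0
    t1, t2 = base.trials
    s1 = pd.Series(
        base.g_eblups[base.g_indices(t1)], index=[base.g_labels[i][1] for i in base.g_indices(t1)]
    )
    s2 = pd.Series(
        base.g_eblups[base.g_indices(t2)], index=[base.g_labels[i][1] for i in base.g_indices(t2)]
    )
    shared = s1.index.intersection(s2.index)
    if len(shared) < 3:
        return 0.0
    r = float(np.corrcoef(s1[shared], s2[shared])[0, 1])
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(r, -0.8, 0.8))


def eblups_and_pev(fit: FitResult) -> tuple[pd.DataFrame, np.ndarray]:
    """Cultivar-by-trial EBLUPs and the PEV block of the fit."""
    if not fit.converged:
        raise RemlError("fit did not converge", best=fit)
    return fit.eblup_frame(), fit.pev
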