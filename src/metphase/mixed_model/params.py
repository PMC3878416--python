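"""Variance-parameter vector with an unconstrained internal transform.

Variances live on the log scale and the cross-trial genetic correlation
on the arctanh scale, so any real vector maps to a valid parameter set
(variances > 0, |correlation| < 1).  The covariance itself is derived as
``rho * sqrt(v1 * v2)``, guaranteeing a positive-definite 2x2 genetic
variance matrix at every optimizer iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .spec import ModelSpec

_LOG_BOUND = 40.0  # clip for exp/log to keep the optimizer finite
_ATANH_BOUND = 6.0  # |rho| <= tanh(6) ~ 0.99998; tanh of larger args rounds to 1.0


def _safe_log(v: float) -> float:
    return float(np.clip(np.log(max(v, 1e-300)), -_LOG_BOUND, _LOG_BOUND))


@dataclass(frozen=True)
class VarianceParams:
    """Natural-scale variance parameters for one ModelSpec."""

    spec: ModelSpec
    g_var: dict[str, float]  # trial -> genetic variance
    term_var: dict[tuple[str, str], float]  # (trial, term) -> variance
    resid: dict[str, float]  # trial -> residual variance
    rho: float | None = None  # genetic correlation (model C only)

    def __post_init__(self) -> None:
        if self.spec.covariance and self.rho is None:
            raise ValueError("spec has a free covariance but rho is None")
        if not self.spec.covariance and self.rho is not None:
            raise ValueError("rho given for a spec without covariance")
        for m in (self.g_var, self.resid):
            for t, v in m.items():
                if v <= 0:
                    raise ValueError(f"non-positive variance for trial {t!r}")
        for k, v in self.term_var.items():
            if v <= 0:
                raise ValueError(f"non-positive variance for term {k}")
        if self.rho is not None and abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")

    @property
    def genetic_covariance(self) -> float | None:
        if self.rho is None:
            return None
        t1, t2 = self.spec.trials[:2]
        return self.rho * float(np.sqrt(self.g_var[t1] * self.g_var[t2]))

    def to_vector(self) -> np.ndarray:
        """Unconstrained vector: [log g_var..., atanh rho?, log terms..., log resid...]."""
        parts = [_safe_log(self.g_var[t]) for t in self.spec.trials]
        if self.spec.covariance:
            z = float(np.arctanh(np.clip(self.rho, -0.999999, 0.999999)))
            parts.append(float(np.clip(z, -_ATANH_BOUND, _ATANH_BOUND)))
        parts += [_safe_log(self.term_var[k]) for k in self.spec.random_terms]
        parts += [_safe_log(self.resid[t]) for t in self.spec.trials]
        return np.array(parts)

    @classmethod
    def from_vector(cls, spec: ModelSpec, x: np.ndarray) -> "VarianceParams":
        x = np.clip(np.asarray(x, float), -_LOG_BOUND, _LOG_BOUND)
        k = len(spec.trials)
        i = 0
        g_var = {t: float(np.exp(x[i + j])) for j, t in enumerate(spec.trials)}
        i += k
        rho = None
        if spec.covariance:
            rho = float(np.tanh(np.clip(x[i], -_ATANH_BOUND, _ATANH_BOUND)))
            i += 1
        term_var = {
            key: float(np.exp(x[i + j])) for j, key in enumerate(spec.random_terms)
        }
        i += len(spec.random_terms)
        resid = {t: float(np.exp(x[i + j])) for j, t in enumerate(spec.trials)}
        return cls(spec=spec, g_var=g_var, term_var=term_var, resid=resid, rho=rho)

    @classmethod
    def initial(cls, spec: ModelSpec, y_var: float | Mapping[str, float]) -> "VarianceParams":
        """Equal-split starting values from the phenotypic variance."""
        trials = spec.trials
        if not isinstance(y_var, Mapping):
            y_var = {t: float(y_var) for t in trials}
        n_per_trial = {t: 2 + sum(1 for (tt, _) in spec.random_terms if tt == t) for t in trials}
        g_var = {t: max(y_var[t], 1e-8) / n_per_trial[t] for t in trials}
        term_var = {
            (t, term): max(y_var[t], 1e-8) / n_per_trial[t] for (t, term) in spec.random_terms
        }
        resid = {t: max(y_var[t], 1e-8) / n_per_trial[t] for t in trials}
        rho = 0.0 if spec.covariance else None
        return cls(spec=spec, g_var=g_var, term_var=term_var, resid=resid, rho=rho)

    def drop_terms(self, terms: list[tuple[str, str]]) -> "VarianceParams":
        new_spec = replace(
            self.spec,
            random_terms=tuple(k for k in self.spec.random_terms if k not in terms),
        )
        return VarianceParams(
            spec=new_spec,
            g_var=dict(self.g_var),
            term_var={k: v for k, v in self.term_var.items() if k not in terms},
            resid=dict(self.resid),
            rho=self.rho,
        )

    def as_dict(self) -> dict[str, float]:
        """Flat name -> value mapping on the natural scale."""
        out = {f"genetic:{t}": v for t, v in self.g_var.items()}
        if self.rho is not None:
            out["genetic_covariance"] = float(self.genetic_covariance)
            out["genetic_correlation"] = self.rho
        out.update({f"{t}:{term}": v for (t, term), v in self.term_var.items()})
        out.update({f"residual:{t}": v for t, v in self.resid.items()})
        return out
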