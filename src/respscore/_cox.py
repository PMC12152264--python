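"""Thin wrapper around lifelines' Cox proportional-hazards fitter.

Centralizes convergence handling: every caller gets back a result object
with a ``converged`` flag instead of an exception, so subset searches can
rank past pathological candidates (separation, monotone likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError


@dataclass
class CoxResult:
    params: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    n: int = 0
    n_events: int = 0
    converged: bool = False
    message: str = ""

    def hr(self, name: str) -> float:
        return float(np.exp(self.params[name]))

    def ci(self, name: str, z: float = 1.959963984540054) -> tuple[float, float]:
        """95% Wald interval on the HR scale."""
        b, s = self.params[name], self.se[name]
        return float(np.exp(b - z * s)), float(np.exp(b + z * s))


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_days",
    event_col: str = "event",
) -> CoxResult:
    """Partial-likelihood Cox fit (Efron ties, lifelines defaults)."""
    n = len(df)
    n_events = int(df[event_col].sum())
    if n_events < 1:
        return CoxResult(n=n, n_events=n_events, message="no events")
    sub = df[covariates + [duration_col, event_col]]
    if sub[covariates].std(ddof=0).min() == 0:
        return CoxResult(n=n, n_events=n_events, message="constant covariate")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return CoxResult(n=n, n_events=n_events, message=f"{type(exc).__name__}: {exc}")
    se = cph.standard_errors_
    if not np.isfinite(list(se)).all() or max(se) > 50:
        return CoxResult(n=n, n_events=n_events, message="unstable fit (huge SE)")
    return CoxResult(
        params={k: float(v) for k, v in cph.params_.items()},
        se={k: float(v) for k, v in se.items()},
        p={k: float(v) for k, v in cph.summary["p"].items()},
        log_likelihood=float(cph.log_likelihood_),
        n=n,
        n_events=n_events,
        converged=True,
    )
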