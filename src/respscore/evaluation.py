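"""Performance measures for response-score models.

* subgroup treatment effects (unadjusted Cox HRs with Wald CIs),
* treatment-by-score interaction tests (continuous score or binary label),
* the AD(q) discrimination curve: the treatment HR re-estimated inside the
  best-scoring fraction q of patients as q sweeps a grid; its normalized
  trapezoidal mean is the curve's AUC (a flat curve at the overall HR means
  no heterogeneity; the lower the curve at small q, the more the benefit
  concentrates in the predicted responders),
* calibration of predicted vs observed log HRs across score-quartile bins,
* bootstrap replicability of the whole select-and-validate procedure,
* conditional-permutation variable importance from a random forest,
* Kaplan-Meier step tables for plotting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._cox import CoxResult, fit_cox
from ._utils import spawn_seed
from .model_selection import SelectionResult, apply_validation_rule, rank_candidates
from .response_score import ResponseScoreModel, overall_treatment_effect
from .trial_io import TrialDataset, VariableSet, split_train_validation


@dataclass
class TreatmentEffectEstimate:
    group: str
    hr: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    evaluable: bool = True
    message: str = ""


def _estimate(df: pd.DataFrame, group: str) -> TreatmentEffectEstimate:
    if df.empty or df["treat"].nunique() < 2:
        return TreatmentEffectEstimate(
            group, math.nan, math.nan, math.nan, len(df), int(df["event"].sum()) if len(df) else 0,
            evaluable=False, message="single-arm or empty group",
        )
    res = fit_cox(df, ["treat"])
    if not res.converged:
        return TreatmentEffectEstimate(
            group, math.nan, math.nan, math.nan, res.n, res.n_events,
            evaluable=False, message=res.message,
        )
    lo, hi = res.ci("treat")
    return TreatmentEffectEstimate(group, res.hr("treat"), lo, hi, res.n, res.n_events)


def subgroup_hr(
    dataset: TrialDataset, outcome: str, group_labels: pd.Series
) -> list[TreatmentEffectEstimate]:
    """Treatment-only Cox HR with 95% Wald CI per group.

    ``group_labels`` is indexed by patient_id.
    """
    merged = dataset.merged(outcome)
    merged["group"] = group_labels.reindex(merged["patient_id"]).to_numpy()
    return [_estimate(g, str(name)) for name, g in merged.groupby("group", sort=True)]


def interaction_test(
    dataset: TrialDataset, outcome: str, score_or_label: pd.Series
) -> float:
    """Wald p-value of the treatment-by-covariate product term.

    The covariate may be a continuous RS or a binary responder indicator
    (indexed by patient_id). Returns NaN when the fit is degenerate
    (e.g. a constant score makes the product collinear).
    """
    merged = dataset.merged(outcome)
    x = pd.to_numeric(score_or_label.reindex(merged["patient_id"])).to_numpy(dtype=float)
    merged["x"] = x
    merged["treat_x"] = merged["treat"] * x
    res = fit_cox(merged, ["treat", "x", "treat_x"])
    return res.p["treat_x"] if res.converged else float("nan")


# ---------------------------------------------------------------------------
# AD(q)
# ---------------------------------------------------------------------------


@dataclass
class ADqCurve:
    q: list[float]
    hr_at_q: list[float]
    auc: float
    skipped: list[float] = field(default_factory=list)


DEFAULT_ADQ_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))


def adq_curve(
    dataset: TrialDataset,
    outcome: str,
    scores: pd.Series,
    grid: Sequence[float] = DEFAULT_ADQ_GRID,
) -> ADqCurve:
    """Treatment HR within the best-scoring fraction q, for q over a grid.

    At q = 1 the subgroup is everyone, so the curve ends at the overall HR.
    AUC = trapezoidal integral over the evaluable grid divided by its
    q-span (a normalized mean curve height, on the HR scale).
    """
    grid = sorted(grid)
    if not grid or grid[-1] != 1.0 or grid[0] <= 0:
        raise ValueError("grid must lie in (0, 1] and include 1.0")
    merged = dataset.merged(outcome)
    s = scores.reindex(merged["patient_id"]).to_numpy(dtype=float)
    qs, hrs, skipped = [], [], []
    for q in grid:
        cutoff = np.quantile(scores.to_numpy(dtype=float), q)
        sub = merged[s <= cutoff]
        est = _estimate(sub, f"q={q}")
        if est.evaluable:
            qs.append(q)
            hrs.append(est.hr)
        else:
            skipped.append(q)
    if len(qs) < 2:
        raise ValueError("fewer than two evaluable grid points")
    auc = float(np.trapezoid(hrs, qs) / (qs[-1] - qs[0]))
    return ADqCurve(qs, hrs, auc, skipped)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationBin:
    bin_index: int
    n: int
    predicted_mean_score: float
    observed_log_hr: float
    ci_low: float
    ci_high: float
    evaluable: bool = True


def calibration(
    dataset: TrialDataset, outcome: str, scores: pd.Series, n_bins: int = 4
) -> list[CalibrationBin]:
    """Predicted mean RS vs observed log HR per score-quantile bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    merged = dataset.merged(outcome)
    s = pd.Series(scores.reindex(merged["patient_id"]).to_numpy(dtype=float))
    bins = pd.qcut(s, n_bins, labels=False, duplicates="drop")
    out: list[CalibrationBin] = []
    for b in range(n_bins):
        mask = (bins == b).to_numpy()
        if not mask.any():
            out.append(CalibrationBin(b, 0, math.nan, math.nan, math.nan, math.nan, False))
            continue
        est = _estimate(merged[mask], f"bin{b}")
        out.append(
            CalibrationBin(
                b,
                int(mask.sum()),
                float(s[mask].mean()),
                math.log(est.hr) if est.evaluable else math.nan,
                math.log(est.ci_low) if est.evaluable else math.nan,
                math.log(est.ci_high) if est.evaluable else math.nan,
                est.evaluable,
            )
        )
    return out


# ---------------------------------------------------------------------------
# bootstrap replicability
# ---------------------------------------------------------------------------


@dataclass
class ReplicabilityResult:
    n_replicates: int
    n_evaluable: int
    n_validated: int
    pass_rate: float
    subset_frequency: dict[tuple[str, ...], int]
    failures: int = 0


def bootstrap_resample(dataset: TrialDataset, seed: int) -> TrialDataset:
    """Resample patients with replacement, re-keying duplicates."""
    rng = np.random.default_rng(seed)
    ids = dataset.baselines["patient_id"].to_numpy()
    picks = rng.integers(0, len(ids), size=len(ids))
    base = dataset.baselines.iloc[picks].reset_index(drop=True)
    counts: Counter = Counter()
    new_ids = []
    for pid in base["patient_id"]:
        counts[pid] += 1
        new_ids.append(pid if counts[pid] == 1 else f"{pid}#{counts[pid]}")
    id_of_pick = dict(zip(new_ids, base["patient_id"]))
    base = base.copy()
    base["patient_id"] = new_ids
    ev = dataset.events.set_index("patient_id")
    frames = []
    for new_id, old_id in id_of_pick.items():
        sub = ev.loc[[old_id]].reset_index()
        sub["patient_id"] = new_id
        frames.append(sub)
    events = pd.concat(frames, ignore_index=True)
    return TrialDataset(base, events, provenance=f"{dataset.provenance}|boot", seed=seed)


def replicability(
    dataset: TrialDataset,
    outcome: str,
    variable_set: VariableSet,
    n_replicates: int = 500,
    seed: int = 0,
    fraction: float = 0.7,
    resample: bool = True,
    method: Literal["pooled_interaction", "two_fit"] = "pooled_interaction",
) -> ReplicabilityResult:
    """Fraction of bootstrap train/validation splits where the selected RS
    re-validates, plus how often each subset wins.

    With ``resample=False`` only the 70/30 split is redrawn per replicate.
    """
    rng = np.random.default_rng(seed)
    n_validated = 0
    n_evaluable = 0
    failures = 0
    freq: Counter = Counter()
    for _ in range(n_replicates):
        rep_seed = spawn_seed(rng)
        try:
            rep = bootstrap_resample(dataset, rep_seed) if resample else dataset
            split = split_train_validation(rep, fraction, spawn_seed(rng))
            ranked = rank_candidates(split.train, outcome, variable_set, method=method)
            selected = next(c for c in ranked if c.valid)
            overall = overall_treatment_effect(rep, outcome)
            if not overall.converged:
                raise RuntimeError("overall HR fit failed")
            verdict = apply_validation_rule(selected, split.validation, overall.hr("treat"))
        except (RuntimeError, ValueError, StopIteration):
            failures += 1
            continue
        n_evaluable += 1
        freq[selected.subset] += 1
        n_validated += int(verdict.validated)
    pass_rate = n_validated / n_evaluable if n_evaluable else float("nan")
    return ReplicabilityResult(
        n_replicates, n_evaluable, n_validated, pass_rate, dict(freq), failures
    )


# ---------------------------------------------------------------------------
# conditional-permutation variable importance
# ---------------------------------------------------------------------------


@dataclass
class ImportanceRow:
    variable: str
    vi: float
    pct_vi: float


def variable_importance(
    covariates: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 1000,
    n_repeats: int = 5,
    correlation_threshold: float = 0.2,
    seed: int = 0,
) -> list[ImportanceRow]:
    """Random-forest conditional permutation importance of each covariate.

    The forest is grown on one random half of the data and importance is
    measured on the held-out half, so that a forest memorizing noise scores
    zero. Each variable is permuted *within strata* defined by quartile
    bins of the covariates it correlates with (|Pearson r| above the
    threshold), so that importance reflects the variable's own contribution
    rather than shared signal. vi = mean held-out accuracy drop;
    pct_vi = 100 * vi / max vi (negative raw values are clipped for the
    percentage but retained).
    """
    from sklearn.ensemble import RandomForestClassifier

    y_all = np.asarray(labels)
    if len(np.unique(y_all)) < 2:
        raise ValueError("labels must contain both classes")
    X_all = covariates.copy()
    if "sex" in X_all.columns:
        X_all["sex"] = (X_all["sex"] == "male").astype(float)
    X_all = X_all.astype(float).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X_all))
    half = len(X_all) // 2
    fit_idx, eval_idx = perm[:half], perm[half:]
    if len(np.unique(y_all[fit_idx])) < 2:
        raise ValueError("labels must contain both classes in each fold")
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    rf.fit(X_all.iloc[fit_idx], y_all[fit_idx])
    X = X_all.iloc[eval_idx].reset_index(drop=True)
    y = y_all[eval_idx]
    base_acc = float((rf.predict(X) == y).mean())
    corr = X.corr().abs()
    rows: list[ImportanceRow] = []
    for col in X.columns:
        partners = [c for c in X.columns if c != col and corr.loc[col, c] > correlation_threshold]
        if partners:
            key = pd.DataFrame(
                {c: pd.qcut(X[c], 4, labels=False, duplicates="drop") for c in partners}
            )
            stratum = key.astype(str).agg("|".join, axis=1).to_numpy()
        else:
            stratum = np.zeros(len(X), dtype=int)
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            vals = Xp[col].to_numpy().copy()
            for s in np.unique(stratum):
                pos = np.nonzero(stratum == s)[0]
                vals[pos] = vals[rng.permutation(pos)]
            Xp[col] = vals
            drops.append(base_acc - float((rf.predict(Xp) == y).mean()))
        rows.append(ImportanceRow(col, float(np.mean(drops)), 0.0))
    max_vi = max((r.vi for r in rows), default=0.0)
    for r in rows:
        r.pct_vi = 100.0 * max(r.vi, 0.0) / max_vi if max_vi > 0 else 0.0
    rows.sort(key=lambda r: -r.vi)
    return rows


# ---------------------------------------------------------------------------
# Kaplan-Meier summaries
# ---------------------------------------------------------------------------


def km_summary(
    dataset: TrialDataset, outcome: str, group_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Product-limit survival step tables per group x arm for plotting."""
    from lifelines import KaplanMeierFitter

    merged = dataset.merged(outcome)
    if group_labels is not None:
        merged["group"] = group_labels.reindex(merged["patient_id"]).to_numpy()
    else:
        merged["group"] = "all"
    frames = []
    for (group, arm), sub in merged.groupby(["group", "arm"], sort=True):
        if sub.empty:
            continue
        km = KaplanMeierFitter()
        km.fit(sub["time_days"], sub["event"])
        tbl = km.survival_function_.reset_index()
        tbl.columns = ["time_days", "survival"]
        tbl.insert(0, "arm", arm)
        tbl.insert(0, "group", group)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)
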