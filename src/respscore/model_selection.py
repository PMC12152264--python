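"""All-possible-subset search over baseline variables and the validation rule.

Every non-empty subset of the candidate variables yields one response-score
model on the training set. Training patients are split at the first
quartile of the score distribution into potential responders (lowest 25%)
and non-responders; each candidate is scored by the ratio of the treatment
HR in responders to the HR in non-responders and candidates are ranked
ascending (a smaller ratio = stronger discrimination of benefit).

The top-ranked candidate is then taken to the validation set, where
patients are re-classified against the whole-group HR threshold, and the
model counts as *validated* when the responder/non-responder HR ratio is
below 0.80 and/or the treatment-by-group interaction p-value is below the
(deliberately liberal) 0.20 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._cox import fit_cox
from .response_score import ResponseScoreModel, build_response_score, classify
from .trial_io import TrialDataset, VariableSet

MAX_SUBSET_VARIABLES = 20


def enumerate_subsets(variables: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^n - 1 non-empty subsets, ordered by size then lexicographically."""
    names = list(variables)
    if not 1 <= len(names) <= MAX_SUBSET_VARIABLES:
        raise ValueError(
            f"subset search supports 1..{MAX_SUBSET_VARIABLES} variables "
            f"(got {len(names)}); prune the candidate set"
        )
    out: list[tuple[str, ...]] = []
    for size in range(1, len(names) + 1):
        out.extend(combinations(sorted(names), size))
    return out


@dataclass
class CandidateModel:
    subset: tuple[str, ...]
    rs: ResponseScoreModel | None
    train_hr_responders: float = float("nan")
    train_hr_nonresponders: float = float("nan")
    hr_ratio: float = float("nan")
    valid: bool = False
    message: str = ""


@dataclass
class ValidationVerdict:
    hr_responders: float = float("nan")
    hr_nonresponders: float = float("nan")
    hr_ratio: float = float("nan")
    hr_criterion_met: bool | None = None  # None = not evaluable
    interaction_p: float = float("nan")
    interaction_criterion_met: bool | None = None
    interaction_p_continuous: float = float("nan")
    validated: bool = False


@dataclass
class SelectionResult:
    outcome: str
    ranked: list[CandidateModel]
    selected: CandidateModel | None
    verdict: ValidationVerdict | None
    overall_hr: float = float("nan")
    settings: dict = field(default_factory=dict)


def _stratum_hr(df: pd.DataFrame, mask: np.ndarray) -> tuple[float, str]:
    sub = df[mask]
    if sub.empty or sub["treat"].nunique() < 2:
        return float("nan"), "single-arm or empty stratum"
    res = fit_cox(sub, ["treat"])
    if not res.converged:
        return float("nan"), res.message
    return res.hr("treat"), ""


def rank_candidates(
    train: TrialDataset,
    outcome: str,
    variable_set: VariableSet,
    method: Literal["pooled_interaction", "two_fit"] = "pooled_interaction",
    ranking: Literal["ratio", "responders_hr"] = "ratio",
) -> list[CandidateModel]:
    """Fit and rank a response score for every variable subset.

    ``ranking="ratio"`` orders by HR_responders / HR_non-responders (the
    default reading of the discrimination criterion);
    ``"responders_hr"`` orders by the responders' HR alone.
    """
    merged = train.merged(outcome)
    candidates: list[CandidateModel] = []
    for subset in enumerate_subsets(variable_set.raw_names):
        variables = variable_set.subset(subset)
        rs = build_response_score(train, outcome, variables, method=method)
        if not rs.converged:
            candidates.append(CandidateModel(subset, rs, message="fit did not converge"))
            continue
        scores = rs.score_frame(train.baselines)
        labels = classify(rs, scores, "train_quartile", scores.to_numpy())
        responder_ids = set(labels.loc[labels["label"] == "responder", "patient_id"])
        is_resp = merged["patient_id"].isin(responder_ids).to_numpy()
        hr_r, msg_r = _stratum_hr(merged, is_resp)
        hr_n, msg_n = _stratum_hr(merged, ~is_resp)
        if math.isnan(hr_r) or math.isnan(hr_n):
            candidates.append(
                CandidateModel(subset, rs, hr_r, hr_n, message=(msg_r or msg_n) or "stratum HR failed")
            )
            continue
        key = hr_r / hr_n if ranking == "ratio" else hr_r
        candidates.append(CandidateModel(subset, rs, hr_r, hr_n, hr_ratio=key, valid=True))
    if not any(c.valid for c in candidates):
        raise RuntimeError(f"no candidate subset converged for outcome {outcome}")
    # valid candidates first, ascending ratio; parsimony then name tie-breaks
    candidates.sort(key=lambda c: (not c.valid, c.hr_ratio if c.valid else np.inf, len(c.subset), c.subset))
    return candidates


def apply_validation_rule(
    selected: CandidateModel,
    validation: TrialDataset,
    overall_hr: float,
    hr_ratio_threshold: float = 0.80,
    interaction_alpha: float = 0.20,
) -> ValidationVerdict:
    """Evaluate the selected RS on held-out data.

    Classification uses the whole-group HR as threshold; the verdict is the
    OR of the HR-ratio criterion (< 0.80) and the treatment-by-group
    interaction criterion (p < 0.20). A criterion that cannot be evaluated
    (e.g. a stratum with no events) is left undecided and the other decides.
    """
    if selected.rs is None or not selected.rs.converged:
        raise ValueError("selected candidate has no converged response score")
    merged = validation.merged(selected.rs.outcome)
    scores = selected.rs.score_frame(validation.baselines)
    labels = classify(selected.rs, scores, "overall_hr", overall_hr)
    responder_ids = set(labels.loc[labels["label"] == "responder", "patient_id"])
    is_resp = merged["patient_id"].isin(responder_ids).to_numpy()

    verdict = ValidationVerdict()
    hr_r, _ = _stratum_hr(merged, is_resp)
    hr_n, _ = _stratum_hr(merged, ~is_resp)
    verdict.hr_responders, verdict.hr_nonresponders = hr_r, hr_n
    if not (math.isnan(hr_r) or math.isnan(hr_n)):
        verdict.hr_ratio = hr_r / hr_n
        verdict.hr_criterion_met = verdict.hr_ratio < hr_ratio_threshold

    work = merged.copy()
    work["resp"] = is_resp.astype(float)
    work["treat_x_resp"] = work["treat"] * work["resp"]
    res = fit_cox(work, ["treat", "resp", "treat_x_resp"])
    if res.converged:
        verdict.interaction_p = res.p["treat_x_resp"]
        verdict.interaction_criterion_met = verdict.interaction_p < interaction_alpha

    # continuous treatment-by-RS interaction, reported alongside
    work["rs"] = scores.reindex(work["patient_id"]).to_numpy()
    work["treat_x_rs"] = work["treat"] * work["rs"]
    res_c = fit_cox(work, ["treat", "rs", "treat_x_rs"])
    if res_c.converged:
        verdict.interaction_p_continuous = res_c.p["treat_x_rs"]

    verdict.validated = bool(verdict.hr_criterion_met) or bool(verdict.interaction_criterion_met)
    return verdict


def select_response_score(
    train: TrialDataset,
    validation: TrialDataset,
    outcome: str,
    variable_set: VariableSet,
    overall_hr: float,
    method: Literal["pooled_interaction", "two_fit"] = "pooled_interaction",
    ranking: Literal["ratio", "responders_hr"] = "ratio",
) -> SelectionResult:
    """Rank all subsets on the training set and validate the winner."""
    ranked = rank_candidates(train, outcome, variable_set, method=method, ranking=ranking)
    selected = next(c for c in ranked if c.valid)
    verdict = apply_validation_rule(selected, validation, overall_hr)
    return SelectionResult(
        outcome=outcome,
        ranked=ranked,
        selected=selected,
        verdict=verdict,
        overall_hr=overall_hr,
        settings={"method": method, "ranking": ranking, "variable_set": variable_set.name},
    )
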