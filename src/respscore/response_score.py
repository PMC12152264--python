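"""Response-score construction, scoring and responder classification.

The response score (RS) of a patient is a linear combination of transformed
baseline covariates on the log hazard-ratio scale: it predicts the
patient-specific treatment effect, with more negative values meaning larger
expected benefit. The slope of each covariate is the difference between its
prognostic coefficient in the treatment arm and in the control arm; the
intercept is the treatment main effect at covariate value zero.

Two fitting routes are provided:

* ``pooled_interaction`` (default) — one Cox model on the pooled arms with
  treatment, covariates and treatment-by-covariate products; the product
  coefficients are the arm-wise coefficient differences and the treatment
  main effect supplies the intercept, all from a single partial likelihood.
* ``two_fit`` — the literal construction: separate Cox fits per arm,
  slopes = coefficient difference, intercept = the treatment main effect of
  a pooled main-effects model.

Covariates are left on their raw transformed scale (uncentered), matching
the functional form of the published score formulas.

The four published clinical-practice scores ship as fixtures
(:func:`published_scores`) together with their responder thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._cox import CoxResult, fit_cox
from .trial_io import ARM_CONTROL, ARM_TREATMENT, TrialDataset, VariableSet


class FitError(RuntimeError):
    """A required proportional-hazards fit failed to converge."""


@dataclass
class ArmModelFit:
    """Prognostic Cox model for a single arm."""

    arm: str
    outcome: str
    coefficients: dict[str, float]
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    message: str = ""


@dataclass
class ResponseScoreModel:
    """intercept + sum(coef_j * transformed covariate_j), a log HR."""

    outcome: str
    variables: VariableSet
    intercept: float
    coefficients: dict[str, float]
    provenance: Literal["fitted", "published"] = "fitted"
    n_treatment: int = 0
    n_control: int = 0
    converged: bool = True
    threshold_hr: float | None = None  # published whole-group HR cut-off

    def score_frame(self, baselines: pd.DataFrame) -> pd.Series:
        """RS for every patient in a baseline table (indexed by patient_id)."""
        design = self.variables.design_matrix(baselines)
        s = pd.Series(self.intercept, index=baselines.index, dtype=float)
        for name, coef in self.coefficients.items():
            if name not in design.columns:
                raise KeyError(f"design matrix lacks column {name!r}")
            s = s + coef * design[name]
        s.index = pd.Index(baselines["patient_id"], name="patient_id")
        return s

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "variables": [list(v) for v in self.variables.variables],
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "provenance": self.provenance,
            "threshold_hr": self.threshold_hr,
        }


def published_scores() -> dict[str, ResponseScoreModel]:
    """The four published clinical-practice response scores.

    Coefficients are sign/value-reconciled against the printed worked
    examples (see the fixture's comment and the methods note): the EDSS
    relapse term is +0.05 and the SDMT disease-duration term is -0.15.
    """
    raw = json.loads(
        resources.files("respscore").joinpath("data/published_scores.json").read_text()
    )
    out = {}
    for outcome, spec in raw.items():
        if outcome.startswith("_"):
            continue
        from .synthetic_trial import variables_for_design_names

        out[outcome] = ResponseScoreModel(
            outcome=outcome,
            variables=variables_for_design_names(list(spec["coefficients"])),
            intercept=float(spec["intercept"]),
            coefficients={k: float(v) for k, v in spec["coefficients"].items()},
            provenance="published",
            threshold_hr=float(spec["threshold_hr"]),
        )
    return out


def score_patient(model: ResponseScoreModel, profile: Mapping[str, object]) -> float:
    """RS for a single patient given raw baseline fields.

    ``profile`` uses raw names (age, sex, edss, relapses_2y,
    disease_duration, ...); transforms are applied per the model.
    """
    value = model.intercept
    for (raw, transform), name in zip(model.variables.variables, model.variables.design_names):
        if name not in model.coefficients:
            continue
        if raw not in profile or profile[raw] is None:
            raise ValueError(f"profile missing required variable {raw!r}")
        x = profile[raw]
        if transform == "male":
            z = 1.0 if x == "male" else 0.0
        elif transform == "log10":
            z = math.log10(float(x))
        else:
            z = float(x)
        value += model.coefficients[name] * z
    return float(value)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _merged_design(dataset: TrialDataset, outcome: str, variables: VariableSet) -> pd.DataFrame:
    merged = dataset.merged(outcome)
    design = variables.design_matrix(merged)
    if design.isna().any().any():
        raise ValueError("missing covariate values; impute before fitting")
    out = pd.concat([merged[["patient_id", "treat", "time_days", "event"]], design], axis=1)
    return out


def fit_arm_model(
    dataset: TrialDataset, arm: str, outcome: str, variables: VariableSet
) -> ArmModelFit:
    """Prognostic Cox fit of one outcome on one arm's transformed covariates."""
    if arm not in (ARM_TREATMENT, ARM_CONTROL):
        raise ValueError(f"unknown arm {arm!r}")
    df = _merged_design(dataset, outcome, variables)
    df = df[df["treat"] == (1 if arm == ARM_TREATMENT else 0)]
    if df["event"].sum() < 1:
        raise ValueError(f"no events in {arm} arm for outcome {outcome}")
    res = fit_cox(df, list(variables.design_names))
    return ArmModelFit(
        arm=arm,
        outcome=outcome,
        coefficients=res.params,
        log_partial_likelihood=res.log_likelihood,
        n=res.n,
        n_events=res.n_events,
        converged=res.converged,
        message=res.message,
    )


def build_response_score(
    train: TrialDataset,
    outcome: str,
    variables: VariableSet,
    method: Literal["pooled_interaction", "two_fit"] = "pooled_interaction",
) -> ResponseScoreModel:
    """Build the RS for one outcome from training data.

    Returns a model with ``converged=False`` (rather than raising) when the
    underlying fits fail, so subset searches can skip the candidate.
    """
    df = _merged_design(train, outcome, variables)
    names = list(variables.design_names)
    n_t = int((df["treat"] == 1).sum())
    n_c = int((df["treat"] == 0).sum())

    def failed() -> ResponseScoreModel:
        return ResponseScoreModel(
            outcome, variables, float("nan"), {}, "fitted", n_t, n_c, converged=False
        )

    if method == "pooled_interaction":
        work = df.copy()
        inter_names = []
        for name in names:
            work[f"treat_x_{name}"] = work["treat"] * work[name]
            inter_names.append(f"treat_x_{name}")
        res = fit_cox(work, ["treat"] + names + inter_names)
        if not res.converged:
            return failed()
        coefs = {name: res.params[f"treat_x_{name}"] for name in names}
        intercept = res.params["treat"]
    elif method == "two_fit":
        fits = {}
        for arm in (ARM_TREATMENT, ARM_CONTROL):
            sub = df[df["treat"] == (1 if arm == ARM_TREATMENT else 0)]
            if sub["event"].sum() < 1:
                return failed()
            fits[arm] = fit_cox(sub, names)
            if not fits[arm].converged:
                return failed()
        coefs = {
            name: fits[ARM_TREATMENT].params[name] - fits[ARM_CONTROL].params[name]
            for name in names
        }
        main = df.copy()
        res_main = fit_cox(main, ["treat"] + names)
        if not res_main.converged:
            return failed()
        intercept = res_main.params["treat"]
    else:
        raise ValueError(f"unknown method {method!r}")

    if not names:  # degenerate empty subset: RS = overall treatment log HR
        res0 = fit_cox(df, ["treat"])
        if not res0.converged:
            return failed()
        intercept = res0.params["treat"]
        coefs = {}
    return ResponseScoreModel(
        outcome=outcome,
        variables=variables,
        intercept=float(intercept),
        coefficients={k: float(v) for k, v in coefs.items()},
        provenance="fitted",
        n_treatment=n_t,
        n_control=n_c,
        converged=True,
    )


def overall_treatment_effect(dataset: TrialDataset, outcome: str) -> CoxResult:
    """Unadjusted (treatment-only) Cox fit on the whole dataset."""
    df = dataset.merged(outcome)
    return fit_cox(df, ["treat"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Classification:
    patient_id: str
    outcome: str
    score: float
    hr: float
    threshold: float
    label: Literal["responder", "non_responder"]
    threshold_kind: Literal["train_quartile", "overall_hr"]


def classify(
    model: ResponseScoreModel,
    scores: pd.Series,
    threshold_kind: Literal["train_quartile", "overall_hr"],
    reference,
) -> pd.DataFrame:
    """Label patients responder / non-responder.

    * ``train_quartile``: threshold = 25th percentile (linear-interpolation
      quantile) of ``reference`` (the training-score distribution).
    * ``overall_hr``: threshold = log(reference), the whole-group HR.

    Ties are inclusive: score <= threshold -> responder.
    """
    if threshold_kind == "train_quartile":
        ref = np.asarray(reference, dtype=float)
        threshold = float(np.quantile(ref, 0.25))
    elif threshold_kind == "overall_hr":
        hr = float(reference)
        if hr <= 0:
            raise ValueError("overall HR must be positive")
        threshold = math.log(hr)
    else:
        raise ValueError(f"unknown threshold_kind {threshold_kind!r}")
    out = pd.DataFrame(
        {
            "patient_id": scores.index,
            "outcome": model.outcome,
            "score": scores.to_numpy(dtype=float),
            "hr": np.exp(scores.to_numpy(dtype=float)),
            "threshold": threshold,
            "threshold_kind": threshold_kind,
        }
    )
    out["label"] = np.where(out["score"] <= threshold, "responder", "non_responder")
    return out
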