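"""Trial data model, file I/O, cohort splitting, balance checks, imputation.

The in-memory containers are pandas DataFrames: one baseline table (one row
per patient) and one long event table (one row per patient x outcome).
A :class:`TrialDataset` bundles the two and enforces referential integrity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._utils import DegenerateInputError, round_half_up

ARM_TREATMENT = "treatment"
ARM_CONTROL = "control"

#: default mapping of external arm labels to the canonical two arms
DEFAULT_ARM_MAP = {
    "treatment": ARM_TREATMENT,
    "control": ARM_CONTROL,
    "active": ARM_TREATMENT,
    "placebo": ARM_CONTROL,
    "siponimod": ARM_TREATMENT,
}

OUTCOMES = ("EDSS", "T25FW", "9HPT", "SDMT")

#: baseline covariate columns by tier (tier 1 is required by readers)
TIER1_COLUMNS = ("age", "sex", "edss", "relapses_2y", "disease_duration")
TIER2_COLUMNS = ("t25fw_base", "hpt9_base", "sdmt_base")
TIER3_COLUMNS = ("gd_count", "t2_volume")
TIER4_COLUMNS = ("cgm_volume", "thalamus_volume", "gfap", "nfl")
ALL_COVARIATE_COLUMNS = TIER1_COLUMNS + TIER2_COLUMNS + TIER3_COLUMNS + TIER4_COLUMNS


@dataclass
class BaselineProfile:
    """One patient's baseline covariates; any non-id field may be missing."""

    patient_id: str
    arm: str
    age: float | None = None
    sex: str | None = None
    edss: float | None = None
    relapses_2y: float | None = None
    disease_duration: float | None = None
    t25fw_base: float | None = None
    hpt9_base: float | None = None
    sdmt_base: float | None = None
    gd_count: float | None = None
    t2_volume: float | None = None
    cgm_volume: float | None = None
    thalamus_volume: float | None = None
    gfap: float | None = None
    nfl: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in (ARM_TREATMENT, ARM_CONTROL):
            raise ValueError(f"unknown arm {self.arm!r} for patient {self.patient_id!r}")
        if self.age is not None and not (0 < self.age < 120):
            raise ValueError(f"age {self.age} outside (0, 120)")
        if self.edss is not None and not (0 <= self.edss <= 10):
            raise ValueError(f"EDSS {self.edss} outside [0, 10]")
        if self.relapses_2y is not None and self.relapses_2y < 0:
            raise ValueError("relapses_2y must be non-negative")
        if self.disease_duration is not None and self.disease_duration <= 0:
            raise ValueError("disease_duration must be > 0")


# ---------------------------------------------------------------------------
# variable sets and transforms
# ---------------------------------------------------------------------------

Transform = Literal["identity", "log10", "male"]


def transformed_name(raw: str, transform: Transform) -> str:
    if transform == "identity":
        return raw
    if transform == "log10":
        return f"log10_{raw}"
    if transform == "male":
        return "male"
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class VariableSet:
    """An ordered list of (raw baseline field, transform) pairs.

    The transformed columns are the covariates every proportional-hazards
    fit in the pipeline sees; e.g. disease duration enters as its base-10
    logarithm and sex as a male indicator.
    """

    name: str
    variables: tuple[tuple[str, Transform], ...]

    @property
    def raw_names(self) -> tuple[str, ...]:
        return tuple(raw for raw, _ in self.variables)

    @property
    def design_names(self) -> tuple[str, ...]:
        return tuple(transformed_name(raw, tr) for raw, tr in self.variables)

    def subset(self, raw_names: Sequence[str]) -> "VariableSet":
        keep = [v for v in self.variables if v[0] in set(raw_names)]
        return VariableSet(name=f"{self.name}[{','.join(r for r, _ in keep)}]", variables=tuple(keep))

    def design_matrix(self, baselines: pd.DataFrame) -> pd.DataFrame:
        """Apply the transforms and return the design columns."""
        cols = {}
        for raw, tr in self.variables:
            if raw not in baselines.columns:
                raise KeyError(f"baseline table lacks column {raw!r}")
            x = baselines[raw]
            if tr == "identity":
                cols[raw] = pd.to_numeric(x)
            elif tr == "log10":
                vals = pd.to_numeric(x)
                if (vals <= 0).any():
                    raise ValueError(f"log10 transform of {raw!r} requires positive values")
                cols[f"log10_{raw}"] = np.log10(vals)
            elif tr == "male":
                cols["male"] = (x == "male").astype(float).where(x.notna())
            else:  # pragma: no cover
                raise ValueError(f"unknown transform {tr!r}")
        return pd.DataFrame(cols, index=baselines.index)


CLINICAL_PRACTICE = VariableSet(
    "CLINICAL_PRACTICE",
    (
        ("age", "identity"),
        ("sex", "male"),
        ("relapses_2y", "identity"),
        ("disease_duration", "log10"),
        ("edss", "identity"),
    ),
)

ADVANCED_CLINICAL = VariableSet(
    "ADVANCED_CLINICAL",
    CLINICAL_PRACTICE.variables
    + (("t25fw_base", "log10"), ("hpt9_base", "log10"), ("sdmt_base", "identity")),
)

CLINICAL_MRI = VariableSet(
    "CLINICAL_MRI",
    ADVANCED_CLINICAL.variables + (("gd_count", "identity"), ("t2_volume", "log10")),
)

EXPERIMENTAL = VariableSet(
    "EXPERIMENTAL",
    CLINICAL_MRI.variables
    + (
        ("cgm_volume", "identity"),
        ("thalamus_volume", "identity"),
        ("gfap", "log10"),
        ("nfl", "log10"),
    ),
)

VARIABLE_SETS = {
    vs.name: vs for vs in (CLINICAL_PRACTICE, ADVANCED_CLINICAL, CLINICAL_MRI, EXPERIMENTAL)
}


def load_variable_set(path: str | Path) -> VariableSet:
    """Read a custom variable set from a JSON config.

    Format: ``{"name": ..., "variables": [["age", "identity"], ...]}``.
    """
    spec = json.loads(Path(path).read_text())
    return VariableSet(spec["name"], tuple((r, t) for r, t in spec["variables"]))


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class TrialDataset:
    """Baseline table + long event table with referential integrity."""

    baselines: pd.DataFrame
    events: pd.DataFrame
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        b, e = self.baselines, self.events
        if b["patient_id"].duplicated().any():
            dup = b.loc[b["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValueError(f"duplicate patient_id {dup!r} in baseline table")
        if len(e):
            known = set(b["patient_id"])
            orphan = set(e["patient_id"]) - known
            if orphan:
                raise ValueError(f"events refer to unknown patients: {sorted(orphan)[:5]}")
            if e.duplicated(subset=["patient_id", "outcome"]).any():
                raise ValueError("more than one event record per (patient, outcome)")

    @property
    def n_patients(self) -> int:
        return len(self.baselines)

    def subset(self, patient_ids: Iterable[str]) -> "TrialDataset":
        ids = set(patient_ids)
        return TrialDataset(
            self.baselines[self.baselines["patient_id"].isin(ids)].reset_index(drop=True),
            self.events[self.events["patient_id"].isin(ids)].reset_index(drop=True),
            provenance=self.provenance,
            seed=self.seed,
        )

    def merged(self, outcome: str) -> pd.DataFrame:
        """Baselines joined with (time_days, event) for one outcome.

        Adds a 0/1 ``treat`` indicator column.
        """
        ev = self.events[self.events["outcome"] == outcome]
        if ev.empty:
            raise ValueError(f"no event records for outcome {outcome!r}")
        out = self.baselines.merge(ev[["patient_id", "time_days", "event"]], on="patient_id")
        out["treat"] = (out["arm"] == ARM_TREATMENT).astype(int)
        return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA"]


def _to_numeric(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    for col in columns:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric value in column {col!r}") from exc
    return df


def read_baseline_table(path: str | Path, arm_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a baseline CSV; missing cells are empty or "NA".

    Rejects duplicate patient ids, unknown arm labels (reporting the row
    number) and non-numeric values in numeric columns (reporting the
    column name).
    """
    arm_map = {k.lower(): v for k, v in (arm_map or DEFAULT_ARM_MAP).items()}
    df = pd.read_csv(path, dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    required = {"patient_id", "arm", *TIER1_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"baseline table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup!r}")
    arms = df["arm"].str.lower().map(arm_map)
    if arms.isna().any():
        row = int(arms.index[arms.isna()][0])
        raise ValueError(f"unknown arm label {df['arm'].iloc[row]!r} at row {row + 2}")
    df["arm"] = arms
    sex = df["sex"].str.lower()
    bad_sex = sex.notna() & ~sex.isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(f"unknown sex label {df.loc[bad_sex, 'sex'].iloc[0]!r}")
    df["sex"] = sex
    numeric = [c for c in df.columns if c not in ("patient_id", "arm", "sex")]
    return _to_numeric(df, numeric)


def write_baseline_table(baselines: pd.DataFrame, path: str | Path) -> None:
    baselines.to_csv(path, index=False, na_rep="NA")


def read_events_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=_NA_VALUES, keep_default_na=False)
    required = {"patient_id", "outcome", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    bad = set(df["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes in events table: {sorted(bad)}")
    df = _to_numeric(df, ["time_days", "event"])
    df["event"] = df["event"].astype(int)
    return df


def write_events_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_visits_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=_NA_VALUES, keep_default_na=False)
    if not {"patient_id", "day"} <= set(df.columns):
        raise ValueError("visits table needs patient_id and day columns")
    return _to_numeric(df, [c for c in df.columns if c != "patient_id"])


def write_visits_table(visits: pd.DataFrame, path: str | Path) -> None:
    visits.to_csv(path, index=False, na_rep="")


def write_dataset(dataset: TrialDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_baseline_table(dataset.baselines, out / "baselines.csv")
    write_events_table(dataset.events, out / "events.csv")


def read_dataset(in_dir: str | Path, provenance: str = "") -> TrialDataset:
    in_dir = Path(in_dir)
    return TrialDataset(
        read_baseline_table(in_dir / "baselines.csv"),
        read_events_table(in_dir / "events.csv"),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Cohen's d and the 70/30 split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohensD:
    variable: str
    d: float
    flag: bool  # |d| > 0.10, the conventional balance alarm


def cohens_d(
    values_a: Sequence[float],
    values_b: Sequence[float],
    kind: Literal["continuous", "proportion"] = "continuous",
    variable: str = "",
) -> CohensD:
    """Standardized mean (or proportion) difference between two groups.

    Continuous: (mean_a - mean_b) / pooled SD with n-1 weights.
    Proportion: (p_a - p_b) / sqrt(pbar (1 - pbar)) with pbar pooled.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        na, nb = len(a), len(b)
        pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        diff = a.mean() - b.mean()
        if pooled_var == 0:
            if diff != 0:
                raise DegenerateInputError("zero pooled SD with unequal means")
            d = 0.0
        else:
            d = diff / math.sqrt(pooled_var)
    elif kind == "proportion":
        pa, pb = a.mean(), b.mean()
        pbar = (a.sum() + b.sum()) / (len(a) + len(b))
        denom = math.sqrt(pbar * (1 - pbar))
        diff = pa - pb
        if denom == 0:
            if diff != 0:
                raise DegenerateInputError("degenerate pooled proportion")
            d = 0.0
        else:
            d = diff / denom
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return CohensD(variable=variable, d=float(d), flag=abs(d) > 0.10)


def _balance_table(train: pd.DataFrame, valid: pd.DataFrame) -> list[CohensD]:
    out: list[CohensD] = []
    for col in train.columns:
        if col == "patient_id":
            continue
        try:
            if col == "arm":
                out.append(
                    cohens_d(
                        (train[col] == ARM_TREATMENT).astype(float),
                        (valid[col] == ARM_TREATMENT).astype(float),
                        kind="proportion",
                        variable="arm",
                    )
                )
            elif col == "sex":
                out.append(
                    cohens_d(
                        (train[col] == "male").astype(float)[train[col].notna()],
                        (valid[col] == "male").astype(float)[valid[col].notna()],
                        kind="proportion",
                        variable="sex",
                    )
                )
            else:
                out.append(cohens_d(train[col], valid[col], "continuous", variable=col))
        except (ValueError, DegenerateInputError):
            continue
    return out


@dataclass
class SplitResult:
    train: TrialDataset
    validation: TrialDataset
    fraction: float
    seed: int
    balance: list[CohensD] = field(default_factory=list)


def split_train_validation(dataset: TrialDataset, fraction: float = 0.7, seed: int = 0) -> SplitResult:
    """Simple (unstratified) random split; size = round-half-up(fraction*N).

    N=1645 at fraction 0.7 gives 1152 training / 493 validation patients.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if dataset.n_patients == 0:
        raise ValueError("dataset is empty")
    n = dataset.n_patients
    n_train = int(round_half_up(fraction * n, 0))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = dataset.baselines["patient_id"].to_numpy()
    train_ids = ids[perm[:n_train]]
    valid_ids = ids[perm[n_train:]]
    train = dataset.subset(train_ids)
    valid = dataset.subset(valid_ids)
    balance = _balance_table(train.baselines, valid.baselines)
    return SplitResult(train, valid, fraction, seed, balance)


# ---------------------------------------------------------------------------
# multiple imputation by chained equations
# ---------------------------------------------------------------------------


def mice_impute(
    dataset: TrialDataset,
    n_imputations: int = 10,
    seed: int = 0,
    n_cycles: int = 10,
    k_pmm: int = 5,
) -> list[TrialDataset]:
    """Chained-equation imputation of baseline covariates (m completed sets).

    Each covariate is regressed on all others, cycling ``n_cycles`` times
    per imputation; draws use predictive-mean matching, so imputed values
    stay on the observed support (EDSS grid, integer relapse counts).
    Observed cells are preserved exactly. Arm and outcomes must be complete.
    """
    from statsmodels.imputation.mice import MICEData

    b = dataset.baselines
    if b["arm"].isna().any():
        raise ValueError("missingness in arm is not supported")
    covs = [c for c in b.columns if c not in ("patient_id", "arm")]
    fully_missing = [c for c in covs if b[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variable 100% missing: {fully_missing[0]!r}")

    work = b[covs].copy()
    if "sex" in work.columns:
        work["sex"] = (work["sex"] == "male").astype(float).where(b["sex"].notna())

    def restore(completed: pd.DataFrame) -> pd.DataFrame:
        out = b.copy()
        for c in covs:
            if c == "sex":
                out["sex"] = np.where(completed["sex"] >= 0.5, "male", "female")
            else:
                out[c] = completed[c].to_numpy()
        return out

    if not work.isna().any().any():
        return [
            replace(dataset, baselines=b.copy(), provenance=f"{dataset.provenance}|imp{i + 1}")
            for i in range(n_imputations)
        ]

    # MICEData draws from numpy's legacy global RNG
    np.random.seed(seed % (2**31))
    md = MICEData(work.reset_index(drop=True))
    for col in work.columns[work.isna().any()]:
        md.set_imputer(col, k_pmm=k_pmm)
    completed_sets = []
    for i in range(n_imputations):
        md.update_all(n_cycles)
        completed_sets.append(
            replace(
                dataset,
                baselines=restore(md.data.copy()),
                provenance=f"{dataset.provenance}|imp{i + 1}",
            )
        )
    return completed_sets
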