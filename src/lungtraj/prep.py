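"""Visit-table preparation: Z-scoring, age centering, design matrix, filters.

The trajectory model's time axis is "years since presumed peak lung
function": age centered at 20 for men and 18 for women, so the intercept is
interpretable as the Z-score near peak lung function. The predictor set is
fixed to [intercept, t, pack-years, smoker x t].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PEAK_AGE = {"male": 20.0, "female": 18.0}
REQUIRED_VISIT_COLUMNS = (
    "subject_id", "sex", "age", "fev1_z", "fvc_z", "packyears", "current_smoker",
)
#: observations are tolerated slightly below the centering age
MIN_YEARS_SINCE_PEAK = -5.0


def years_since_peak(age: float, sex: str) -> float:
    """Age centered at the presumed peak of lung function (20 M / 18 F)."""
    if age <= 0:
        raise ValueError("age must be positive")
    try:
        return float(age) - PEAK_AGE[sex]
    except KeyError:
        raise ValueError(f"unknown sex category {sex!r}; expected male/female")


def years_since_peak_vec(age, sex):
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if not np.isin(sex, list(PEAK_AGE)).all():
        bad = sorted(set(sex.ravel()) - set(PEAK_AGE))
        raise ValueError(f"unknown sex categories {bad}")
    peak = np.where(sex == "male", PEAK_AGE["male"], PEAK_AGE["female"])
    return age - peak


def zscore(measured, reference_mean, reference_sd):
    """Standardized deviation from a pluggable reference equation."""
    reference_sd = np.asarray(reference_sd, dtype=float)
    if np.any(reference_sd <= 0):
        raise ValueError("reference SD must be positive")
    return (np.asarray(measured, dtype=float) - reference_mean) / reference_sd


@dataclass
class DesignMatrix:
    """Per-observation predictors and bivariate Z-score targets.

    ``X`` has columns [1, t, packyears, smoker*t]; ``Y`` columns
    [fev1_z, fvc_z]. ``subject_ids`` holds the unique ids in first-appearance
    order and ``subject_index`` maps each observation row to its position.
    """

    X: np.ndarray
    Y: np.ndarray
    subject_ids: np.ndarray
    subject_index: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def __post_init__(self):
        if self.X.shape != (len(self.subject_index), 4):
            raise ValueError("X must be (n_obs, 4)")
        if self.Y.shape != (len(self.subject_index), 2):
            raise ValueError("Y must be (n_obs, 2)")


def build_design(visits: pd.DataFrame) -> DesignMatrix:
    """One design row per visit; order preserved, no filtering applied."""
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"visit table missing required columns: {missing}")
    y = visits[["fev1_z", "fvc_z"]].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite Z-score in visit table; drop or impute upstream")
    t = years_since_peak_vec(visits["age"].to_numpy(), visits["sex"].to_numpy())
    if np.any(t < MIN_YEARS_SINCE_PEAK):
        raise ValueError(
            f"years since peak below the tolerated minimum {MIN_YEARS_SINCE_PEAK}"
        )
    py = visits["packyears"].to_numpy(dtype=float)
    if np.any(py < 0):
        raise ValueError("negative pack-years")
    smoker = visits["current_smoker"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(visits)), t, py, smoker * t])

    ids = visits["subject_id"].to_numpy()
    uniq, idx = np.unique(ids, return_index=True)
    subject_ids = ids[np.sort(idx)]  # first-appearance order
    lookup = {s: i for i, s in enumerate(subject_ids)}
    subject_index = np.array([lookup[s] for s in ids], dtype=int)
    return DesignMatrix(X=X, Y=y, subject_ids=subject_ids, subject_index=subject_index)


def filter_training(
    visits: pd.DataFrame,
    max_packyears: float = 150.0,
    min_visits: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Training-sample filters: drop >150 pack-year observations first, then
    subjects left with fewer than two usable visits.

    Visits with a missing FEV1 or FVC Z-score are dropped (not imputed).
    Returns the retained table and an exclusion log with one row per dropped
    visit or subject. Raises if nothing survives.
    """
    log: list[dict] = []
    df = visits.copy()

    bad_z = df["fev1_z"].isna() | df["fvc_z"].isna()
    for _, row in df[bad_z].iterrows():
        log.append({"subject_id": row["subject_id"], "visit": row.get("visit"),
                    "reason": "missing_zscore"})
    df = df[~bad_z]

    over = df["packyears"] > max_packyears
    for _, row in df[over].iterrows():
        log.append({"subject_id": row["subject_id"], "visit": row.get("visit"),
                    "reason": f"packyears_gt_{max_packyears:g}"})
    df = df[~over]

    counts = df.groupby("subject_id", sort=False)["subject_id"].transform("size")
    few = counts < min_visits
    for sid in df.loc[few, "subject_id"].unique():
        log.append({"subject_id": sid, "visit": None,
                    "reason": f"fewer_than_{min_visits}_visits"})
    df = df[~few].reset_index(drop=True)

    if df.empty:
        raise ValueError("no observations survive the training filters")
    log_df = pd.DataFrame(log, columns=["subject_id", "visit", "reason"])
    return df, log_df


def read_visits(path) -> pd.DataFrame:
    """CSV visit-table reader (columns documented in the README)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
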