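"""CT dysanapsis: the airway-to-lung (a/l) ratio and its group comparisons.

The a/l ratio is the geometric mean of 13 labeled airway lumen diameters
(mm) divided by the cube root of total lung volume (converted from liters
to mm^3), so the ratio is dimensionless; lower values mean smaller airways
relative to lung size, i.e. greater dysanapsis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .synthetic import AIRWAY_SITES

MM3_PER_L = 1.0e6


def al_ratio(diameters, lung_volume_l: float) -> float:
    """a/l ratio for one subject.

    ``diameters`` maps each of the 13 anatomic labels to a lumen diameter in
    mm; ``lung_volume_l`` is total lung volume in liters. All 13 labeled
    locations must be present and positive.
    """
    if lung_volume_l is None or not np.isfinite(lung_volume_l) or lung_volume_l <= 0:
        raise ValueError("lung volume must be positive and finite")
    diameters = dict(diameters)
    logs = []
    for site in AIRWAY_SITES:
        if site not in diameters:
            raise ValueError(f"missing airway diameter for location {site!r}")
        d = diameters[site]
        if not np.isfinite(d) or d <= 0:
            raise ValueError(f"non-positive airway diameter at location {site!r}")
        logs.append(np.log(d))
    extra = set(diameters) - set(AIRWAY_SITES)
    if extra:
        raise ValueError(f"unexpected airway locations: {sorted(extra)}")
    geo = np.exp(np.mean(logs))
    return float(geo / np.cbrt(lung_volume_l * MM3_PER_L))


def al_ratio_table(ct: pd.DataFrame) -> pd.Series:
    """Vectorized a/l ratio over a CT table (one row per subject)."""
    missing = [s for s in AIRWAY_SITES if s not in ct.columns]
    if missing:
        raise ValueError(f"CT table missing diameter columns: {missing}")
    d = ct[list(AIRWAY_SITES)].to_numpy(dtype=float)
    vol = ct["lung_volume_l"].to_numpy(dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        bad = np.argwhere(~np.isfinite(d) | (d <= 0))[0]
        raise ValueError(
            f"non-positive diameter at row {bad[0]}, location {AIRWAY_SITES[bad[1]]!r}"
        )
    if np.any(~np.isfinite(vol)) or np.any(vol <= 0):
        raise ValueError("non-positive lung volume in CT table")
    geo = np.exp(np.log(d).mean(axis=1))
    return pd.Series(geo / np.cbrt(vol * MM3_PER_L), index=ct.index, name="al_ratio")


def tertiles(values) -> np.ndarray:
    """Empirical tertile labels 1..3; tertile 1 = lowest a/l = most dysanapsis."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 3:
        raise ValueError("need at least 3 finite values for tertiles")
    if np.ptp(finite) == 0:
        raise ValueError("tertile cut-points undefined: all values identical")
    labels = pd.qcut(values, 3, labels=False, duplicates="drop")
    labels = np.asarray(labels, dtype=float) + 1
    if np.nanmax(labels) < 3:
        raise ValueError("tertile cut-points collapse under heavy ties")
    return labels


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U: exact null distribution when n+m <= 12 and
    there are no cross-ties, otherwise the tie-corrected normal approximation
    with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_to_reference(values_by_group: dict, pairs: list[tuple]) -> pd.DataFrame:
    """Mann-Whitney tests over an explicit pair list with Bonferroni
    adjustment; the family size is the number of testable pairs.

    Groups with fewer than 2 values are flagged and excluded from the family.
    Returns columns (group_a, group_b, n_a, n_b, U, p_raw, p_adj, tested).
    """
    rows = []
    for a, b in pairs:
        xa = np.asarray(values_by_group.get(a, []), dtype=float)
        xb = np.asarray(values_by_group.get(b, []), dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"group_a": a, "group_b": b, "n_a": len(xa),
                         "n_b": len(xb), "U": np.nan, "p_raw": np.nan,
                         "tested": False})
            continue
        U, p = mann_whitney(xa, xb)
        rows.append({"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
                     "U": U, "p_raw": p, "tested": True})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                     "U", "p_raw", "tested"])
    m = int(df["tested"].sum())
    df["p_adj"] = np.where(df["tested"], np.minimum(1.0, df["p_raw"] * max(m, 1)),
                           np.nan)
    return df


def age_trend(measure, age, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group OLS of a CT measure on age.

    Returns slope, normal-theory CI, p and R^2 per group; groups with fewer
    than 3 points or no age variance are skipped with a log entry. Used as a
    cross-sectional confound check (a static anatomic feature should show no
    age trend).
    """
    import statsmodels.api as sm

    measure = np.asarray(measure, dtype=float)
    age = np.asarray(age, dtype=float)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sel = (groups == g) & np.isfinite(measure) & np.isfinite(age)
        if sel.sum() < 3 or np.var(age[sel]) == 0:
            rows.append({"group": g, "n": int(sel.sum()), "slope": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                         "r2": np.nan, "skipped": True,
                         "reason": "degenerate group"})
            continue
        if np.ptp(measure[sel]) == 0:  # flat measure: slope 0 by definition
            rows.append({"group": g, "n": int(sel.sum()), "slope": 0.0,
                         "ci_lo": 0.0, "ci_hi": 0.0, "p": 1.0, "r2": 0.0,
                         "skipped": False, "reason": ""})
            continue
        X = sm.add_constant(age[sel])
        fit = sm.OLS(measure[sel], X).fit()
        lo, hi = fit.conf_int(alpha)[1]
        rows.append({"group": g, "n": int(sel.sum()),
                     "slope": float(fit.params[1]), "ci_lo": float(lo),
                     "ci_hi": float(hi), "p": float(fit.pvalues[1]),
                     "r2": float(fit.rsquared), "skipped": False, "reason": ""})
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    return df


def read_ct(path) -> pd.DataFrame:
    """CT table CSV reader (13 diameter columns + volume + Pi10 + Perc15)."""
    df = pd.read_csv(path)
    required = ["subject_id", *AIRWAY_SITES, "lung_volume_l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing CT columns {missing}")
    return df
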