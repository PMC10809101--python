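"""Compare CT dysanapsis across fitted trajectories.

Computes the a/l ratio per subject, assigns a/l tertiles, runs Mann-Whitney
comparisons (reference vs each at-risk trajectory, and adjacent at-risk
pairs, Bonferroni-adjusted within each family), and checks cross-sectional
age trends of a/l, Pi10 and Perc15 as confound diagnostics.
"""

import numpy as np
import pandas as pd

from lungtraj import dysanapsis as dys
from lungtraj import trajectory as traj
from lungtraj.pipeline import _pair_families

COHORT = "results/cohort"
OUT = "results/dysanapsis"


def main():
    import os

    os.makedirs(OUT, exist_ok=True)
    model = traj.TrajectoryModel.from_json("results/model/model.json")
    ct = dys.read_ct(f"{COHORT}/ct.csv")
    assignments = pd.read_csv("results/assignments/training_assignments.csv")

    ct = ct.copy()
    ct["al_ratio"] = dys.al_ratio_table(ct)
    ct["al_tertile"] = dys.tertiles(ct["al_ratio"])
    merged = ct.merge(
        assignments[["subject_id", "hard_label"]].rename(
            columns={"hard_label": "trajectory"}),
        on="subject_id", how="inner",
    )
    merged[["subject_id", "al_ratio", "al_tertile", "trajectory"]].to_csv(
        f"{OUT}/al_ratios.csv", index=False)

    scores = model.severity_scores()
    reference = int(np.argmin(np.abs(scores)))
    chain = [reference] + [int(k) for k in np.argsort(-scores)
                           if scores[k] < scores[reference]]
    groups = {int(k): g["al_ratio"].to_numpy()
              for k, g in merged.groupby("trajectory")}
    fam_ref, fam_adj = _pair_families(reference, chain)
    tab_ref = dys.compare_to_reference(groups, fam_ref)
    tab_ref["family"] = "reference_vs_at_risk"
    tab_adj = dys.compare_to_reference(groups, fam_adj)
    tab_adj["family"] = "adjacent_at_risk"
    table = pd.concat([tab_ref, tab_adj], ignore_index=True)
    table.to_csv(f"{OUT}/comparisons.csv", index=False)
    print(f"reference trajectory: {reference}; severity chain: {chain}")
    print("group medians (a/l):",
          {k: round(float(np.median(v)), 4) for k, v in sorted(groups.items())})
    sig = table[table["tested"] & (table["p_adj"] < 0.05)]
    print(f"{len(sig)}/{int(table['tested'].sum())} comparisons significant "
          "after Bonferroni")

    base_age = pd.read_csv(f"{COHORT}/visits.csv").sort_values(
        ["subject_id", "age"]).groupby("subject_id").head(1)[["subject_id", "age"]]
    trend_df = merged.merge(base_age, on="subject_id")
    trends = []
    for measure in ("al_ratio", "pi10", "perc15"):
        t = dys.age_trend(trend_df[measure], trend_df["age"],
                          trend_df["trajectory"])
        t["measure"] = measure
        trends.append(t)
    trend = pd.concat(trends, ignore_index=True)
    trend.to_csv(f"{OUT}/age_trends.csv", index=False)
    n_sig = int(trend["significant"].fillna(False).sum())
    print(f"age-trend check: {n_sig}/{len(trend)} per-trajectory slopes "
          "differ from 0 at alpha=0.05")


if __name__ == "__main__":
    main()
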