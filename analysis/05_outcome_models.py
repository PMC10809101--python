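"""Trajectory-stratified outcome models and the dysanapsis association.

Fits reduced and full extended Cox (mortality, age time scale) and
zero-inflated negative binomial (exacerbations, person-years offset) models
with the reference trajectory as baseline, then the forward-stepwise
multinomial logistic model of trajectory assignment on the reference-SD
scaled a/l ratio and parental history flags.
"""

import numpy as np
import pandas as pd

from lungtraj import risk
from lungtraj import trajectory as traj
from lungtraj.synthetic import PARENTAL_FLAGS

COHORT = "results/cohort"
OUT = "results/outcomes"


def main():
    import os

    os.makedirs(OUT, exist_ok=True)
    model = traj.TrajectoryModel.from_json("results/model/model.json")
    outcomes = pd.read_csv(f"{COHORT}/outcomes.csv")
    assignments = pd.read_csv("results/assignments/training_assignments.csv")
    al = pd.read_csv("results/dysanapsis/al_ratios.csv")

    lab = assignments[["subject_id", "hard_label"]].rename(
        columns={"hard_label": "trajectory"})
    merged = outcomes.merge(lab, on="subject_id", how="inner")
    scores = model.severity_scores(
        packyears=float(merged["packyears"].median()))
    reference = int(np.argmin(np.abs(scores)))

    hr_tabs, irr_tabs = [], []
    for form in ("reduced", "full"):
        hr = risk.cox_mortality(merged, merged["trajectory"], form,
                                reference=reference)
        hr["model_form"] = form
        hr["ph_p"] = hr.attrs["ph_p"]
        hr_tabs.append(hr)
        irr = risk.zinb_exacerbations(merged, merged["trajectory"], form,
                                      reference=reference)
        irr["model_form"] = form
        irr["fit"] = irr.attrs["model"]
        irr_tabs.append(irr)
    hr_df = pd.concat(hr_tabs, ignore_index=True)
    irr_df = pd.concat(irr_tabs, ignore_index=True)
    hr_df.to_csv(f"{OUT}/hr_table.csv", index=False)
    irr_df.to_csv(f"{OUT}/irr_table.csv", index=False)
    red = hr_df[hr_df["model_form"] == "reduced"]
    print(f"reference trajectory {reference}; reduced-model HRs:")
    for _, r in red.iterrows():
        print(f"  traj {int(r['trajectory'])}: HR {r['hr']:.2f} "
              f"({r['ci_lo']:.2f}, {r['ci_hi']:.2f})")
    print(f"PH check (min scaled-Schoenfeld p over trajectory dummies): "
          f"{red['ph_p'].iloc[0]:.3f}")

    assoc = al.merge(outcomes, on="subject_id", how="inner")
    scaled, sd_ref = risk.scale_by_reference_sd(
        assoc["al_ratio"], assoc["trajectory"], reference)
    preds = pd.DataFrame({"al_scaled": scaled})
    for flag in PARENTAL_FLAGS:
        preds[flag] = assoc[flag].astype(float)
    rrr, path = risk.multinomial_stepwise(
        assoc["trajectory"], preds, reference=reference)
    rrr.to_csv(f"{OUT}/rrr_table.csv", index=False)
    print(f"a/l scaled by reference-trajectory SD {sd_ref:.4f}")
    print("stepwise selection path:", [s["entered"] for s in path])
    al_rows = rrr[rrr["predictor"] == "al_scaled"]
    for _, r in al_rows.iterrows():
        print(f"  traj {int(r['trajectory'])} vs {reference}: RRR per SD "
              f"decrease {r['rrr']:.2f} ({r['ci_lo']:.2f}, {r['ci_hi']:.2f})")


if __name__ == "__main__":
    main()
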