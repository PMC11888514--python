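"""Fit ITT, per-protocol and biomarker-based Cox contrasts on a simulated trial.

The generator plants a true protective effect of actual flavanol exposure
(total CVD hazard ratio 0.65 in the exposed).  Because 20% of participants
obtain the dose from their background diet and a third of the intervention
arm does not adhere, the randomized (ITT) contrast is attenuated toward the
null; per-protocol censoring at self-reported non-adherence recovers part of
the effect and the biomarker-defined groups nearly all of it.  Fits use the
full covariate ladder's model 2 (age, sex, recruitment cohort, BMI, smoking,
aspirin; continuous terms as 3-knot restricted cubic splines) with the
proportional-hazards check, and adjusted cumulative-incidence curves are
written at the reference profile (age 75, male, BMI 25, never-smoker, no
aspirin, WHI).
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from flavatrial import (
    COSMOS_THRESHOLDS,
    CohortParams,
    classify_participants,
    cumulative_incidence,
    generate_cohort,
    run_contrasts,
)
from flavatrial.cohort import ENDPOINTS


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=20000)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = parser.parse_args()

    params = CohortParams(n_total=args.n, seed=args.seed)
    participants, samples, reports, events, _ = generate_cohort(params)
    cls = classify_participants(participants, samples, COSMOS_THRESHOLDS)

    table, results = run_contrasts(
        participants, events, self_reports=reports, classifications=cls,
        model_ids=[2], endpoints=ENDPOINTS, run_ph_test=True,
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "table2.csv", index=False)

    print(f"simulated {args.n} participants; true exposure HRs: "
          + ", ".join(f"{ep} {np.exp(b):.2f}" for ep, b in params.true_log_hr.items()))
    print("\nHR (95% CI) by contrast, model 2:")
    for ep in ENDPOINTS:
        sub = table[table["endpoint"] == ep].set_index("contrast")
        cells = "  ".join(
            f"{c}: {sub.loc[c, 'hr']:.2f} ({sub.loc[c, 'ci_low']:.2f}-{sub.loc[c, 'ci_high']:.2f})"
            for c in ("itt", "pp", "biomarker")
        )
        print(f"  {ep:20s} {cells}")
    ph_ps = [min(v["p"] for v in r.ph_test.values()) for r in results if r.ph_test]
    print(f"\nproportional-hazards check: smallest per-term p across fits = {min(ph_ps):.3f}")

    for r in results:
        if r.endpoint == "total_cvd" and r.contrast == "biomarker":
            for group, label in ((1, "active"), (0, "control")):
                curve = cumulative_incidence(r, group=group, model=2)
                curve.to_csv(args.outdir / f"incidence_total_cvd_{label}.csv", index=False)
                print(f"cumulative incidence at 3.6 y, biomarker {label}: "
                      f"{curve['incidence'].iloc[-1]:.3f}")


if __name__ == "__main__":
    main()
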