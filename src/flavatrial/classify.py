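"""Threshold classification of urine samples and participants.

A sample is "above" when either biomarker reaches its threshold (boundary
values count as above): gVLM_B and SREM_B have different half-lives, so
either one being high is evidence of intake at or above the reference dose.

Participants are assigned to biomarker-defined analysis groups:

* ``biomarker_active`` — above threshold at baseline or at any follow-up
  visit (an any-visit OR rule);
* ``biomarker_control`` — below at baseline and at every available follow-up;
* ``excluded`` — intervention-arm participants with no follow-up sample and a
  below-threshold baseline: their adherence cannot be determined, so neither
  group fits them;
* ``unclassifiable`` — no baseline sample (tracked in diagnostics, dropped
  from all biomarker analyses).

Note the asymmetry: a placebo-arm participant with no follow-up sample and a
below-threshold baseline is a valid control — their exposure is their
background diet, which the baseline sample measures.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .calibration import ThresholdPair
from .cohort import NONADHERENT_STATUSES

GROUPS = ("biomarker_active", "biomarker_control", "excluded", "unclassifiable")


def round_half_up_pct(numer: float, denom: float):
    """Integer percentage, half rounded up; None for an empty denominator."""
    if denom == 0:
        return None
    return int(math.floor(100.0 * numer / denom + 0.5))


def classify_samples(samples: pd.DataFrame, thresholds: ThresholdPair) -> pd.DataFrame:
    """Per-sample above/below status under the OR rule.

    Returns columns (participant_id, visit, above).  A sample missing both
    biomarker values is an error — silent classification of an empty sample
    would corrupt the group assignment.
    """
    gvlm = samples["gvlm"].to_numpy(float)
    srem = samples["srem"].to_numpy(float)
    both_missing = np.isnan(gvlm) & np.isnan(srem)
    if both_missing.any():
        rows = samples.index[both_missing].tolist()
        raise ValueError(f"samples with both biomarkers missing at rows {rows}; drop them upstream")
    above = (gvlm >= thresholds.t_gvlm) | (srem >= thresholds.t_srem)
    return pd.DataFrame(
        {
            "participant_id": samples["participant_id"].to_numpy(),
            "visit": samples["visit"].to_numpy(),
            "above": above,
        }
    )


def classify_participants(
    participants: pd.DataFrame, samples: pd.DataFrame, thresholds: ThresholdPair
) -> pd.DataFrame:
    """Assign every participant a biomarker analysis group.

    Vectorised: baseline status from the baseline sample, follow-up status as
    an OR over all follow-up visits.  Participants without a baseline sample
    are flagged ``unclassifiable``.
    """
    status = classify_samples(samples, thresholds)
    is_base = status["visit"] == "baseline"
    if status.loc[is_base].duplicated("participant_id").any():
        raise ValueError("multiple baseline samples for one participant")

    base = status.loc[is_base].set_index("participant_id")["above"]
    fu = (
        status.loc[~is_base]
        .groupby("participant_id")["above"]
        .any()
    )

    out = participants[["participant_id", "arm"]].copy()
    out["baseline_above"] = out["participant_id"].map(base)
    out["has_followup"] = out["participant_id"].isin(fu.index)
    out["followup_above"] = out["participant_id"].map(fu)  # NaN when no follow-up

    no_base = out["baseline_above"].isna()
    base_above = out["baseline_above"].eq(True)
    fu_above = out["followup_above"].eq(True)
    excluded = (out["arm"] == "intervention") & ~out["has_followup"] & ~base_above

    group = np.where(
        no_base,
        "unclassifiable",
        np.where(
            excluded,
            "excluded",
            np.where(base_above | fu_above, "biomarker_active", "biomarker_control"),
        ),
    )
    out["group"] = group
    out["baseline_above"] = base_above.where(~no_base)
    return out


def tabulate(
    classifications: pd.DataFrame,
    participants: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> dict:
    """Classification margins and group composition, with integer percentages.

    Mirrors the layout of a baseline/follow-up threshold table: above-threshold
    counts by arm at baseline over the whole cohort, baseline and follow-up
    counts within the follow-up subset, group sizes by arm with the percentage
    randomized to intervention, the excluded count, and (if ``samples`` is
    given) the share of participants below the LOQ on both biomarkers at
    baseline.
    """
    cls = classifications
    arm = cls["arm"]

    def cell(mask_n, mask_above):
        n = int(mask_n.sum())
        above = int((mask_n & mask_above).sum())
        return {"n": n, "above": above, "pct": round_half_up_pct(above, n)}

    classified = cls["group"] != "unclassifiable"
    base_above = cls["baseline_above"].eq(True)
    fu_above = cls["followup_above"].eq(True)
    has_fu = cls["has_followup"]

    table = {
        "baseline": {
            "all": cell(classified, base_above),
            "placebo": cell(classified & (arm == "placebo"), base_above),
            "intervention": cell(classified & (arm == "intervention"), base_above),
        },
        "followup_subset": {},
        "groups": {},
    }
    for label, mask in (
        ("all", classified & has_fu),
        ("placebo", classified & has_fu & (arm == "placebo")),
        ("intervention", classified & has_fu & (arm == "intervention")),
    ):
        table["followup_subset"][label] = {
            "baseline": cell(mask, base_above),
            "followup": cell(mask, fu_above),
        }

    n_total = int(classified.sum())
    for g in ("biomarker_active", "biomarker_control"):
        mask = cls["group"] == g
        n = int(mask.sum())
        n_i = int((mask & (arm == "intervention")).sum())
        table["groups"][g] = {
            "n": n,
            "placebo": n - n_i,
            "intervention": n_i,
            "pct_intervention": round_half_up_pct(n_i, n),
        }
    n_excl = int((cls["group"] == "excluded").sum())
    table["groups"]["excluded"] = {
        "n": n_excl,
        "pct_of_cohort": round_half_up_pct(n_excl, n_total),
    }
    table["groups"]["unclassifiable"] = {"n": int((~classified).sum())}
    table["analysis_n"] = int(cls["group"].isin(["biomarker_active", "biomarker_control"]).sum())
    table["cohort_n"] = n_total

    if samples is not None and {"below_loq_gvlm", "below_loq_srem"} <= set(samples.columns):
        base = samples[samples["visit"] == "baseline"]
        n_loq = int((base["below_loq_gvlm"] & base["below_loq_srem"]).sum())
        table["below_loq"] = {"n": n_loq, "pct": round_half_up_pct(n_loq, len(base))}
    return table


def adherence_summary(classifications: pd.DataFrame, self_reports: pd.DataFrame) -> dict:
    """Biomarker-measured vs self-reported adherence in the intervention arm.

    Biomarker adherence: share of intervention-arm participants *with a
    follow-up sample* whose follow-up status is above threshold.  Self-report
    adherence: share of intervention-arm participants who never report a miss
    of more than 8 pills/month, uncertainty, or outside supplement use.
    """
    cls = classifications
    interv = cls["arm"] == "intervention"
    fu = interv & cls["has_followup"] & (cls["group"] != "unclassifiable")
    n_fu = int(fu.sum())
    n_above = int((fu & cls["followup_above"].eq(True)).sum())

    bad = self_reports["status"].isin(NONADHERENT_STATUSES)
    ever_bad = set(self_reports.loc[bad, "participant_id"])
    interv_ids = cls.loc[interv, "participant_id"]
    n_selfadh = int((~interv_ids.isin(ever_bad)).sum())

    return {
        "biomarker_adherence_pct": round_half_up_pct(n_above, n_fu),
        "biomarker_adherence_frac": n_above / n_fu if n_fu else None,
        "selfreport_adherence_pct": round_half_up_pct(n_selfadh, len(interv_ids)),
        "n_followup_intervention": n_fu,
    }
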