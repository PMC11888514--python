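"""Threshold-grid sensitivity of the biomarker-based association.

The classification thresholds are themselves estimates, so the biomarker
contrast is re-run over a 2-D grid of candidate thresholds (default 1 µM
steps, 1-50 µM for gVLM_B × 1-30 µM for SREM_B).  The headline summary per
cell is the *upper* 95% confidence limit of the hazard ratio: if it stays
below 1 across a wide threshold rectangle, the finding does not hinge on the
particular thresholds chosen.  The exclusion rule is re-applied at every grid
point, since who is excludable depends on baseline status.

Confidence intervals are not adjusted for multiple comparisons across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ThresholdPair
from .classify import classify_participants
from .cohort import ENDPOINTS
from .survival import MODEL_SPECS, NotEstimableError, build_survival_dataset, fit_cox

MIN_EVENTS_PER_GROUP = 5


@dataclass
class ThresholdSweepSurface:
    grid_gvlm: np.ndarray
    grid_srem: np.ndarray
    endpoints: tuple
    hr: dict  # endpoint -> (len(grid_gvlm), len(grid_srem)) matrix
    ci_low: dict
    ci_high: dict
    n_active: np.ndarray
    n_control: np.ndarray
    estimable: dict
    model_id: int = 2

    def to_frame(self) -> pd.DataFrame:
        """Long-format (t_gvlm, t_srem, endpoint, hr, ci_low, ci_high, ...)."""
        rows = []
        for ep in self.endpoints:
            for i, tg in enumerate(self.grid_gvlm):
                for j, ts in enumerate(self.grid_srem):
                    rows.append(
                        {
                            "t_gvlm": tg,
                            "t_srem": ts,
                            "endpoint": ep,
                            "hr": self.hr[ep][i, j],
                            "ci_low": self.ci_low[ep][i, j],
                            "ci_high": self.ci_high[ep][i, j],
                            "n_active": self.n_active[i, j],
                            "n_control": self.n_control[i, j],
                            "estimable": self.estimable[ep][i, j],
                        }
                    )
        return pd.DataFrame(rows)


def sweep(
    participants: pd.DataFrame,
    samples: pd.DataFrame,
    events: pd.DataFrame,
    grid_gvlm,
    grid_srem,
    endpoints=ENDPOINTS,
    model=2,
) -> ThresholdSweepSurface:
    """Reclassify and refit the biomarker contrast at every grid point.

    Deterministic given its inputs.  Cells where either group has fewer than
    ``MIN_EVENTS_PER_GROUP`` events, or where the fit fails, are flagged
    not-estimable (NaN in the numeric matrices).
    """
    grid_gvlm = np.asarray(grid_gvlm, float)
    grid_srem = np.asarray(grid_srem, float)
    for name, g in (("grid_gvlm", grid_gvlm), ("grid_srem", grid_srem)):
        if g.size == 0 or (g.size > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError(f"{name} must be non-empty and strictly increasing")
    if isinstance(model, int):
        model = MODEL_SPECS[model]

    shape = (grid_gvlm.size, grid_srem.size)
    hr = {ep: np.full(shape, np.nan) for ep in endpoints}
    lo = {ep: np.full(shape, np.nan) for ep in endpoints}
    hi = {ep: np.full(shape, np.nan) for ep in endpoints}
    ok = {ep: np.zeros(shape, bool) for ep in endpoints}
    n_active = np.zeros(shape, int)
    n_control = np.zeros(shape, int)

    ev_by_ep = {ep: events[events["endpoint"] == ep] for ep in endpoints}
    for i, tg in enumerate(grid_gvlm):
        for j, ts in enumerate(grid_srem):
            cls = classify_participants(participants, samples, ThresholdPair(tg, ts))
            n_active[i, j] = int((cls["group"] == "biomarker_active").sum())
            n_control[i, j] = int((cls["group"] == "biomarker_control").sum())
            for ep in endpoints:
                try:
                    ds = build_survival_dataset(
                        participants, ev_by_ep[ep], ep, "biomarker", model,
                        classifications=cls,
                    )
                    fr = ds.frame
                    d_active = int(fr.loc[fr["exposure"] == 1, "event"].sum())
                    d_control = int(fr.loc[fr["exposure"] == 0, "event"].sum())
                    if min(d_active, d_control) < MIN_EVENTS_PER_GROUP:
                        continue
                    res = fit_cox(ds)
                except NotEstimableError:
                    continue
                hr[ep][i, j] = res.hr
                lo[ep][i, j] = res.ci_low
                hi[ep][i, j] = res.ci_high
                ok[ep][i, j] = True
    return ThresholdSweepSurface(
        grid_gvlm, grid_srem, tuple(endpoints), hr, lo, hi, n_active, n_control, ok,
        model_id=model.model_id,
    )


@dataclass
class StableRange:
    endpoint: str
    gvlm_range: tuple  # (low µM, high µM) of the stable rectangle
    srem_range: tuple
    reference_upper_ci: float


def stability_report(
    surface: ThresholdSweepSurface,
    reference: ThresholdPair,
    tolerance: float = 0.10,
) -> dict:
    """Maximal contiguous grid rectangle around the reference thresholds in
    which the HR upper confidence limit shows no material change.

    "Material change" is operationalized as a relative departure of the upper
    CI beyond ``tolerance`` from its value at the reference cell, or the upper
    CI crossing 1 to the other side of the reference cell's.  The rectangle is
    grown greedily, one full grid line at a time, alternating over the four
    directions while expansion remains admissible.
    """
    gi = int(np.argmin(np.abs(surface.grid_gvlm - reference.t_gvlm)))
    si = int(np.argmin(np.abs(surface.grid_srem - reference.t_srem)))
    report = {}
    for ep in surface.endpoints:
        uci = surface.ci_high[ep]
        if not surface.estimable[ep][gi, si]:
            raise ValueError(f"reference cell not estimable for endpoint {ep!r}")
        ref = uci[gi, si]
        ref_below_one = ref < 1.0

        def stable(vals):
            vals = np.asarray(vals)
            if np.isnan(vals).any():
                return False
            rel_ok = np.all(np.abs(vals / ref - 1.0) <= tolerance)
            side_ok = np.all((vals < 1.0) == ref_below_one)
            return bool(rel_ok and side_ok)

        lo_g, hi_g, lo_s, hi_s = gi, gi, si, si
        grew = True
        while grew:
            grew = False
            if lo_g > 0 and stable(uci[lo_g - 1, lo_s : hi_s + 1]):
                lo_g -= 1
                grew = True
            if hi_g < uci.shape[0] - 1 and stable(uci[hi_g + 1, lo_s : hi_s + 1]):
                hi_g += 1
                grew = True
            if lo_s > 0 and stable(uci[lo_g : hi_g + 1, lo_s - 1]):
                lo_s -= 1
                grew = True
            if hi_s < uci.shape[1] - 1 and stable(uci[lo_g : hi_g + 1, hi_s + 1]):
                hi_s += 1
                grew = True
        report[ep] = StableRange(
            endpoint=ep,
            gvlm_range=(float(surface.grid_gvlm[lo_g]), float(surface.grid_gvlm[hi_g])),
            srem_range=(float(surface.grid_srem[lo_s]), float(surface.grid_srem[hi_s])),
            reference_upper_ci=float(ref),
        )
    return report


def model_ladder(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    classifications: pd.DataFrame,
    endpoints=ENDPOINTS,
    model_ids=(1, 2, 3, 4, 5),
):
    """Biomarker contrast refit under each covariate model (sensitivity table)."""
    from .survival import run_contrasts

    return run_contrasts(
        participants,
        events,
        classifications=classifications,
        model_ids=model_ids,
        endpoints=endpoints,
        contrasts=("biomarker",),
    )
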