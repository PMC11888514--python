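"""Cox proportional-hazards contrasts: intention-to-treat, per-protocol, and
biomarker-based.

The three contrasts answer different questions about the same trial:

* **ITT** compares arms as randomized — unbiased for the effect of
  *assignment*, attenuated for the effect of *exposure* whenever the placebo
  arm eats flavanols (background diet) or the active arm skips pills;
* **PP** censors participants at their first self-reported non-adherence
  (>8 pills/month missed, unsure, or outside supplement use) — partial
  correction, limited by misreporting;
* **biomarker** compares groups defined by measured urinary biomarker status,
  excluding intervention-arm participants whose adherence is unobservable
  (no follow-up sample, below-threshold baseline).

Covariate ladders (models 1-5) follow the convention of adjusting continuous
covariates with restricted cubic splines (3 knots at the 0.1/0.5/0.9 sample
quantiles).  Fitting uses the Cox partial likelihood with Efron tie handling;
the proportional-hazards assumption is checked with the scaled-Schoenfeld
construction (cox.zph).  Missing covariates are handled by chained-equation
multiple imputation that includes the event indicator and the Nelson-Aalen
cumulative-hazard estimate among the predictors, pooled by Rubin's rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .cohort import ENDPOINTS, NONADHERENT_STATUSES

log = logging.getLogger(__name__)

CONTRASTS = ("itt", "pp", "biomarker")

#: Reference covariate profile for adjusted cumulative-incidence curves:
#: age 75, male, BMI 25, never-smoker, no aspirin, WHI recruitment cohort.
REFERENCE_PROFILE = {
    "age_at_randomization": 75.0,
    "sex": "male",
    "bmi": 25.0,
    "smoking": "never",
    "aspirin_use": False,
    "cohort": "WHI",
    "ahei": 50.0,
    "family_history": False,
    "hypertension_history": False,
    "randomization": False,
}


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def rcs3_basis(x, knots=None, quantiles=(0.1, 0.5, 0.9)):
    """Restricted cubic spline basis with 3 knots (truncated-power form).

    Returns ``(basis, knots)`` where ``basis`` has the linear column and one
    nonlinear column; the function is linear beyond the outer knots.  Knots
    default to the sample quantiles.  With fewer than 3 distinct values the
    basis degrades to the linear column alone (logged).
    """
    x = np.asarray(x, float)
    if knots is None:
        if np.unique(x[~np.isnan(x)]).size < 3:
            log.warning("rcs3_basis: <3 distinct values, falling back to linear term")
            return x[:, None], None
        knots = np.quantile(x[~np.isnan(x)], quantiles)
        if np.unique(knots).size < 3:
            log.warning("rcs3_basis: degenerate knots %s, falling back to linear term", knots)
            return x[:, None], None
    t1, t2, t3 = knots

    def cube(t):
        return np.clip(x - t, 0.0, None) ** 3

    nonlin = (
        cube(t1) - cube(t2) * (t3 - t1) / (t3 - t2) + cube(t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, nonlin]), np.asarray(knots, float)


# ---------------------------------------------------------------------------
# Model specifications (covariate ladders)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    covariates: tuple  # of (column, encoding) pairs

    def names(self):
        return [c for c, _ in self.covariates]


_M1 = (
    ("sex", "binary"),
    ("age_at_randomization", "rcs3"),
    ("cohort", "binary"),
)
_M2 = _M1 + (("bmi", "rcs3"), ("smoking", "categorical"), ("aspirin_use", "binary"))
_M3 = _M2 + (("ahei", "rcs3"), ("family_history", "binary"), ("hypertension_history", "binary"))

MODEL_SPECS = {
    0: ModelSpec(0, ()),  # unadjusted exposure-only contrast
    1: ModelSpec(1, _M1),
    2: ModelSpec(2, _M2),
    3: ModelSpec(3, _M3),
    4: ModelSpec(4, _M2 + (("randomization", "binary"),)),
    5: ModelSpec(5, _M2 + (("ahei", "rcs3"),)),
}

_BINARY_CODING = {
    "sex": lambda s: (s == "male").astype(float),
    "cohort": lambda s: (s == "WHI").astype(float),
}


def encode_covariates(df: pd.DataFrame, spec: ModelSpec, meta: dict | None = None):
    """Encode the model's covariates into numeric design columns.

    ``meta`` (knots per spline column, category levels) is produced on first
    use and must be re-passed to encode new data — e.g. a reference profile —
    consistently with the fitted design.
    """
    fit_meta = meta is None
    if fit_meta:
        meta = {"knots": {}, "levels": {}}
    cols = {}
    for name, enc in spec.covariates:
        s = df[name] if name != "randomization" else (df["arm"] == "intervention")
        if enc == "binary":
            coder = _BINARY_CODING.get(name)
            cols[name] = coder(s) if coder else s.astype(float)
        elif enc == "linear":
            cols[name] = s.astype(float)
        elif enc == "categorical":
            if fit_meta:
                meta["levels"][name] = sorted(s.unique())
            for lev in meta["levels"][name][1:]:
                cols[f"{name}_{lev}"] = (s == lev).astype(float)
        elif enc == "rcs3":
            basis, knots = rcs3_basis(
                s.to_numpy(float), knots=meta["knots"].get(name) if not fit_meta else None
            )
            if fit_meta:
                meta["knots"][name] = knots
            cols[name] = basis[:, 0]
            if basis.shape[1] == 2:
                cols[f"{name}_rcs1"] = basis[:, 1]
        else:
            raise ValueError(f"unknown encoding {enc!r} for {name!r}")
    X = pd.DataFrame(cols, index=df.index)
    return X, meta


# ---------------------------------------------------------------------------
# Datasets and fitting
# ---------------------------------------------------------------------------

@dataclass
class SurvivalDataset:
    endpoint: str
    contrast: str
    model_id: int
    frame: pd.DataFrame  # exposure, time, event + encoded covariates
    meta: dict = field(default_factory=dict)


@dataclass
class CoxResult:
    endpoint: str
    contrast: str
    model_id: int
    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    log_hr_se: float
    n_used: int
    n_events: int
    ph_test: dict | None = None
    n_imputations_pooled: int = 1
    fitter: object | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "contrast": self.contrast,
            "model": self.model_id,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_hr": self.log_hr,
            "log_hr_se": self.log_hr_se,
            "n": self.n_used,
            "events": self.n_events,
        }


class NotEstimableError(RuntimeError):
    """A contrast cell cannot be fitted (empty group or no events in a group)."""


def pp_censor(events: pd.DataFrame, self_reports: pd.DataFrame, return_diagnostics=False):
    """Apply per-protocol censoring at the first non-adherent self-report.

    Event rows with time after the participant's first report of
    >8 missed pills/month, uncertainty, or outside supplement use are censored
    at that report date.  Reports dated after the recorded event time change
    nothing (the participant completed follow-up for that endpoint first);
    these are counted in the diagnostics.
    """
    bad = self_reports[self_reports["status"].isin(NONADHERENT_STATUSES)]
    censor_years = (bad.groupby("participant_id")["report_date"].min() / 365.25).rename("censor")
    out = events.merge(censor_years, on="participant_id", how="left")
    has_censor = out["censor"].notna()
    applies = has_censor & (out["censor"] < out["time"])
    ignored = int((has_censor & ~applies & out["event"]).sum())
    out.loc[applies, "event"] = False
    out.loc[applies, "time"] = out.loc[applies, "censor"]
    out = out.drop(columns="censor")
    if return_diagnostics:
        return out, {"n_censored_rows": int(applies.sum()), "n_reports_after_event": ignored}
    return out


def build_survival_dataset(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    endpoint: str,
    contrast: str,
    model: ModelSpec | int = 2,
    classifications: pd.DataFrame | None = None,
    self_reports: pd.DataFrame | None = None,
) -> SurvivalDataset:
    """Assemble one analysis dataset: exposure indicator per the contrast,
    encoded covariates, and (time, event) for the endpoint."""
    if isinstance(model, int):
        model = MODEL_SPECS[model]
    ev = events[events["endpoint"] == endpoint]
    if contrast == "pp":
        if self_reports is None:
            raise ValueError("pp contrast requires self_reports")
        ev = pp_censor(ev, self_reports)

    df = participants.merge(ev[["participant_id", "time", "event"]], on="participant_id")
    if contrast in ("itt", "pp"):
        df["exposure"] = (df["arm"] == "intervention").astype(float)
    elif contrast == "biomarker":
        if classifications is None:
            raise ValueError("biomarker contrast requires classifications")
        grp = classifications.set_index("participant_id")["group"]
        df["group"] = df["participant_id"].map(grp)
        df = df[df["group"].isin(["biomarker_active", "biomarker_control"])].copy()
        df["exposure"] = (df["group"] == "biomarker_active").astype(float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    X, meta = encode_covariates(df, model)
    frame = pd.concat(
        [df[["exposure"]].reset_index(drop=True), X.reset_index(drop=True)], axis=1
    )
    frame["time"] = df["time"].to_numpy(float)
    frame["event"] = df["event"].to_numpy(bool)
    return SurvivalDataset(endpoint, contrast, model.model_id, frame, meta)


def fit_cox(
    dataset: SurvivalDataset,
    ph_time_transform: str = "identity",
    run_ph_test: bool = False,
) -> CoxResult:
    """Fit the Cox model (Efron ties) and return the exposure hazard ratio
    with its Wald 95% CI.

    Raises :class:`NotEstimableError` when either exposure group is empty or
    event-free, and surfaces convergence failures with the gradient norm.
    """
    df = dataset.frame
    for level in (0.0, 1.0):
        sub = df[df["exposure"] == level]
        if len(sub) == 0 or sub["event"].sum() == 0:
            raise NotEstimableError(
                f"exposure group {int(level)} has no "
                f"{'rows' if len(sub) == 0 else 'events'} "
                f"({dataset.endpoint}/{dataset.contrast}/model {dataset.model_id})"
            )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise NotEstimableError(
            f"Cox fit failed for {dataset.endpoint}/{dataset.contrast}: {exc}"
        ) from exc

    log_hr = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    ph = None
    if run_ph_test:
        res = proportional_hazard_test(cph, df, time_transform=ph_time_transform)
        ph = {
            term: {"stat": float(s), "p": float(p)}
            for term, s, p in zip(
                res.summary.index.get_level_values(0),
                res.summary["test_statistic"],
                res.summary["p"],
            )
        }
    z = stats.norm.ppf(0.975)
    return CoxResult(
        endpoint=dataset.endpoint,
        contrast=dataset.contrast,
        model_id=dataset.model_id,
        hr=float(np.exp(log_hr)),
        ci_low=float(np.exp(log_hr - z * se)),
        ci_high=float(np.exp(log_hr + z * se)),
        log_hr=log_hr,
        log_hr_se=se,
        n_used=len(df),
        n_events=int(df["event"].sum()),
        ph_test=ph,
        fitter=cph,
        meta=dataset.meta,
    )


def run_contrasts(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    self_reports: pd.DataFrame | None = None,
    classifications: pd.DataFrame | None = None,
    model_ids=(2,),
    endpoints=ENDPOINTS,
    contrasts=CONTRASTS,
    run_ph_test: bool = False,
):
    """Fit every requested endpoint × contrast × model cell.

    Returns ``(table, results)``: a tidy DataFrame (not-estimable cells carry
    NaNs and a note) and the list of :class:`CoxResult` objects.
    """
    rows, results = [], []
    for endpoint in endpoints:
        for contrast in contrasts:
            for mid in model_ids:
                try:
                    ds = build_survival_dataset(
                        participants, events, endpoint, contrast, mid,
                        classifications=classifications, self_reports=self_reports,
                    )
                    res = fit_cox(ds, run_ph_test=run_ph_test)
                    results.append(res)
                    rows.append({**res.as_row(), "note": ""})
                except NotEstimableError as exc:
                    rows.append(
                        {
                            "endpoint": endpoint,
                            "contrast": contrast,
                            "model": mid,
                            "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "log_hr": np.nan, "log_hr_se": np.nan,
                            "n": np.nan, "events": np.nan,
                            "note": f"not estimable: {exc}",
                        }
                    )
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# Multiple imputation
# ---------------------------------------------------------------------------

def nelson_aalen_cumhaz(time, event) -> np.ndarray:
    """Nelson-Aalen cumulative-hazard estimate evaluated at each row's time."""
    naf = NelsonAalenFitter()
    naf.fit(time, event_observed=event)
    return (
        naf.cumulative_hazard_["NA_estimate"]
        .reindex(np.asarray(time, float), method="ffill")
        .fillna(0.0)
        .to_numpy()
    )


def impute_missing(
    table: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    time_col: str = "time",
    event_col: str = "event",
    n_burn: int = 5,
):
    """Chained-equation imputation of missing covariates, survival-aware.

    The imputation model includes the event indicator and the Nelson-Aalen
    cumulative-hazard estimate (computed once, on the full data, before
    imputation) as predictors — the standard recipe for imputing covariates
    in Cox models.  Missingness is only allowed in covariates; rows' time and
    event must be complete.  Returns ``m`` completed copies of ``table``.
    """
    from statsmodels.imputation.mice import MICEData

    if table[time_col].isna().any() or table[event_col].isna().any():
        raise ValueError("time/event columns must be complete")
    missing = table.columns[table.isna().any()].tolist()
    for col in missing:
        frac = table[col].isna().mean()
        if frac == 1.0:
            raise ValueError(f"column {col!r} is entirely missing")
        if frac > 0.5:
            warnings.warn(f"column {col!r} is {frac:.0%} missing", stacklevel=2)
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"only numeric covariates can be imputed, {col!r} is not")
    if not missing:
        return [table.copy() for _ in range(m)]

    work = table.copy().reset_index(drop=True)
    work["_na_cumhaz"] = nelson_aalen_cumhaz(work[time_col], work[event_col])
    work["_event"] = work[event_col].astype(float)
    aux = [c for c in work.columns if c not in missing and pd.api.types.is_numeric_dtype(work[c])]
    aux = [c for c in aux if c != time_col]  # NA estimate replaces raw time

    np.random.seed(seed % (2**32))  # MICEData draws from the global state
    mdata = MICEData(work[missing + aux].astype(float))
    completed = []
    for _ in range(m):
        mdata.update_all(n_burn)
        filled = table.copy().reset_index(drop=True)
        for col in missing:
            filled[col] = mdata.data[col].to_numpy()
        completed.append(filled)
    return completed


def pool_cox_results(results) -> CoxResult:
    """Rubin's rules over per-imputation Cox fits of the same cell."""
    results = list(results)
    m = len(results)
    q = np.array([r.log_hr for r in results])
    w = np.array([r.log_hr_se**2 for r in results])
    qbar = q.mean()
    wbar = w.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t_var = wbar + (1 + 1 / m) * b
    se = float(np.sqrt(t_var))
    if b > 0:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
        quant = stats.t.ppf(0.975, df)
    else:
        quant = stats.norm.ppf(0.975)
    first = results[0]
    return CoxResult(
        endpoint=first.endpoint,
        contrast=first.contrast,
        model_id=first.model_id,
        hr=float(np.exp(qbar)),
        ci_low=float(np.exp(qbar - quant * se)),
        ci_high=float(np.exp(qbar + quant * se)),
        log_hr=float(qbar),
        log_hr_se=se,
        n_used=first.n_used,
        n_events=first.n_events,
        n_imputations_pooled=m,
        meta=first.meta,
    )


# ---------------------------------------------------------------------------
# Adjusted cumulative incidence
# ---------------------------------------------------------------------------

def cumulative_incidence(
    result: CoxResult,
    reference: dict | None = None,
    group: int = 1,
    model: ModelSpec | int = 2,
) -> pd.DataFrame:
    """Cumulative incidence 1 - S(t) at the reference covariate profile for
    one exposure group, from the fitted model's Breslow baseline hazard.

    Reference values outside the observed covariate range are warned about;
    the spline basis is linear beyond its outer knots, so evaluation there is
    a linear extrapolation by construction.
    """
    if result.fitter is None:
        raise ValueError("CoxResult has no attached fitter (pooled results cannot draw curves)")
    if isinstance(model, int):
        model = MODEL_SPECS[model]
    profile = dict(REFERENCE_PROFILE)
    if reference:
        profile.update(reference)
    ref_df = pd.DataFrame([profile])
    if "randomization" in [c for c, _ in model.covariates]:
        ref_df["arm"] = "intervention" if profile.get("randomization") else "placebo"
    X, _ = encode_covariates(ref_df, model, meta=result.meta)
    for name, knots in result.meta.get("knots", {}).items():
        v = float(ref_df[name].iloc[0])
        if knots is not None and not (knots[0] <= v <= knots[-1]):
            warnings.warn(
                f"reference {name}={v} outside knot range {knots[[0, -1]]}; "
                "linear extrapolation on the spline scale",
                stacklevel=2,
            )
    X.insert(0, "exposure", float(group))
    ch = result.fitter.predict_cumulative_hazard(X)
    out = pd.DataFrame(
        {"time": ch.index.to_numpy(float), "incidence": 1.0 - np.exp(-ch.iloc[:, 0].to_numpy())}
    )
    return out
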