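"""Dose-response calibration of urinary flavanol biomarkers.

A dose-escalation study relates consumed cocoa-flavanol dose (mg) to urinary
biomarker concentration (µM).  Concentrations are log2-transformed and
regressed on dose (or log2-dose); the classification threshold for a target
intake is the *lower* bound of a 95% interval for the concentration expected
at that intake — conservatively low, so that a truly dosed individual is
rarely classified below it (few false negatives).

Two interval kinds are offered.  ``prediction`` (the default) is the
new-individual prediction interval: inter-individual variability is the
stated reason the threshold is set low, and a prediction interval is the
interval that covers a new individual's value.  ``mean_ci`` is the confidence
interval for the mean response; it gives a higher (less conservative)
threshold.  The choice is exposed because published threshold derivations are
often ambiguous between the two readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Published reference thresholds (µM) for an intake of 500 mg/day,
#: shipped as the named profile "cosmos".
COSMOS_THRESHOLDS = None  # set below, after ThresholdPair is defined


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS fit of log2(concentration) on (transformed) dose for one biomarker."""

    biomarker: str
    intercept: float
    slope: float
    residual_sd: float
    n: int
    design_covariance: np.ndarray  # 2x2, (intercept, slope)
    dose_transform: str = "identity"
    xtx_inv: np.ndarray | None = None  # unscaled (X'X)^-1, kept for intervals

    def predict_log2(self, dose: float) -> float:
        return self.intercept + self.slope * _transform(dose, self.dose_transform)


@dataclass(frozen=True)
class ThresholdPair:
    """Classification thresholds (µM) for the two biomarkers."""

    t_gvlm: float
    t_srem: float
    level: float = 0.95
    interval_kind: str = "prediction"

    def __post_init__(self):
        if not (self.t_gvlm > 0 and self.t_srem > 0):
            raise ValueError("thresholds must be positive")


COSMOS_THRESHOLDS = ThresholdPair(18.2, 7.8)
THRESHOLD_PROFILES = {"cosmos": COSMOS_THRESHOLDS}


def _transform(dose, kind: str):
    if kind == "identity":
        return dose
    if kind == "log2":
        return np.log2(dose)
    raise ValueError(f"unknown dose_transform {kind!r}")


def fit_dose_response(
    records: pd.DataFrame, dose_transform: str = "identity", biomarker: str | None = None
) -> DoseResponseFit:
    """OLS of log2(concentration) on transformed dose.

    ``records`` needs columns ``dose`` and ``concentration`` (and optionally
    ``biomarker``; pass ``biomarker=`` to select one when several are mixed).
    Non-positive concentrations are rejected with the offending row indices;
    a single distinct dose is a degenerate design.
    """
    df = records
    if biomarker is not None:
        df = df[df["biomarker"] == biomarker]
    elif "biomarker" in df.columns:
        kinds = df["biomarker"].unique()
        if len(kinds) > 1:
            raise ValueError(f"records mix biomarkers {sorted(kinds)}; pass biomarker=")
        biomarker = kinds[0] if len(kinds) else "unknown"
    bad = df.index[~(df["concentration"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive concentrations at rows {bad}; exclude below-LOQ records")
    if len(df) < 3:
        raise ValueError(f"need at least 3 calibration records, got {len(df)}")
    if df["dose"].nunique() < 2:
        raise ValueError("degenerate design: all records share a single dose")

    x = _transform(df["dose"].to_numpy(float), dose_transform)
    y = np.log2(df["concentration"].to_numpy(float))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    xtx_inv = np.linalg.inv(X.T @ X)
    return DoseResponseFit(
        biomarker=str(biomarker),
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(res.mse_resid)) if len(df) > 2 else 0.0,
        n=len(df),
        design_covariance=np.asarray(res.cov_params()),
        dose_transform=dose_transform,
        xtx_inv=xtx_inv,
    )


def derive_threshold(
    fit: DoseResponseFit,
    dose: float = 500.0,
    level: float = 0.95,
    interval_kind: str = "prediction",
) -> float:
    """Lower bound of the ``level`` two-sided interval for log2-concentration
    at ``dose``, back-transformed to µM.

    Uses the Student-t quantile with n-2 df.  ``mean_ci`` uses the standard
    error of the fitted mean; ``prediction`` adds the residual variance, so its
    bound is never above the mean-CI bound.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if interval_kind not in ("mean_ci", "prediction"):
        raise ValueError(f"interval_kind must be 'mean_ci' or 'prediction', got {interval_kind!r}")
    x0 = np.array([1.0, _transform(dose, fit.dose_transform)])
    mean = float(x0 @ (fit.intercept, fit.slope))
    # leverage of the new point under the fitted design
    h = float(x0 @ fit.xtx_inv @ x0)
    var = fit.residual_sd**2 * (h + (1.0 if interval_kind == "prediction" else 0.0))
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.n - 2)
    lower = mean - tq * np.sqrt(var)
    return float(2.0**lower)


def derive_threshold_pair(
    fits: dict,
    dose: float = 500.0,
    level: float = 0.95,
    interval_kind: str = "prediction",
) -> ThresholdPair:
    """Thresholds for both biomarkers from a dict of per-biomarker fits."""
    return ThresholdPair(
        t_gvlm=derive_threshold(fits["gvlm"], dose, level, interval_kind),
        t_srem=derive_threshold(fits["srem"], dose, level, interval_kind),
        level=level,
        interval_kind=interval_kind,
    )


def resolve_thresholds(spec) -> ThresholdPair:
    """Accept a profile name ('cosmos'), a 't_g,t_s' string, a pair, or a
    ThresholdPair and return a ThresholdPair."""
    if isinstance(spec, ThresholdPair):
        return spec
    if isinstance(spec, str):
        if spec in THRESHOLD_PROFILES:
            return THRESHOLD_PROFILES[spec]
        parts = spec.split(",")
        if len(parts) == 2:
            return ThresholdPair(float(parts[0]), float(parts[1]))
        raise ValueError(f"unknown threshold profile {spec!r}")
    t_g, t_s = spec
    return ThresholdPair(float(t_g), float(t_s))
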