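"""Independent oracles used by the test suite.

Everything here is written from first principles (closed forms, numerical
integration, explicit likelihood evaluation, Monte-Carlo) and deliberately
avoids the code paths — and the library routines — it is used to check.
"""

import numpy as np
from scipy import stats

from flavatrial.cohort import BIOMARKER_RHO, MODERATE_DOSE_RANGE


def prob_above(dose, params, thresholds, n_grid=201):
    """P(gVLM >= t_g or SREM >= t_s) at a given actual dose, from the
    bivariate log2-normal measurement model (zero dose is below LOQ)."""
    if dose <= 0:
        return 0.0
    a_g, b_g, s_g = params.dose_response["gvlm"]
    a_s, b_s, s_s = params.dose_response["srem"]
    zg = (np.log2(thresholds.t_gvlm) - a_g - b_g * dose) / s_g
    zs = (np.log2(thresholds.t_srem) - a_s - b_s * dose) / s_s
    mvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, BIOMARKER_RHO], [BIOMARKER_RHO, 1.0]]
    )
    return 1.0 - float(mvn.cdf([zg, zs]))


def prob_above_background(params, thresholds, extra_dose=0.0, n_grid=201):
    """Mixture-tail probability of an above-threshold sample for a participant
    drawn from the background-intake mixture, optionally shifted by a
    supplement dose (numerical integration over the moderate component)."""
    lo, hi = MODERATE_DOSE_RANGE
    doses = np.linspace(lo, hi, n_grid)
    p_mod = np.trapezoid(
        [prob_above(d + extra_dose, params, thresholds) for d in doses], doses
    ) / (hi - lo)
    p_zero = prob_above(extra_dose, params, thresholds)
    p_high = prob_above(params.dose_ref + extra_dose, params, thresholds)
    w_zero, w_high = params.p_background_zero, params.p_background_high
    return w_zero * p_zero + w_high * p_high + (1 - w_zero - w_high) * p_mod


def cox_loghr_brute(x, time, event, lo=-6.0, hi=6.0):
    """Maximize the explicit Cox partial likelihood (untied data, one binary
    covariate) over a fine grid of beta, refined to 1e-6 resolution."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if len(np.unique(time)) != len(time):
        raise ValueError("oracle assumes untied event times")

    def loglik(betas):
        ll = np.zeros_like(betas)
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += betas * x[i] - np.log(
                np.exp(betas[:, None] * x[None, risk]).sum(axis=1)
            )
        return ll

    grid = np.arange(lo, hi, 1e-3)
    best = grid[np.argmax(loglik(grid))]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-6)
    return float(fine[np.argmax(loglik(fine))])


def prediction_bound_mc(fit, dose, level=0.95, interval_kind="prediction",
                        n_draws=10_000, seed=0):
    """Monte-Carlo lower bound of the interval for log2-concentration at
    ``dose``: for the normal linear model, the classical t-based interval
    coincides with the quantile of the posterior-predictive distribution under
    the standard noninformative prior, which is straightforward to sample."""
    rng = np.random.default_rng(seed)
    df = fit.n - 2
    x0 = np.array([1.0, dose])
    sigma = fit.residual_sd * np.sqrt(df / rng.chisquare(df, n_draws))
    mean = np.array([fit.intercept, fit.slope])
    chol = np.linalg.cholesky(fit.xtx_inv)
    beta = mean[None, :] + sigma[:, None] * (rng.standard_normal((n_draws, 2)) @ chol.T)
    y = beta @ x0
    if interval_kind == "prediction":
        y = y + sigma * rng.standard_normal(n_draws)
    return float(np.quantile(y, (1.0 - level) / 2.0))


def breslow_baseline_cumhaz(x, time, event, beta, times_out):
    """Breslow estimator of the baseline cumulative hazard at ``times_out``
    for a single-covariate Cox model with coefficient ``beta``."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    risk_score = np.exp(beta * x)
    event_times = np.sort(time[event])
    increments = []
    for t in event_times:
        d = ((time == t) & event).sum()
        denom = risk_score[time >= t].sum()
        increments.append(d / denom)
    ch = np.cumsum(increments)
    out = np.zeros(len(times_out))
    for k, t in enumerate(np.asarray(times_out, float)):
        idx = np.searchsorted(event_times, t, side="right")
        out[k] = ch[idx - 1] if idx > 0 else 0.0
    return out
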