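"""Clinical statistics: pathological response classes, CPS, Kaplan-Meier and
log-rank (optionally inverse-probability weighted), IPTW balance diagnostics and
the exact operating characteristics of the trial's Simon two-stage design.

Pathological response is graded on percent residual viable tumour: pCR (0%),
MPR (<= 10%), pPR (10-33%], pNR (> 33%); patients at or below 33% are *well*
responders, above are *poor* responders.

The historical comparison estimates propensity scores by multinomial logistic
regression on tumour site and clinical stage, weights each patient by the inverse
probability of their assigned arm (optionally stabilised by the marginal arm
frequency) and checks balance with standardised mean differences (balanced when
SMD < 0.25).  Survival curves and log-rank tests accept those weights; the
hazard ratio is delegated to a standard weighted proportional-hazards routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UsageError

SMD_BALANCE_CUTOFF = 0.25


# ---------------------------------------------------------------------------
# response classification and CPS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathologicResponse:
    residual_tumor_percent: float
    category: str       # finest class: pCR / MPR / pPR / pNR
    responder: str      # well / poor
    is_pcr: bool
    is_mpr: bool        # pCR is a subset of MPR


def classify_pathologic_response(residual_percent: float) -> PathologicResponse:
    """Grade a resected tumour by percent residual viable tumour cells."""
    p = float(residual_percent)
    if not 0.0 <= p <= 100.0:
        raise DataError(f"residual tumor percent must lie in [0, 100], got {p}")
    is_pcr = p == 0.0
    is_mpr = p <= 10.0
    if is_pcr:
        category = "pCR"
    elif is_mpr:
        category = "MPR"
    elif p <= 33.0:
        category = "pPR"
    else:
        category = "pNR"
    return PathologicResponse(p, category, "well" if p <= 33.0 else "poor", is_pcr, is_mpr)


def cps(pdl1_positive_cells: int, tumor_cells: int) -> float:
    """Combined positive score: 100 x PD-L1-positive cells / tumour cells, capped at 100."""
    if tumor_cells == 0:
        raise DataError("CPS undefined for zero tumour cells")
    if pdl1_positive_cells < 0 or tumor_cells < 0:
        raise DataError("cell counts must be non-negative")
    if tumor_cells < 100:
        warnings.warn("CPS is conventionally evaluated on >= 100 tumour cells", stacklevel=2)
    return min(100.0, 100.0 * pdl1_positive_cells / tumor_cells)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank (weighted variants)
# ---------------------------------------------------------------------------

def _as_survival_arrays(times, events, weights):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t <= 0).any():
        raise DataError("survival times must be positive")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise DataError("weights must be positive")
    if not (len(t) == len(e) == len(w)):
        raise UsageError("times, events and weights must have equal length")
    return t, e, w


@dataclass
class KaplanMeierResult:
    """Product-limit estimate: a right-continuous step function with Greenwood CIs."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_subjects: int
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])

    def summary(self, milestones: Sequence[float] = (12.0, 24.0)) -> pd.DataFrame:
        rows = []
        for m in milestones:
            lo, hi = self.ci_at(m)
            rows.append({"months": m, "survival": self.survival_at(m), "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[0.0], self.event_times])
        ys = np.concatenate([[1.0], self.survival])
        ax.step(xs, ys, where="post", **kwargs)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(times, events, weights=None, ci_alpha: float = 0.05) -> KaplanMeierResult:
    """(Weighted) Kaplan-Meier product-limit estimator.

    Ties are handled in the standard way: deaths precede censorings at equal times.
    With weights, risk-set and event counts are weighted sums; Greenwood's formula
    gives pointwise normal-approximation confidence intervals clipped to [0, 1].
    """
    t, e, w = _as_survival_arrays(times, events, weights)
    if not e.any():
        return KaplanMeierResult(
            event_times=np.array([]), survival=np.array([]),
            ci_lower=np.array([]), ci_upper=np.array([]),
            n_subjects=len(t), all_censored=True,
        )
    uniq = np.unique(t[e])
    surv, var_sum, s_list, lo, hi = 1.0, 0.0, [], [], []
    zq = stats.norm.ppf(1 - ci_alpha / 2)
    for u in uniq:
        at_risk = w[t >= u].sum()
        deaths = w[(t == u) & e].sum()
        if at_risk <= 0:
            continue
        surv *= 1.0 - deaths / at_risk
        if at_risk > deaths:
            var_sum += deaths / (at_risk * (at_risk - deaths))
        se = surv * np.sqrt(var_sum)
        s_list.append(surv)
        lo.append(max(0.0, surv - zq * se))
        hi.append(min(1.0, surv + zq * se))
    return KaplanMeierResult(
        event_times=uniq, survival=np.array(s_list),
        ci_lower=np.array(lo), ci_upper=np.array(hi), n_subjects=len(t),
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    dof: int

    def __iter__(self):  # allow `chi2, p = logrank(...)`
        yield self.statistic
        yield self.p_value


def logrank(groups, times, events, weights=None) -> LogrankResult:
    """(Weighted) K-group log-rank test with the hypergeometric variance.

    With weights the observed/expected counts use weighted risk sets (the usual
    IPTW-adjusted log-rank); the chi-square statistic uses the generalised inverse
    of the covariance of the first K-1 groups.
    """
    t, e, w = _as_survival_arrays(times, events, weights)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise UsageError("log-rank test requires at least two groups")
    k = len(labels)
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for u in np.unique(t[e]):
        at_risk_mask = t >= u
        death_mask = (t == u) & e
        y = w[at_risk_mask].sum()
        d = w[death_mask].sum()
        if y <= 0:
            continue
        yg = np.array([w[at_risk_mask & (g == lab)].sum() for lab in labels])
        dg = np.array([w[death_mask & (g == lab)].sum() for lab in labels])
        obs += dg
        exp += d * yg / y
        frac = yg / y
        if y > 1:
            scale = d * (y - d) / (y - 1)
        else:
            scale = 0.0
        cov += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (obs - exp)[:-1]
    vmat = cov[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogrankResult(chi2, p, k - 1)


# ---------------------------------------------------------------------------
# IPTW: propensity weights and balance
# ---------------------------------------------------------------------------

@dataclass
class PropensityResult:
    weights: pd.Series
    propensity: pd.DataFrame  # patients x arms, P(arm | covariates)
    stabilized: bool


def propensity_weights(
    covariates: pd.DataFrame, arms: pd.Series, stabilized: bool = True
) -> PropensityResult:
    """Inverse-probability-of-treatment weights from a multinomial logistic model.

    Covariates are treated as categorical and one-hot encoded.  A covariate level
    observed in only one arm separates the likelihood and raises an error naming
    the level.  Stabilised weights multiply by the marginal arm frequency (their
    mean is then ~1).
    """
    arms = pd.Series(arms).astype(str)
    if len(covariates) != len(arms):
        raise UsageError("covariates and arms must align")
    labels = np.unique(arms)
    if len(labels) < 2:
        raise UsageError("need at least two arms")
    for col in covariates.columns:
        tab = pd.crosstab(covariates[col], arms)
        exclusive = tab.index[(tab > 0).sum(axis=1) == 1]
        if len(exclusive):
            raise DataError(
                f"covariate {col!r} level {exclusive[0]!r} occurs in a single arm "
                "(perfect separation); merge levels or drop the covariate"
            )
    from sklearn.linear_model import LogisticRegression

    x = pd.get_dummies(covariates.astype(str), drop_first=True).to_numpy(dtype=float)
    if x.shape[1] == 0:  # all covariates constant: propensity is the marginal frequency
        marg = arms.value_counts(normalize=True)
        probs = pd.DataFrame(
            np.tile(marg[labels].to_numpy(), (len(arms), 1)), columns=labels, index=arms.index
        )
    else:
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        model.fit(x, arms.to_numpy())
        probs = pd.DataFrame(model.predict_proba(x), columns=model.classes_, index=arms.index)
    p_assigned = np.array([probs.loc[i, a] for i, a in arms.items()])
    weights = 1.0 / p_assigned
    if stabilized:
        marginal = arms.value_counts(normalize=True)
        weights = weights * arms.map(marginal).to_numpy()
    return PropensityResult(pd.Series(weights, index=arms.index, name="iptw"), probs, stabilized)


def standardized_mean_difference(covariate, arms, weights=None) -> float:
    """SMD between two arms: (mean1 - mean2) / pooled SD, optionally weighted.

    Categorical covariates should be passed as binary level indicators (see
    :func:`balance_table`).  Zero pooled SD returns NaN with a warning.
    """
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(arms)
    labels = np.unique(g)
    if len(labels) != 2:
        raise UsageError("SMD is defined for exactly two arms")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    stats_ = []
    for lab in labels:
        m = g == lab
        mean = np.average(x[m], weights=w[m])
        var = np.average((x[m] - mean) ** 2, weights=w[m])
        stats_.append((mean, var))
    (m1, v1), (m2, v2) = stats_
    pooled = np.sqrt((v1 + v2) / 2.0)
    if pooled == 0:
        warnings.warn("zero pooled SD; SMD undefined", stacklevel=2)
        return float("nan")
    return float((m1 - m2) / pooled)


def balance_table(
    data: pd.DataFrame, arm_col: str, covariates: Sequence[str], weights=None
) -> pd.DataFrame:
    """Per-level SMD table for categorical covariates, with a balance flag (< 0.25)."""
    rows = []
    for cov in covariates:
        for level in sorted(data[cov].astype(str).unique()):
            indicator = (data[cov].astype(str) == level).astype(float)
            smd = standardized_mean_difference(indicator, data[arm_col], weights)
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "smd": smd,
                    "balanced": bool(abs(smd) < SMD_BALANCE_CUTOFF) if np.isfinite(smd) else False,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class IptwResult:
    """IPTW comparison of two (or more) arms on one survival endpoint."""

    weights: pd.Series
    balance_before: pd.DataFrame
    balance_after: pd.DataFrame
    logrank_unweighted: LogrankResult
    logrank_weighted: LogrankResult
    km_by_arm: dict
    hazard_ratio: float | None = None
    hr_ci: tuple[float, float] | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            {"quantity": "max |SMD| before", "value": self.balance_before["smd"].abs().max()},
            {"quantity": "max |SMD| after", "value": self.balance_after["smd"].abs().max()},
            {"quantity": "log-rank p (unweighted)", "value": self.logrank_unweighted.p_value},
            {"quantity": "log-rank p (weighted)", "value": self.logrank_weighted.p_value},
        ]
        if self.hazard_ratio is not None:
            rows.append({"quantity": "weighted HR", "value": self.hazard_ratio})
        return pd.DataFrame(rows)


def iptw_survival_comparison(
    data: pd.DataFrame,
    arm_col: str = "arm",
    time_col: str = "os_time",
    event_col: str = "os_event",
    covariates: Sequence[str] = ("stage", "site"),
    stabilized: bool = True,
    fit_hazard_ratio: bool = True,
) -> IptwResult:
    """End-to-end IPTW comparison: weights, balance before/after, weighted KM and
    log-rank, and a pass-through weighted Cox hazard ratio (two-arm case)."""
    prop = propensity_weights(data[list(covariates)], data[arm_col], stabilized=stabilized)
    w = prop.weights
    bal_before = balance_table(data, arm_col, covariates)
    bal_after = balance_table(data, arm_col, covariates, weights=w)
    lr_un = logrank(data[arm_col], data[time_col], data[event_col])
    lr_w = logrank(data[arm_col], data[time_col], data[event_col], weights=w)
    km = {
        arm: km_estimate(sub[time_col], sub[event_col], weights=w[sub.index])
        for arm, sub in data.groupby(arm_col)
    }
    hr = hr_ci = None
    if fit_hazard_ratio and data[arm_col].nunique() == 2:
        from lifelines import CoxPHFitter

        arms = sorted(data[arm_col].unique())
        frame = pd.DataFrame(
            {
                "T": data[time_col].to_numpy(dtype=float),
                "E": data[event_col].to_numpy(dtype=bool),
                "treated": (data[arm_col] == arms[0]).to_numpy(dtype=float),
                "w": w.to_numpy(),
            }
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="T", event_col="E", weights_col="w", robust=True)
        hr = float(np.exp(cph.params_["treated"]))
        ci = cph.confidence_intervals_.loc["treated"]
        hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    return IptwResult(w, bal_before, bal_after, lr_un, lr_w, km, hr, hr_ci)


# ---------------------------------------------------------------------------
# Simon two-stage design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimonDesign:
    """The trial's two-stage rule: accrue 6; continue iff >= 5 stage-1 successes;
    declare success iff > 23 successes among the first 27."""

    n1: int = 6
    r1_go: int = 5          # continue when stage-1 successes >= r1_go
    n_total: int = 27
    r_success: int = 24     # success when total successes >= r_success
    alpha: float = 0.05
    beta: float = 0.20

    def __post_init__(self):
        if not (0 < self.n1 <= self.n_total):
            raise DataError("need 0 < n1 <= n_total")
        if not (0 <= self.r1_go <= self.n1 and 0 <= self.r_success <= self.n_total):
            raise DataError("thresholds must lie within their sample sizes")


def simon_oc(design: SimonDesign = SimonDesign(), p: float = 0.9) -> dict[str, float]:
    """Exact operating characteristics of the two-stage rule at success probability p.

    Returns P(stop at stage 1), P(declare success) and the expected sample size,
    all from exact binomial sums.
    """
    if not 0.0 <= p <= 1.0:
        raise DataError("p must lie in [0, 1]")
    n1, go, n2 = design.n1, design.r1_go, design.n_total - design.n1
    p_stage1 = stats.binom.pmf(np.arange(n1 + 1), n1, p)
    p_stop = float(p_stage1[:go].sum())
    p_continue = 1.0 - p_stop
    p_success = 0.0
    for k in range(go, n1 + 1):
        need = design.r_success - k
        p_success += float(p_stage1[k]) * float(stats.binom.sf(need - 1, n2, p))
    return {
        "p_stop_stage1": p_stop,
        "p_success": min(1.0, p_success),
        "expected_n": design.n1 + n2 * p_continue,
    }
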