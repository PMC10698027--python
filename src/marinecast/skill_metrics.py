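"""Forecast verification: autocorrelation-aware correlation significance,
accuracy against a random baseline, SEDI, and bootstrap significance.

Correlation skill is Pearson r between yearly observed and forecast index
values for a given target month and lead.  Because both series are
autocorrelated, significance uses an effective sample size

    N_eff = N / sum_{t=-(N-1)}^{N-1} (1 - |t|/N) * rF_|t| * rO_|t|
          = N / [1 + 2 * sum_{t=1}^{N-1} (1 - t/N) * rF_t * rO_t],

where rF_t and rO_t are the sample autocorrelations (biased 1/N
normalization, r_0 = 1) of the forecast and observed series; for paired
AR(1) series with coefficient rho this converges to the classic
N_eff/N = (1 - rho^2) / (1 + rho^2).  The 95%
confidence interval comes from the Fisher Z transform with standard error
1 / sqrt(N_eff - 3); skill is significant when the lower bound exceeds zero.

Categorical skill compares event forecasts (high compression / closure) in a
contingency table.  Accuracy is (TP + TN) / total, judged against the
expected accuracy of a frequency-matched random forecast,
FA_rand = f^2 + (1 - f)^2 for event frequency f.  SEDI,

    SEDI = [log F - log H - log(1-F) + log(1-H)]
         / [log F + log H + log(1-F) + log(1-H)],

with hit rate H and false-alarm rate F, is base-rate robust for rare events:
random forecasts score 0 in expectation and 1 is perfect.  SEDI is undefined
(NaN, never silently 0) whenever H or F is 0 or 1 — e.g. months with no
false positives.  Bootstrap significance draws random binary forecasts from
the observed event labels, rebuilds the metric 1000 times, and flags skill
exceeding the 97.5th percentile of that null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf

from ._core import ConfigurationError, IndexSeries, align_series
from .forecast_engine import LeadForecast

__all__ = [
    "ContingencyTable",
    "CorrelationResult",
    "BootstrapResult",
    "contingency",
    "effective_n",
    "correlation_with_ci",
    "accuracy",
    "random_accuracy",
    "random_accuracy_bound",
    "sedi",
    "sedi_from_rates",
    "bootstrap_significance",
    "skill_report",
]

_Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Counts of forecast/observed event agreement."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("contingency counts must be nonnegative")
        if self.total < 1:
            raise ConfigurationError("contingency table must contain at least one forecast")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def hit_rate(self) -> float:
        """H = TP / observed events; NaN when no events were observed."""
        n_event = self.tp + self.fn
        return self.tp / n_event if n_event else float("nan")

    @property
    def false_alarm_rate(self) -> float:
        """F = FP / observed non-events; NaN when every month was an event."""
        n_non = self.fp + self.tn
        return self.fp / n_non if n_non else float("nan")


def contingency(forecast_events, observed_events) -> ContingencyTable:
    """Build a contingency table from paired binary event vectors.

    Pairs where either side is NaN (undefined index month) are dropped.
    """
    f = np.asarray(forecast_events, dtype=float)
    o = np.asarray(observed_events, dtype=float)
    if f.shape != o.shape:
        raise ConfigurationError("event vectors must have equal length")
    keep = np.isfinite(f) & np.isfinite(o)
    fb, ob = f[keep].astype(bool), o[keep].astype(bool)
    return ContingencyTable(
        tp=int(np.sum(fb & ob)),
        fp=int(np.sum(fb & ~ob)),
        fn=int(np.sum(~fb & ob)),
        tn=int(np.sum(~fb & ~ob)),
    )


# ---------------------------------------------------------------------------
# correlation with effective degrees of freedom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    n_eff: float
    ci_low: float
    ci_high: float
    significant: bool
    degenerate: bool  # non-positive autocorrelation sum; N_eff clamped
    r_t_forecast: np.ndarray | None = None
    r_t_observed: np.ndarray | None = None


def _biased_acf(x: np.ndarray) -> np.ndarray:
    """Sample autocorrelations at lags 0..N-1 with 1/N normalization."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        # constant series: autocorrelation undefined; treat as fully correlated
        return np.ones(x.size)
    return acf(x, nlags=x.size - 1, fft=True, adjusted=False)


def effective_n(forecast_series, observed_series) -> float:
    """Effective sample size of a forecast/observed pair under autocorrelation.

    Pairs with a missing value are dropped first.  The triangular-weighted
    sum of autocorrelation products can fall below 1 (or even below 0) from
    sampling noise; the result is clamped to at most N (and flagged as
    degenerate via :func:`correlation_with_ci` when the sum is non-positive).
    """
    n_eff, _, _, _ = _effective_n_detail(forecast_series, observed_series)
    return n_eff


def _effective_n_detail(forecast_series, observed_series):
    f = np.asarray(forecast_series, dtype=float)
    o = np.asarray(observed_series, dtype=float)
    if f.shape != o.shape:
        raise ConfigurationError("series must have equal length")
    keep = np.isfinite(f) & np.isfinite(o)
    f, o = f[keep], o[keep]
    n = f.size
    if n < 4:
        raise ConfigurationError(f"need at least 4 paired samples, got {n}")
    r_f = _biased_acf(f)
    r_o = _biased_acf(o)
    t = np.arange(n)
    weighted = (1.0 - t / n) * r_f * r_o
    denom = float(1.0 + 2.0 * weighted[1:].sum())  # two-sided sum, lag-0 term = 1
    degenerate = denom <= 0.0
    n_eff = float(n) if denom <= 1.0 else float(n / denom)
    return n_eff, degenerate, r_f, r_o


def correlation_with_ci(forecast_series, observed_series) -> CorrelationResult:
    """Pearson correlation with a Fisher-Z CI at N_eff - 3 degrees of freedom.

    Significant means the lower 95% bound exceeds zero.  If N_eff <= 3 the
    CI is undefined and the result is not significant.
    """
    f = np.asarray(forecast_series, dtype=float)
    o = np.asarray(observed_series, dtype=float)
    keep = np.isfinite(f) & np.isfinite(o)
    f, o = f[keep], o[keep]
    n = f.size
    n_eff, degenerate, r_f, r_o = _effective_n_detail(f, o)
    if np.ptp(f) == 0 or np.ptp(o) == 0:
        return CorrelationResult(
            r=float("nan"), n=n, n_eff=n_eff, ci_low=float("nan"), ci_high=float("nan"),
            significant=False, degenerate=True, r_t_forecast=r_f, r_t_observed=r_o,
        )
    r = float(stats.pearsonr(f, o).statistic)
    if degenerate or n_eff <= 3.0:
        return CorrelationResult(
            r=r, n=n, n_eff=n_eff, ci_low=float("nan"), ci_high=float("nan"),
            significant=False, degenerate=degenerate, r_t_forecast=r_f, r_t_observed=r_o,
        )
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    z = math.atanh(r_c)
    se = 1.0 / math.sqrt(n_eff - 3.0)
    lo, hi = math.tanh(z - _Z975 * se), math.tanh(z + _Z975 * se)
    return CorrelationResult(
        r=r, n=n, n_eff=n_eff, ci_low=lo, ci_high=hi,
        significant=bool(lo > 0.0), degenerate=degenerate,
        r_t_forecast=r_f, r_t_observed=r_o,
    )


# ---------------------------------------------------------------------------
# categorical metrics
# ---------------------------------------------------------------------------

def accuracy(ct: ContingencyTable) -> float:
    """Fraction of correct forecasts, (TP + TN) / total."""
    return (ct.tp + ct.tn) / ct.total


def random_accuracy(f: float) -> float:
    """Expected accuracy of a random forecast at event frequency f: f^2 + (1-f)^2."""
    if not (0.0 <= f <= 1.0):
        raise ConfigurationError("event frequency must be in [0, 1]")
    return f**2 + (1.0 - f) ** 2


def random_accuracy_bound(f: float, grid: float = 0.01) -> float:
    """Conservative printed form of the random baseline.

    The smallest multiple of ``grid`` strictly above the raw baseline, so
    quoting "accuracy above X" never understates the bar (0.6152 -> 0.62,
    0.7048 -> 0.71); the exact value 0.5 stays 0.5.
    """
    raw = random_accuracy(f)
    steps = math.floor(raw / grid + 1e-12)
    bound = steps * grid if math.isclose(steps * grid, raw, rel_tol=0, abs_tol=1e-12) else (steps + 1) * grid
    return round(bound, 10)


def sedi_from_rates(h: float, f: float) -> float:
    """SEDI from hit rate H and false-alarm rate F; NaN when undefined.

    Undefined whenever H or F lies on {0, 1} (log singularities) — e.g. a
    month with no false positives — which is reported as missing, never as 0.
    """
    if not (np.isfinite(h) and np.isfinite(f)):
        return float("nan")
    if not (0.0 < h < 1.0 and 0.0 < f < 1.0):
        return float("nan")
    num = math.log(f) - math.log(h) - math.log(1.0 - f) + math.log(1.0 - h)
    den = math.log(f) + math.log(h) + math.log(1.0 - f) + math.log(1.0 - h)
    return num / den


def sedi(ct: ContingencyTable) -> float:
    """Symmetric Extremal Dependence Index of a contingency table (NaN if undefined)."""
    return sedi_from_rates(ct.hit_rate, ct.false_alarm_rate)


# ---------------------------------------------------------------------------
# bootstrap significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    significant: bool | None  # None when not assessed
    null_low: float
    null_high: float
    n_valid: int
    assessed: bool


def _null_metrics(
    obs: np.ndarray, n_boot: int, metric: str, rng: np.random.Generator, sampling: str
) -> np.ndarray:
    n = obs.size
    if sampling == "resample":
        draws = obs[rng.integers(0, n, size=(n_boot, n))]
    elif sampling == "permutation":
        draws = rng.permuted(np.broadcast_to(obs, (n_boot, n)).copy(), axis=1)
    else:
        raise ConfigurationError("sampling must be 'resample' or 'permutation'")
    o = obs[None, :]
    tp = np.sum(draws & o, axis=1)
    fp = np.sum(draws & ~o, axis=1)
    fn = np.sum(~draws & o, axis=1)
    tn = np.sum(~draws & ~o, axis=1)
    if metric == "accuracy":
        return (tp + tn) / n
    if metric == "sedi":
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
            f = np.where(fp + tn > 0, fp / np.maximum(fp + tn, 1), np.nan)
            ok = (h > 0) & (h < 1) & (f > 0) & (f < 1)
            h = np.where(ok, h, 0.5)
            f = np.where(ok, f, 0.5)
            num = np.log(f) - np.log(h) - np.log1p(-f) + np.log1p(-h)
            den = np.log(f) + np.log(h) + np.log1p(-f) + np.log1p(-h)
            vals = num / den
        return np.where(ok, vals, np.nan)
    raise ConfigurationError("metric must be 'accuracy' or 'sedi'")


def bootstrap_significance(
    observed_events,
    metric_value: float,
    metric: Literal["accuracy", "sedi"],
    n_boot: int = 1000,
    seed=None,
    sampling: str = "resample",
) -> BootstrapResult:
    """Significance of a categorical skill value against random forecasts.

    The null forecasts are binary vectors sampled with replacement from the
    observed event labels (equivalently Bernoulli at the observed event
    frequency; a label-permutation null is available via ``sampling``),
    scored against the fixed observed events.  Skill is significant when it
    strictly exceeds the 97.5th percentile of the null distribution.  If the
    metric is undefined in more than half of the null draws (or the skill
    value itself is undefined), significance is not assessed.
    """
    if n_boot < 100:
        raise ConfigurationError("need at least 100 bootstrap draws")
    obs = np.asarray(observed_events, dtype=float)
    obs = obs[np.isfinite(obs)].astype(bool)
    if obs.size < 2:
        raise ConfigurationError("need at least 2 observed events/non-events")
    rng = np.random.default_rng(seed)
    null = _null_metrics(obs, n_boot, metric, rng, sampling)
    valid = np.isfinite(null)
    n_valid = int(valid.sum())
    if n_valid < n_boot / 2 or not np.isfinite(metric_value):
        return BootstrapResult(
            significant=None, null_low=float("nan"), null_high=float("nan"),
            n_valid=n_valid, assessed=False,
        )
    lo, hi = np.percentile(null[valid], [2.5, 97.5])
    return BootstrapResult(
        significant=bool(metric_value > hi),
        null_low=float(lo),
        null_high=float(hi),
        n_valid=n_valid,
        assessed=True,
    )


# ---------------------------------------------------------------------------
# tidy skill report
# ---------------------------------------------------------------------------

def skill_report(
    observed: IndexSeries,
    lead_forecasts: Sequence[LeadForecast] | Mapping[float, LeadForecast],
    config: str,
    n_boot: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Per (target month, lead) verification of ensemble-mean index forecasts.

    Returns a tidy frame with one row per metric and cell: correlation (with
    N_eff, CI, and CI-based significance), accuracy, and SEDI (the latter
    two with bootstrap significance).  Undefined SEDI cells carry NaN.
    ``observed`` must already carry event flags, as must each forecast's
    ensemble series.
    """
    if observed.event_flags is None:
        raise ConfigurationError("observed series needs event flags")
    if isinstance(lead_forecasts, Mapping):
        lead_forecasts = [lead_forecasts[k] for k in sorted(lead_forecasts)]
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for lf in lead_forecasts:
        ens = lf.ensemble
        if ens.event_flags is None:
            raise ConfigurationError(f"forecast at lead {lf.lead} lacks event flags")
        months = (
            [lf.closure_month]
            if lf.closure_month is not None
            else sorted(np.unique(ens.months))
        )
        for m in months:
            f_sub = ens.select_month(int(m))
            o_sub = observed.select_month(int(m))
            common = f_sub.times.intersection(o_sub.times)
            if len(common) < 4:
                continue
            fi = f_sub.times.get_indexer(common)
            oi = o_sub.times.get_indexer(common)
            fv, ov = f_sub.values[fi], o_sub.values[oi]
            fe, oe = f_sub.event_flags[fi], o_sub.event_flags[oi]
            keep = np.isfinite(fv) & np.isfinite(ov)
            if keep.sum() < 4:
                continue
            corr = correlation_with_ci(fv[keep], ov[keep])
            ct = contingency(fe, oe)
            acc = accuracy(ct)
            sed = sedi(ct)
            child = seed_seq.spawn(1)[0]
            boot_seed_a, boot_seed_s = child.spawn(2)
            boot_acc = bootstrap_significance(oe, acc, "accuracy", n_boot=n_boot, seed=boot_seed_a)
            boot_sed = bootstrap_significance(oe, sed, "sedi", n_boot=n_boot, seed=boot_seed_s)
            base = dict(config=config, target_month=int(m), lead=lf.lead, n=int(keep.sum()))
            rows.append(
                base
                | dict(
                    metric="correlation", value=corr.r, significant=corr.significant,
                    n_eff=corr.n_eff, ci_low=corr.ci_low, ci_high=corr.ci_high,
                )
            )
            rows.append(
                base
                | dict(
                    metric="accuracy", value=acc, significant=boot_acc.significant,
                    n_eff=np.nan, ci_low=boot_acc.null_low, ci_high=boot_acc.null_high,
                )
            )
            rows.append(
                base
                | dict(
                    metric="sedi",
                    value=sed,
                    significant=boot_sed.significant if np.isfinite(sed) else None,
                    n_eff=np.nan, ci_low=boot_sed.null_low, ci_high=boot_sed.null_high,
                )
            )
    return pd.DataFrame(rows)
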