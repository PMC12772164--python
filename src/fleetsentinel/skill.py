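"""Rare-event skill scoring with the Symmetric Extremal Dependence Index.

Indicator anomaly series are binarized into extreme events at percentile
thresholds (70th-95th), paired into 2x2 contingency tables, and scored with
SEDI:

    SEDI = [ln F - ln H - ln(1-F) + ln(1-H)] / [ln F + ln H + ln(1-F) + ln(1-H)]

where H = TP/(TP+FN) is the hit ratio and F = FP/(FP+TN) the false-alarm
rate.  SEDI lies in [-1, 1]; 0 is random, 1 is perfect, and unlike many
categorical scores it does not degenerate as events become rare.  Because H
and F of 0 or 1 put the formula on a log singularity, rates are clamped to
[eps, 1-eps] and the result is flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fleetsentinel.indicators import quantile_nearest

DEFAULT_PERCENTILES = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def hit_ratio(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def false_alarm_rate(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else float("nan")


def binarize_extreme(series: pd.Series, percentile: float) -> pd.Series:
    """Boolean extreme-event series: value strictly above the pooled
    nearest-rank percentile threshold of all non-missing days."""
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    s = series.dropna()
    if len(s) < 10:
        raise ValueError(f"need at least 10 non-missing days, got {len(s)}")
    thr = quantile_nearest(s.to_numpy(), percentile)
    out = s > thr
    out.name = series.name
    return out


def contingency(pred_events: pd.Series, resp_events: pd.Series) -> ContingencyTable:
    """2x2 table from two boolean event series, pairwise-complete on days."""
    joined = pd.concat([pred_events, resp_events], axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no overlapping days between predictor and response events")
    p = joined.iloc[:, 0].astype(bool).to_numpy()
    r = joined.iloc[:, 1].astype(bool).to_numpy()
    return ContingencyTable(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def sedi_from_rates(H: float, F: float, eps: float = DEFAULT_EPS) -> float:
    """SEDI from a hit ratio and false-alarm rate, with the eps-clamp."""
    if np.isnan(H) or np.isnan(F):
        return float("nan")
    H = min(max(H, eps), 1.0 - eps)
    F = min(max(F, eps), 1.0 - eps)
    num = np.log(F) - np.log(H) - np.log1p(-F) + np.log1p(-H)
    den = np.log(F) + np.log(H) + np.log1p(-F) + np.log1p(-H)
    return float(num / den)


def sedi(table: ContingencyTable, eps: float = DEFAULT_EPS) -> float:
    """SEDI score of a 2x2 table; NaN if H or F is undefined (empty margin).

    Rates exactly 0 or 1 are clamped to [eps, 1-eps] (degenerate-limit
    convention); use :func:`is_degenerate` to detect that case.
    """
    return sedi_from_rates(table.hit_ratio, table.false_alarm_rate, eps)


def is_degenerate(table: ContingencyTable) -> bool:
    """True when H or F sits on the 0/1 boundary and the eps-clamp applies."""
    return table.hit_ratio in (0.0, 1.0) or table.false_alarm_rate in (0.0, 1.0)


def sedi_grid(
    indicator_set: dict[str, pd.Series],
    predictors: tuple[str, ...] = ("vms_y", "vms_shore", "ssta"),
    responses: tuple[str, ...] | None = None,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Score every (predictor, response, percentile) combination.

    Returns a tidy frame with columns predictor, response, percentile, sedi,
    tp, fp, fn, tn, degenerate, worse_than_random (sedi <= 0, the blanked
    tiles of a skill heat-map).
    """
    if responses is None:
        responses = tuple(n for n in indicator_set if n.startswith("habitat_"))
    if not predictors or not responses:
        raise ValueError("predictor and response sets must be nonempty")
    rows = []
    for pred in predictors:
        for resp in responses:
            for p in percentiles:
                pe = binarize_extreme(indicator_set[pred], p)
                re_ = binarize_extreme(indicator_set[resp], p)
                tab = contingency(pe, re_)
                score = sedi(tab, eps)
                rows.append({
                    "predictor": pred, "response": resp, "percentile": p,
                    "sedi": score, "tp": tab.tp, "fp": tab.fp, "fn": tab.fn,
                    "tn": tab.tn, "degenerate": is_degenerate(tab),
                    "worse_than_random": bool(score <= 0) if np.isfinite(score) else True,
                })
    return pd.DataFrame(rows)


def bootstrap_sedi(
    pred_events: pd.Series,
    resp_events: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    eps: float = DEFAULT_EPS,
) -> tuple[float, float]:
    """Percentile bootstrap interval for SEDI, resampling whole years.

    Whole fishing seasons (calendar years) are resampled with replacement so
    the strong within-season autocorrelation of smoothed anomalies does not
    fake precision.  Requires at least 3 years and n_boot >= 100.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    joined = pd.concat([pred_events, resp_events], axis=1, join="inner").dropna()
    years = joined.index.year.unique()
    if len(years) < 3:
        raise ValueError(f"need at least 3 years for a block bootstrap, got {len(years)}")
    by_year = {y: joined[joined.index.year == y].to_numpy(dtype=bool) for y in years}
    rng = np.random.default_rng(seed)
    scores = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(years, size=len(years), replace=True)
        block = np.concatenate([by_year[y] for y in pick])
        p, r = block[:, 0], block[:, 1]
        tab = ContingencyTable(int(np.sum(p & r)), int(np.sum(p & ~r)),
                               int(np.sum(~p & r)), int(np.sum(~p & ~r)))
        scores[b] = sedi(tab, eps)
    scores = scores[np.isfinite(scores)]
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(scores, alpha)), float(np.quantile(scores, 1.0 - alpha)))
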