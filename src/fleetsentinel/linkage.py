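"""Link VMS pings to landings receipts and isolate fishing activity.

The chain mirrors standard fisheries practice for joining vessel-tracking
data to fish tickets: keep receipts that are essentially pure albacore
(>= 90% of landed weight), assign each vessel's pings backward in time from
each receipt up to the previous receipt or a trip-length cap (75th
percentile of inter-receipt trip lengths, 16 days in the reference fleet),
drop flagged / in-port / signal-break pings, classify pings slower than
3.74 knots as fishing, and distribute each receipt's albacore pounds over
its fishing pings proportionally to each ping's "time forward" (minutes
until the next ping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALBACORE = "albacore"

#: Field-standard defaults of the reference fleet: 90% albacore rule, 121-minute
#: signal-break cut (one missed ~hourly ping), 3.74-knot fishing speed, 16-day
#: trip cap.
DEFAULT_MIN_FRACTION = 0.9
DEFAULT_MAX_GAP_MIN = 121.0
DEFAULT_MAX_SPEED_KN = 3.74
DEFAULT_TRIP_CAP_DAYS = 16.0

REQUIRED_PING_FIELDS = ("timestamp", "vessel_id", "lat", "lon", "event_type",
                        "time_forward", "speed", "gis_flag")


@dataclass
class FilterReport:
    """Counts of pings removed by each fishing filter."""

    n_input: int = 0
    missing_fields: int = 0
    flagged: int = 0
    not_at_sea: int = 0
    gap: int = 0
    speed: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "missing_fields": self.missing_fields,
            "flagged": self.flagged,
            "not_at_sea": self.not_at_sea,
            "gap": self.gap,
            "speed": self.speed,
            "n_output": self.n_output,
        }


def _receipt_totals(receipts: pd.DataFrame, species: str = ALBACORE) -> pd.DataFrame:
    grp = receipts.groupby("ticket_id", sort=False)
    total = grp["pounds"].sum()
    alb = receipts.loc[receipts["species"] == species].groupby("ticket_id")["pounds"].sum()
    out = pd.DataFrame({"total": total})
    out["albacore"] = alb.reindex(out.index).fillna(0.0)
    return out


def filter_albacore_receipts(
    receipts: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    species: str = ALBACORE,
) -> pd.DataFrame:
    """Retain receipts whose target-species share of landed weight is >= min_fraction.

    Receipts with zero total pounds have an undefined share and are excluded
    (logged).  The inequality is inclusive: a receipt at exactly the
    threshold is retained.
    """
    if receipts.empty:
        return receipts.copy()
    totals = _receipt_totals(receipts, species)
    zero = totals.index[totals["total"] <= 0.0]
    if len(zero):
        logger.warning("excluding %d receipt(s) with zero total pounds", len(zero))
    ok = totals.index[(totals["total"] > 0.0) & (totals["albacore"] / totals["total"] >= min_fraction)]
    return receipts.loc[receipts["ticket_id"].isin(set(ok))].copy()


def compute_trip_cap(
    receipts: pd.DataFrame,
    percentile: float = 0.75,
    fallback: float = DEFAULT_TRIP_CAP_DAYS,
) -> float:
    """Nearest-rank percentile (in days) of per-vessel inter-receipt durations.

    Successive receipts of one vessel bound a trip; the cap keeps pings from
    unrelated at-sea activity (e.g., a months-long gap between tickets) out
    of the assignment window.  With no computable trip lengths, falls back
    to ``fallback`` (default 16 days) with a warning.
    """
    durations: list[float] = []
    if not receipts.empty:
        t = receipts.drop_duplicates("ticket_id").sort_values("timestamp")
        for _, g in t.groupby("vessel_id", sort=False):
            if len(g) >= 2:
                d = g["timestamp"].diff().dropna().dt.total_seconds() / 86400.0
                durations.extend(d.tolist())
    if not durations:
        logger.warning("no inter-receipt trip lengths computable; using fallback %.1f d", fallback)
        return float(fallback)
    arr = np.sort(np.asarray(durations))
    k = max(int(math.ceil(percentile * len(arr))), 1)
    return float(arr[k - 1])


def assign_pings_to_receipts(
    pings: pd.DataFrame,
    receipts: pd.DataFrame,
    trip_cap: float = DEFAULT_TRIP_CAP_DAYS,
) -> pd.DataFrame:
    """Assign each ping to the first receipt of its vessel at or after it.

    A ping at time t belongs to receipt R (timestamp t_R) of the same vessel
    iff ``max(t_prev, t_R - trip_cap) < t <= t_R`` where t_prev is the
    vessel's previous receipt timestamp.  Each ping joins at most one
    receipt.  Returns the assigned pings with a ``ticket_id`` column;
    unassigned pings are dropped.
    """
    cap = pd.Timedelta(days=float(trip_cap))
    tickets = receipts.drop_duplicates("ticket_id")[["ticket_id", "vessel_id", "timestamp"]]
    out: list[pd.DataFrame] = []
    for vessel, recs in tickets.groupby("vessel_id", sort=False):
        vp = pings.loc[pings["vessel_id"] == vessel]
        if vp.empty:
            continue
        vp = vp.sort_values("timestamp", kind="stable")
        recs = recs.sort_values(["timestamp", "ticket_id"], kind="stable")
        dup = recs["timestamp"].duplicated(keep=False)
        if dup.any():
            logger.warning(
                "vessel %s has %d receipts sharing a timestamp; later ticket wins the boundary",
                vessel, int(dup.sum()),
            )
        rec_times = recs["timestamp"].to_numpy()
        ping_times = vp["timestamp"].to_numpy()
        # first receipt with t_R >= ping time
        idx = np.searchsorted(rec_times, ping_times, side="left")
        # among receipts sharing a timestamp the last ticket takes the boundary ping
        last_at_time = np.searchsorted(rec_times, rec_times, side="right") - 1
        valid = idx < len(rec_times)
        idx_clip = np.where(valid, idx, 0)
        idx_clip = np.where(valid, last_at_time[idx_clip], 0)
        t_r = rec_times[idx_clip]
        prev = np.full(len(rec_times), np.datetime64("1677-09-22"), dtype=rec_times.dtype)
        prev[1:] = rec_times[:-1]
        lower = np.maximum(prev[idx_clip], t_r - cap)
        ok = valid & (ping_times > lower) & (ping_times <= t_r)
        assigned = vp.loc[ok].copy()
        assigned["ticket_id"] = recs["ticket_id"].to_numpy()[idx_clip[ok]]
        out.append(assigned)
    if not out:
        return pings.iloc[0:0].assign(ticket_id=pd.Series(dtype=object))
    return pd.concat(out, ignore_index=True)


def apply_fishing_filters(
    pings: pd.DataFrame,
    max_gap: float = DEFAULT_MAX_GAP_MIN,
    max_speed: float = DEFAULT_MAX_SPEED_KN,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Keep quality-clean, at-sea, fishing-speed pings.

    Removes pings with the GIS quality flag set, non-at-sea event types,
    time-forward strictly greater than ``max_gap`` minutes (a missed ping /
    signal break), and speed at or above ``max_speed`` knots (fishing means
    strictly slower).  The four rules intersect, so filter order is
    irrelevant and the operation is idempotent.  Pass a FilterReport to
    collect per-rule removal counts.
    """
    rep = report if report is not None else FilterReport()
    rep.n_input = len(pings)
    needed = ["event_type", "gis_flag", "time_forward", "speed"]
    complete = pings[needed].notna().all(axis=1)
    rep.missing_fields = int((~complete).sum())
    p = pings.loc[complete]
    flagged = p["gis_flag"].astype(bool)
    not_sea = p["event_type"] != "at_sea"
    gap = p["time_forward"] > max_gap
    fast = p["speed"] >= max_speed
    rep.flagged = int(flagged.sum())
    rep.not_at_sea = int(not_sea.sum())
    rep.gap = int(gap.sum())
    rep.speed = int(fast.sum())
    keep = ~(flagged | not_sea | gap | fast)
    out = p.loc[keep].copy()
    rep.n_output = len(out)
    logger.info("fishing filters: %s", rep.as_dict())
    return out


def allocate_pounds(
    receipts: pd.DataFrame,
    assigned_pings: pd.DataFrame,
    species: str = ALBACORE,
) -> pd.DataFrame:
    """Distribute each receipt's albacore pounds over its pings by time-forward.

    ``allocated_pounds_i = pounds * time_forward_i / sum(time_forward)``
    within each ticket, so pounds are conserved per receipt.  Receipts whose
    assigned pings have zero total time-forward cannot be allocated and are
    dropped with a warning.
    """
    if assigned_pings.empty:
        return assigned_pings.assign(allocated_pounds=pd.Series(dtype=float))
    alb = (
        receipts.loc[receipts["species"] == species]
        .groupby("ticket_id")["pounds"]
        .sum()
    )
    p = assigned_pings.copy()
    tf_sum = p.groupby("ticket_id")["time_forward"].transform("sum")
    zero = tf_sum <= 0.0
    if zero.any():
        bad = p.loc[zero, "ticket_id"].unique()
        logger.warning("dropping %d receipt(s) with zero total time-forward: %s",
                       len(bad), list(bad[:5]))
        p = p.loc[~zero]
        tf_sum = tf_sum.loc[~zero]
    pounds = p["ticket_id"].map(alb).fillna(0.0)
    p["allocated_pounds"] = pounds * p["time_forward"] / tf_sum
    return p


def link(
    pings: pd.DataFrame,
    receipts: pd.DataFrame,
    trip_cap: float | str = "auto",
    min_fraction: float = DEFAULT_MIN_FRACTION,
    max_gap: float = DEFAULT_MAX_GAP_MIN,
    max_speed: float = DEFAULT_MAX_SPEED_KN,
    species: str = ALBACORE,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Full linkage pipeline: receipt filter -> vessel filter -> assignment ->
    fishing filters -> proportional allocation.

    ``trip_cap="auto"`` computes the 75th-percentile inter-receipt trip
    length from the filtered receipts; pass a number of days to override.
    Returns fishing-classified pings with ``ticket_id`` and
    ``allocated_pounds`` columns.
    """
    recs = filter_albacore_receipts(receipts, min_fraction, species)
    vessels = set(recs["vessel_id"].unique()) if not recs.empty else set()
    p = pings.loc[pings["vessel_id"].isin(vessels)]
    cap = compute_trip_cap(recs) if trip_cap == "auto" else float(trip_cap)
    assigned = assign_pings_to_receipts(p, recs, cap)
    fishing = apply_fishing_filters(assigned, max_gap, max_speed, report=report)
    return allocate_pounds(recs, fishing, species)
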