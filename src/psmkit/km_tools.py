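"""Kaplan-Meier estimation and pseudo-IPD reconstruction from digitized curves.

Published survival curves rarely come with individual patient data (IPD).
When only the plotted curve and the numbers-at-risk row are available, a
pseudo-IPD dataset can be reconstructed by allocating integer event and
censoring counts inside each risk-table interval so that (a) the
product-limit curve recomputed from the output matches the digitized
survival probabilities and (b) the numbers at risk match the risk table at
interval starts, with censoring spread uniformly within intervals
(the Guyot-style boundary-matching allocation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

log = logging.getLogger(__name__)

__all__ = [
    "PseudoIPD",
    "KMCurve",
    "DigitizedCurve",
    "km_estimate",
    "repair_monotone",
    "reconstruct_ipd",
]


@dataclass
class PseudoIPD:
    """Individual time-to-event records for one endpoint and arm.

    ``records`` is a DataFrame with columns ``time`` (>= 0) and ``event``
    (1 = event, 0 = censored).
    """

    records: pd.DataFrame
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        if not {"time", "event"}.issubset(df.columns):
            raise ValueError("PseudoIPD records need 'time' and 'event' columns")
        if len(df) == 0:
            raise ValueError("PseudoIPD needs at least one record")
        if (df["time"] < 0).any():
            raise ValueError("PseudoIPD times must be non-negative")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("PseudoIPD event flags must be 0 (censored) or 1 (event)")
        self.records = df.reset_index(drop=True)

    @property
    def n(self):
        return len(self.records)

    @property
    def times(self):
        return self.records["time"].to_numpy(dtype=float)

    @property
    def events(self):
        return self.records["event"].to_numpy(dtype=int)

    def to_csv(self, path):
        self.records[["time", "event"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm="", endpoint=""):
        return cls(pd.read_csv(path), arm=arm, endpoint=endpoint)


@dataclass
class KMCurve:
    """A product-limit curve: step times with survival, at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def at(self, t):
        """Step-function lookup Shat(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    @property
    def n0(self):
        return int(self.n_at_risk[0]) if len(self.n_at_risk) else 0


@dataclass
class DigitizedCurve:
    """Digitized curve coordinates plus the published numbers-at-risk table."""

    points: pd.DataFrame  # columns: time, survival
    risk_table: pd.DataFrame  # columns: time, n_risk
    total_events: int | None = None

    def __post_init__(self):
        pts = pd.DataFrame(self.points)
        rt = pd.DataFrame(self.risk_table)
        if not {"time", "survival"}.issubset(pts.columns):
            raise ValueError("points need 'time' and 'survival' columns")
        if not {"time", "n_risk"}.issubset(rt.columns):
            raise ValueError("risk_table needs 'time' and 'n_risk' columns")
        if (pts["time"] < 0).any() or (rt["time"] < 0).any():
            raise ValueError("times must be non-negative")
        if ((pts["survival"] < 0) | (pts["survival"] > 1)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        rt = rt.sort_values("time").reset_index(drop=True)
        if (np.diff(rt["n_risk"].to_numpy()) > 0).any():
            raise ValueError("risk-table counts must be non-increasing in time")
        self.points = pts.reset_index(drop=True)
        self.risk_table = rt


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    Ties between events and censorings at the same time follow the standard
    convention (events first).  An all-censored input yields a flat curve at
    1.0 with a logged warning.
    """
    if ipd.events.sum() == 0:
        log.warning("km_estimate: all observations censored; curve is flat at 1.0")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    tbl = kmf.event_table
    # drop the t=0 bookkeeping row unless something actually happened there
    keep = (tbl["observed"] > 0) | (tbl["censored"] > 0)
    tbl = tbl[keep]
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        n_at_risk=tbl["at_risk"].to_numpy(dtype=int),
        n_events=tbl["observed"].to_numpy(dtype=int),
        n_censored=tbl["censored"].to_numpy(dtype=int),
    )


def repair_monotone(points) -> pd.DataFrame:
    """Sort digitized points by time and enforce non-increasing survival.

    Digitized times are treated as exact; survival readings as noisy, so a
    running minimum is applied to the survival values only.  Duplicate times
    collapse to the minimum survival at that time.
    """
    pts = pd.DataFrame(points, columns=None)
    if not {"time", "survival"}.issubset(pts.columns):
        pts = pd.DataFrame(np.asarray(points, dtype=float), columns=["time", "survival"])
    pts = pts.sort_values("time", kind="stable")
    pts = pts.groupby("time", as_index=False)["survival"].min()
    pts["survival"] = np.minimum.accumulate(pts["survival"].to_numpy(dtype=float))
    return pts.reset_index(drop=True)


def _allocate_clicks(tt, SS, n_start, n_censor, km_prev):
    """Allocate integer events along a local click sequence.

    ``n_censor`` censorings are spread uniformly over [tt[0], tt[-1]];
    events at each click come from the product-limit ratio to the running
    reconstructed curve, with a fractional carry so rounding never drifts
    from the cumulative target.  Returns (events, censorings, n at end,
    running KM after the last click).
    """
    m = len(tt)
    d = np.zeros(m, dtype=int)
    c = np.zeros(m, dtype=int)
    if n_censor > 0:
        span_lo, span_hi = tt[0], tt[-1]
        if span_hi <= span_lo:
            c[0] = n_censor
        else:
            cen_times = span_lo + (np.arange(1, n_censor + 1) - 0.5) * (
                span_hi - span_lo
            ) / n_censor
            idx = np.clip(np.searchsorted(tt, cen_times, side="right") - 1, 0, m - 1)
            for j in idx:
                c[j] += 1
    n = n_start
    km = km_prev
    carry = 0.0
    for j in range(m):
        if n > 0 and km > 0:
            d_real = n * (1.0 - SS[j] / km)
            dj = int(round(d_real + carry))
            dj = max(0, min(dj, n))
            carry += d_real - dj
        else:
            dj = 0
        if dj > 0:
            km = km * (1.0 - dj / n)
        d[j] = dj
        n = n - dj - c[j]
        if n < 0:
            # infeasible censor placement: pull back censorings
            c[j] += n
            n = 0
    return d, c, n, km


def reconstruct_ipd(curve: DigitizedCurve, arm="", endpoint="", max_iter=60) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized curve and its risk table.

    Within each risk-table interval the censoring count is found iteratively
    so that the implied number at risk at the next interval start matches the
    published risk table exactly; events at each digitized click are set from
    the product-limit ratio to the running curve.  Because digitized clicks
    rarely fall exactly on the risk-table times, a virtual click is
    interpolated at each interval boundary so that survival drops straddling
    a boundary are attributed to the correct interval.  In the final
    interval, ``total_events`` (when supplied) pins down the event count;
    remaining subjects are censored at the final digitized time.
    """
    pts = repair_monotone(curve.points)
    t = pts["time"].to_numpy(dtype=float)
    S = pts["survival"].to_numpy(dtype=float)
    if t[0] > 0:
        t = np.insert(t, 0, 0.0)
        S = np.insert(S, 0, 1.0)
    rt = curve.risk_table
    trisk = rt["time"].to_numpy(dtype=float)
    nrisk = rt["n_risk"].to_numpy(dtype=int)
    if len(trisk) < 2:
        raise ValueError("risk table needs at least 2 intervals")

    K = len(t)
    # lower[i] = first click inside risk interval i; may equal K (no clicks)
    lower = np.searchsorted(t, trisk, side="left")

    events = np.zeros(K, dtype=int)
    censors = np.zeros(K, dtype=int)
    extra = []  # (time, n_events, n_censored) at virtual boundary clicks
    km = 1.0
    n = int(nrisk[0])
    residual = 0

    for i in range(len(trisk) - 1):
        k_lo, k_hi = int(lower[i]), int(lower[i + 1]) - 1
        tb = float(trisk[i + 1])
        sb = float(np.interp(tb, t, S))
        if k_hi >= k_lo and k_lo < K:
            tt = np.append(t[k_lo : k_hi + 1], tb)
            SS = np.append(S[k_lo : k_hi + 1], sb)
        else:
            tt = np.array([tb])
            SS = np.array([sb])
            k_lo = k_hi = None
        target = int(nrisk[i + 1])
        guess = int(round(n * sb / km)) - target if km > 0 else n - target
        cen = max(0, min(guess, n))
        best = None
        seen = set()
        for _ in range(max_iter):
            d, c, n_end, km_end = _allocate_clicks(tt, SS, n, cen, km)
            diff = n_end - target
            if best is None or abs(diff) < abs(best[0]):
                best = (diff, d, c, n_end, km_end, cen)
            if diff == 0 or cen in seen:
                break
            seen.add(cen)
            cen = max(0, min(cen + diff, n))
        diff, d, c, n_end, km_end, cen = best
        if diff != 0:
            if diff > 0:
                # surplus subjects: censor them at the interval boundary
                c[-1] += diff
                n_end -= diff
            else:
                # shortfall: first restore censorings, then events, from the tail
                need = -diff
                for arr in (c, d):
                    for j in range(len(arr) - 1, -1, -1):
                        r = min(arr[j], need)
                        arr[j] -= r
                        n_end += r
                        need -= r
                        if need == 0:
                            break
                    if need == 0:
                        break
                residual += need
                # recompute the running curve consistently with the trimmed events
                km_end = km
                nn = n
                for j in range(len(d)):
                    if d[j] > 0:
                        km_end *= 1.0 - d[j] / nn
                    nn -= d[j] + c[j]
            log.warning(
                "reconstruct_ipd: interval %d required residual adjustment of %d", i, diff
            )
        # allocations at the virtual boundary click happened strictly before
        # the boundary; record them at the midpoint of the final gap so the
        # at-risk count at the boundary time matches the risk table
        if k_lo is not None:
            events[k_lo : k_hi + 1] += d[:-1]
            censors[k_lo : k_hi + 1] += c[:-1]
            t_prev = tt[-2] if len(tt) > 1 else trisk[i]
            extra.append(((t_prev + tb) / 2.0, int(d[-1]), int(c[-1])))
        else:
            extra.append(((trisk[i] + tb) / 2.0, int(d[0]), int(c[0])))
        km = km_end
        n = n_end

    # final interval (beyond the last risk time)
    k_lo = int(lower[-1])
    if k_lo <= K - 1 and n > 0:
        d, c, n_end, km = _allocate_clicks(t[k_lo:], S[k_lo:], n, 0, km)
        if curve.total_events is not None:
            want = max(0, int(curve.total_events) - int(events.sum()) - sum(e for _, e, _ in extra))
            if d.sum() > want:
                excess = int(d.sum()) - want
                for j in range(len(d) - 1, -1, -1):
                    r = min(d[j], excess)
                    d[j] -= r
                    n_end += r
                    excess -= r
                    if excess == 0:
                        break
        events[k_lo:] += d
        censors[k_lo:] += c
        n = n_end
    if n > 0:
        censors[-1] += n  # administratively censored at the final digitized time
        n = 0

    ex_et = np.array([tt for tt, ne, _ in extra for _ in range(ne)])
    ex_ct = np.array([tt for tt, _, nc in extra for _ in range(nc)])
    rec_t = np.concatenate([np.repeat(t, events), ex_et, np.repeat(t, censors), ex_ct])
    rec_e = np.concatenate(
        [
            np.ones(events.sum() + len(ex_et), int),
            np.zeros(censors.sum() + len(ex_ct), int),
        ]
    )
    order = np.argsort(rec_t, kind="stable")
    df = pd.DataFrame({"time": rec_t[order], "event": rec_e[order]})
    if len(df) != nrisk[0]:
        log.warning(
            "reconstruct_ipd: reconstructed %d subjects vs %d in risk table", len(df), nrisk[0]
        )
    return PseudoIPD(df, arm=arm, endpoint=endpoint)


def read_digitized(points_csv, risk_csv, total_events=None) -> DigitizedCurve:
    """Load a digitized curve from two delimited text files."""
    pts = pd.read_csv(points_csv)
    rt = pd.read_csv(risk_csv)
    return DigitizedCurve(points=pts, risk_table=rt, total_events=total_events)
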