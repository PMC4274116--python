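"""Mass-partitioning statistics for detected division events.

Covers the daughter-cell mass asymmetry Dm = 2|m_d1 - m_d2| / (m_d1 + m_d2),
its dynamics after the furrow (initial asymmetry Dm0, least-squares rate r,
heatmap ordering key theta = atan2(r, Dm0)), population summaries
(mean |Dm| vs time, coefficient of variation of mass in 10-min bins, binned
growth rates), and the two significance tests used for condition
comparisons: Welch's unequal-variance t test and the regression F test
against a constant-only model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .division import DivisionEvent
from .tracking import CellTrack

logger = logging.getLogger(__name__)

R_FIT_HORIZON_DEFAULT = 60.0   # min after the furrow used for the slope fit


def delta_m(m_d1: float, m_d2: float, signed: bool = False) -> float:
    """Daughter mass asymmetry 2|m1 - m2|/(m1 + m2) (signed form keeps the sign).

    Dimensionless, in [0, 2]; invariant under rescaling both masses.
    """
    total = m_d1 + m_d2
    if total <= 0:
        raise ValueError("daughter pair mass must be positive")
    dm = 2.0 * (m_d1 - m_d2) / total
    return dm if signed else abs(dm)


@dataclass
class AsymmetryRecord:
    """Per-event asymmetry dynamics."""

    event_id: int
    dm0: float                 # signed asymmetry at t = 0 (>= 0 by convention)
    rate: float                # 1/min, OLS slope of signed dm over [0, horizon]
    theta: float               # atan2(rate, dm0), the heatmap ordering key
    times: np.ndarray = field(default=None, repr=False)   # min since furrow
    dm_signed: np.ndarray = field(default=None, repr=False)
    valid: bool = True


def asymmetry_dynamics(event: DivisionEvent,
                       horizon: float = R_FIT_HORIZON_DEFAULT
                       ) -> AsymmetryRecord:
    """Dm0, rate r, and ordering key theta for one event.

    Events with fewer than three post-furrow frames are flagged invalid and
    excluded from heatmaps.
    """
    t = np.asarray(event.times, float)
    dm = np.asarray(event.dm_signed, float)
    sel = (t >= 0) & (t <= horizon)
    if sel.sum() < 3:
        logger.info("event %d: fewer than 3 post-furrow frames; flagged",
                    event.event_id)
        return AsymmetryRecord(event_id=event.event_id, dm0=np.nan,
                               rate=np.nan, theta=np.nan,
                               times=t, dm_signed=dm, valid=False)
    dm0 = float(dm[np.argmin(np.abs(t))])
    rate = float(np.polyfit(t[sel], dm[sel], 1)[0])
    return AsymmetryRecord(event_id=event.event_id, dm0=dm0, rate=rate,
                           theta=float(np.arctan2(rate, dm0)),
                           times=t, dm_signed=dm)


def order_events(records: list[AsymmetryRecord]) -> list[int]:
    """Heatmap row order: indices sorted by theta, descending; ties by id."""
    idx = [i for i, r in enumerate(records) if r.valid]
    return sorted(idx, key=lambda i: (-records[i].theta, records[i].event_id))


def heatmap_matrix(records: list[AsymmetryRecord], bin_width: float = 3.0,
                   t_range: tuple[float, float] = (0.0, 60.0),
                   signed: bool = True) -> pd.DataFrame:
    """Events x time-bins matrix of (signed or absolute) Dm, ordered by theta."""
    edges = np.arange(t_range[0], t_range[1] + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for i in order_events(records):
        r = records[i]
        vals = np.full(centers.size, np.nan)
        which = np.digitize(r.times, edges) - 1
        for k in range(centers.size):
            sel = which == k
            if sel.any():
                v = np.nanmean(r.dm_signed[sel])
                vals[k] = v if signed else abs(v)
        rows.append(pd.Series(vals, index=centers, name=r.event_id))
    return pd.DataFrame(rows)


def coefficient_of_variation(values) -> float:
    """CV = standard deviation / mean (sample sd, ddof = 1)."""
    values = np.asarray(values, float)
    if values.size < 2:
        return 0.0
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


@dataclass
class PopulationSummary:
    """Binned population curves over all events."""

    mean_abs_dm: pd.DataFrame      # columns: t_min, mean_abs_dm, sem, n
    mass_cv: pd.DataFrame          # columns: t_min, cv, n
    growth_vs_time: pd.DataFrame   # columns: t_min, growth_pg_min, sem, n
    growth_vs_mass: pd.DataFrame   # columns: rel_mass, growth_pg_min, sem, n


def _binned(x, y, edges, reducer):
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    which = np.digitize(x, edges) - 1
    for k, c in enumerate(centers):
        sel = which == k
        if not sel.any():
            continue   # empty bins are reported missing, not zero
        rows.append((c, *reducer(np.asarray(y)[sel]), int(sel.sum())))
    return rows


def mean_abs_dm_curve(events: list[DivisionEvent], bin_width: float = 10.0,
                      t_range: tuple[float, float] = (0.0, 60.0)) -> pd.DataFrame:
    """Mean |Dm| vs time since furrow, with s.e.m. over events per bin."""
    ts, dms, ids = [], [], []
    for ev in events:
        ts.extend(np.asarray(ev.times, float))
        dms.extend(np.abs(np.asarray(ev.dm_signed, float)))
        ids.extend([ev.event_id] * len(ev.times))
    df = pd.DataFrame({"t": ts, "dm": dms, "id": ids})
    edges = np.arange(t_range[0], t_range[1] + bin_width, bin_width)
    rows = []
    for k in range(edges.size - 1):
        sel = df[(df.t >= edges[k]) & (df.t < edges[k + 1])]
        if sel.empty:
            continue
        per_event = sel.groupby("id").dm.mean()
        rows.append((0.5 * (edges[k] + edges[k + 1]), per_event.mean(),
                     per_event.sem() if len(per_event) > 1 else 0.0,
                     len(per_event)))
    return pd.DataFrame(rows, columns=["t_min", "mean_abs_dm", "sem", "n"])


def mass_cv_curve(samples_t: np.ndarray, samples_mass: np.ndarray,
                  bin_width: float = 10.0,
                  t_range: tuple[float, float] = (-90.0, 90.0)) -> pd.DataFrame:
    """CV of mass in division-aligned time bins (10-min bins, -90..90 min)."""
    edges = np.arange(t_range[0], t_range[1] + bin_width, bin_width)
    rows = _binned(np.asarray(samples_t, float), np.asarray(samples_mass, float),
                   edges, lambda v: (coefficient_of_variation(v),))
    return pd.DataFrame(rows, columns=["t_min", "cv", "n"])


def growth_rate_samples(tracks: list[CellTrack]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-difference growth rates: (t midpoints, relative mass, dm/dt)."""
    ts, rel, rates = [], [], []
    for tr in tracks:
        t = tr.times
        m = tr.masses
        if t.size < 2:
            continue
        dm = np.diff(m) / np.diff(t)
        ts.extend(0.5 * (t[:-1] + t[1:]))
        rel.extend(0.5 * (m[:-1] + m[1:]) / m[-1])
        rates.extend(dm)
    return np.array(ts), np.array(rel), np.array(rates)


def population_curves(events: list[DivisionEvent],
                      tracks: list[CellTrack] | None = None,
                      bin_width: float = 10.0) -> PopulationSummary:
    """Assemble the population summary from events (and optionally tracks)."""
    if not events:
        raise ValueError("at least one event required")
    mean_dm = mean_abs_dm_curve(events, bin_width=bin_width)

    ts, masses = [], []
    for ev in events:
        t = np.asarray(ev.times, float)
        dm = np.asarray(ev.dm_signed, float)
        pair = ev.m_d1 + ev.m_d2
        # daughter masses reconstructed from the pair total and signed dm
        masses.extend(pair * (0.5 + dm / 4.0))
        masses.extend(pair * (0.5 - dm / 4.0))
        ts.extend(t)
        ts.extend(t)
    cv = mass_cv_curve(np.array(ts), np.array(masses), bin_width=10.0)

    if tracks:
        gt, gm, gr = growth_rate_samples(tracks)
        edges_t = np.arange(gt.min(), gt.max() + 60.0, 60.0) if gt.size else [0, 1]
        gvt = pd.DataFrame(
            _binned(gt, gr, np.asarray(edges_t),
                    lambda v: (v.mean(), v.std(ddof=1) / np.sqrt(v.size)
                               if v.size > 1 else 0.0)),
            columns=["t_min", "growth_pg_min", "sem", "n"])
        edges_m = np.linspace(0.4, 1.2, 9)
        gvm = pd.DataFrame(
            _binned(gm, gr, edges_m,
                    lambda v: (v.mean(), v.std(ddof=1) / np.sqrt(v.size)
                               if v.size > 1 else 0.0)),
            columns=["rel_mass", "growth_pg_min", "sem", "n"])
    else:
        gvt = pd.DataFrame(columns=["t_min", "growth_pg_min", "sem", "n"])
        gvm = pd.DataFrame(columns=["rel_mass", "growth_pg_min", "sem", "n"])

    return PopulationSummary(mean_abs_dm=mean_dm, mass_cv=cv,
                             growth_vs_time=gvt, growth_vs_mass=gvm)


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-tailed Welch's t test with unequal variances and sample sizes."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:   # both samples constant
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def regression_f_test(x, y) -> tuple[float, float, float]:
    """OLS slope and F test of the line against a constant-only model.

    F = (SSE_const - SSE_line) / (SSE_line / (n - 2)) with p from F(1, n-2).
    Returns (slope, F, p); a perfect linear fit yields p = 0 and a constant
    response yields p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    slope, intercept = np.polyfit(x, y, 1)
    sse_line = float(np.sum((y - (slope * x + intercept)) ** 2))
    sse_const = float(np.sum((y - y.mean()) ** 2))
    n = x.size
    if sse_line <= 1e-12 * sse_const or sse_line == 0:
        if sse_const == 0:
            return float(slope), 0.0, 1.0   # constant response: no fit to test
        return float(slope), np.inf, 0.0    # perfect line up to roundoff
    f = (sse_const - sse_line) / (sse_line / (n - 2))
    p = float(sps.f.sf(f, 1, n - 2))
    return float(slope), float(f), p
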