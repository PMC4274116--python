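"""Division detection: sigmoid matched filtering and parent-daughter pairing.

Adherent cells round up before cytokinesis (mean phase shift — mass per
area — rises sigmoidally) and the daughters flatten afterwards (mean phase
decays sigmoidally).  A division is emitted when (1) a parent track ends and
two new tracks begin nearby, each carrying roughly half the parent mass;
(2) the parent's mean-phase trace matches a rising sigmoid; and (3) both
daughters' traces match a falling sigmoid.  Non-adherent cells keep their
shape, so only criterion (1) applies and mitotic timing is undefined.
t = 0 (the deep cleavage furrow) is the first frame in which the watershed
separates the two daughters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tracking import CellTrack

logger = logging.getLogger(__name__)


@dataclass
class DivisionParams:
    """Detection tunables (times in min, masses relative to the parent)."""

    sigmoid_tau: float = 6.0          # min, logistic time constant
    sigmoid_window: float = 24.0      # min, half-width of the matched filter
    score_threshold: float = 0.7      # normalized correlation peak
    min_amplitude: float = 20.0       # nm, minimum fitted sigmoid step
    daughter_mass_window: tuple[float, float] = (0.35, 0.65)
    combined_mass_window: tuple[float, float] = (0.8, 1.2)
    vicinity_radius: float = 30.0     # um from the parent's last centroid
    boundary_frames: int = 3          # reject events this close to movie ends


@dataclass
class SigmoidFit:
    """One matched-filter detection on a mean-phase trace."""

    midpoint: float        # min, time of 50% rise/decay
    amplitude: float       # nm, fitted step height
    width: float           # min, template time constant
    score: float           # normalized correlation in [-1, 1]
    direction: str         # "rising" | "falling"


@dataclass
class DivisionEvent:
    """One detected division; daughter 1 is the heavier daughter at t = 0."""

    event_id: int
    parent_track: int
    d1_track: int
    d2_track: int
    t_furrow: float                       # min, absolute movie time
    m_parent: float                       # pg, last parent mass
    m_d1: float                           # pg at t = 0
    m_d2: float                           # pg at t = 0
    times: np.ndarray = field(default=None)      # min relative to furrow
    dm_signed: np.ndarray = field(default=None)  # 2(m1-m2)/(m1+m2)
    entry_mid: float | None = None        # min, absolute
    exit_mid_d1: float | None = None
    exit_mid_d2: float | None = None
    adherent: bool = True

    @property
    def dm0(self) -> float:
        """Signed asymmetry at the furrow (>= 0 by the d1 convention)."""
        return 2.0 * (self.m_d1 - self.m_d2) / (self.m_d1 + self.m_d2)


def sigmoid_template(interval: float, tau: float, window: float,
                     direction: str = "rising") -> np.ndarray:
    """Unit logistic sampled on the frame grid over +/- window minutes."""
    half = int(round(window / interval))
    t = np.arange(-half, half + 1) * interval
    s = 1.0 / (1.0 + np.exp(-t / tau))
    if direction == "falling":
        s = s[::-1]
    elif direction != "rising":
        raise ValueError("direction must be 'rising' or 'falling'")
    return s


def fit_sigmoid_trace(times: np.ndarray, values: np.ndarray, direction: str,
                      params: DivisionParams | None = None) -> list[SigmoidFit]:
    """Slide a zero-mean unit-norm sigmoid along the trace.

    Local maxima of the normalized correlation above the score threshold,
    with a fitted step height above the amplitude floor, are returned as
    candidate mitotic entry (rising) or exit (falling) midpoints.
    """
    params = params or DivisionParams()
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size < 2:
        return []
    interval = float(np.median(np.diff(times)))
    templ = sigmoid_template(interval, params.sigmoid_tau,
                             params.sigmoid_window, direction)
    w = templ.size
    if values.size < w:
        return []
    templ_zm = templ - templ.mean()
    templ_norm = np.linalg.norm(templ_zm)
    templ_unit = templ_zm / templ_norm

    n_pos = values.size - w + 1
    scores = np.full(n_pos, -np.inf)
    amps = np.zeros(n_pos)
    for k in range(n_pos):
        seg = values[k:k + w]
        seg_zm = seg - seg.mean()
        nrm = np.linalg.norm(seg_zm)
        if nrm == 0:
            continue
        corr = float(seg_zm @ templ_unit) / nrm
        scores[k] = corr
        # least-squares projection onto the template gives the step height
        amps[k] = float(seg_zm @ templ_unit) / templ_norm

    fits: list[SigmoidFit] = []
    half = w // 2
    for k in range(n_pos):
        if scores[k] < params.score_threshold or amps[k] < params.min_amplitude:
            continue
        lo, hi = max(0, k - 1), min(n_pos, k + 2)
        if scores[k] < np.max(scores[lo:hi]) - 1e-12:
            continue
        if k > 0 and scores[k - 1] == scores[k] and \
                any(f.midpoint == times[k - 1 + half] for f in fits):
            continue
        fits.append(SigmoidFit(midpoint=float(times[k + half]),
                               amplitude=float(amps[k]),
                               width=params.sigmoid_tau,
                               score=float(scores[k]),
                               direction=direction))
    return fits


def _pair_candidates(parent: CellTrack, tracks: list[CellTrack],
                     params: DivisionParams):
    """Tracks starting right after the parent ends, within the vicinity."""
    start = parent.end_frame + 1
    cy, cx = parent.regions[-1].centroid
    out = []
    for tr in tracks:
        if tr.track_id == parent.track_id or tr.start_frame != start:
            continue
        ry, rx = tr.regions[0].centroid
        if np.hypot(ry - cy, rx - cx) <= params.vicinity_radius:
            out.append(tr)
    return out


def _select_daughters(parent: CellTrack, cands: list[CellTrack],
                      params: DivisionParams):
    mp = parent.regions[-1].mass
    lo, hi = params.daughter_mass_window
    clo, chi = params.combined_mass_window
    best, best_err = None, np.inf
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            m1 = cands[i].regions[0].mass
            m2 = cands[j].regions[0].mass
            if not (lo * mp <= m1 <= hi * mp and lo * mp <= m2 <= hi * mp):
                continue
            if not (clo * mp <= m1 + m2 <= chi * mp):
                continue
            err = abs(m1 + m2 - mp)
            if err < best_err:
                best, best_err = (cands[i], cands[j]), err
    return best


def _dm_series(d1: CellTrack, d2: CellTrack,
               t_furrow: float) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(set(d1.frames) & set(d2.frames))
    t, dm = [], []
    for f in common:
        r1 = d1.regions[d1.frames.index(f)]
        r2 = d2.regions[d2.frames.index(f)]
        t.append(r1.time - t_furrow)
        dm.append(2.0 * (r1.mass - r2.mass) / (r1.mass + r2.mass))
    return np.array(t), np.array(dm)


def _make_event(event_id: int, parent: CellTrack, da: CellTrack,
                db: CellTrack, adherent: bool) -> DivisionEvent:
    ma, mb = da.regions[0].mass, db.regions[0].mass
    d1, d2 = (da, db) if ma >= mb else (db, da)
    t_furrow = d1.regions[0].time
    times, dm = _dm_series(d1, d2, t_furrow)
    return DivisionEvent(
        event_id=event_id, parent_track=parent.track_id,
        d1_track=d1.track_id, d2_track=d2.track_id,
        t_furrow=t_furrow, m_parent=parent.regions[-1].mass,
        m_d1=max(ma, mb), m_d2=min(ma, mb),
        times=times, dm_signed=dm, adherent=adherent,
    )


def detect_divisions_nonadherent(tracks: list[CellTrack],
                                 params: DivisionParams | None = None,
                                 n_frames: int | None = None,
                                 ) -> list[DivisionEvent]:
    """Division = parent splitting into two ~50%-mass daughters (criterion 1)."""
    params = params or DivisionParams()
    events: list[DivisionEvent] = []
    last_frame = n_frames - 1 if n_frames is not None else \
        max((t.end_frame for t in tracks), default=0)
    for parent in tracks:
        if parent.end_frame >= last_frame:
            continue
        cands = _pair_candidates(parent, tracks, params)
        if len(cands) < 2:
            if cands:
                logger.info("track %d: criterion 1 failed (single successor)",
                            parent.track_id)
            continue
        pair = _select_daughters(parent, cands, params)
        if pair is None:
            logger.info("track %d: criterion 1 failed (daughter mass window)",
                        parent.track_id)
            continue
        events.append(_make_event(len(events), parent, *pair, adherent=False))
    return events


def detect_divisions_adherent(tracks: list[CellTrack],
                              params: DivisionParams | None = None,
                              n_frames: int | None = None,
                              ) -> list[DivisionEvent]:
    """Full three-criterion detection for adherent cells."""
    params = params or DivisionParams()
    events: list[DivisionEvent] = []
    last_frame = n_frames - 1 if n_frames is not None else \
        max((t.end_frame for t in tracks), default=0)
    for parent in tracks:
        if parent.end_frame >= last_frame:
            continue
        if parent.end_frame < params.boundary_frames or \
                parent.end_frame > last_frame - params.boundary_frames:
            logger.info("track %d: candidate too close to movie boundary",
                        parent.track_id)
            continue
        cands = _pair_candidates(parent, tracks, params)
        if len(cands) < 2:
            if cands:
                logger.info("track %d: criterion 1 failed (single successor)",
                            parent.track_id)
            continue
        pair = _select_daughters(parent, cands, params)
        if pair is None:
            logger.info("track %d: criterion 1 failed (daughter mass window)",
                        parent.track_id)
            continue

        rising = fit_sigmoid_trace(parent.times, parent.mean_phases,
                                   "rising", params)
        if not rising:
            logger.info("track %d: criterion 2 failed (no rising sigmoid)",
                        parent.track_id)
            continue
        falling = [fit_sigmoid_trace(d.times, d.mean_phases, "falling", params)
                   for d in pair]
        if not all(falling):
            logger.info("track %d: criterion 3 failed (daughter without "
                        "falling sigmoid)", parent.track_id)
            continue

        event = _make_event(len(events), parent, *pair, adherent=True)
        pre = [f.midpoint for f in rising if f.midpoint <= event.t_furrow]
        if not pre:
            logger.info("track %d: criterion 2 failed (rising fit after "
                        "furrow only)", parent.track_id)
            continue
        event.entry_mid = max(pre)
        # falling fits are per candidate in `pair`; reorder to (d1, d2)
        fits_by_track = {pair[0].track_id: falling[0],
                         pair[1].track_id: falling[1]}
        exits = []
        for tid in (event.d1_track, event.d2_track):
            post = [f.midpoint for f in fits_by_track[tid]
                    if f.midpoint >= event.t_furrow]
            exits.append(min(post) if post else None)
        event.exit_mid_d1, event.exit_mid_d2 = exits
        events.append(event)
    return events


def detect_divisions(tracks: list[CellTrack], adherent: bool,
                     params: DivisionParams | None = None,
                     n_frames: int | None = None) -> list[DivisionEvent]:
    if adherent:
        return detect_divisions_adherent(tracks, params, n_frames)
    return detect_divisions_nonadherent(tracks, params, n_frames)


def measure_division_times(event: DivisionEvent
                           ) -> tuple[float | None, float | None]:
    """(time in mitosis, time rounded post-division), both in min.

    Time in mitosis runs from the parent's mean-phase rise midpoint to the
    furrow; the post-division rounded time runs from the furrow to the first
    daughter's flattening midpoint.  Undefined (None) for non-adherent events
    or when the sigmoid fits are missing.
    """
    if not event.adherent or event.entry_mid is None:
        return None, None
    time_in_mitosis = event.t_furrow - event.entry_mid
    exits = [e for e in (event.exit_mid_d1, event.exit_mid_d2) if e is not None]
    time_rounded_post = (min(exits) - event.t_furrow) if exits else None
    return time_in_mitosis, time_rounded_post
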