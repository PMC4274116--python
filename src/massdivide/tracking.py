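"""Frame-to-frame linking of segmented cells into tracks.

Linking follows the colloid-tracking formulation: between consecutive frames
the one-to-one assignment minimizing total squared centroid displacement is
chosen, restricted to pairs closer than ``max_disp``.  Unmatched regions end
or start tracks; there is no gap closing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segment import CellRegion

logger = logging.getLogger(__name__)

MAX_DISP_DEFAULT = 20.0  # um/frame


@dataclass
class CellTrack:
    """Time-ordered sequence of one cell's per-frame measurements."""

    track_id: int
    regions: list[CellRegion] = field(default_factory=list)
    frames: list[int] = field(default_factory=list)
    parent: int | None = None

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.regions])

    @property
    def masses(self) -> np.ndarray:
        return np.array([r.mass for r in self.regions])

    @property
    def mean_phases(self) -> np.ndarray:
        return np.array([r.mean_phase for r in self.regions])

    def centroid_at_frame(self, frame: int) -> tuple[float, float]:
        return self.regions[self.frames.index(frame)].centroid


def link_frames(regions_a: list[CellRegion], regions_b: list[CellRegion],
                max_disp: float = MAX_DISP_DEFAULT) -> list[tuple[int, int]]:
    """Minimum-cost assignment between two frames' regions.

    Returns index pairs (i, j) into the two input lists.  Pairs farther
    apart than ``max_disp`` are never linked; equal-cost ties resolve toward
    lower label ids because inputs are processed in label order.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if not regions_a or not regions_b:
        return []
    a = np.array([r.centroid for r in regions_a])
    b = np.array([r.centroid for r in regions_b])
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    gate = max_disp**2

    # augment with per-region dummy nodes so non-assignment is always feasible
    n, m = d2.shape
    big = 2.0 * gate
    forbid = 1e9
    cost = np.zeros((n + m, n + m))           # dummy-dummy pairings are free
    cost[:n, :m] = np.where(d2 <= gate, d2, forbid)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), big, forbid)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), big, forbid)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)
             if i < n and j < m and d2[i, j] <= gate]
    return pairs


def build_tracks(frames_regions: list[list[CellRegion]],
                 max_disp: float = MAX_DISP_DEFAULT,
                 times: list[float] | None = None,
                 mass_break_ratio: float = 0.7) -> list[CellTrack]:
    """Link every frame's regions into tracks.

    ``frames_regions[k]`` holds the regions of frame k, in time order.
    Every region ends up in exactly one track; re-runs are deterministic.

    Positional links whose mass changes by more than ``mass_break_ratio``
    between frames are severed: when a cell divides, the watershed suddenly
    reports a ~50%-mass object where the parent was, and carrying the parent
    identity onto one daughter would hide the division.  Severed links
    terminate the old track and start a new one.
    """
    if times is None:
        times = [rs[0].time if rs else np.nan for rs in frames_regions]
    finite = [t for t in times if np.isfinite(t)]
    if any(t2 <= t1 for t1, t2 in zip(finite, finite[1:])):
        raise ValueError("frames must be strictly time-ordered")

    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}   # region index in previous frame -> track
    prev: list[CellRegion] = []
    for k, regions in enumerate(frames_regions):
        regions = sorted(regions, key=lambda r: r.label)
        pairs = link_frames(prev, regions, max_disp) if prev else []
        if mass_break_ratio:
            kept = []
            for i, j in pairs:
                ratio = regions[j].mass / prev[i].mass if prev[i].mass > 0 else 1.0
                if mass_break_ratio <= ratio <= 1.0 / mass_break_ratio:
                    kept.append((i, j))
                else:
                    logger.info("severed link at frame %d: mass ratio %.2f", k, ratio)
            pairs = kept
        linked_b = {j: i for i, j in pairs}
        new_active: dict[int, CellTrack] = {}
        for j, region in enumerate(regions):
            if j in linked_b and linked_b[j] in active:
                tr = active[linked_b[j]]
            else:
                tr = CellTrack(track_id=len(tracks))
                tracks.append(tr)
            tr.regions.append(region)
            tr.frames.append(k)
            new_active[j] = tr
        active = new_active
        prev = regions
    return tracks


def brute_force_link(regions_a: list[CellRegion], regions_b: list[CellRegion],
                     max_disp: float = MAX_DISP_DEFAULT) -> list[tuple[int, int]]:
    """Exhaustive minimum-cost matching (oracle; feasible for <= ~6 regions).

    Enumerates every one-to-one partial matching within the displacement
    gate; unmatched regions pay the gate cost, mirroring the production
    linker's dummy-node augmentation.
    """
    a = np.array([r.centroid for r in regions_a]).reshape(-1, 2)
    b = np.array([r.centroid for r in regions_b]).reshape(-1, 2)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    gate = max_disp**2
    big = 2.0 * gate

    best_cost, best_pairs = np.inf, []
    indices_b = list(range(m))
    for r in range(min(n, m) + 1):
        for subset_a in itertools.combinations(range(n), r):
            for perm_b in itertools.permutations(indices_b, r):
                if any(d2[i, j] > gate for i, j in zip(subset_a, perm_b)):
                    continue
                matched = sum(d2[i, j] for i, j in zip(subset_a, perm_b))
                cost = matched + big * (n - r) + big * (m - r)
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_pairs = sorted(zip(subset_a, perm_b))
    return [(int(i), int(j)) for i, j in best_pairs]
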