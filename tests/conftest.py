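"""Shared fixtures: synthetic movies, a trained unwrap model, region factories."""

from __future__ import annotations

import numpy as np
import pytest

import massdivide as md
from massdivide.segment import CellRegion, SegmentationConfig
from massdivide.unwrap import (compute_pixel_statistics, train_unwrap_model,
                               wrap_boundary_labels)


@pytest.fixture(scope="session")
def seg_cfg() -> SegmentationConfig:
    return SegmentationConfig()


def make_region(label: int, y: float, x: float, mass: float = 100.0,
                time: float = 0.0, mean_phase: float = 50.0) -> CellRegion:
    """Minimal CellRegion for tracking/division tests."""
    return CellRegion(label=label, mass=mass, area=100.0, perimeter=40.0,
                      centroid=(y, x), mean_phase=mean_phase,
                      shape_factor=0.9, time=time, n_pixels=100)


def rounded_cell_scenario(i: int, rng: np.random.Generator,
                          frame_um: float = 120.0) -> md.CellScenario:
    """A fully rounded (phase-wrapped) mitotic cell placed near the centre."""
    # mass/radius ranges keep the rounded peak OPD in (~610, ~910) nm:
    # always wrapped, never beyond the single-correction regime (< 2 lambda)
    return md.CellScenario(
        cell_id=f"c{i}",
        center=(frame_um / 2 + float(rng.integers(-8, 8)),
                frame_um / 2 + float(rng.integers(-8, 8))),
        initial_mass=300.0 + 20.0 * float(rng.integers(0, 5)),
        round_radius=5.2 + 0.1 * float(rng.integers(0, 5)),
        t_furrow=1e9, t_entry_mid=-60.0,
    )


def wrapped_frame(i: int, rng: np.random.Generator, noise_sd: float = 0.0):
    """One wrapped single-cell frame plus its true wrap mask and clean frame."""
    s = rounded_cell_scenario(i, rng)
    frames, _ = md.simulate_movie([s], n_frames=1, noise_sd=noise_sd,
                                  shape=(120, 120), seed=100 + i)
    wrapped, mask = md.apply_wrapping(frames[0])
    return frames[0], wrapped, mask


@pytest.fixture(scope="session")
def unwrap_model() -> md.UnwrapModel:
    """Model trained on 24 noiseless wrapped mitotic-cell frames."""
    rng = np.random.default_rng(0)
    stacks, labels = [], []
    for i in range(24):
        _, wrapped, mask = wrapped_frame(i, rng)
        stacks.append(compute_pixel_statistics(wrapped))
        labels.append(wrap_boundary_labels(mask))
    return train_unwrap_model(stacks, labels, seed=0)


def division_movie(seed: int, *, adherent: bool = True,
                   split_fraction: float = 0.5, noise_sd: float = 3.0,
                   t_furrow: float = 96.0, n_frames: int = 50,
                   shape=(96, 96), redistribution_rate: float = 0.0):
    """One-cell division movie with its ground truth."""
    s = md.CellScenario(cell_id="c", center=(shape[0] / 2, shape[1] / 2),
                        initial_mass=300.0, growth_rate=0.3,
                        adherent=adherent, split_fraction=split_fraction,
                        t_furrow=t_furrow,
                        redistribution_rate=redistribution_rate,
                        flat_radius=12.0 if adherent else 9.0)
    return md.simulate_movie([s], n_frames=n_frames, interval=3.0,
                             noise_sd=noise_sd, shape=shape, seed=seed)


def analyze_movie(frames, seg_cfg, adherent: bool):
    """segment -> track -> detect on an in-memory movie."""
    regions = [md.segment_and_measure(f, seg_cfg) for f in frames]
    tracks = md.build_tracks(regions, 20.0, [f.time for f in frames])
    events = md.detect_divisions(tracks, adherent=adherent,
                                 n_frames=len(frames))
    return regions, tracks, events
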