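"""Synthetic quantitative-phase movies of growing, rounding, dividing cells.

Generates time-lapse optical-path-difference (OPD) image stacks that emulate
live-cell interferometry of adherent and non-adherent cells, together with a
complete ground-truth ledger (true per-cell masses, wrap masks, event times,
daughter mass asymmetry).  Cells are rendered as super-Gaussian OPD profiles
whose discrete integral is normalized to the programmed dry mass, so mass is
conserved by construction.  Adherent cells flatten/round with a logistic
radius transition (mean phase shift rises sigmoidally before division and
decays after); dividing cells split into two touching lobes separated by an
OPD saddle, with an optional linear mass redistribution between the connected
daughters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: specific refractive increment, m^3/kg (whole-cell average)
ALPHA_DEFAULT = 1.8e-4

#: default illumination wavelength, nm
WAVELENGTH_DEFAULT = 530.0

#: default frame geometry: 240 x 320 um field at 1 um/px
FRAME_SHAPE_DEFAULT = (240, 320)
PIXEL_SIZE_DEFAULT = 1.0

#: super-Gaussian exponent is 2*PROFILE_ORDER; order 3 gives compact,
#: plateau-topped cells with steep skirts (sharp watershed saddles)
PROFILE_ORDER = 3

#: profile support radius in units of the nominal radius: where the
#: super-Gaussian drops below 1e-4 of its peak
_SUPPORT_FACTOR = float(np.log(1e4) ** (1.0 / (2 * PROFILE_ORDER)))


def mass_conversion_factor(alpha: float = ALPHA_DEFAULT) -> float:
    """pg of dry mass per (nm of OPD x um^2 of pixel area).

    mass [kg] = OPD volume [m^3] / alpha, with 1 nm*um^2 = 1e-21 m^3 and
    1 kg = 1e15 pg, giving 1e-6/alpha pg per nm*um^2.
    """
    return 1e-6 / alpha


def opd_volume_m3(opd_nm: np.ndarray, pixel_size_um: float) -> float:
    """Integrated OPD volume of a frame or patch, in m^3."""
    return float(np.sum(opd_nm)) * 1e-9 * (pixel_size_um * 1e-6) ** 2


def mass_from_opd(opd_nm: np.ndarray, pixel_size_um: float,
                  alpha: float = ALPHA_DEFAULT) -> float:
    """Dry mass (pg) of an OPD patch via the specific refractive increment."""
    return float(np.sum(opd_nm)) * pixel_size_um**2 * mass_conversion_factor(alpha)


@dataclass
class PhaseFrame:
    """One quantitative phase image: OPD in nm plus a companion intensity image.

    The intensity channel carries no mass information; it exists only as a
    feature for wrap detection.
    """

    opd: np.ndarray              # 2-D, nm
    intensity: np.ndarray        # 2-D, arbitrary units
    pixel_size: float            # um/px
    wavelength: float            # nm
    time: float                  # min

    def __post_init__(self):
        self.opd = np.asarray(self.opd, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.opd)):
            bad = np.argwhere(~np.isfinite(self.opd))
            raise ValueError(
                f"non-finite OPD pixels at t={self.time} min, "
                f"first at (row, col) = {tuple(bad[0])}"
            )


@dataclass
class CellScenario:
    """Programmed life history of one (possibly dividing) synthetic cell.

    Masses in pg, times in min, lengths in um.  ``t_furrow`` is the time of
    the deep cleavage furrow (the first two-lobe frame defines t = 0 for the
    daughters); set it to None for a non-dividing cell.  ``split_fraction``
    is daughter-1's share of the parent mass at the furrow.
    ``redistribution_rate`` is the fraction of the furrow-time parent mass
    transferred per minute from daughter 2 to daughter 1 (negative reverses
    direction) while the daughters remain connected
    (``redistribution_duration``).
    """

    cell_id: str = "cell0"
    center: tuple[float, float] = (120.0, 160.0)   # (row, col) um
    initial_mass: float = 300.0                    # pg at t = 0 of the movie
    growth_rate: float = 0.3                       # pg/min
    adherent: bool = True
    flat_radius: float = 12.0                      # um, spread interphase cell
    round_radius: float = 5.5                      # um, rounded mitotic cell
    steepness: float = 6.0                         # min, logistic tau of rounding
    t_entry_mid: float | None = None               # min, rounding midpoint
    t_furrow: float | None = None                  # min, cleavage furrow
    t_exit_mid: tuple[float, float] | None = None  # min, per-daughter flattening
    split_fraction: float = 0.5                    # f in (0, 1)
    redistribution_rate: float = 0.0               # /min (fraction of pair mass)
    redistribution_duration: float = 30.0          # min
    division_axis: float = 0.0                     # rad, daughter separation axis
    separation_factor: float = 2.2                 # lobe spacing / mean lobe radius

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie strictly in (0, 1)")
        if self.adherent and not (self.flat_radius > self.round_radius > 0):
            raise ValueError("need flat_radius > round_radius > 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.t_furrow is not None:
            if self.adherent and self.t_entry_mid is None:
                self.t_entry_mid = self.t_furrow - 30.0
            if self.adherent and self.t_exit_mid is None:
                self.t_exit_mid = (self.t_furrow + 24.0, self.t_furrow + 24.0)

    # ------------------------------------------------------------------
    # programmed (ground-truth) kinematics
    # ------------------------------------------------------------------

    def mass_at(self, time: float) -> float:
        """Total mass of the cell (or daughter pair) at ``time``."""
        return self.initial_mass + self.growth_rate * time

    def daughter_fractions(self, time: float) -> tuple[float, float]:
        """Mass fractions (f1, f2) of the daughter pair at ``time`` >= t_furrow."""
        if self.t_furrow is None or time < self.t_furrow:
            raise ValueError("daughter fractions undefined before the furrow")
        dt = min(time - self.t_furrow, self.redistribution_duration)
        f1 = self.split_fraction + self.redistribution_rate * dt
        f1 = min(max(f1, 0.005), 0.995)
        return f1, 1.0 - f1

    def daughter_masses(self, time: float) -> tuple[float, float]:
        f1, f2 = self.daughter_fractions(time)
        total = self.mass_at(time)
        return f1 * total, f2 * total

    def true_delta_m(self, time: float, signed: bool = True) -> float:
        """Programmed daughter mass asymmetry 2(m1 - m2)/(m1 + m2)."""
        f1, f2 = self.daughter_fractions(time)
        dm = 2.0 * (f1 - f2)
        return dm if signed else abs(dm)

    def _radius_single(self, time: float) -> float:
        if not self.adherent:
            return self.flat_radius
        if self.t_entry_mid is None:
            return self.flat_radius
        s = _logistic((time - self.t_entry_mid) / self.steepness)
        return self.flat_radius + (self.round_radius - self.flat_radius) * s

    def _daughter_radius(self, which: int, time: float) -> float:
        f = self.daughter_fractions(time)[which]
        if not self.adherent:
            return self.flat_radius * np.sqrt(f)
        r_round = self.round_radius * np.sqrt(max(f, 0.02))
        r_flat = self.flat_radius * np.sqrt(max(f, 0.02))
        if self.t_exit_mid is None:
            return r_round
        s = _logistic((time - self.t_exit_mid[which]) / self.steepness)
        return r_round + (r_flat - r_round) * s

    def _daughter_centers(self, time: float) -> list[tuple[float, float]]:
        r1 = self._daughter_radius(0, time)
        r2 = self._daughter_radius(1, time)
        sep = self.separation_factor * 0.5 * (r1 + r2)
        dy = 0.5 * sep * np.sin(self.division_axis)
        dx = 0.5 * sep * np.cos(self.division_axis)
        cy, cx = self.center
        return [(cy + dy, cx + dx), (cy - dy, cx - dx)]

    def footprint_radius(self, times: np.ndarray) -> float:
        """Maximum extent (um) from ``center`` over the given times."""
        ext = 0.0
        for t in np.atleast_1d(times):
            for c, r in self.blobs_at(float(t)):
                d = np.hypot(c[0] - self.center[0], c[1] - self.center[1])
                ext = max(ext, d + _SUPPORT_FACTOR * r)
        return ext

    def blobs_at(self, time: float) -> list[tuple[tuple[float, float], float]]:
        """(center, radius) of each rendered lobe at ``time``."""
        if self.t_furrow is None or time < self.t_furrow:
            return [(self.center, self._radius_single(time))]
        centers = self._daughter_centers(time)
        return [(centers[0], self._daughter_radius(0, time)),
                (centers[1], self._daughter_radius(1, time))]

    def blob_masses_at(self, time: float) -> list[float]:
        if self.t_furrow is None or time < self.t_furrow:
            return [self.mass_at(time)]
        return list(self.daughter_masses(time))


def _logistic(x) -> float:
    return float(1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))))


def _super_gaussian(shape: tuple[int, int], pixel_size: float,
                    center_um: tuple[float, float], radius_um: float) -> np.ndarray:
    h, w = shape
    yy = (np.arange(h) + 0.5) * pixel_size
    xx = (np.arange(w) + 0.5) * pixel_size
    r2 = ((yy[:, None] - center_um[0]) ** 2 + (xx[None, :] - center_um[1]) ** 2)
    z = (r2 / radius_um**2) ** PROFILE_ORDER
    return np.exp(-np.clip(z, 0, 700))


def render_blob(shape: tuple[int, int], pixel_size: float,
                center_um: tuple[float, float], radius_um: float,
                mass_pg: float, alpha: float = ALPHA_DEFAULT, *,
                cell_id: str = "?", time: float | None = None) -> np.ndarray:
    """Render one super-Gaussian lobe as an additive OPD patch (nm).

    The peak is chosen so the *discrete* integral recovers ``mass_pg``
    exactly, hence mass is conserved to machine precision regardless of
    pixelation.  Raises if the lobe's support leaves the frame.
    """
    if mass_pg < 0:
        raise ValueError("mass must be non-negative")
    if mass_pg == 0:
        return np.zeros(shape)
    h, w = shape
    ext = _SUPPORT_FACTOR * radius_um
    cy, cx = center_um
    if (cy - ext < 0 or cx - ext < 0
            or cy + ext > h * pixel_size or cx + ext > w * pixel_size):
        when = "" if time is None else f" at t={time} min"
        raise ValueError(
            f"cell {cell_id!r}{when}: footprint (radius {ext:.1f} um around "
            f"({cy:.1f}, {cx:.1f})) exceeds the {h * pixel_size:.0f} x "
            f"{w * pixel_size:.0f} um frame"
        )
    prof = _super_gaussian(shape, pixel_size, center_um, radius_um)
    volume_nm_um2 = mass_pg / mass_conversion_factor(alpha)
    peak = volume_nm_um2 / (prof.sum() * pixel_size**2)
    return peak * prof


def render_cell(scenario: CellScenario, time: float, shape: tuple[int, int],
                pixel_size: float = PIXEL_SIZE_DEFAULT,
                alpha: float = ALPHA_DEFAULT) -> np.ndarray:
    """Additive OPD patch (nm) for one scenario at one time point."""
    opd = np.zeros(shape)
    for (center, radius), mass in zip(scenario.blobs_at(time),
                                      scenario.blob_masses_at(time)):
        opd += render_blob(shape, pixel_size, center, radius, mass, alpha,
                           cell_id=scenario.cell_id, time=time)
    return opd


@dataclass
class GroundTruth:
    """Generator ledger: everything the analysis is later asked to recover."""

    times: np.ndarray                                # min, one per frame
    masses: dict[str, np.ndarray]                    # cell/daughter id -> pg (NaN absent)
    wrap_masks: list[np.ndarray]                     # per-frame bool, true OPD >= lambda
    events: dict[str, dict]                          # scenario id -> event times/params
    delta_m: dict[str, np.ndarray]                   # scenario id -> signed dm(t), NaN pre-furrow
    total_mass: np.ndarray = field(default=None)     # pg per frame

    def __post_init__(self):
        if self.total_mass is None:
            stacked = np.vstack([np.nan_to_num(m) for m in self.masses.values()])
            self.total_mass = stacked.sum(axis=0)


def _check_overlap(scenarios: list[CellScenario], times: np.ndarray) -> None:
    ext = [s.footprint_radius(times) for s in scenarios]
    colliding = []
    for i in range(len(scenarios)):
        for j in range(i + 1, len(scenarios)):
            d = np.hypot(scenarios[i].center[0] - scenarios[j].center[0],
                         scenarios[i].center[1] - scenarios[j].center[1])
            if d < ext[i] + ext[j]:
                colliding.append((scenarios[i].cell_id, scenarios[j].cell_id))
    if colliding:
        raise ValueError(f"overlapping cell placements: {colliding}")


def simulate_movie(scenarios: list[CellScenario], n_frames: int,
                   interval: float = 3.0, noise_sd: float = 3.0,
                   seed: int | None = 0,
                   shape: tuple[int, int] = FRAME_SHAPE_DEFAULT,
                   pixel_size: float = PIXEL_SIZE_DEFAULT,
                   wavelength: float = WAVELENGTH_DEFAULT,
                   alpha: float = ALPHA_DEFAULT,
                   intensity_offset: float = 100.0,
                   ) -> tuple[list[PhaseFrame], GroundTruth]:
    """Simulate a seeded phase movie plus its ground-truth ledger.

    Frames contain the *true* (unwrapped) OPD plus additive Gaussian noise;
    use :func:`apply_wrapping` to produce wrapped inputs for the unwrapping
    stage.  Identical arguments and seed give bit-identical movies.
    """
    times = np.arange(n_frames) * interval
    _check_overlap(scenarios, times)
    rng = np.random.default_rng(seed)

    masses: dict[str, np.ndarray] = {}
    delta_m: dict[str, np.ndarray] = {}
    events: dict[str, dict] = {}
    for s in scenarios:
        if s.t_furrow is None:
            masses[s.cell_id] = np.array([s.mass_at(t) for t in times])
        else:
            parent = np.full(n_frames, np.nan)
            d1 = np.full(n_frames, np.nan)
            d2 = np.full(n_frames, np.nan)
            dm = np.full(n_frames, np.nan)
            for k, t in enumerate(times):
                if t < s.t_furrow:
                    parent[k] = s.mass_at(t)
                else:
                    d1[k], d2[k] = s.daughter_masses(t)
                    dm[k] = s.true_delta_m(t)
            masses[s.cell_id] = parent
            masses[s.cell_id + ".d1"] = d1
            masses[s.cell_id + ".d2"] = d2
            delta_m[s.cell_id] = dm
        post = times[times >= (s.t_furrow if s.t_furrow is not None else np.inf)]
        events[s.cell_id] = {
            "t_entry_mid": s.t_entry_mid,
            "t_furrow": s.t_furrow,
            "t_furrow_frame": float(post[0]) if post.size else None,
            "t_exit_mid": list(s.t_exit_mid) if s.t_exit_mid else None,
            "split_fraction": s.split_fraction,
            "redistribution_rate": s.redistribution_rate,
            "adherent": s.adherent,
        }

    frames: list[PhaseFrame] = []
    wrap_masks: list[np.ndarray] = []
    for t in times:
        opd = np.zeros(shape)
        for s in scenarios:
            opd += render_cell(s, float(t), shape, pixel_size, alpha)
        wrap_masks.append(opd >= wavelength)
        gy, gx = np.gradient(opd)
        grad = np.hypot(gy, gx)
        intensity = intensity_offset - grad
        if noise_sd > 0:
            opd = opd + rng.normal(0.0, noise_sd, shape)
            intensity = intensity + rng.normal(0.0, noise_sd, shape)
        frames.append(PhaseFrame(opd=opd, intensity=intensity,
                                 pixel_size=pixel_size, wavelength=wavelength,
                                 time=float(t)))

    truth = GroundTruth(times=times, masses=masses, wrap_masks=wrap_masks,
                        events=events, delta_m=delta_m)
    return frames, truth


def apply_wrapping(frame: PhaseFrame) -> tuple[PhaseFrame, np.ndarray]:
    """Wrap OPD modulo one wavelength, as an interferometer would report it.

    Subtracts exactly one wavelength wherever OPD >= lambda (the "single,
    positive correction" regime) and returns the wrapped frame together with
    the wrap mask.  OPD reaching two wavelengths is outside that regime and
    raises.
    """
    lam = frame.wavelength
    if np.any(frame.opd >= 2 * lam):
        raise ValueError(
            f"true OPD exceeds two wavelengths at t={frame.time} min; "
            "single-correction wrapping model does not apply"
        )
    mask = frame.opd >= lam
    wrapped = np.where(mask, frame.opd - lam, frame.opd)
    return replace(frame, opd=wrapped), mask
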