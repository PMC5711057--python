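"""Parametric photon source and meterset-synchronized delivery state.

The source replaces a stored linac phase space with a parametric model: an
energy-bin spectrum plus a radial lateral-fluence profile sampled on a
phase plane below the jaws (default 55 cm from the target).  Photons are
focused at the source point, so a sampled position fully determines the
direction.

Dynamic (VMAT / dynamic-MLC) deliveries are driven by the cumulative
meterset fraction u in [0, 1]: each history draws u uniformly and the
machine state (gantry angle, jaws, every leaf) is interpolated linearly in
meterset between the bracketing control points, which delivers fluence per
control-point interval proportional to its meterset width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ApertureState

_DATA = Path(__file__).parent / "data"


class SourceConfigError(ValueError):
    pass


@dataclass
class Spectrum:
    """Histogram energy spectrum: bin edges (MeV) and per-bin weights."""

    e_min: np.ndarray
    e_max: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.e_min = np.asarray(self.e_min, dtype=float)
        self.e_max = np.asarray(self.e_max, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if len(w) == 0:
            raise SourceConfigError("empty spectrum")
        if np.any(w < 0) or w.sum() <= 0:
            raise SourceConfigError("spectrum weights must be >= 0, sum > 0")
        self.weight = w / w.sum()

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.weight * 0.5 * (self.e_min + self.e_max)))

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        rows = np.loadtxt(path, delimiter=",", comments="#")
        return cls(rows[:, 0], rows[:, 1], rows[:, 2])


def sample_energy(spectrum: Spectrum, rng, size=None):
    """Inverse-CDF sampling over bins, uniform within each bin (MeV)."""
    n = 1 if size is None else size
    bins = rng.choice(len(spectrum.weight), size=n, p=spectrum.weight)
    e = spectrum.e_min[bins] + rng.random(n) * (
        spectrum.e_max[bins] - spectrum.e_min[bins])
    return float(e[0]) if size is None else e


def _flat_profile(r):
    """Flattened-beam radial fluence: flat with mild off-axis horns."""
    r = np.asarray(r, dtype=float)
    return 1.0 + 0.04 * np.clip(r / 10.0, 0.0, 2.0) ** 2


def _fff_profile(r):
    """Flattening-filter-free: forward-peaked (cone-like falloff)."""
    r = np.asarray(r, dtype=float)
    return 0.25 + 0.75 * np.exp(-0.5 * (r / 7.5) ** 2)


@dataclass
class SourceModel:
    """Energy spectrum + lateral fluence profile at the phase plane."""

    spectrum: Spectrum
    lateral_profile: callable = _flat_profile
    phase_plane_z: float = 55.0   # cm from source
    sad: float = 100.0
    name: str = "custom"

    @classmethod
    def preset(cls, beam: str = "6X") -> "SourceModel":
        key = beam.replace(" ", "").upper()
        if key == "6X":
            return cls(Spectrum.from_csv(_DATA / "spectrum_6x.csv"),
                       _flat_profile, name="6X")
        if key in ("6XFFF", "6FFF"):
            return cls(Spectrum.from_csv(_DATA / "spectrum_6xfff.csv"),
                       _fff_profile, name="6X FFF")
        raise SourceConfigError(f"unknown beam preset {beam!r}")


def sample_source_photon(source_model: SourceModel, field_rect, rng,
                         size=None):
    """Sample photon(s) on the phase plane inside the projected field.

    ``field_rect`` = (x1, x2, y1, y2) at the isocenter plane (cm); returns
    dict of arrays: energy (MeV), position (n,3) at the phase plane
    (isocenter coordinates, gantry 0), direction (n,3, unit, through the
    focal point), weight (lateral-profile importance).
    """
    x1, x2, y1, y2 = field_rect
    if not (x2 > x1 and y2 > y1):
        raise SourceConfigError("degenerate (zero-area) field rectangle")
    n = 1 if size is None else size
    xi = x1 + rng.random(n) * (x2 - x1)
    yi = y1 + rng.random(n) * (y2 - y1)
    e = sample_energy(source_model.spectrum, rng, size=n)

    sad = source_model.sad
    zp = sad - source_model.phase_plane_z     # isocenter coords
    s = source_model.phase_plane_z / sad      # projection factor
    pos = np.stack([xi * s, yi * s, np.full(n, zp)], axis=1)
    d = np.stack([xi, yi, np.full(n, -sad)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = np.hypot(pos[:, 0], pos[:, 1])
    w = np.asarray(source_model.lateral_profile(r), dtype=float)
    if np.any(w <= 0):
        raise SourceConfigError("lateral profile must be positive in field")
    return {"energy": np.atleast_1d(e), "position": pos, "direction": d,
            "weight": w}


# -- delivery plans ------------------------------------------------------

@dataclass
class ControlPoint:
    cumulative_meterset: float
    gantry_angle_deg: float
    aperture: ApertureState


@dataclass
class Plan:
    """Time-ordered machine states indexed by cumulative meterset."""

    control_points: list
    total_MU: float
    beam: str = "6X"
    name: str = "plan"

    def __post_init__(self):
        cps = self.control_points
        if len(cps) < 2:
            raise ValueError("a plan needs at least 2 control points")
        if self.total_MU <= 0:
            raise ValueError("total_MU must be positive")
        ms = np.array([cp.cumulative_meterset for cp in cps])
        if abs(ms[0]) > 1e-9 or abs(ms[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative meterset must start at 0, end at 1")
        if np.any(np.diff(ms) < 0):
            raise ValueError("cumulative meterset must be non-decreasing")

    def _arrays(self):
        """Stack control-point state into arrays (cached)."""
        if not hasattr(self, "_cache"):
            cps = self.control_points
            ms = np.array([cp.cumulative_meterset for cp in cps])
            gantry = np.unwrap(np.deg2rad(
                [cp.gantry_angle_deg for cp in cps]))
            bank_a = np.stack([cp.aperture.bank_A_positions for cp in cps])
            bank_b = np.stack([cp.aperture.bank_B_positions for cp in cps])
            jaws = np.array([[cp.aperture.jaw_x1, cp.aperture.jaw_x2,
                              cp.aperture.jaw_y1, cp.aperture.jaw_y2]
                             for cp in cps])
            self._cache = (ms, np.rad2deg(gantry), bank_a, bank_b, jaws)
        return self._cache


def interpolate_plan_state(plan: Plan, u):
    """Vectorized machine state at meterset fraction(s) u.

    Returns (gantry_deg (n,), bank_a (n, n_leaves), bank_b, jaws (n, 4)).
    Exact at control points; linear in meterset between them.  Gantry
    angles are unwrapped before interpolation so full arcs have no 360
    degree seam.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any((u < 0) | (u > 1)):
        raise ValueError("meterset fraction u must lie in [0, 1]")
    ms, gantry, bank_a, bank_b, jaws = plan._arrays()
    k = np.clip(np.searchsorted(ms, u, side="right") - 1, 0, len(ms) - 2)
    span = ms[k + 1] - ms[k]
    w = np.where(span > 0, (u - ms[k]) / np.where(span > 0, span, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)

    def lerp(arr):
        a0, a1 = arr[k], arr[k + 1]
        return a0 + (a1 - a0) * w[(...,) + (None,) * (arr.ndim - 1)]

    return lerp(gantry), lerp(bank_a), lerp(bank_b), lerp(jaws)


def sample_control_point_state(plan: Plan, u: float):
    """(gantry_angle_deg, ApertureState) at a single meterset fraction."""
    g, ba, bb, jw = interpolate_plan_state(plan, u)
    ap = ApertureState(ba[0], bb[0], jaw_x1=jw[0, 0], jaw_x2=jw[0, 1],
                       jaw_y1=jw[0, 2], jaw_y2=jw[0, 3])
    return float(g[0]), ap
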