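"""MLC geometry: config parsing, thickness profiles, tips, path integrals.

Coordinate conventions (right-handed, lengths in cm):

* origin at isocenter, source on the +z axis at ``sad`` (100 cm), beam along
  -z at gantry 0;
* leaf motion along x: bank A occupies ``x <= tip_A``, bank B occupies
  ``x >= tip_B``, so the open slit of a pair is ``(tip_A, tip_B)``;
* leaves stack along y; leaf positions are stored projected to the
  isocenter plane and divergence-projected internally.

The cross-leaf thickness of each bank half (upper / lower) is a
piecewise-constant table in *physical* MLC-plane coordinates: a row
``leaf_number  y_breakpoint  thickness`` opens a segment that extends to
the next row's breakpoint.  Tungsten in the upper half abuts the
half-interface plane and grows upward; lower-half tungsten grows downward,
so tongue-and-groove steps are cut from the outer leaf surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_DATA = Path(__file__).parent / "data"


class MLCConfigError(ValueError):
    """Malformed or inconsistent MLC configuration input."""


@dataclass
class Ray:
    """A straight line: ``origin + t * direction`` (direction normalized)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-12:
            if n == 0:
                raise ValueError("ray direction must be nonzero")
            self.direction = self.direction / n


@dataclass
class HalfProfile:
    """Piecewise-constant thickness vs cross-leaf position for one half.

    Segment k spans [y[k], y[k+1]) with thickness th[k] owned by leaf
    owner[k]; the final row is a sentinel closing the last segment.
    """

    y: np.ndarray          # breakpoints, strictly increasing
    thickness: np.ndarray  # cm of tungsten, same length (last is sentinel)
    owner: np.ndarray      # 0-based leaf index per segment

    def lookup(self, y_mlc):
        """Exact (thickness, owner) at physical y; 0/-1 outside the stack."""
        y_arr = np.asarray(y_mlc, dtype=float)
        k = np.searchsorted(self.y, y_arr, side="right") - 1
        inside = (k >= 0) & (k < len(self.y) - 1)
        kk = np.clip(k, 0, len(self.y) - 2)
        th = np.where(inside, self.thickness[kk], 0.0)
        ow = np.where(inside, self.owner[kk], -1)
        return th, ow


@dataclass
class MLCGeometry:
    """Full physical description of a two-bank MLC."""

    model_name: str
    leaf_widths_iso: np.ndarray      # per-leaf projected widths at 100 cm
    upper_profile: HalfProfile
    lower_profile: HalfProfile
    physical_thickness: float        # total leaf height, cm
    tip_radius: float                # leaf-end radius of curvature, cm
    tip_angle: float = 0.0           # deg; 0 = pure arc (HD120)
    tip_max_thickness: float | None = None
    density: float = 18.9            # g/cm^3
    leaf_offset: float = 0.0         # physical closed-pair tip gap, cm
    z_upper: float = 50.9            # upper MLC surface from source, cm
    sad: float = 100.0

    def __post_init__(self):
        self.leaf_widths_iso = np.asarray(self.leaf_widths_iso, dtype=float)
        if self.tip_max_thickness is None:
            self.tip_max_thickness = self.physical_thickness
        if self.density <= 0 or self.tip_radius <= 0:
            raise MLCConfigError("density and tip radius must be positive")
        nu = int(self.upper_profile.owner.max()) + 1
        nl = int(self.lower_profile.owner.max()) + 1
        if nu != nl:
            raise MLCConfigError(
                f"leaf count mismatch between halves: {nu} vs {nl}")
        if nu != self.n_leaves:
            raise MLCConfigError(
                f"table leaf count {nu} != leaf_widths length {self.n_leaves}")

    # -- derived geometry -------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_widths_iso)

    @property
    def z_top(self) -> float:
        """Upper MLC surface, isocenter coordinates."""
        return self.sad - self.z_upper

    @property
    def z_interface(self) -> float:
        """Plane separating upper and lower halves (= leaf mid-height)."""
        return self.z_top - 0.5 * self.physical_thickness

    @property
    def proj_scale(self) -> float:
        """Isocenter -> MLC mid-plane projection factor."""
        return (self.sad - self.z_interface) / self.sad

    def leaf_boundaries_iso(self) -> np.ndarray:
        half = 0.5 * self.leaf_widths_iso.sum()
        return np.concatenate([[-half], -half + np.cumsum(self.leaf_widths_iso)])

    # -- tip shape --------------------------------------------------------
    def tip_penetration(self, h):
        """Tip surface recession p(h) at height h from leaf mid-height.

        Circular arc of radius R tangent to the nominal tip at mid-height;
        for Millennium-style tips a planar facet continues tangentially at
        ``tip_angle`` beyond the arc contact point.
        """
        h = np.abs(np.asarray(h, dtype=float))
        r = self.tip_radius
        ha = np.minimum(h, r)
        p = r - np.sqrt(np.maximum(r * r - ha * ha, 0.0))
        if self.tip_angle > 0.0:
            a = np.deg2rad(self.tip_angle)
            hf = r * np.sin(a)
            p = np.where(h > hf,
                         r * (1.0 - np.cos(a)) + (h - hf) * np.tan(a), p)
        return p

    def tip_half_height(self, d):
        """Inverse of ``tip_penetration``: tungsten half-height at depth d
        behind the nominal tip (capped at the leaf half-height and at half
        the maximum tip thickness)."""
        d = np.maximum(np.asarray(d, dtype=float), 0.0)
        r = self.tip_radius
        h = np.sqrt(np.maximum(2.0 * r * d - d * d, 0.0))  # arc branch
        if self.tip_angle > 0.0:
            a = np.deg2rad(self.tip_angle)
            df = r * (1.0 - np.cos(a))
            h = np.where(d > df, r * np.sin(a) + (d - df) / np.tan(a), h)
        cap = min(0.5 * self.physical_thickness, 0.5 * self.tip_max_thickness)
        return np.minimum(h, cap)


# -- packaged presets and config loading ---------------------------------

def _parse_table(path) -> HalfProfile:
    leaf, ybr, th = [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MLCConfigError(
                    f"{path}:{ln}: expected 'leaf y thickness', got {raw!r}")
            try:
                leaf.append(int(parts[0]))
                ybr.append(float(parts[1]))
                th.append(float(parts[2]))
            except ValueError as exc:
                raise MLCConfigError(f"{path}:{ln}: {exc}") from None
    if len(ybr) < 2:
        raise MLCConfigError(f"{path}: needs at least two rows")
    y = np.asarray(ybr)
    if np.any(np.diff(y) <= 0):
        bad = int(np.nonzero(np.diff(y) <= 0)[0][0])
        raise MLCConfigError(
            f"{path}: breakpoints not strictly increasing near row {bad + 1}")
    return HalfProfile(y=y, thickness=np.asarray(th),
                       owner=np.asarray(leaf, dtype=int) - 1)


def _parse_widths(spec: str) -> np.ndarray:
    out = []
    for tok in spec.split(","):
        tok = tok.strip()
        if "*" in tok:
            n, w = tok.split("*")
            out.extend([float(w)] * int(n))
        elif tok:
            out.append(float(tok))
    return np.asarray(out)


def _parse_config(path) -> dict:
    cfg = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise MLCConfigError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg[key] = val
    return cfg


def load_mlc_config(upper_table_path, lower_table_path, config_path
                    ) -> MLCGeometry:
    """Build an :class:`MLCGeometry` from the three config files."""
    upper = _parse_table(upper_table_path)
    lower = _parse_table(lower_table_path)
    cfg = _parse_config(config_path)
    try:
        widths = _parse_widths(cfg["leaf_widths_iso"])
        geo = MLCGeometry(
            model_name=cfg.get("model_name", "custom"),
            leaf_widths_iso=widths,
            upper_profile=upper, lower_profile=lower,
            physical_thickness=float(cfg["physical_thickness"]),
            tip_radius=float(cfg["tip_radius"]),
            tip_angle=float(cfg.get("tip_angle", 0.0)),
            tip_max_thickness=(float(cfg["tip_max_thickness"])
                               if "tip_max_thickness" in cfg else None),
            density=float(cfg.get("density", 18.9)),
            leaf_offset=float(cfg.get("leaf_offset", 0.0)),
            z_upper=float(cfg.get("z_upper", 50.9)),
        )
    except KeyError as exc:
        raise MLCConfigError(f"{config_path}: missing key {exc}") from None
    return geo


def hd120() -> MLCGeometry:
    """Packaged Varian HD120 model (synthesized thickness tables)."""
    return load_mlc_config(_DATA / "hd120_upperhalf.table",
                           _DATA / "hd120_lowerhalf.table",
                           _DATA / "hd120_particledmlc.config")


def millennium120() -> MLCGeometry:
    """Packaged Varian Millennium 120 model (synthesized tables)."""
    return load_mlc_config(_DATA / "millennium120_upperhalf.table",
                           _DATA / "millennium120_lowerhalf.table",
                           _DATA / "millennium120_particledmlc.config")


# -- aperture ------------------------------------------------------------

@dataclass
class ApertureState:
    """Per-leaf tip positions (isocenter plane, cm) plus jaw settings."""

    bank_A_positions: np.ndarray
    bank_B_positions: np.ndarray
    jaw_x1: float = -20.0
    jaw_x2: float = 20.0
    jaw_y1: float = -20.0
    jaw_y2: float = 20.0

    def __post_init__(self):
        self.bank_A_positions = np.asarray(self.bank_A_positions, dtype=float)
        self.bank_B_positions = np.asarray(self.bank_B_positions, dtype=float)
        if self.bank_A_positions.shape != self.bank_B_positions.shape:
            raise ValueError("bank position arrays must match in length")

    def validate(self, geometry: MLCGeometry):
        if len(self.bank_A_positions) != geometry.n_leaves:
            raise ValueError(
                f"{len(self.bank_A_positions)} leaf positions for a "
                f"{geometry.n_leaves}-leaf geometry")
        tol = geometry.leaf_offset / geometry.proj_scale + 1e-9
        if np.any(self.bank_A_positions > self.bank_B_positions + tol):
            raise ValueError("bank A tip beyond bank B tip (overlapping pair)")
        return self

    @property
    def field_rect(self):
        """Jaw-defined (x1, x2, y1, y2) at isocenter."""
        return (self.jaw_x1, self.jaw_x2, self.jaw_y1, self.jaw_y2)


def open_aperture(geometry: MLCGeometry, retract_cm: float = 20.0,
                  **jaws) -> ApertureState:
    n = geometry.n_leaves
    return ApertureState(np.full(n, -retract_cm), np.full(n, retract_cm),
                         **jaws)


# -- geometry queries ----------------------------------------------------

def projected_field_length(geometry: MLCGeometry) -> float:
    """Total MLC-defined field length perpendicular to leaf motion (cm,
    projected to the isocenter plane)."""
    return float(geometry.leaf_widths_iso.sum())


def leaf_index_at(geometry: MLCGeometry, y_iso: float):
    """(leaf index, offset within leaf) at isocenter-plane y.

    Boundaries are half-open: a boundary coordinate belongs to the
    higher-index leaf; the top edge of the stack is therefore out of range.
    """
    b = geometry.leaf_boundaries_iso()
    if y_iso < b[0] or y_iso >= b[-1]:
        raise ValueError(f"y={y_iso} outside leaf stack [{b[0]}, {b[-1]})")
    idx = int(np.searchsorted(b, y_iso, side="right") - 1)
    return idx, float(y_iso - b[idx])


def thickness_profile(geometry: MLCGeometry, y_mlc: float):
    """(upper, lower) tungsten thickness at physical MLC-plane y."""
    lo = min(geometry.upper_profile.y[0], geometry.lower_profile.y[0])
    hi = max(geometry.upper_profile.y[-1], geometry.lower_profile.y[-1])
    if not (lo <= y_mlc <= hi):
        raise ValueError(f"y={y_mlc} outside the physical leaf stack")
    up, _ = geometry.upper_profile.lookup(y_mlc)
    low, _ = geometry.lower_profile.lookup(y_mlc)
    return float(up), float(low)


def tip_thickness(geometry: MLCGeometry, x_ray_mlc, leaf_position_mlc):
    """Vertical tungsten chord (cm) through a rounded leaf tip.

    ``x_ray_mlc`` and ``leaf_position_mlc`` are physical MLC-plane
    coordinates for a bank-A-style leaf (body extends toward -x); the
    chord is 0 on the open side of the tip and saturates at the full leaf
    height behind it.
    """
    d = leaf_position_mlc - np.asarray(x_ray_mlc, dtype=float)
    return 2.0 * geometry.tip_half_height(np.maximum(d, 0.0)) * (d > 0)


def _bank_tips_physical(geometry, aperture, owner, photon_idx=None):
    """Projected physical tip x for the owner leaf of each query.

    ``aperture`` banks may be (n_leaves,) for a static state or
    (n_queries, n_leaves) for per-photon dynamic states.
    """
    scale = geometry.proj_scale
    a = np.asarray(aperture.bank_A_positions, dtype=float)
    b = np.asarray(aperture.bank_B_positions, dtype=float)
    ow = np.clip(owner, 0, geometry.n_leaves - 1)
    if a.ndim == 1:
        xa = a[ow]
        xb = b[ow]
    else:
        xa = a[photon_idx, ow]
        xb = b[photon_idx, ow]
    half_off = 0.5 * geometry.leaf_offset
    return xa * scale - half_off, xb * scale + half_off


def radiological_path(geometry: MLCGeometry, aperture: ApertureState, ray,
                      step_cm: float = 0.05) -> float | np.ndarray:
    """Areal density (g/cm^2) of tungsten along ``ray`` through the MLC.

    Integrates leaf presence over midpoint slabs of height ``step_cm``
    through both halves, including tongue-and-groove steps, interleaf gaps,
    and rounded (HD120) or faceted (Millennium) tips; divergence is exact
    because the ray is evaluated continuously in each slab.

    ``ray`` may be a :class:`Ray` or a tuple of stacked arrays
    ``(origins (n,3), directions (n,3))`` for vectorized evaluation.
    """
    if isinstance(ray, Ray):
        origins = ray.origin[None, :]
        dirs = ray.direction[None, :]
        scalar = True
    else:
        origins, dirs = ray
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        scalar = False
    if np.any(np.abs(dirs[:, 2]) < 1e-9):
        raise ValueError("ray parallel to the MLC plane")

    chord = _chord_length(geometry, aperture, origins, dirs, step_cm)
    areal = geometry.density * chord
    return float(areal[0]) if scalar else areal


def _chord_length(geometry, aperture, origins, dirs, step_cm,
                  photon_idx=None):
    """Total tungsten chord length (cm) per ray; vectorized over rays."""
    z_top = geometry.z_top
    z_if = geometry.z_interface
    z_bot = z_top - geometry.physical_thickness
    half_h = 0.5 * geometry.physical_thickness
    n_sub = max(1, int(np.ceil(half_h / step_cm)))
    dz = half_h / n_sub

    n = origins.shape[0]
    total = np.zeros(n)
    inv_dz_dir = 1.0 / dirs[:, 2]
    # segment length through one slab along each ray
    seg = dz * np.sqrt(1.0 + (dirs[:, 0] ** 2 + dirs[:, 1] ** 2)
                       * inv_dz_dir ** 2)
    cap_h = min(half_h, 0.5 * geometry.tip_max_thickness)
    fan_scale = geometry.sad - geometry.z_interface

    for half, prof in (("upper", geometry.upper_profile),
                       ("lower", geometry.lower_profile)):
        z_hi = z_top if half == "upper" else z_if
        for k in range(n_sub):
            z_mid = z_hi - (k + 0.5) * dz
            t = (z_mid - origins[:, 2]) * inv_dz_dir
            x = origins[:, 0] + t * dirs[:, 0]
            y = origins[:, 1] + t * dirs[:, 1]
            # leaf sides are focused to the source (trapezoidal leaf
            # cross-sections), so cross-leaf lookups happen in the fan
            # coordinate projected onto the table's reference plane
            y_fan = y * fan_scale / (geometry.sad - z_mid)
            th, owner = prof.lookup(y_fan)
            # vertical extent: tungsten abuts the half interface
            dist_if = np.abs(z_mid - z_if)
            vert = dist_if <= th
            if not np.any(vert):
                continue
            xa, xb = _bank_tips_physical(geometry, aperture, owner,
                                         photon_idx)
            h = z_mid - z_if  # height w.r.t. leaf mid-height (tip center)
            # outside the capped tip height the tip zone is carved flat to
            # the penetration at the cap height (no effect at default cap)
            p = float(geometry.tip_penetration(min(abs(h), cap_h)))
            blocked_a = x <= xa - p
            blocked_b = x >= xb + p
            present = vert & (blocked_a | blocked_b) & (owner >= 0)
            total += np.where(present, seg, 0.0)
    return total
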