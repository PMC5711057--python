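"""QA computations downstream of simulation.

Absolute-dose conversion (linear virtual-linac calibration with the
monitor-backscatter term set to zero), locally adaptive Savitzky-Golay
denoising, 3D gamma analysis, transmission / output-factor analysis, and
transmission-matching density calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dosegrid import DoseGrid, GridSpec
from .geometry import MLCGeometry
from .source import SourceModel
from .transport import simulate


# -- absolute dose (Eq.-style linear conversion) -------------------------

@dataclass
class AbsoluteDoseCalibration:
    """Calibration-field doses for the raw -> absolute linear conversion.

    ``D_cal_measured``: measured dose per MU for the 10x10 cm^2 calibration
    field (Gy/MU, SAD 100, depth 10 cm); ``D_cal_mc``: simulated raw dose
    for the same field (Gy/particle).  The monitor-backscatter term is
    fixed at zero (the validated simplification for machines whose monitor
    chamber cannot be modeled), making the conversion a single linear
    factor.
    """

    D_cal_measured: float
    D_cal_mc: float
    D_chback: float = 0.0

    def __post_init__(self):
        if self.D_cal_measured <= 0 or self.D_cal_mc <= 0:
            raise ValueError("calibration doses must be positive")
        if self.D_chback != 0.0:
            raise ValueError("monitor backscatter term is fixed at zero")


def absolute_dose(dose_grid_raw: DoseGrid,
                  calibration: AbsoluteDoseCalibration, U: float) -> DoseGrid:
    """Convert raw MC dose (Gy/particle) to absolute dose (Gy).

    Every voxel is multiplied by (D_cal_measured / D_cal_mc) * U, where U
    is the plan's monitor units; relative uncertainties are unchanged.
    """
    if U <= 0:
        raise ValueError("monitor units U must be positive")
    factor = calibration.D_cal_measured / calibration.D_cal_mc * U
    return dose_grid_raw.scaled(factor, units="Gy", MU=U)


# -- adaptive Savitzky-Golay denoising ----------------------------------

def _poly_design(hw: tuple, order: int = 2):
    """Order-2 3D polynomial design matrix over a centered window."""
    axes = [np.arange(-h, h + 1, dtype=float) / max(h, 1) for h in hw]
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    x, y, z = xx.ravel(), yy.ravel(), zz.ravel()
    cols = [np.ones_like(x), x, y, z, x * x, y * y, z * z,
            x * y, x * z, y * z]
    return np.stack(cols, axis=1)


def sg_denoise(dose_grid: DoseGrid, half_widths=(4, 3, 2, 1),
               chi2_slack: float = 2.0, chunk: int = 1024) -> DoseGrid:
    """Locally adaptive Savitzky-Golay filter on a noisy dose grid.

    Per voxel, the largest candidate cubic window (half-widths tried in
    the given order) whose order-2 weighted least-squares polynomial fit
    passes a chi-squared test against the stated voxel uncertainties
    (reduced chi^2 <= 1 + ``chi2_slack`` * sqrt(2/nu)) supplies the fitted
    central value; voxels where no window passes are returned unsmoothed.
    Output uncertainties are recomputed from the fit covariance.
    """
    d = dose_grid.dose
    rel = dose_grid.rel_uncertainty
    if np.all(rel[d > 0] == 0) and np.any(d > 0):
        raise ValueError("uncertainty array must be populated (> 0) "
                         "where dose > 0")
    sigma = d * rel
    floor = 1e-12 * max(d.max(), 1.0)
    sigma = np.maximum(sigma, floor)

    out = d.copy()
    out_sigma = sigma.copy()
    decided = np.zeros(d.shape, dtype=bool)
    shape = np.array(d.shape)

    for hw in half_widths:
        hws = (min(hw, (shape[0] - 1) // 2), min(hw, (shape[1] - 1) // 2),
               (0 if shape[2] == 1 else min(hw, (shape[2] - 1) // 2)))
        win = tuple(2 * h + 1 for h in hws)
        m = int(np.prod(win))
        if m <= 10:
            continue
        X = _poly_design(hws)
        core = tuple(slice(h, s - h) for h, s in zip(hws, shape))
        cand = ~decided[core]
        if not np.any(cand):
            continue
        dv = np.lib.stride_tricks.sliding_window_view(d, win)
        sv = np.lib.stride_tricks.sliding_window_view(sigma, win)
        idx = np.nonzero(cand)
        nu = m - X.shape[1]
        thresh = nu * (1.0 + chi2_slack * np.sqrt(2.0 / nu))
        for lo in range(0, idx[0].size, chunk):
            sel = tuple(ax[lo:lo + chunk] for ax in idx)
            vals = dv[sel].reshape(-1, m)
            w = 1.0 / sv[sel].reshape(-1, m) ** 2
            xw = w[:, :, None] * X[None, :, :]
            xtw = np.swapaxes(xw, 1, 2)
            A = xtw @ X
            rhs = np.concatenate(
                [xtw @ vals[:, :, None],
                 np.broadcast_to(np.eye(10)[:, :1],
                                 (A.shape[0], 10, 1))], axis=2)
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            coef, cov0 = sol[:, :, 0], sol[:, :, 1]
            fit = coef @ X.T
            chi2 = np.sum(w * (vals - fit) ** 2, axis=1)
            ok = chi2 <= thresh
            if not np.any(ok):
                continue
            gi = tuple(ax[ok] + h for ax, h in zip(sel, hws))
            out[gi] = coef[ok, 0]
            out_sigma[gi] = np.sqrt(np.maximum(cov0[ok, 0], 0.0))
            decided[gi] = True

    out = np.maximum(out, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_out = np.where(out > 0, out_sigma / np.where(out > 0, out, 1.0),
                           0.0)
    meta = dict(dose_grid.meta)
    meta["denoised"] = True
    return DoseGrid(dose_grid.spec, out, rel_out, meta)


# -- gamma analysis ------------------------------------------------------

@dataclass
class GammaCriteria:
    """Gamma criteria: dose difference (% of reference max), DTA (mm),
    and the ROI threshold (% of reference max)."""

    dose_percent: float = 3.0
    dta_mm: float = 3.0
    roi_threshold_percent: float = 20.0

    def __post_init__(self):
        if min(self.dose_percent, self.dta_mm,
               self.roi_threshold_percent) <= 0:
            raise ValueError("gamma criteria must all be positive")


@dataclass
class GammaResult:
    gamma: np.ndarray          # per-voxel gamma; NaN outside the ROI
    roi: np.ndarray            # boolean ROI mask
    pass_fraction: float       # fraction of ROI voxels with gamma < 1
    criteria: GammaCriteria = field(default_factory=GammaCriteria)

    @property
    def pass_percent(self) -> float:
        return 100.0 * self.pass_fraction


def _offsets(spec_axes, radius_cm, sub_cm):
    """Search offsets within a sphere, sorted by distance; degenerate axes
    (single-voxel) are not searched."""
    grids = []
    for active in spec_axes:
        if active:
            n = int(np.floor(radius_cm / sub_cm))
            grids.append(np.arange(-n, n + 1) * sub_cm)
        else:
            grids.append(np.array([0.0]))
    dx, dy, dz = np.meshgrid(*grids, indexing="ij")
    off = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    r2 = np.sum(off**2, axis=1)
    keep = r2 <= radius_cm**2 + 1e-12
    off, r2 = off[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return off[order], r2[order]


def _interpolator(grid: DoseGrid):
    axes, keep = [], []
    for ax in range(3):
        c = grid.spec.centers(ax)
        if len(c) > 1:
            axes.append(c)
            keep.append(ax)
    data = np.squeeze(grid.dose, axis=tuple(
        ax for ax in range(3) if ax not in keep))
    interp = RegularGridInterpolator(axes, data, bounds_error=False,
                                     fill_value=np.nan)
    return lambda pts: interp(pts[:, keep])


def gamma_3d(reference: DoseGrid, evaluated: DoseGrid,
             criteria: GammaCriteria = None, *, subsample_mm: float = 0.3,
             search_factor: float = 3.0, chunk: int = 512) -> GammaResult:
    """Global-normalization gamma index of ``evaluated`` vs ``reference``.

    gamma(r) = min over the search neighborhood (radius ``search_factor`` x
    DTA, evaluated dose interpolated on a ``subsample_mm`` subgrid) of
    sqrt((dD / dD_crit)^2 + (dr / dr_crit)^2), with dD_crit a percentage of
    the reference maximum.  The ROI is reference dose above the threshold
    percentage of the reference max; the pass fraction counts gamma < 1.
    Note the measure is asymmetric: swapping the grids changes both the
    normalization and the ROI.
    """
    criteria = criteria or GammaCriteria()
    ref = reference.dose
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference grid has no dose")
    roi = ref > criteria.roi_threshold_percent / 100.0 * ref_max
    dd_crit = criteria.dose_percent / 100.0 * ref_max
    dta_cm = criteria.dta_mm / 10.0
    radius = search_factor * dta_cm
    sub_cm = subsample_mm / 10.0

    centers = [reference.spec.centers(ax) for ax in range(3)]
    pts = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)[roi]
    ref_vals = ref[roi]
    ev = _interpolator(evaluated)
    # sanity: grids must overlap
    probe = ev(pts[:1])
    if pts.size and np.all(np.isnan(probe)) and np.all(
            np.isnan(ev(pts[-1:]))):
        raise ValueError("reference and evaluated grids do not overlap")

    active_axes = [len(c) > 1 for c in centers]
    off, r2 = _offsets(active_axes, radius, sub_cm)
    g2 = np.full(ref_vals.shape, np.inf)
    active = np.arange(ref_vals.size)
    for lo in range(0, off.shape[0], chunk):
        o = off[lo:lo + chunk]
        rr = r2[lo:lo + chunk]
        if active.size == 0:
            break
        p = pts[active][:, None, :] + o[None, :, :]
        vals = ev(p.reshape(-1, 3)).reshape(active.size, o.shape[0])
        dd2 = (vals - ref_vals[active][:, None]) ** 2 / dd_crit**2
        cand = dd2 + rr[None, :] / dta_cm**2
        cand = np.where(np.isnan(cand), np.inf, cand)
        g2[active] = np.minimum(g2[active], cand.min(axis=1))
        if lo + chunk < off.shape[0]:
            next_r2 = r2[lo + chunk]
            active = active[g2[active] > next_r2 / dta_cm**2]

    gamma = np.full(ref.shape, np.nan)
    gamma[roi] = np.sqrt(g2)
    pass_fraction = float(np.mean(g2 < 1.0)) if g2.size else 0.0
    return GammaResult(gamma, roi, pass_fraction, criteria)


# -- transmission and output factors ------------------------------------

def mean_transmission(blocked_grid: DoseGrid, open_grid: DoseGrid,
                      span_cm: float = 12.0, band_cm: float = 1.0) -> float:
    """Mean blocked/open dose ratio over a cross-leaf span on the axis.

    Averages the voxelwise ratio over |y| <= span/2 (perpendicular to leaf
    motion) and |x| <= band/2, centered on the beam axis.
    """
    if blocked_grid.spec.shape != open_grid.spec.shape:
        raise ValueError("grids must be co-registered")
    xc = blocked_grid.spec.centers(0)
    yc = blocked_grid.spec.centers(1)
    mx = np.abs(xc) <= band_cm / 2.0
    my = np.abs(yc) <= span_cm / 2.0
    sel = np.ix_(mx, my, np.arange(blocked_grid.spec.shape[2]))
    ob = open_grid.dose[sel]
    bb = blocked_grid.dose[sel]
    if ob.size == 0 or np.any(ob <= 1e-3 * open_grid.dose.max()):
        raise ValueError("open-field dose vanishes inside the span")
    return float(np.mean(bb / ob))


def output_factor(dose_field: DoseGrid, dose_reference_field: DoseGrid,
                  roi_halfwidth_cm: float = 0.4) -> float:
    """Central-axis dose ratio of a field to the reference field."""
    def central(g):
        xc, yc = g.spec.centers(0), g.spec.centers(1)
        m = (np.abs(xc)[:, None] <= roi_halfwidth_cm) & \
            (np.abs(yc)[None, :] <= roi_halfwidth_cm)
        iz = g.spec.shape[2] // 2
        if not np.any(m):  # coarse grid: fall back to the axis voxel
            m[np.argmin(np.abs(xc)), np.argmin(np.abs(yc))] = True
        return float(np.mean(g.dose[:, :, iz][m]))
    ref = central(dose_reference_field)
    if ref <= 0:
        raise ValueError("reference field has zero central dose")
    return central(dose_field) / ref


def simulated_transmission(geometry: MLCGeometry, source_model: SourceModel,
                           *, n_histories: int = 200_000, seed: int = 0,
                           depth_cm: float = 5.0, span_cm: float = 12.0,
                           voxel_cm: float = 0.2, scatter: bool = True,
                           field=(15.0, 17.0), n_batches: int = 10) -> float:
    """Simulate the paired open/blocked fields and return the mean
    transmission (the measurement protocol: 15x17 cm^2 field, 5 cm depth,
    12 cm cross-leaf averaging span)."""
    from .patterns import make_transmission_fields
    open_plan, blocked_plan = make_transmission_fields(field_size=field)
    nx = int(round(field[0] / voxel_cm))
    ny = int(round(field[1] / voxel_cm))
    spec = GridSpec.plane((-field[0] / 2, field[0] / 2),
                          (-field[1] / 2, field[1] / 2), nx, ny, 0.0)
    grids = []
    for plan in (open_plan, blocked_plan):
        ap = plan.control_points[0].aperture  # static delivery
        grids.append(simulate(ap, source_model, geometry, spec,
                              n_histories, seed, depth_cm=depth_cm,
                              scatter=scatter, n_batches=n_batches))
    return mean_transmission(grids[1], grids[0], span_cm=span_cm)


def calibrate_density(geometry: MLCGeometry, source: SourceModel,
                      target_transmission: float, tolerance: float = 5e-4,
                      *, bracket=(10.0, 25.0), max_iter: int = 40,
                      **sim_kwargs) -> float:
    """Find the tungsten density reproducing a measured transmission.

    Bracketing bisection on the simulated mean transmission, which is
    monotone decreasing in density; simulations share a fixed seed so the
    objective is smooth (common random numbers).
    """
    if not (0.0 < target_transmission < 0.1):
        raise ValueError("target transmission must lie in (0, 0.1)")

    def trans(rho):
        g = dataclasses.replace(geometry, density=rho)
        return simulated_transmission(g, source, **sim_kwargs)

    lo, hi = bracket
    t_lo, t_hi = trans(lo), trans(hi)
    if not (t_hi <= target_transmission <= t_lo):
        raise ValueError(
            f"target {target_transmission} unreachable in density bracket "
            f"{bracket}: transmission range [{t_hi:.4g}, {t_lo:.4g}]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        t_mid = trans(mid)
        if abs(t_mid - target_transmission) <= tolerance:
            return mid
        if t_mid > target_transmission:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
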