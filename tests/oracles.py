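"""Independent brute-force oracles used by the test suite.

These re-derive the quantities under test by direct fine-grained
enumeration / quadrature, sharing only the *definitions* (table contents,
focused-side fan geometry, tip arc) with the implementation -- never its
algorithms.
"""

import numpy as np
from scipy.integrate import quad

from mlcport.attenuation import ELECTRON_REST_MEV, _R_E2


def voxelized_path(geometry, aperture, origins, dirs, dz=0.01):
    """Tungsten areal density by fine z-marching with exact table walks."""
    origins = np.atleast_2d(origins)
    dirs = np.atleast_2d(dirs)
    z_top = geometry.z_top
    z_if = geometry.z_interface
    z_bot = z_top - geometry.physical_thickness
    sad = geometry.sad
    scale_ref = sad - z_if
    a = np.asarray(aperture.bank_A_positions) * geometry.proj_scale \
        - 0.5 * geometry.leaf_offset
    b = np.asarray(aperture.bank_B_positions) * geometry.proj_scale \
        + 0.5 * geometry.leaf_offset
    cap_h = min(0.5 * geometry.physical_thickness,
                0.5 * geometry.tip_max_thickness)

    total = np.zeros(origins.shape[0])
    zs = np.arange(z_bot + dz / 2, z_top, dz)
    seg = dz * np.linalg.norm(dirs, axis=1) / np.abs(dirs[:, 2])
    for z in zs:
        t = (z - origins[:, 2]) / dirs[:, 2]
        x = origins[:, 0] + t * dirs[:, 0]
        y = origins[:, 1] + t * dirs[:, 1]
        y_fan = y * scale_ref / (sad - z)
        prof = geometry.upper_profile if z > z_if else geometry.lower_profile
        th, owner = prof.lookup(y_fan)
        vert = np.abs(z - z_if) <= th
        h = abs(z - z_if)
        p = _penetration(geometry, min(h, cap_h))
        ow = np.clip(owner, 0, geometry.n_leaves - 1)
        blocked = (x <= a[ow] - p) | (x >= b[ow] + p)
        total += np.where(vert & blocked & (owner >= 0), seg, 0.0)
    return geometry.density * total


def _penetration(geometry, h):
    r = geometry.tip_radius
    h = abs(h)
    if geometry.tip_angle > 0:
        alpha = np.deg2rad(geometry.tip_angle)
        hf = r * np.sin(alpha)
        if h > hf:
            return r * (1 - np.cos(alpha)) + (h - hf) * np.tan(alpha)
    return r - np.sqrt(max(r * r - min(h, r) ** 2, 0.0))


def tip_chord_numeric(geometry, depth, n=400_000):
    """Vertical tungsten chord through the tip at depth d behind the
    nominal tip, by dense height sampling of the surface inequality."""
    half = 0.5 * geometry.physical_thickness
    cap = min(half, 0.5 * geometry.tip_max_thickness)
    h = (np.arange(n) + 0.5) / n * cap  # one side; symmetric
    inside = np.array([_penetration(geometry, hh) <= depth for hh in h])
    return 2.0 * cap * inside.mean()


def kn_mean_scatter_fraction(energy_mev):
    """Mean E'/E over the Klein-Nishina distribution, by quadrature."""
    k = energy_mev / ELECTRON_REST_MEV

    def eps(ct):
        return 1.0 / (1.0 + k * (1.0 - ct))

    def dcs(ct):
        e = eps(ct)
        return 0.5 * _R_E2 * e * e * (e + 1.0 / e - (1.0 - ct * ct))

    num = quad(lambda ct: dcs(ct) * eps(ct), -1, 1, limit=200)[0]
    den = quad(dcs, -1, 1, limit=200)[0]
    return num / den


def gamma_brute_force(reference, evaluated, criteria, subsample_cm,
                      search_radius_cm):
    """Exhaustive gamma search over the full offset grid (no pruning)."""
    from scipy.interpolate import RegularGridInterpolator

    ref = reference.dose
    ref_max = ref.max()
    roi = ref > criteria.roi_threshold_percent / 100 * ref_max
    dd = criteria.dose_percent / 100 * ref_max
    dta = criteria.dta_mm / 10.0

    centers = [reference.spec.centers(ax) for ax in range(3)]
    axes = [c for c in centers if len(c) > 1]
    keep = [i for i, c in enumerate(centers) if len(c) > 1]
    interp = RegularGridInterpolator(
        axes, np.squeeze(evaluated.dose,
                         axis=tuple(i for i in range(3) if i not in keep)),
        bounds_error=False, fill_value=np.nan)

    grids = []
    for ax in range(3):
        if len(centers[ax]) > 1:
            nn = int(np.floor(search_radius_cm / subsample_cm))
            grids.append(np.arange(-nn, nn + 1) * subsample_cm)
        else:
            grids.append(np.array([0.0]))
    off = np.stack([g.ravel() for g in np.meshgrid(*grids, indexing="ij")],
                   axis=1)
    off = off[np.sum(off**2, axis=1) <= search_radius_cm**2 + 1e-12]

    pts = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)[roi]
    refs = ref[roi]
    g2 = np.full(refs.shape, np.inf)
    for o in off:
        vals = interp((pts + o)[:, keep])
        cand = (vals - refs) ** 2 / dd**2 + np.sum(o**2) / dta**2
        cand = np.where(np.isnan(cand), np.inf, cand)
        g2 = np.minimum(g2, cand)
    gamma = np.full(ref.shape, np.nan)
    gamma[roi] = np.sqrt(g2)
    return gamma, roi, float(np.mean(g2 < 1.0))


def fixed_window_sg(dose, sigma, hw=2):
    """Plain (non-adaptive) order-2 Savitzky-Golay smoothing, for
    edge-blurring comparisons."""
    from mlcport.qa import _poly_design

    shape = dose.shape
    hws = tuple(min(hw, (s - 1) // 2) for s in shape)
    X = _poly_design(hws)
    win = tuple(2 * h + 1 for h in hws)
    out = dose.copy()
    dv = np.lib.stride_tricks.sliding_window_view(dose, win)
    core = tuple(slice(h, s - h) for h, s in zip(hws, shape))
    vals = dv.reshape(-1, int(np.prod(win)))
    coef, *_ = np.linalg.lstsq(X, vals.T, rcond=None)
    out[core] = coef[0].reshape(dv.shape[:3])
    return out
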