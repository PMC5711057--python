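"""Generators for the MLC validation fields and toy VMAT arcs.

Static and dynamic test patterns used to exercise the MLC model: the
paired open/blocked transmission fields, the static odd-leaf bar pattern,
sliding-window dynamic patterns (7-5-2 mm multibar, cross-leaf gradient,
negative pyramid), and a toy VMAT arc.  Dynamic patterns are realized as
sliding-window leaf sequences whose *intended cumulative fluence* matches
the named shape; they are equivalents of the clinical test files, not
replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ApertureState
from .source import ControlPoint, Plan

N_LEAVES = 60          # HD120 leaves per bank
_HD_WIDTHS = np.array([0.5] * 14 + [0.25] * 32 + [0.5] * 14)


@dataclass
class PatternSpec:
    name: str
    field_size: tuple      # (x, y) cm at isocenter
    MU: float
    depth_cm: float = 5.0
    mode: str = "static"   # static | dynamic


def _leaf_centers_iso():
    b = np.concatenate([[0.0], np.cumsum(_HD_WIDTHS)]) - 11.0
    return 0.5 * (b[:-1] + b[1:])


def _plan_from_apertures(apertures, metersets, total_mu, gantry=0.0,
                         beam="6X", name="plan"):
    cps = [ControlPoint(float(u), float(gantry), ap)
           for u, ap in zip(metersets, apertures)]
    return Plan(cps, total_MU=total_mu, beam=beam, name=name)


# -- transmission --------------------------------------------------------

def make_transmission_fields(field_size=(15.0, 17.0), mu_blocked=4000.0,
                             mu_open=100.0):
    """(open Plan, blocked Plan) for the MLC transmission measurement.

    Same jaw settings in both plans; the blocked plan has one bank (A)
    fully covering the field, the open plan has both banks retracted.
    """
    fx, fy = field_size
    jaws = dict(jaw_x1=-fx / 2, jaw_x2=fx / 2, jaw_y1=-fy / 2,
                jaw_y2=fy / 2)
    retract = fx / 2 + 0.5
    open_ap = ApertureState(np.full(N_LEAVES, -retract),
                            np.full(N_LEAVES, retract), **jaws)
    blocked_ap = ApertureState(np.full(N_LEAVES, retract),
                               np.full(N_LEAVES, retract), **jaws)
    mk = lambda ap, mu, nm: _plan_from_apertures(
        [ap, ap], [0.0, 1.0], mu, name=nm)
    return (mk(open_ap, mu_open, "transmission-open"),
            mk(blocked_ap, mu_blocked, "transmission-blocked"))


# -- static odd-leaf bar -------------------------------------------------

def make_odd_leaf_bar(extension_cm=3.5, retract_cm=7.5,
                      field_size=(15.0, 17.0)) -> ApertureState:
    """Odd-numbered bank-A leaves project into the field (bar pattern)."""
    fx, fy = field_size
    bank_a = np.full(N_LEAVES, -retract_cm)
    odd = np.arange(N_LEAVES) % 2 == 0      # leaf numbers 1, 3, 5, ...
    bank_a[odd] = extension_cm
    bank_b = np.full(N_LEAVES, retract_cm)
    return ApertureState(bank_a, bank_b, jaw_x1=-fx / 2, jaw_x2=fx / 2,
                         jaw_y1=-fy / 2, jaw_y2=fy / 2)


# -- sliding-window sequencer -------------------------------------------

def sliding_window_sequence(x, fluence, n_cp=60):
    """Unidirectional sliding-window leaf sequencing for a 1D fluence.

    Returns (metersets, tip_A, tip_B): the minimal-time leaf trajectories
    such that the time interval position x is uncovered (between the
    leading B tip passing and the trailing A tip arriving) equals
    ``fluence(x)``; both tips move monotonically from x[0] to x[-1].
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(fluence, dtype=float)
    if np.any(f < 0):
        raise ValueError("fluence must be non-negative")
    df = np.diff(f, prepend=f[0])
    t_b = np.cumsum(np.maximum(0.0, -df))      # leading (uncover) times
    t_a = t_b + f                              # trailing (cover) times
    t_total = t_a[-1]
    if t_total <= 0:
        raise ValueError("fluence is identically zero")
    # strictly increasing support for interpolation inverses
    eps = 1e-9 * np.arange(len(x))
    u = np.linspace(0.0, 1.0, n_cp)
    t = u * t_total
    tip_b = np.interp(t, t_b + eps, x)
    tip_a = np.interp(t, t_a + eps, x)
    return u, np.minimum(tip_a, tip_b), np.maximum(tip_b, tip_a)


def _sliding_window_plan(x, fluence, n_cp, jaws, total_mu, name,
                         u_range=(0.0, 1.0), leaf_mask=None):
    u, tip_a, tip_b = sliding_window_sequence(x, fluence, n_cp)
    u = u_range[0] + u * (u_range[1] - u_range[0])
    mask = np.ones(N_LEAVES, dtype=bool) if leaf_mask is None else leaf_mask
    aps = []
    for a, b in zip(tip_a, tip_b):
        ba = np.where(mask, a, 0.0)
        bb = np.where(mask, b, 0.0)
        aps.append(ApertureState(ba, bb, **jaws))
    return _plan_from_apertures(aps, u, total_mu, name=name)


def multibar_target_fluence(x):
    """Intended multibar fluence: 7, 5 and 2 mm bars on a low background."""
    x = np.asarray(x, dtype=float)
    f = np.full(x.shape, 0.25)
    for lo, hi in ((-4.35, -3.65), (-0.25, 0.25), (3.90, 4.10)):
        f[(x >= lo) & (x < hi)] = 1.0
    return f


def make_multibar(n_cp=80, total_mu=600.0) -> Plan:
    """Dynamic sliding-window plan delivering the 7-5-2 mm multibar."""
    jaws = dict(jaw_x1=-6.0, jaw_x2=6.0, jaw_y1=-8.5, jaw_y2=8.5)
    x = np.arange(-6.0, 6.0 + 1e-9, 0.025)
    return _sliding_window_plan(x, multibar_target_fluence(x), n_cp, jaws,
                                total_mu, "multibar-7-5-2")


def make_gradient_y(n_cp=31, total_mu=600.0) -> Plan:
    """Dynamic plan with fluence increasing monotonically along +y.

    Leaf pairs close one group at a time in order of increasing y, so a
    pair's open meterset fraction grows linearly with its y index.
    """
    jaws = dict(jaw_x1=-5.0, jaw_x2=5.0, jaw_y1=-8.5, jaw_y2=8.5)
    close_u = np.linspace(0.05, 1.0, N_LEAVES)  # pair j closes at close_u[j]
    us = np.concatenate([[0.0], close_u])
    aps = []
    for u in us:
        open_mask = close_u > u + 1e-12
        ba = np.where(open_mask, -5.0, 0.0)
        bb = np.where(open_mask, 5.0, 0.0)
        aps.append(ApertureState(ba, bb, **jaws))
    return _plan_from_apertures(aps, us, total_mu, name="gradient-y")


def make_negative_pyramid(n_cp=60, total_mu=800.0) -> Plan:
    """Dynamic plan whose fluence is minimal at the field center and grows
    outward along both the leaf-motion (x) and cross-leaf (y) axes."""
    jaws = dict(jaw_x1=-6.0, jaw_x2=6.0, jaw_y1=-8.0, jaw_y2=8.0)
    # phase 1 (u in [0, 0.5]): sliding window delivering a V along x
    x = np.arange(-6.0, 6.0 + 1e-9, 0.05)
    fx = 0.1 + 0.9 * np.abs(x) / 6.0
    u1, tip_a, tip_b = sliding_window_sequence(x, fx, n_cp // 2)
    cps = [ControlPoint(float(0.5 * u), 0.0,
                        ApertureState(np.full(N_LEAVES, a),
                                      np.full(N_LEAVES, b), **jaws))
           for u, a, b in zip(u1[:-1], tip_a[:-1], tip_b[:-1])]
    # phase 2 (u in (0.5, 1]): pairs reopen in order of |y| (outer pairs
    # open longest), adding a V along y
    yc = _leaf_centers_iso()
    open_u = 0.5 + 0.5 * (1.0 - np.abs(yc) / np.abs(yc).max())
    us = np.concatenate([[0.5], np.sort(np.unique(open_u)), [1.0]])
    for u in us:
        open_mask = (open_u <= u + 1e-12) & (np.abs(yc) <= 8.0)
        ba = np.where(open_mask, -6.0, 0.0)
        bb = np.where(open_mask, 6.0, 0.0)
        cps.append(ControlPoint(float(min(u, 1.0)), 0.0,
                                ApertureState(ba, bb, **jaws)))
    # deduplicate meterset and force exact endpoint
    cps[-1] = ControlPoint(1.0, 0.0, cps[-1].aperture)
    return Plan(cps, total_MU=total_mu, name="negative-pyramid")


def make_toy_vmat_arc(n_control_points=90, field_size=(6.0, 6.0),
                      total_MU=2000.0, beam="6X") -> Plan:
    """A full 358-degree arc (gantry 181 -> 179) with a modulated gap."""
    fx, fy = field_size
    jaws = dict(jaw_x1=-fx / 2, jaw_x2=fx / 2, jaw_y1=-fy / 2,
                jaw_y2=fy / 2)
    us = np.linspace(0.0, 1.0, n_control_points)
    gantry = 181.0 + 358.0 * us                # unwrapped; 539 == 179 deg
    cps = []
    for u, g in zip(us, gantry):
        c = 0.3 * fx * np.sin(2.0 * np.pi * u)
        w = 0.5 * fx * (0.6 + 0.4 * np.cos(2.0 * np.pi * u) ** 2)
        ba = np.full(N_LEAVES, c - w / 2)
        bb = np.full(N_LEAVES, c + w / 2)
        cps.append(ControlPoint(float(u), float(g % 360.0),
                                ApertureState(ba, bb, **jaws)))
    return Plan(cps, total_MU=total_MU, beam=beam, name="toy-vmat-arc")


# -- ideal fluence renderer (test oracle support) ------------------------

def ideal_fluence(plan: Plan, x_grid, n_u=2000, leaf_widths=None):
    """Accumulated ideal (geometric) fluence map of a plan.

    Integrates the open-aperture indicator over meterset with the plan's
    interpolated leaf trajectories; returns an (n_leaf_pairs, nx) map in
    leaf-pair rows.  Purely geometric: no transmission, no penumbra.
    """
    from .source import interpolate_plan_state
    x = np.asarray(x_grid, dtype=float)
    us = (np.arange(n_u) + 0.5) / n_u
    _, ba, bb, jaws = interpolate_plan_state(plan, us)
    n_leaves = ba.shape[1]
    fl = np.zeros((n_leaves, x.size))
    x1, x2 = jaws[:, 0], jaws[:, 1]
    for i in range(n_u):
        open_x = (x[None, :] > np.maximum(ba[i], x1[i])[:, None]) & \
                 (x[None, :] < np.minimum(bb[i], x2[i])[:, None])
        fl += open_x
    return fl / n_u


def make_synthetic_noisy_dose(n=50, sigma_vox=None, noise_rel=0.02,
                              seed=0, voxel_cm=0.25, amplitude=2.0):
    """Synthetic smooth 3D dose grid with stated-uncertainty noise.

    A broad Gaussian-edged field on an n^3 grid with independent Gaussian
    noise of ``noise_rel`` relative deviation and matching per-voxel
    stated uncertainties -- the standard fixture for denoising studies.
    Returns (noisy DoseGrid, noiseless truth array).
    """
    from .dosegrid import DoseGrid, GridSpec
    sigma_vox = sigma_vox if sigma_vox is not None else n / 3.5
    ax = np.arange(n) - (n - 1) / 2
    r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    truth = amplitude * np.exp(-r2 / (2.0 * sigma_vox**2))
    rng = np.random.default_rng(seed)
    noisy = truth * (1.0 + noise_rel * rng.standard_normal(truth.shape))
    spec = GridSpec((-n * voxel_cm / 2,) * 3, (voxel_cm,) * 3, (n, n, n))
    grid = DoseGrid(spec, np.maximum(noisy, 0.0),
                    np.full(truth.shape, noise_rel),
                    {"synthetic": True, "seed": seed})
    return grid, truth


def make_pattern(name: str):
    """Pattern registry for the CLI: name -> Plan."""
    makers = {
        "transmission-open": lambda: make_transmission_fields()[0],
        "transmission-blocked": lambda: make_transmission_fields()[1],
        "multibar": make_multibar,
        "gradient-y": make_gradient_y,
        "negative-pyramid": make_negative_pyramid,
        "toy-vmat-arc": make_toy_vmat_arc,
    }
    if name not in makers:
        raise KeyError(f"unknown pattern {name!r}; "
                       f"choose from {sorted(makers)}")
    return makers[name]()
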