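"""Simplified photon transport through the MLC with kerma scoring.

The transport model keeps exactly two interaction channels in tungsten:

* deterministic primary attenuation -- every photon's statistical weight is
  multiplied by exp(-mu * t) over its tungsten path (a forced-transmission
  estimator, so the dominant leakage signal carries almost no variance);
* forced first Compton scatter -- one scattered photon per attenuated
  primary, weighted by the interaction probability times the Compton share
  of the cross section, with Klein-Nishina energy/angle sampling and
  attenuation over its residual tungsten path.  Electrons, photoelectric
  absorption, pair production and higher-order scatter are not transported.

Dose is scored as collision kerma in water at depth under a CPE
assumption: no electron transport and no buildup modeling, which is the
minimal physics for comparisons at depths beyond the buildup region.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from .attenuation import (AttenuationTable, default_attenuation,
                          sample_klein_nishina)
from .dosegrid import DoseGrid, GridSpec
from .geometry import ApertureState, MLCGeometry, _chord_length
from .source import (Plan, SourceModel, interpolate_plan_state,
                     sample_source_photon)

__all__ = ["Photon", "transport_through_mlc", "score_plane_kerma",
           "simulate"]


@dataclass
class Photon:
    """Single particle record (energies MeV, lengths cm, unit direction)."""

    energy: float
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    generation: str = "primary"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.energy <= 0:
            raise ValueError("photon energy must be positive")
        if not self.weight > 0:
            raise ValueError("photon weight must be positive")


def _rotate_about_axis(dirs, theta, phi):
    """Rotate unit vectors by polar angle theta (about themselves) with
    azimuth phi -- standard scatter-frame rotation."""
    d = dirs
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    # build an orthonormal frame (u, v, d)
    small = np.abs(d[:, 2]) > 0.99
    a = np.where(small[:, None], np.array([1.0, 0.0, 0.0]),
                 np.array([0.0, 0.0, 1.0]))
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (st * cp)[:, None] * u + (st * sp)[:, None] * v + ct[:, None] * d


def _transport_batch(batch, geometry, aperture, rng, *, scatter=True,
                     table=None, photon_idx=None, step_cm=0.05, aux=None):
    """Vectorized MLC transport.  ``batch`` holds energy/position/direction/
    weight arrays; returns (primary batch, scatter batch or None).  ``aux``
    arrays (e.g. per-photon gantry angles) are subset through the scatter
    masks and attached to each output batch."""
    table = table or default_attenuation()
    pos, dirs = batch["position"], batch["direction"]
    e, w = batch["energy"], batch["weight"]

    chord = _chord_length(geometry, aperture, pos, dirs, step_cm,
                          photon_idx=photon_idx)
    ell = geometry.density * chord
    mu = table.mu("tungsten", e)
    trans = np.exp(-mu * ell)
    primary = {"energy": e, "position": pos, "direction": dirs,
               "weight": w * trans}
    if aux:
        primary["aux"] = dict(aux)

    if not scatter:
        return primary, None
    hit = ell > 0
    if not np.any(hit):
        return primary, None
    eh, wh = e[hit], w[hit]
    mu_h = mu[hit]
    ell_h = ell[hit]
    p_int = -np.expm1(-mu_h * ell_h)
    cf = table.compton_fraction("tungsten", eh)
    # forced interaction site along the tungsten path (truncated exponential)
    xi = rng.random(eh.size)
    ell_s = -np.log1p(-xi * p_int) / mu_h
    e_s, theta = sample_klein_nishina(eh, rng, size=eh.size)
    phi = 2.0 * np.pi * rng.random(eh.size)
    d_new = _rotate_about_axis(dirs[hit], theta, phi)

    # residual tungsten path along the outgoing direction, approximated by
    # scaling the remaining primary-path areal density by the slant ratio;
    # upward-scattered photons cannot reach the phantom and are dropped
    down = d_new[:, 2] < -1e-3
    ratio = np.where(down,
                     np.abs(dirs[hit][:, 2] / np.where(down, d_new[:, 2], 1.0)),
                     0.0)
    resid = np.clip((ell_h - ell_s) * ratio, 0.0, 10.0 * ell_h)
    mu_s = table.mu("tungsten", e_s)
    w_s = wh * p_int * cf * np.exp(-mu_s * resid) * down

    # geometric scatter point: areal-density fraction mapped onto the slab
    frac = np.where(ell_h > 0, ell_s / ell_h, 0.5)
    z0, z1 = geometry.z_top, geometry.z_top - geometry.physical_thickness
    ph = pos[hit]
    dh = dirs[hit]
    t0 = (z0 - ph[:, 2]) / dh[:, 2]
    t1 = (z1 - ph[:, 2]) / dh[:, 2]
    ts = t0 + frac * (t1 - t0)
    pos_s = ph + ts[:, None] * dh

    keep = w_s > 0
    if not np.any(keep):
        return primary, None
    scat = {"energy": e_s[keep], "position": pos_s[keep],
            "direction": d_new[keep], "weight": w_s[keep]}
    if aux:
        scat["aux"] = {k: v[hit][keep] for k, v in aux.items()}
    return primary, scat


def transport_through_mlc(photon: Photon, geometry: MLCGeometry,
                          aperture: ApertureState, rng, *, scatter=True,
                          table: AttenuationTable | None = None):
    """Transport one photon; returns the output photon list.

    The primary always survives with weight * exp(-mu t) (forced
    transmission); if the path crossed tungsten and ``scatter`` is on, a
    single first-Compton photon is appended as a weighted particle.
    """
    batch = {"energy": np.array([photon.energy]),
             "position": photon.position[None, :],
             "direction": photon.direction[None, :],
             "weight": np.array([photon.weight])}
    prim, scat = _transport_batch(batch, geometry, aperture, rng,
                                  scatter=scatter, table=table)
    out = [Photon(float(prim["energy"][0]), prim["position"][0],
                  prim["direction"][0], float(prim["weight"][0]), "primary")]
    if scat is not None and scat["energy"].size:
        out.append(Photon(float(scat["energy"][0]), scat["position"][0],
                          scat["direction"][0], float(scat["weight"][0]),
                          "compton1"))
    return out


# -- scoring -------------------------------------------------------------

def _rotate_gantry(vec, gantry_deg):
    """Collimator frame -> room frame (rotation about the y axis)."""
    g = np.deg2rad(gantry_deg)
    cg, sg = np.cos(g), np.sin(g)
    x, y, z = vec[:, 0], vec[:, 1], vec[:, 2]
    return np.stack([x * cg + z * sg, y, -x * sg + z * cg], axis=1)


def _box_entry_t(pos, dirs, spec):
    """Ray parameter at which each ray enters the grid bounding box."""
    t_entry = np.full(pos.shape[0], -np.inf)
    for ax in range(3):
        lo = spec.origin[ax]
        hi = spec.origin[ax] + spec.shape[ax] * spec.voxel[ax]
        d = dirs[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - pos[:, ax]) / d
            t2 = (hi - pos[:, ax]) / d
        tmin = np.where(np.abs(d) > 1e-12, np.minimum(t1, t2), -np.inf)
        t_entry = np.maximum(t_entry, tmin)
    return t_entry


def _score_batch(batch, spec, accum, *, depth_cm=None, table=None,
                 missed=None):
    """Deposit kerma from a photon batch into per-batch accumulator.

    Each z-plane crossing deposits  w * E * (muen/rho) * exp(-mu_w * depth)
    per unit voxel area.  ``depth_cm`` fixes the water depth explicitly
    (planar slab geometry); otherwise depth is the distance from the ray's
    entry into the grid bounding box (water-box phantom).
    """
    table = table or default_attenuation()
    pos, dirs = batch["position"], batch["direction"]
    e, w = batch["energy"], batch["weight"]
    ok = np.abs(dirs[:, 2]) > 1e-6
    if not np.all(ok):
        pos, dirs, e, w = pos[ok], dirs[ok], e[ok], w[ok]
    muen = table.muen(e)
    mu_w = table.mu("water", e)
    nx, ny, nz = spec.shape
    inv_area = 1.0 / (spec.voxel[0] * spec.voxel[1])
    zc = spec.centers(2)
    if depth_cm is None:
        t_entry = _box_entry_t(pos, dirs, spec)
    n_missed = 0
    for iz in range(nz):
        t = (zc[iz] - pos[:, 2]) / dirs[:, 2]
        x = pos[:, 0] + t * dirs[:, 0]
        y = pos[:, 1] + t * dirs[:, 1]
        ix = np.floor((x - spec.origin[0]) / spec.voxel[0]).astype(np.int64)
        iy = np.floor((y - spec.origin[1]) / spec.voxel[1]).astype(np.int64)
        inside = (t > 0) & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        if depth_cm is None:
            depth = np.maximum(t - t_entry, 0.0)
        else:
            depth = depth_cm / np.abs(dirs[:, 2])
        val = w * e * muen * np.exp(-mu_w * depth) * inv_area
        np.add.at(accum[:, :, iz],
                  (ix[inside], iy[inside]), val[inside])
        if iz == 0:
            n_missed = int(np.sum(~inside))
    if missed is not None:
        missed["count"] = missed.get("count", 0) + n_missed


def score_plane_kerma(photons, grid_spec: GridSpec, depth_cm: float,
                      table: AttenuationTable | None = None,
                      n_batches: int = 10) -> DoseGrid:
    """Score a list/batch of photons onto a planar grid at water depth.

    Per-voxel relative uncertainty comes from splitting the photons into
    ``n_batches`` sequential batches.
    """
    if isinstance(photons, dict):
        batch = photons
    else:
        batch = {"energy": np.array([p.energy for p in photons]),
                 "position": np.stack([p.position for p in photons]),
                 "direction": np.stack([p.direction for p in photons]),
                 "weight": np.array([p.weight for p in photons])}
    n = batch["energy"].size
    shape = tuple(grid_spec.shape)
    sums = np.zeros((n_batches,) + shape)
    edges = np.linspace(0, n, n_batches + 1).astype(int)
    missed = {}
    for b in range(n_batches):
        sl = slice(edges[b], edges[b + 1])
        sub = {k: v[sl] for k, v in batch.items()}
        _score_batch(sub, grid_spec, sums[b], depth_cm=depth_cm,
                     table=table, missed=missed)
    return _finalize(grid_spec, sums, n, {"missed": missed.get("count", 0)})


def _finalize(spec, batch_sums, n_histories, meta):
    nb = batch_sums.shape[0]
    total = batch_sums.sum(axis=0)
    mean_b = total / nb
    var_b = np.sum((batch_sums - mean_b) ** 2, axis=0) / max(nb - 1, 1)
    sigma_mean = np.sqrt(var_b / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(total > 0, sigma_mean / np.where(
            mean_b > 0, mean_b, 1.0), 0.0)
    dose = total / max(n_histories, 1)
    meta = dict(meta)
    meta["n_histories"] = n_histories
    return DoseGrid(spec, dose, rel, meta)


# -- full pipeline -------------------------------------------------------

def simulate(plan_or_aperture, source_model: SourceModel,
             geometry: MLCGeometry, grid_spec: GridSpec,
             n_histories: int, seed: int, *, depth_cm: float | None = None,
             n_batches: int = 10, scatter: bool = True,
             table: AttenuationTable | None = None,
             chunk_size: int = 100_000, step_cm: float = 0.05) -> DoseGrid:
    """Run the full source -> MLC -> kerma-scoring pipeline.

    ``plan_or_aperture`` is a :class:`Plan` (dynamic, meterset-synchronized
    sampling with per-history machine-state interpolation) or a static
    :class:`ApertureState`.  Reproducible bit-for-bit for a fixed seed.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    table = table or default_attenuation()
    is_plan = isinstance(plan_or_aperture, Plan)
    if not is_plan:
        plan_or_aperture.validate(geometry)

    shape = tuple(grid_spec.shape)
    sums = np.zeros((n_batches,) + shape)
    ss = np.random.SeedSequence(seed)
    batch_seeds = ss.spawn(n_batches)
    edges = np.linspace(0, n_histories, n_batches + 1).astype(int)
    missed = {}

    for b in range(n_batches):
        rng = np.random.default_rng(batch_seeds[b])
        n_b = int(edges[b + 1] - edges[b])
        done = 0
        while done < n_b:
            m = min(chunk_size, n_b - done)
            if is_plan:
                u = rng.random(m)
                gantry, ba, bb, jaws = interpolate_plan_state(
                    plan_or_aperture, u)
                x1, x2 = jaws[:, 0], jaws[:, 1]
                y1, y2 = jaws[:, 2], jaws[:, 3]
                xi = x1 + rng.random(m) * (x2 - x1)
                yi = y1 + rng.random(m) * (y2 - y1)
                batch = _focused_batch(source_model, xi, yi, rng)
                # histories represent a fluence: weight by jaw area so
                # output is per unit incident fluence at isocenter
                batch["weight"] = batch["weight"] * (x2 - x1) * (y2 - y1)
                aperture = SimpleNamespace(bank_A_positions=ba,
                                           bank_B_positions=bb)
                photon_idx = np.arange(m)
            else:
                ap = plan_or_aperture
                batch = sample_source_photon(source_model, ap.field_rect,
                                             rng, size=m)
                fx1, fx2, fy1, fy2 = ap.field_rect
                batch["weight"] = batch["weight"] * (fx2 - fx1) * (fy2 - fy1)
                gantry = None
                aperture, photon_idx = ap, None

            aux = {"gantry": gantry} if gantry is not None else None
            prim, scat = _transport_batch(
                batch, geometry, aperture, rng, scatter=scatter,
                table=table, photon_idx=photon_idx, step_cm=step_cm,
                aux=aux)
            for part in (prim, scat):
                if part is None:
                    continue
                g = part.pop("aux", {}).get("gantry")
                if g is not None:
                    part["position"] = _rotate_gantry(part["position"], g)
                    part["direction"] = _rotate_gantry(part["direction"], g)
                _score_batch(part, grid_spec, sums[b], depth_cm=depth_cm,
                             table=table, missed=missed)
            done += m

    meta = {"seed": seed, "missed": missed.get("count", 0),
            "scatter": scatter,
            "source": getattr(source_model, "name", "custom")}
    return _finalize(grid_spec, sums, n_histories, meta)


def _focused_batch(source_model, xi, yi, rng):
    from .source import sample_energy
    n = xi.size
    sad = source_model.sad
    zp = sad - source_model.phase_plane_z
    s = source_model.phase_plane_z / sad
    pos = np.stack([xi * s, yi * s, np.full(n, zp)], axis=1)
    d = np.stack([xi, yi, np.full(n, -sad)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = np.hypot(pos[:, 0], pos[:, 1])
    w = np.asarray(source_model.lateral_profile(r), dtype=float)
    e = sample_energy(source_model.spectrum, rng, size=n)
    return {"energy": e, "position": pos, "direction": d, "weight": w}
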