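"""File formats: dose-grid text dialect and JSON plan files.

The dose-grid dialect follows the familiar EGSnrc ``.3ddose`` layout
(voxel counts; x/y/z boundary lists; dose values; relative errors), with
leading ``#`` comment lines carrying provenance metadata (tool version,
seed, config hash) as ``# key: value`` pairs.  Plans are plain JSON.
An optional DICOM-RT plan importer is provided when pydicom is installed.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from . import __version__
from .dosegrid import DoseGrid, GridSpec
from .geometry import ApertureState
from .source import ControlPoint, Plan


class ParseError(ValueError):
    pass


def _meta_header(meta: dict) -> str:
    lines = [f"# mlcport {__version__} dose grid"]
    for k, v in sorted(meta.items()):
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_dose_grid(grid: DoseGrid, path):
    """Write a DoseGrid in the 3ddose-style text dialect."""
    spec = grid.spec
    with open(path, "w") as fh:
        fh.write(_meta_header(grid.meta))
        fh.write(" ".join(str(n) for n in spec.shape) + "\n")
        for ax in range(3):
            fh.write(" ".join(f"{b:.6g}" for b in spec.boundaries(ax))
                     + "\n")
        # x-fastest ordering, matching the 3ddose convention
        for arr in (grid.dose, grid.rel_uncertainty):
            flat = arr.transpose(2, 1, 0).ravel()
            fh.write(" ".join(f"{v:.8g}" for v in flat) + "\n")


def read_dose_grid(path) -> DoseGrid:
    meta = {}
    lines = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            s = raw.strip()
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if s:
                lines.append((ln, s))
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated dose grid file")
    ln0, head = lines[0]
    try:
        nx, ny, nz = (int(t) for t in head.split())
    except ValueError:
        raise ParseError(f"{path}:{ln0}: bad voxel-count line") from None
    bounds = []
    for ax, (ln, s) in zip(range(3), lines[1:4]):
        vals = np.array([float(t) for t in s.split()])
        n_expect = (nx, ny, nz)[ax] + 1
        if len(vals) != n_expect:
            raise ParseError(
                f"{path}:{ln}: expected {n_expect} boundaries, "
                f"got {len(vals)}")
        if np.any(np.diff(vals) <= 0):
            raise ParseError(f"{path}:{ln}: boundaries not increasing")
        bounds.append(vals)
    spec = GridSpec(tuple(b[0] for b in bounds),
                    tuple(float(b[1] - b[0]) for b in bounds),
                    (nx, ny, nz))
    arrays = []
    for ln, s in lines[4:6]:
        vals = np.array([float(t) for t in s.split()])
        if vals.size != nx * ny * nz:
            raise ParseError(
                f"{path}:{ln}: expected {nx * ny * nz} values, "
                f"got {vals.size}")
        arrays.append(vals.reshape(nz, ny, nx).transpose(2, 1, 0))
    return DoseGrid(spec, arrays[0], arrays[1], meta)


# -- plans ---------------------------------------------------------------

def write_plan(plan: Plan, path):
    doc = {
        "format": "mlcport-plan-1",
        "version": __version__,
        "name": plan.name,
        "beam": plan.beam,
        "total_MU": plan.total_MU,
        "control_points": [
            {
                "cumulative_meterset": cp.cumulative_meterset,
                "gantry_angle_deg": cp.gantry_angle_deg,
                "jaws": [cp.aperture.jaw_x1, cp.aperture.jaw_x2,
                         cp.aperture.jaw_y1, cp.aperture.jaw_y2],
                "bank_A": list(np.asarray(cp.aperture.bank_A_positions)),
                "bank_B": list(np.asarray(cp.aperture.bank_B_positions)),
            }
            for cp in plan.control_points
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_plan(path) -> Plan:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        cps = []
        for c in doc["control_points"]:
            jaws = c["jaws"]
            ap = ApertureState(np.asarray(c["bank_A"]),
                               np.asarray(c["bank_B"]),
                               jaw_x1=jaws[0], jaw_x2=jaws[1],
                               jaw_y1=jaws[2], jaw_y2=jaws[3])
            cps.append(ControlPoint(c["cumulative_meterset"],
                                    c["gantry_angle_deg"], ap))
        return Plan(cps, total_MU=doc["total_MU"],
                    beam=doc.get("beam", "6X"),
                    name=doc.get("name", "plan"))
    except (KeyError, IndexError, ValueError) as exc:
        raise ParseError(f"{path}: invalid plan file: {exc}") from None


def import_dicom_plan(path, total_mu=None) -> Plan:
    """Import control points from a DICOM-RT Plan (requires pydicom).

    Reads the first beam's control-point sequence: cumulative meterset
    weight, gantry angle, and MLCX beam-limiting-device positions.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("DICOM import requires pydicom") from exc
    ds = pydicom.dcmread(path, force=True)
    beam = ds.BeamSequence[0]
    final = float(beam.FinalCumulativeMetersetWeight)
    jaws = [-20.0, 20.0, -20.0, 20.0]
    cps = []
    for cp in beam.ControlPointSequence:
        banks = None
        for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            pos = np.asarray(bld.LeafJawPositions, dtype=float) / 10.0
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                banks = pos
            elif bld.RTBeamLimitingDeviceType in ("X", "ASYMX"):
                jaws[0], jaws[1] = pos[:2]
            elif bld.RTBeamLimitingDeviceType in ("Y", "ASYMY"):
                jaws[2], jaws[3] = pos[:2]
        if banks is None and cps:
            banks = np.concatenate([cps[-1].aperture.bank_A_positions,
                                    cps[-1].aperture.bank_B_positions])
        n = banks.size // 2
        ap = ApertureState(banks[:n], banks[n:], jaw_x1=jaws[0],
                           jaw_x2=jaws[1], jaw_y1=jaws[2], jaw_y2=jaws[3])
        gantry = float(getattr(cp, "GantryAngle",
                               cps[-1].gantry_angle_deg if cps else 0.0))
        cps.append(ControlPoint(
            float(cp.CumulativeMetersetWeight) / final, gantry, ap))
    mu = total_mu or float(getattr(
        ds.FractionGroupSequence[0].ReferencedBeamSequence[0],
        "BeamMeterset", 100.0))
    return Plan(cps, total_MU=mu, name=str(getattr(ds, "RTPlanLabel",
                                                   "dicom-plan")))


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable run configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
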