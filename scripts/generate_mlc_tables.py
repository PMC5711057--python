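"""Generate the packaged synthesized MLC thickness tables.

Run from repo root:  python scripts/generate_mlc_tables.py [--gap G_CM]

Each leaf half is the leaf's physical y-span shifted by +/- the
tongue-and-groove half-shift s (upper half toward +y, lower toward -y) and
shrunk by half the interleaf air gap g on each side.  This interlocks
adjacent leaves (full total thickness across the step) while leaving two
air strips of width g per leaf boundary where only one half's tungsten is
present.
"""

import argparse
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "mlcport" / "data"

HEADER = """\
# Synthesized {model} {half}-half thickness table (cm at the MLC plane).
# Vendor tables are proprietary; this table reproduces the published
# construction qualitatively (leaf widths, total thickness, interlocking
# tongue-and-groove halves, interleaf air gap). Columns:
# leaf_number  y_breakpoint_cm  thickness_cm
# A row opens a segment extending to the next row's breakpoint.
"""


def write_tables(model, widths_iso, height, z_upper, s, gap, sad=100.0):
    z_top = sad - z_upper
    z_if = z_top - 0.5 * height
    scale = (sad - z_if) / sad
    half_th = 0.5 * height
    bounds = np.concatenate([[0.0], np.cumsum(widths_iso)])
    bounds = (bounds - 0.5 * widths_iso.sum()) * scale  # physical
    for half, shift in (("upper", +s), ("lower", -s)):
        rows = []
        for i in range(len(widths_iso)):
            y0 = bounds[i] + shift + 0.5 * gap
            y1 = bounds[i + 1] + shift - 0.5 * gap
            rows.append((i + 1, y0, half_th))
            rows.append((i + 1, y1, 0.0))
        path = DATA / f"{model}_{half}half.table"
        with open(path, "w") as fh:
            fh.write(HEADER.format(model=model, half=half))
            for leaf, y, th in rows:
                fh.write(f"{leaf:3d}  {y:+10.5f}  {th:7.4f}\n")
        print("wrote", path)


def write_config(model, model_name, widths_spec, height, tip_radius,
                 tip_angle, density, z_upper):
    path = DATA / f"{model}_particledmlc.config"
    with open(path, "w") as fh:
        fh.write(f"""\
# Synthesized {model_name} MLC configuration (vendor values proprietary;
# geometry follows the published construction data; density and interleaf
# gap calibrated to the measured 6X transmission).
model_name = {model_name}
leaf_widths_iso = {widths_spec}
physical_thickness = {height}
tip_radius = {tip_radius}
tip_angle = {tip_angle}
density = {density}
leaf_offset = 0.0
z_upper = {z_upper}
""")
    print("wrote", path)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--gap", type=float, default=0.006,
                    help="interleaf air gap, cm (HD120)")
    ap.add_argument("--gap-mill", type=float, default=0.006)
    args = ap.parse_args()

    hd_widths = np.array([0.5] * 14 + [0.25] * 32 + [0.5] * 14)
    write_tables("hd120", hd_widths, 6.9, 50.9, s=0.015, gap=args.gap)
    write_config("hd120", "HD120", "14*0.5,32*0.25,14*0.5", 6.9,
                 tip_radius=16.0, tip_angle=0.0, density=18.9, z_upper=50.9)

    mil_widths = np.array([1.0] * 10 + [0.5] * 40 + [1.0] * 10)
    write_tables("millennium120", mil_widths, 6.7, 50.9, s=0.015,
                 gap=args.gap_mill)
    write_config("millennium120", "Millennium120", "10*1.0,40*0.5,10*1.0",
                 6.7, tip_radius=8.0, tip_angle=11.3, density=17.6,
                 z_upper=50.9)


if __name__ == "__main__":
    main()
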