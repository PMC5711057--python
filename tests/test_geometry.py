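"""MLC geometry: config parsing, leaf indexing, tips, path integration."""

import dataclasses

import numpy as np
import pytest

import mlcport as m
from mlcport.geometry import MLCConfigError
from oracles import tip_chord_numeric, voxelized_path

SRC = np.array([0.0, 0.0, 100.0])


def ray_through(x_iso, y_iso):
    d = np.array([x_iso, y_iso, -100.0]) - SRC + np.array([0, 0, 100.0])
    d = np.array([x_iso, y_iso, -100.0])
    d = d / np.linalg.norm(d)
    return m.Ray(SRC, d)


def closed_bank_aperture(n=60, x=8.0):
    return m.ApertureState(np.full(n, x), np.full(n, x))


class TestLoadConfig:
    def test_packaged_hd120(self, hd120_geom):
        g = hd120_geom
        assert g.n_leaves == 60
        assert g.physical_thickness == pytest.approx(6.9)
        assert g.tip_radius == pytest.approx(16.0)
        assert g.tip_angle == 0.0
        assert g.density == pytest.approx(18.9)
        # 32 quarter-cm central + 28 half-cm outer leaves
        assert np.sum(g.leaf_widths_iso == 0.25) == 32
        assert np.sum(g.leaf_widths_iso == 0.5) == 28

    def test_packaged_millennium(self, mill_geom):
        assert mill_geom.tip_radius == pytest.approx(8.0)
        assert mill_geom.tip_angle == pytest.approx(11.3)
        assert mill_geom.physical_thickness == pytest.approx(6.7)

    def test_toy_table_round_trip(self, tmp_path):
        rows = [(1, -0.5, 3.0), (1, -0.02, 0.0), (2, 0.0, 3.0),
                (2, 0.48, 0.0)]
        for name in ("up.table", "lo.table"):
            with open(tmp_path / name, "w") as fh:
                for r in rows:
                    fh.write(f"{r[0]} {r[1]} {r[2]}\n")
        with open(tmp_path / "c.config", "w") as fh:
            fh.write("model_name = toy\nleaf_widths_iso = 2*0.5\n"
                     "physical_thickness = 6.0\ntip_radius = 8.0\n")
        g = m.load_mlc_config(tmp_path / "up.table", tmp_path / "lo.table",
                              tmp_path / "c.config")
        np.testing.assert_allclose(g.upper_profile.y,
                                   [r[1] for r in rows])
        np.testing.assert_allclose(g.upper_profile.thickness,
                                   [r[2] for r in rows])
        assert m.projected_field_length(g) == pytest.approx(1.0)

    def test_malformed_row_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.table"
        p.write_text("1 0.0 3.0\n1 oops 0.0\n")
        with pytest.raises(MLCConfigError, match=r"bad\.table:2"):
            m.load_mlc_config(p, p, tmp_path / "missing.config")

    def test_leaf_count_mismatch_rejected(self, tmp_path):
        (tmp_path / "up.table").write_text("1 0.0 3.0\n1 0.5 0.0\n")
        (tmp_path / "lo.table").write_text(
            "1 0.0 3.0\n1 0.25 0.0\n2 0.25 3.0\n2 0.5 0.0\n")
        (tmp_path / "c.config").write_text(
            "leaf_widths_iso = 1*0.5\nphysical_thickness = 6.0\n"
            "tip_radius = 8.0\n")
        with pytest.raises(MLCConfigError, match="mismatch"):
            m.load_mlc_config(tmp_path / "up.table", tmp_path / "lo.table",
                              tmp_path / "c.config")


class TestLeafIndexing:
    def test_center_is_quarter_leaf(self, hd120_geom):
        idx, off = m.leaf_index_at(hd120_geom, 0.0)
        assert hd120_geom.leaf_widths_iso[idx] == pytest.approx(0.25)
        assert off == 0.0  # y=0 is a boundary -> higher-index leaf

    def test_outer_region_is_half_leaf(self, hd120_geom):
        idx, _ = m.leaf_index_at(hd120_geom, 5.0)
        assert hd120_geom.leaf_widths_iso[idx] == pytest.approx(0.5)

    def test_boundary_belongs_to_higher_leaf(self, hd120_geom):
        idx, off = m.leaf_index_at(hd120_geom, -4.0)
        below, _ = m.leaf_index_at(hd120_geom, -4.0 - 1e-9)
        assert idx == below + 1
        assert off == 0.0

    def test_cumulative_widths_consistent(self, hd120_geom):
        b = hd120_geom.leaf_boundaries_iso()
        for y in (-10.99, -3.1, 0.77, 6.2):
            idx, off = m.leaf_index_at(hd120_geom, y)
            assert b[idx] + off == pytest.approx(y)
            assert 0 <= off < hd120_geom.leaf_widths_iso[idx]

    def test_outside_stack_raises(self, hd120_geom):
        with pytest.raises(ValueError, match="outside"):
            m.leaf_index_at(hd120_geom, 11.5)
        with pytest.raises(ValueError, match="outside"):
            m.leaf_index_at(hd120_geom, 11.0)  # top edge is half-open


class TestThicknessProfile:
    def test_leaf_body_has_full_thickness(self, hd120_geom):
        up, lo = m.thickness_profile(hd120_geom, 0.07)  # mid-leaf
        assert up + lo == pytest.approx(6.9)

    def test_step_region_below_full_thickness(self, hd120_geom):
        # inside the strip where the upper half is recessed
        up, lo = m.thickness_profile(hd120_geom, 0.015)
        assert up + lo < 6.9
        assert up + lo == pytest.approx(3.45)

    def test_matches_naive_table_walk(self, hd120_geom):
        prof = hd120_geom.upper_profile
        rng = np.random.default_rng(7)
        ys = rng.uniform(prof.y[0], prof.y[-1], 200)
        for y in ys:
            k = int(np.searchsorted(prof.y, y, side="right")) - 1
            expect = prof.thickness[k] if k < len(prof.y) - 1 else 0.0
            up, _ = m.thickness_profile(hd120_geom, y)
            assert up == pytest.approx(expect)


class TestTipThickness:
    def test_full_body_behind_tip(self, hd120_geom):
        assert m.tip_thickness(hd120_geom, -2.0, 0.0) == pytest.approx(6.9)

    def test_zero_on_open_side(self, hd120_geom):
        assert m.tip_thickness(hd120_geom, 0.1, 0.0) == 0.0

    @pytest.mark.parametrize("depth_mm", [0.5, 1.0, 2.0])
    def test_chord_matches_numeric_intersection(self, hd120_geom,
                                                mill_geom, depth_mm):
        d = depth_mm / 10.0
        for g in (hd120_geom, mill_geom):
            chord = m.tip_thickness(g, -d, 0.0)
            oracle = tip_chord_numeric(g, d)
            assert chord == pytest.approx(oracle, rel=1e-3)

    def test_monotone_into_leaf(self, hd120_geom):
        xs = np.linspace(0.2, -1.0, 100)
        ch = [m.tip_thickness(hd120_geom, x, 0.0) for x in xs]
        assert np.all(np.diff(ch) >= -1e-12)


class TestRadiologicalPath:
    def test_closed_leaf_body_full_thickness(self, hd120_geom):
        ap = closed_bank_aperture()
        ray = ray_through(0.0, 0.125)  # mid quarter-leaf, near axis
        path = m.radiological_path(hd120_geom, ap, ray)
        assert path == pytest.approx(6.9 * 18.9, rel=5e-3)

    def test_open_aperture_center_is_zero(self, hd120_geom):
        ap = m.open_aperture(hd120_geom)
        assert m.radiological_path(hd120_geom, ap, ray_through(0, 0.1)) == 0

    def test_parallel_ray_rejected(self, hd120_geom):
        ap = m.open_aperture(hd120_geom)
        with pytest.raises(ValueError, match="parallel"):
            m.radiological_path(hd120_geom, ap,
                                m.Ray([0, 0, 60.0], [1, 0, 0]))

    def test_density_scaling_is_exact(self, hd120_geom):
        ap = closed_bank_aperture()
        ray = ray_through(1.3, 2.2)
        p1 = m.radiological_path(hd120_geom, ap, ray)
        g2 = dataclasses.replace(hd120_geom, density=2 * 18.9)
        assert m.radiological_path(g2, ap, ray) == pytest.approx(2 * p1)

    def test_matches_voxelized_volume_oracle(self, hd120_geom):
        rng = np.random.default_rng(11)
        n = 1000
        xy = rng.uniform(-7, 7, (n, 2))
        xy[:, 1] = rng.uniform(-6, 6, n)
        dirs = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, -100.0)])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        origins = np.tile(SRC, (n, 1))
        a = rng.uniform(-6, 2, 60)
        ap = m.ApertureState(a, a + rng.uniform(0, 6, 60))
        got = m.radiological_path(hd120_geom, ap, (origins, dirs))
        expect = voxelized_path(hd120_geom, ap, origins, dirs, dz=0.01)
        # 1% agreement, with an absolute floor of 1% of the closed-leaf
        # path to make grazing near-zero chords comparable
        floor = 0.01 * 6.9 * 18.9
        assert np.all(np.abs(got - expect)
                      <= np.maximum(0.01 * expect, floor))
        # aggregate agreement is much tighter than the per-ray bound
        hit = expect > 1.0
        assert np.mean(np.abs(got[hit] - expect[hit]) / expect[hit]) < 0.01

    def test_zero_iff_misses_all_tungsten(self, hd120_geom):
        ap = closed_bank_aperture()
        blocked = m.radiological_path(hd120_geom, ap, ray_through(0, 0.125))
        assert blocked > 0
        outside = m.radiological_path(hd120_geom, ap, ray_through(0, 11.8))
        assert outside == 0.0

    def test_reflection_symmetry_for_symmetric_stack(self, tmp_path):
        # a symmetric 2-leaf toy geometry (no tongue-and-groove shift)
        rows = [(1, -0.5, 3.0), (1, -0.005, 0.0), (2, 0.005, 3.0),
                (2, 0.5, 0.0)]
        for name in ("up.table", "lo.table"):
            with open(tmp_path / name, "w") as fh:
                for r in rows:
                    fh.write(f"{r[0]} {r[1]} {r[2]}\n")
        (tmp_path / "c.config").write_text(
            "model_name = toy\nleaf_widths_iso = 2*0.92\n"
            "physical_thickness = 6.0\ntip_radius = 8.0\n")
        g = m.load_mlc_config(tmp_path / "up.table", tmp_path / "lo.table",
                              tmp_path / "c.config")
        ap = m.ApertureState([0.5, -1.0], [2.0, 1.5])
        ap_mirror = m.ApertureState([-1.0, 0.5], [1.5, 2.0])
        for x, y in ((0.3, 0.4), (-0.7, 0.2), (1.2, -0.5)):
            p = m.radiological_path(g, ap, ray_through(x, y))
            p_m = m.radiological_path(g, ap_mirror, ray_through(x, -y))
            assert p == pytest.approx(p_m, abs=1e-9)


class TestProjectedFieldLength:
    def test_hd120_is_22cm(self, hd120_geom):
        assert m.projected_field_length(hd120_geom) == pytest.approx(22.0)

    def test_millennium_is_40cm(self, mill_geom):
        assert m.projected_field_length(mill_geom) == pytest.approx(40.0)

    def test_single_toy_leaf(self):
        import mlcport.geometry as geo
        prof = geo.HalfProfile(np.array([0.0, 0.27]), np.array([3.45, 0.0]),
                               np.array([0, 0]))
        g1 = geo.MLCGeometry("toy", np.array([0.5]), prof, prof, 6.9, 16.0)
        assert m.projected_field_length(g1) == pytest.approx(0.5)
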