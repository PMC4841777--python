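"""Segmentation, per-nucleus measurement and the stage statistics."""

import itertools
import math

import numpy as np
import pytest

from multifission import if_quant as ifq
from multifission.geometry import cell_volume_ellipsoid, nc_ratio, nuclear_volume_from_diameter
from multifission.synthetic_data import (
    SyntheticConfig,
    gen_ble_gfp_geometry,
    gen_if_records,
    render_cell_image,
)
from multifission.titration_model import ModelParams


def draw_disks(shape, disks, level=100.0):
    """Rasterize bright disks (cy, cx, r) on a zero background."""
    img = np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for cy, cx, r in disks:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = level
    return img


class TestSegmentation:
    def test_two_disjoint_disks(self):
        disks = [(20, 20, 6), (60, 60, 9)]
        img = draw_disks((90, 90), disks)
        labels, areas = ifq.segment_nuclei(img, pixel_size=0.5)
        assert len(areas) == 2
        pixel_counts = sorted(int(np.sum(labels == k)) for k in areas)
        expected = sorted(int(np.sum(draw_disks((90, 90), [d]) > 0)) for d in disks)
        assert pixel_counts == expected
        assert sorted(areas.values()) == [c * 0.25 for c in expected]

    def test_blank_image_yields_no_nuclei(self):
        labels, areas = ifq.segment_nuclei(np.zeros((32, 32)), pixel_size=0.1)
        assert areas == {}
        assert not labels.any()

    def test_saturated_image_rejected(self):
        with pytest.raises(ValueError):
            ifq.segment_nuclei(np.full((32, 32), 9.0), pixel_size=0.1)

    def test_min_area_filter(self):
        img = draw_disks((80, 80), [(20, 20, 2), (55, 55, 10)])
        labels, areas = ifq.segment_nuclei(img, pixel_size=1.0, min_area=50.0)
        assert len(areas) == 1
        assert labels.max() == 1  # compact relabeling after filtering

    def test_eight_nucleus_synthetic_cell(self):
        cfg = SyntheticConfig(seed=3, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=1)
        cell = next(r for r in records if r.stage == 8)
        dapi, _, truth_labels = render_cell_image(cell, cfg)
        labels, areas = ifq.segment_nuclei(dapi, cfg.image_pixel_size)
        assert len(areas) == 8
        for k in range(1, 9):
            truth_area = np.sum(truth_labels == k) * cfg.image_pixel_size**2
            # recovered disk areas match the rasterized ground truth
            assert any(abs(a - truth_area) / truth_area < 0.10 for a in areas.values())


class TestMeasurement:
    def test_background_equal_signal_gives_zero(self):
        dapi = draw_disks((40, 40), [(20, 20, 6)])
        ha = np.full((40, 40), 7.0)
        labels, _ = ifq.segment_nuclei(dapi, pixel_size=0.1)
        nuclei = ifq.measure_nuclei(ha, labels, background=7.0, pixel_size=0.1)
        assert nuclei[0].intensity_sum == 0.0

    def test_hundred_pixel_nucleus_direct_sum(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[:10, :10] = 1  # exactly 100 pixels
        ha = np.full((20, 20), 12.0)
        nuclei = ifq.measure_nuclei(ha, labels, background=7.0, pixel_size=0.1)
        assert nuclei[0].intensity_sum == 500.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ifq.measure_nuclei(np.zeros((5, 5)), np.zeros((6, 6), dtype=int), 0.0, 0.1)

    def test_equals_brute_force_pixel_loop(self):
        # integer-valued image so both summation orders are exact
        rng = np.random.default_rng(8)
        dapi = draw_disks((64, 64), [(16, 16, 5), (44, 40, 7)])
        ha = rng.integers(0, 50, size=(64, 64)).astype(float)
        background = 3.0
        labels, _ = ifq.segment_nuclei(dapi, pixel_size=0.2)
        nuclei = ifq.measure_nuclei(ha, labels, background, pixel_size=0.2)
        for nuc in nuclei:
            brute = 0.0
            npix = 0
            for y in range(64):
                for x in range(64):
                    if labels[y, x] == nuc.nucleus_id:
                        brute += max(ha[y, x] - background, 0.0)
                        npix += 1
            assert nuc.intensity_sum == brute
            assert nuc.projected_area == npix * 0.2**2

    def test_image_roundtrip_recovers_intensity_sums(self):
        # zero noise, zero cytoplasm signal: sums recovered to float precision
        cfg = SyntheticConfig(seed=5, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=1)
        for rec in records:
            dapi, ha, _ = render_cell_image(rec, cfg, background=2.0)
            out = ifq.quantify_cell(
                dapi, ha, cfg.image_pixel_size, background=2.0, cell_id=rec.cell_id
            )
            assert out.stage == rec.stage
            got = sorted(n.intensity_sum for n in out.nuclei)
            want = sorted(n.intensity_sum for n in rec.nuclei)
            assert np.allclose(got, want, rtol=1e-9)

    def test_max_projection_reduces_stacks(self):
        stack = np.stack([np.zeros((4, 4)), np.eye(4) * 5.0])
        assert np.array_equal(ifq.max_project(stack), np.eye(4) * 5.0)


class TestStageStatistics:
    def test_single_stage_constant(self):
        cfg = SyntheticConfig(seed=1, stage_list=(4,), intensity_noise_cv=0.0,
                              nucleus_radius_by_stage=(1.5,))
        records, truth = gen_if_records(cfg, cells_per_stage=5)
        df = ifq.stage_summaries(records, min_cells_per_stage=5)
        assert df["mean_concentration"].iloc[0] == pytest.approx(
            truth["concentration_means"][0]
        )
        assert df["sd_concentration"].iloc[0] == 0.0

    def test_recovers_known_stage_means(self):
        cfg = SyntheticConfig(seed=17, n_cells=400, intensity_noise_cv=0.1)
        records, truth = gen_if_records(cfg, cells_per_stage=80)
        df = ifq.stage_summaries(records, min_cells_per_stage=68, params=ModelParams())
        for mean, sd, n, want in zip(
            df["mean_concentration"], df["sd_concentration"], df["n_nuclei"],
            truth["concentration_means"],
        ):
            assert abs(mean - want) < 3 * sd / math.sqrt(n)

    def test_size_filter_excludes_small_mothers(self):
        cfg = SyntheticConfig(seed=2, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=3)
        for r in records:
            r.mother_volume = 250.0  # predicts < 3 divisions
        with pytest.raises(ValueError):
            ifq.stage_summaries(records, min_cells_per_stage=1, params=ModelParams())

    def test_no_stage_meets_minimum_rejected(self):
        cfg = SyntheticConfig(seed=2, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=3)
        with pytest.raises(ValueError):
            ifq.stage_summaries(records, min_cells_per_stage=68)


class TestPerDnaSeries:
    def test_first_stage_normalized_to_one(self, small_synth_config):
        records, _ = gen_if_records(small_synth_config, cells_per_stage=20)
        df = ifq.per_dna_series(records)
        assert df["normalized"].iloc[0] == 1.0

    def test_conservation_gives_exact_halving(self):
        cfg = SyntheticConfig(seed=6, degradation_fraction=0.0, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=4)
        df = ifq.per_dna_series(records)
        assert np.allclose(df["normalized"], [1, 0.5, 0.25, 0.125, 0.0625], rtol=1e-12)

    def test_degradation_gives_045_factor(self):
        cfg = SyntheticConfig(seed=6, degradation_fraction=0.1, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=4)
        norm = ifq.per_dna_series(records)["normalized"].to_numpy()
        assert np.allclose(norm[1:] / norm[:-1], 0.45, rtol=1e-12)

    def test_requires_two_stages(self):
        cfg = SyntheticConfig(seed=1, stage_list=(2,), intensity_noise_cv=0.0,
                              nucleus_radius_by_stage=(1.2,))
        records, _ = gen_if_records(cfg, cells_per_stage=3)
        with pytest.raises(ValueError):
            ifq.per_dna_series(records)


class TestLinearFit:
    def test_collinear_means(self):
        slope, intercept, r2 = ifq.linear_fit_means([4.0, 3.0, 2.0, 1.0])
        assert slope == pytest.approx(-1.0)
        assert intercept == pytest.approx(5.0)
        assert r2 == pytest.approx(1.0)

    def test_perturbed_point_matches_hand_formula(self):
        y = np.array([4.0, 3.0, 2.1, 1.0])
        x = np.arange(1.0, 5.0)
        slope, intercept, r2 = ifq.linear_fit_means(y)
        # hand OLS
        bx = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        a0 = y.mean() - bx * x.mean()
        ss_res = np.sum((y - (a0 + bx * x)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(bx)
        assert intercept == pytest.approx(a0)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ifq.linear_fit_means([1.0, 2.0])


def brute_force_rank_sum_p(a, b):
    """Exhaustive two-sided rank-sum p: enumerate every group assignment.

    Two-sided p is twice the smaller (inclusive) tail probability of the U
    statistic under the permutation null, capped at 1 — the standard exact
    test definition.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(idx_a):
        ga = pooled[list(idx_a)]
        gb = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
        u = 0.0
        for x in ga:
            for y in gb:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(tuple(range(n1)))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(1 for u in us if u <= u_obs + 1e-12) / len(us)
    hi = sum(1 for u in us if u >= u_obs - 1e-12) / len(us)
    return min(1.0, 2.0 * min(lo, hi))


class TestCompareStages:
    def test_identical_groups_p_one(self):
        u, p = ifq.compare_stages([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_separated_groups_exact_p(self):
        u, p = ifq.compare_stages([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 7))
        b = rng.normal(0.8, 1, rng.integers(3, 7))
        _, p = ifq.compare_stages(a, b)
        assert p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-9)

    def test_matches_enumeration_with_ties(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        _, p = ifq.compare_stages(a, b)
        assert p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1.0, 1, 100)
        _, p = ifq.compare_stages(a, b)
        assert 0 < p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ifq.compare_stages([], [1.0, 2.0])

    def test_stage_2_vs_8_significant_at_study_size(self):
        # 68 cells per stage, default degradation/noise: stage-2 vs stage-8
        # nuclear concentrations differ with p < 0.005
        cfg = SyntheticConfig(seed=12, intensity_noise_cv=0.1)
        records, _ = gen_if_records(cfg, cells_per_stage=68)
        conc = {
            s: [n.concentration for r in records if r.stage == s for n in r.nuclei]
            for s in (2, 8)
        }
        # compare per-cell means to keep one observation per cell
        cell_means = {
            s: [
                np.mean([n.concentration for n in r.nuclei])
                for r in records
                if r.stage == s
            ]
            for s in (2, 8)
        }
        _, p = ifq.compare_stages(cell_means[2], cell_means[8])
        assert p < 0.005


class TestNcAnova:
    def test_identical_constant_groups(self):
        f, p = ifq.nc_anova([[2.0, 2.0], [2.0, 2.0]])
        assert f == 0.0
        assert p == 1.0

    def test_hand_computed_f(self):
        f, p = ifq.nc_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert f == pytest.approx(1.5)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ifq.nc_anova([[1.0], [2.0, 3.0]])

    def test_null_synthetic_geometry_mostly_nonsignificant(self):
        # constant true N/C with measurement noise: ANOVA should not reject
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = SyntheticConfig(seed=seed, intensity_noise_cv=0.1)
            df = gen_ble_gfp_geometry(cfg)
            groups = []
            for stage, g in df.groupby("stage"):
                vn = stage * nuclear_volume_from_diameter(
                    g["nucleus_diameter_um"].to_numpy()
                )
                vc = cell_volume_ellipsoid(
                    g["major_axis_um"].to_numpy(), g["minor_axis_um"].to_numpy()
                )
                groups.append(nc_ratio(vn, vc))
            _, p = ifq.nc_anova(groups)
            hits += p > 0.05
        assert hits / n_rep >= 0.9


class TestNuclearFraction:
    def make_record(self, cell_id, stage, nuclear, total):
        return ifq.CellIFRecord(
            cell_id=cell_id,
            nuclei=[],
            stage=stage,
            total_intensity_in_cell=total,
            nuclear_fraction=nuclear / total if total > 0 else 0.0,
            per_dna_ratio=0.0,
        )

    def test_all_nuclear_signal(self):
        records = [self.make_record(f"c{i}", 2, 10.0, 10.0) for i in range(5)]
        df = ifq.nuclear_fraction_score(records)
        assert (df["fraction_majority_nuclear"] == 1.0).all()

    def test_exactly_half_counts_as_not_majority(self):
        records = [self.make_record("c0", 2, 5.0, 10.0)]
        df = ifq.nuclear_fraction_score(records)
        assert df["fraction_majority_nuclear"].iloc[0] == 0.0

    def test_thirty_percent_cytoplasmic_still_majority(self):
        cfg = SyntheticConfig(seed=9, cytoplasm_signal_fraction=0.3, intensity_noise_cv=0.0)
        records, _ = gen_if_records(cfg, cells_per_stage=4)
        df = ifq.nuclear_fraction_score(records)
        assert (df["fraction_majority_nuclear"] == 1.0).all()

    def test_zero_signal_cells_excluded(self):
        records = [
            self.make_record("c0", 2, 8.0, 10.0),
            self.make_record("c1", 2, 0.0, 0.0),
        ]
        df = ifq.nuclear_fraction_score(records)
        assert df["n_cells"].iloc[0] == 1
        assert df.attrs["n_excluded"] == 1
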