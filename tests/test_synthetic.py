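"""Generator ground truth, determinism and closure with the analyzers."""

import numpy as np
import pandas as pd
import pytest

from mscmorph import synthetic
from mscmorph.synthetic import (
    FieldSpec,
    MarkerSimSpec,
    PassageSizeModel,
    PlacementError,
    TRFSimSpec,
)


class TestFieldGeneration:
    def test_empty_spec_gives_background_only(self):
        field, truth = synthetic.generate_field(
            FieldSpec(n_cells=0, seed=1), synthetic.TABLE2_SIZE_MODELS[0]
        )
        assert len(truth) == 0
        assert truth.label_mask.max() == 0

    def test_clean_singletons_ground_truth(self):
        spec = FieldSpec(n_cells=20, field_size=(768, 768), seed=5)
        _, truth = synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[0])
        t = truth.table
        assert len(t) == 20
        assert (t.n_nuclei == 1).all()
        assert (~t.touches_border).all()
        assert (~t.is_debris).all()
        assert np.array_equal(np.sort(np.unique(truth.label_mask))[1:], t.object_id)

    def test_true_area_equals_pixel_count_times_pixel_size_sq(self):
        spec = FieldSpec(n_cells=8, pixel_size=0.65, seed=2)
        _, truth = synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[0])
        for _, row in truth.table.iterrows():
            npx = int((truth.label_mask == row.object_id).sum())
            assert row.true_area == pytest.approx(npx * 0.65**2, abs=1e-9)

    def test_mean_area_tracks_size_model_within_5pct(self):
        # 500 cells across fields at the early-passage setting (1827 ± 329)
        model = synthetic.TABLE2_SIZE_MODELS[0]
        areas = []
        for seed in range(25):
            spec = FieldSpec(n_cells=20, field_size=(900, 900), seed=seed)
            _, truth = synthetic.generate_field(spec, model)
            areas.extend(truth.table.true_area)
        assert len(areas) == 500
        assert np.mean(areas) == pytest.approx(1827, rel=0.05)

    def test_determinism_bit_identical(self):
        spec = FieldSpec(
            n_cells=10, fraction_border=0.1, fraction_binucleate=0.1, fraction_debris=0.1, seed=77
        )
        f1, t1 = synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[1])
        f2, t2 = synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[1])
        assert np.array_equal(f1.nucleus_channel, f2.nucleus_channel)
        assert np.array_equal(f1.cytoplasm_channel, f2.cytoplasm_channel)
        assert np.array_equal(t1.label_mask, t2.label_mask)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_overcrowded_field_raises_placement_error(self):
        spec = FieldSpec(n_cells=60, field_size=(128, 128), seed=0)
        with pytest.raises(PlacementError):
            synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[3])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(fraction_border=0.7, fraction_debris=0.6)
        with pytest.raises(ValueError):
            FieldSpec(fraction_border=-0.1)

    def test_debris_is_anucleate_and_below_gate(self):
        spec = FieldSpec(n_cells=10, fraction_debris=0.3, seed=9)
        _, truth = synthetic.generate_field(spec, synthetic.TABLE2_SIZE_MODELS[0])
        debris = truth.table[truth.table.is_debris]
        assert len(debris) == 3
        assert (debris.n_nuclei == 0).all()
        assert (debris.true_area < 765).all()


class TestAreaSampling:
    def test_lognormal_moment_matching(self, rng):
        model = PassageSizeModel("p", 2000.0, 700.0)
        x = synthetic.sample_areas(model, 200_000, rng)
        assert x.mean() == pytest.approx(2000, rel=0.01)
        assert x.std() == pytest.approx(700, rel=0.02)

    def test_areas_positive_and_right_skewed(self, rng):
        from scipy.stats import skew

        x = synthetic.sample_areas(PassageSizeModel("p", 1827, 329), 1000, rng)
        assert (x > 0).all()
        assert skew(x) > 0

    def test_standard_error_scaling(self):
        # convergence of the empirical mean at n = 1e2, 1e3, 1e4
        model = PassageSizeModel("p", 1827, 329)
        for i, n in enumerate([100, 1000, 10000]):
            x = synthetic.sample_areas(model, n, np.random.default_rng(300 + i))
            assert abs(x.mean() - 1827) < 5 * 329 / np.sqrt(n)


class TestPassageDataset:
    def test_record_count(self):
        records, pd_table = synthetic.generate_passage_dataset(
            synthetic.TABLE2_SIZE_MODELS, n_donors=6, cells_per_group=100, seed=0
        )
        assert len(records) == 6 * 4 * 100
        assert len(pd_table) == 24

    def test_records_satisfy_cell_invariants(self):
        records, _ = synthetic.generate_passage_dataset(
            synthetic.TABLE2_SIZE_MODELS, n_donors=2, cells_per_group=500, seed=1
        )
        assert (records.area > 0).all()
        assert (records.length >= records.width).all()
        assert (records.length_width_ratio >= 1).all()
        assert records.boxed_frame_ratio.between(0, 1, inclusive="right").all()
        assert (records.convex_hull_area_ratio >= 1).all()
        assert records.convex_hull_perimeter_ratio.between(0, 1, inclusive="right").all()
        # derived size variables are mutually consistent
        assert np.allclose(records.length * records.width * records.boxed_frame_ratio, records.area)

    def test_identical_models_rarely_rejected_by_ks(self):
        # same distribution at every passage → the passage comparison is null
        from scipy.stats import ks_2samp

        model = PassageSizeModel("pX", 2000, 400)
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            a = synthetic.sample_areas(model, 300, rng)
            b = synthetic.sample_areas(model, 300, rng)
            rejections += ks_2samp(a, b).pvalue < 0.05
        assert rejections / n_seeds <= 0.08

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_passage_dataset([], 3, 10)


class TestTRFLaneSim:
    def test_single_band_analytic_mean(self):
        assert TRFSimSpec((8.0,), (1.0,)).analytic_mean_kbp == 8.0

    def test_symmetric_bands_analytic_mean(self):
        assert TRFSimSpec((4.0, 12.0), (1.0, 1.0)).analytic_mean_kbp == 8.0

    def test_three_band_weighted_mean(self):
        # (1*3 + 2*8 + 1*20)/4 = 9.75
        assert TRFSimSpec((3.0, 8.0, 20.0), (1.0, 2.0, 1.0)).analytic_mean_kbp == 9.75

    def test_fragment_outside_ladder_rejected(self):
        with pytest.raises(ValueError, match="outside ladder range"):
            synthetic.generate_trf_lane(TRFSimSpec((25.0,), (1.0,)))

    def test_lane_determinism(self):
        spec = TRFSimSpec((5.0, 9.0), (1.0, 2.0), smear_sd=0.4, noise_sd=0.01, seed=11)
        l1 = synthetic.generate_trf_lane(spec)
        l2 = synthetic.generate_trf_lane(spec)
        assert np.array_equal(l1.od, l2.od)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TRFSimSpec((), ())
        with pytest.raises(ValueError):
            TRFSimSpec((5.0,), (-1.0,))
        with pytest.raises(ValueError):
            TRFSimSpec((-2.0,), (1.0,))


class TestMarkerPanel:
    def test_identity_target_gives_near_zero_correlations(self):
        spec = MarkerSimSpec(target_correlation=np.eye(6), n_groups=10_000, seed=3)
        panel = synthetic.generate_marker_panel(spec)
        corr = panel[synthetic.MARKER_COLUMNS].corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_two_rows_give_unit_magnitude_correlations(self):
        panel = synthetic.generate_marker_panel(MarkerSimSpec(n_groups=2, seed=4))
        corr = panel[synthetic.MARKER_COLUMNS].corr().to_numpy()
        assert np.allclose(np.abs(corr), 1.0)

    def test_target_matrix_recovered_at_large_n(self):
        panel = synthetic.generate_marker_panel(MarkerSimSpec(n_groups=5000, seed=5))
        corr = panel[synthetic.MARKER_COLUMNS].corr().to_numpy()
        assert np.abs(corr - synthetic.MARKER_CORRELATION).max() < 0.05

    def test_non_psd_target_repaired_with_warning(self):
        bad = np.eye(6)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9  # impossible triple
        with pytest.warns(UserWarning, match="not PSD"):
            panel = synthetic.generate_marker_panel(
                MarkerSimSpec(target_correlation=bad, n_groups=50, seed=6)
            )
        assert len(panel) == 50
        with pytest.raises(ValueError, match="not PSD"):
            synthetic.generate_marker_panel(
                MarkerSimSpec(target_correlation=bad, n_groups=50, seed=6, repair_non_psd=False)
            )

    def test_asymmetric_target_rejected(self):
        bad = np.eye(6)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            MarkerSimSpec(target_correlation=bad)

    def test_determinism(self):
        p1 = synthetic.generate_marker_panel(MarkerSimSpec(n_groups=100, seed=8))
        p2 = synthetic.generate_marker_panel(MarkerSimSpec(n_groups=100, seed=8))
        pd.testing.assert_frame_equal(p1, p2)
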