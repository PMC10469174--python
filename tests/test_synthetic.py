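"""Synthetic generator: tissue maps, point patterns, raters, automated
reader, detection metrics and the response cohort."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import stilkit as sk
from stilkit.synthetic import STROMA


class TestTissueMap:
    def test_realized_fractions_match_request(self):
        tmap = sk.generate_tissue_map(4000, 4000, mpp=2.0, stroma_fraction=0.4, cancer_fraction=0.3, seed=0)
        n = tmap.labels.size
        assert abs(np.count_nonzero(tmap.labels == STROMA) / n - 0.4) < 0.05
        assert abs(np.count_nonzero(tmap.labels == sk.CANCER) / n - 0.3) < 0.05
        # rank-thresholding is exact to the pixel
        assert np.count_nonzero(tmap.labels == STROMA) == round(0.4 * n)

    def test_zero_stroma_fraction_gives_empty_stroma(self):
        tmap = sk.generate_tissue_map(500, 500, mpp=2.0, stroma_fraction=0.0, cancer_fraction=0.5, seed=1)
        assert tmap.stroma_area_um2 == 0.0

    def test_same_seed_bit_identical(self):
        a = sk.generate_tissue_map(600, 600, mpp=2.0, seed=7)
        b = sk.generate_tissue_map(600, 600, mpp=2.0, seed=7)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(width_um=-1, height_um=100),
            dict(width_um=100, height_um=100, mpp=0),
            dict(width_um=100, height_um=100, stroma_fraction=0.7, cancer_fraction=0.5),
            dict(width_um=100, height_um=100, stroma_fraction=-0.1),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(sk.InvalidConfigError):
            sk.generate_tissue_map(**kwargs)

    def test_stroma_area_is_pixel_count_times_mpp_squared(self, small_map):
        n_px = int(np.count_nonzero(small_map.labels == STROMA))
        assert small_map.stroma_area_um2 == n_px * small_map.mpp**2


class TestGenerateCells:
    def test_zero_density_gives_empty_lymphoid_set(self, small_map):
        cells = sk.generate_cells(small_map, sk.IntensityConfig(base_density=0.0, tumor_density=0.0), seed=0)
        assert len(cells) == 0

    def test_homogeneous_poisson_moments(self):
        # stroma area exactly 1 mm² -> count ~ Poisson(100)
        tmap = sk.generate_tissue_map(
            1200, 1200, mpp=2.0, stroma_fraction=1.0 / 1.44, cancer_fraction=0.0, seed=3
        )
        area_mm2 = tmap.stroma_area_um2 / 1e6
        cfg = sk.IntensityConfig(base_density=100.0, heterogeneity=0.0, tumor_density=0.0)
        counts = [
            len(sk.generate_cells(tmap, cfg, seed=s)) for s in range(200)
        ]
        expected = 100.0 * area_mm2
        assert abs(np.mean(counts) - expected) < 2 * np.sqrt(expected / 200)
        assert abs(np.var(counts) - expected) < 3 * expected * np.sqrt(2 / 199)

    def test_lymphoid_points_lie_on_stroma(self, small_map, small_cells):
        lymph = small_cells[small_cells["cell_class"] == sk.LYMPHOID]
        labels = small_map.labels_at(lymph["x_um"].to_numpy(), lymph["y_um"].to_numpy())
        assert (labels == STROMA).all()

    def test_tumor_points_lie_on_cancer_area(self, small_map, small_cells):
        tum = small_cells[small_cells["cell_class"] == sk.TUMOR]
        labels = small_map.labels_at(tum["x_um"].to_numpy(), tum["y_um"].to_numpy())
        assert (labels == sk.CANCER).all()


class TestTrueStil:
    def test_no_lymphoid_cells_scores_zero(self, small_map):
        cells = sk.generate_cells(small_map, sk.IntensityConfig(base_density=0, tumor_density=1000), seed=0)
        assert sk.true_stil(small_map, cells).true_stil == 0.0

    def test_closed_form_coverage(self):
        # 500 lymphoid cells in exactly 1 mm² of stroma -> 100·π·9·500/1e6
        assert sk.coverage_percent(500, 1e6) == pytest.approx(100 * np.pi * 9 * 500 / 1e6, rel=1e-12)
        assert sk.coverage_percent(500, 1e6) == pytest.approx(1.41372, abs=1e-4)

    def test_independent_of_tumor_cells(self, small_map, small_cells):
        base = sk.true_stil(small_map, small_cells).true_stil
        doubled = pd.concat(
            [small_cells, small_cells[small_cells["cell_class"] == sk.TUMOR]], ignore_index=True
        )
        assert sk.true_stil(small_map, doubled).true_stil == base

    def test_zero_stroma_raises(self):
        tmap = sk.generate_tissue_map(300, 300, mpp=2.0, stroma_fraction=0.0, cancer_fraction=0.5, seed=0)
        with pytest.raises(sk.UndefinedScoreError):
            sk.true_stil(tmap, sk.generate_cells(tmap, sk.IntensityConfig(), seed=0))


class TestSimulateRater:
    def _noiseless(self, **kw) -> sk.RaterProfile:
        base = dict(
            rater_id="X", k_fields=1, field_size=10000.0, additive_bias=0.0,
            multiplicative_bias=1.0, noise_sd=0.0, rounding_grain=1.0,
        )
        base.update(kw)
        return sk.RaterProfile(**base)

    def test_noiseless_whole_slide_equals_truth_rounded(self, small_map, small_cells):
        truth = sk.true_stil(small_map, small_cells).true_stil
        score = sk.simulate_rater(small_map, small_cells, self._noiseless(), seed=0)
        assert score == round(truth)

    def test_additive_bias_shifts_score(self, small_map, small_cells):
        truth = sk.true_stil(small_map, small_cells).true_stil
        score = sk.simulate_rater(small_map, small_cells, self._noiseless(additive_bias=5.0), seed=0)
        assert score == pytest.approx(np.clip(round(truth + 5.0), 0, 100))

    def test_no_stroma_raises(self):
        tmap = sk.generate_tissue_map(300, 300, mpp=2.0, stroma_fraction=0.0, cancer_fraction=0.5, seed=0)
        with pytest.raises(sk.UndefinedScoreError):
            sk.simulate_rater(tmap, sk.generate_cells(tmap, sk.IntensityConfig(), seed=0), self._noiseless())

    def test_heterogeneity_inflates_inter_seed_spread(self):
        tmap = sk.generate_tissue_map(800, 800, mpp=2.0, stroma_fraction=0.4, cancer_fraction=0.3, seed=5)
        prof = sk.RaterProfile(
            rater_id="X", k_fields=4, field_size=200.0, noise_sd=0.0, rounding_grain=1.0
        )
        spreads = {}
        for het in (0.0, 2.0):
            cfg = sk.IntensityConfig(base_density=5000.0, heterogeneity=het, tumor_density=0.0)
            scores = []
            for s in range(150):
                cells = sk.generate_cells(tmap, cfg, seed=1000 + s)
                scores.append(sk.simulate_rater(tmap, cells, prof, seed=2000 + s))
            spreads[het] = np.std(scores)
        assert spreads[2.0] > spreads[0.0]


class TestSimulateDLReader:
    def test_perfect_profile_reproduces_truth(self, small_map, small_cells):
        err = sk.ReaderErrorProfile(lymphoid_recall=1.0, false_positive_rate=0.0, mask_iou_target=1.0)
        res = sk.simulate_dl_reader(small_map, small_cells, err, seed=0)
        assert len(res.detected_cells) == len(small_cells)
        assert res.realized_stroma_iou == 1.0
        expected = sk.score_slide(small_cells, small_map).score
        assert res.score == pytest.approx(expected)

    def test_half_recall_thins_lymphoid_count(self, small_map, small_cells):
        err = sk.ReaderErrorProfile(lymphoid_recall=0.5, false_positive_rate=0.0, mask_iou_target=1.0)
        n_true = int((small_cells["cell_class"] == sk.LYMPHOID).sum())
        counts = []
        for s in range(200):
            res = sk.simulate_dl_reader(small_map, small_cells, err, seed=s)
            counts.append(int((res.detected_cells["cell_class"] == sk.LYMPHOID).sum()))
        expected = 0.5 * n_true
        se = np.sqrt(n_true * 0.25 / 200)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_mask_degradation_hits_iou_target(self, small_map, small_cells):
        err = sk.ReaderErrorProfile(mask_iou_target=0.666)
        res = sk.simulate_dl_reader(small_map, small_cells, err, seed=3)
        assert 0.616 <= res.realized_stroma_iou <= 0.716
        # the metric recomputed independently agrees
        m = sk.detection_metrics(
            small_cells, res.detected_cells, truth_map=small_map, degraded_map=res.degraded_map
        )
        assert m["iou"]["cancer_stroma"] == pytest.approx(res.realized_stroma_iou)


class TestDetectionMetrics:
    def test_identity_scores_one(self, small_map, small_cells):
        m = sk.detection_metrics(small_cells, small_cells, truth_map=small_map, degraded_map=small_map)
        assert m["f1"]["lymphoid"].f1 == 1.0
        assert m["iou"]["cancer_stroma"] == 1.0

    def test_half_detected_closed_form(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1000, size=(10, 2))
        truth = pd.DataFrame({"slide_id": "s", "x_um": xy[:, 0], "y_um": xy[:, 1], "cell_class": sk.LYMPHOID})
        det = truth.iloc[:5]
        m = sk.detection_metrics(truth, det)
        stat = m["f1"]["lymphoid"]
        assert stat.precision == 1.0 and stat.recall == 0.5
        assert stat.f1 == pytest.approx(2 / 3)

    def test_disjoint_masks_iou_zero(self):
        a = sk.TissueMap(np.full((4, 4), STROMA, dtype=np.uint8), mpp=1.0)
        b = sk.TissueMap(np.zeros((4, 4), dtype=np.uint8), mpp=1.0)
        m = sk.detection_metrics(
            sk.synthetic.empty_cell_table(), sk.synthetic.empty_cell_table(), truth_map=a, degraded_map=b
        )
        assert m["iou"]["cancer_stroma"] == 0.0
        # empty truth and empty detection: F1 = 1 by convention
        assert m["f1"]["lymphoid"].f1 == 1.0


def _stil_library(rng: np.random.Generator, n: int) -> np.ndarray:
    """Stratified sTIL library: well-populated low/intermediate/high groups."""
    kind = rng.choice(3, size=n, p=(0.4, 0.3, 0.3))
    vals = np.where(
        kind == 0, rng.uniform(0, 10, n), np.where(kind == 1, rng.uniform(10, 50, n), rng.uniform(50, 100, n))
    )
    return vals


class TestGenerateCohort:
    def test_default_subtype_counts(self):
        cfg = sk.CohortConfig()
        rng = np.random.default_rng(0)
        cohort = sk.generate_cohort(cfg, _stil_library(rng, cfg.n_total), seed=1)
        counts = cohort["subtype"].value_counts()
        assert counts["HER2_positive"] == 148
        assert counts["TNBC"] == 55
        assert (cohort["responder"] == (cohort["mp_grade"] >= 4)).all()

    def test_null_model_breaks_stil_response_link(self):
        cfg = sk.CohortConfig(n_total=5000, n_her2=3650, n_tnbc=1350, beta_stil=0.0, beta_subtype=0.0)
        rng = np.random.default_rng(2)
        cohort = sk.generate_cohort(cfg, _stil_library(rng, 5000), seed=3)
        strata = [sk.stil_stratum(s) for s in cohort["true_stil"]]
        table = pd.crosstab(pd.Series(strata), cohort["responder"])
        _, p = sk.chi_square_test(table.to_numpy())
        assert p > 0.01

    def test_logistic_refit_recovers_beta_stil(self):
        # responder = 1[latent >= c4] follows an exact logistic law in sTIL/10
        cfg = sk.CohortConfig(
            n_total=5000, n_her2=3650, n_tnbc=1350, beta0=0.85, beta_stil=0.3, beta_subtype=0.2
        )
        rng = np.random.default_rng(7)
        covered = 0
        for rep in range(100):
            lib = _stil_library(rng, 5000)
            cohort = sk.generate_cohort(cfg, lib, seed=int(rng.integers(2**31)))
            X = sk.add_intercept(
                np.column_stack(
                    [cohort["true_stil"].to_numpy() / 10.0, (cohort["subtype"] == "TNBC").to_numpy(float)]
                )
            )
            fit = sk.fit_logistic(X, cohort["responder"].to_numpy(float))
            lo = fit.coef[1] - 1.96 * fit.se[1]
            hi = fit.coef[1] + 1.96 * fit.se[1]
            covered += lo <= cfg.beta_stil <= hi
        assert covered >= 90
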