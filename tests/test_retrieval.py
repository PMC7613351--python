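"""Hybrid GP retrieval: noise model, training, relevance, scenarios, cubes.

Reduced problem sizes keep the suite fast; the full-scale retrieval accuracy
checks live in the acceptance tests.
"""

import numpy as np
import pytest

from toasense.config import RunConfig
from toasense.coupling import build_lut
from toasense.retrieval import (
    add_noise,
    apply_to_cube,
    band_relevance,
    evaluate_scenarios,
    retrieve,
    soil_band_rows,
    train_retrieval,
)
from toasense.spectral import make_s2_bandset

CFG_SMALL = RunConfig(n_analysis=700, n_subset=350)
BANDS = make_s2_bandset()


@pytest.fixture(scope="module")
def toc_bands_lut():
    return build_lut("retrieval_toc", n=300, seed=5, config=CFG_SMALL, bands=BANDS)


@pytest.fixture(scope="module")
def cab_model(toc_bands_lut):
    return train_retrieval(toc_bands_lut, "Cab", seed=5, config=CFG_SMALL,
                           max_iter=80)


class TestAddNoise:
    def test_zero_level_is_identity(self, rng):
        X = rng.uniform(1, 2, size=(20, 9))
        assert np.array_equal(add_noise(X, level=0.0), X)

    def test_seed_determinism(self, rng):
        X = rng.uniform(1, 2, size=(20, 9))
        assert np.array_equal(add_noise(X, seed=3), add_noise(X, seed=3))

    def test_multiplicative_noise_is_unbiased(self):
        X = np.full((100_000, 1), 5.0)
        ratio = add_noise(X, level=0.02, seed=0) / X
        assert ratio.mean() == pytest.approx(1.0, abs=1e-3)

    def test_reflectance_clipped(self):
        X = np.full((1000, 2), 0.999)
        out = add_noise(X, level=0.5, seed=0, quantity="reflectance")
        assert np.all(out <= 1.0) and np.all(out >= 0.0)


class TestTrainRetrieval:
    def test_internal_validation_shows_skill_for_cab(self, cab_model):
        # at this reduced scale (210 training rows) the model is clearly
        # skilful; full-scale accuracy is checked in the acceptance suite
        assert cab_model.validation.r2 > 0.7

    def test_same_seed_reproduces_hyperparameters(self, toc_bands_lut):
        m1 = train_retrieval(toc_bands_lut, "Cab", seed=2, config=CFG_SMALL,
                             max_iter=40)
        m2 = train_retrieval(toc_bands_lut, "Cab", seed=2, config=CFG_SMALL,
                             max_iter=40)
        assert np.array_equal(m1.model.length_scales_, m2.model.length_scales_)

    def test_shuffled_targets_destroy_skill(self, toc_bands_lut):
        lut = toc_bands_lut.subset(np.arange(toc_bands_lut.n))
        j = lut.input_names.index("Cab")
        rng = np.random.default_rng(0)
        lut.X[:, j] = rng.permutation(lut.X[:, j])
        m = train_retrieval(lut, "Cab", seed=2, config=CFG_SMALL, max_iter=40)
        assert m.validation.r2 < 0.2

    def test_unknown_variable_rejected(self, toc_bands_lut):
        with pytest.raises(ValueError, match="bso"):
            train_retrieval(toc_bands_lut, "bso")

    def test_spectral_level_lut_rejected(self):
        lut = build_lut("retrieval_toc", n=80, seed=5, config=RunConfig(
            n_analysis=200, n_subset=100))
        with pytest.raises(ValueError, match="band level"):
            train_retrieval(lut, "Cab")


class TestBandRelevance:
    def test_synthetic_target_recovers_informative_band(self, toc_bands_lut):
        lut = toc_bands_lut.subset(np.arange(200))
        j = lut.input_names.index("Cab")
        lut.X[:, j] = np.clip(lut.Y[:, 3] * 100.0, 1.0, 70.0)  # target = band 4
        m = train_retrieval(lut, "Cab", seed=0, soils=0, noise=0.0,
                            config=CFG_SMALL, max_iter=80)
        assert band_relevance(m)[0][0] == lut.band_ids[3]

    def test_cab_model_ranks_visible_above_1610(self, cab_model):
        ranking = [b for b, _ in band_relevance(cab_model)]
        visible = {"B2", "B3", "B4", "B5"}
        assert min(ranking.index(b) for b in visible if b in ranking) < ranking.index(
            "B11"
        )


class TestRetrieve:
    def test_training_inputs_recovered(self, toc_bands_lut, cab_model):
        est, _ = retrieve(cab_model, toc_bands_lut.Y)
        y = toc_bands_lut.column("Cab")
        r2 = np.corrcoef(est, y)[0, 1] ** 2
        assert r2 > 0.9

    def test_uncertainty_grows_off_manifold(self, toc_bands_lut, cab_model):
        _, std_in = retrieve(cab_model, toc_bands_lut.Y)
        crazy = np.full((5, 9), toc_bands_lut.Y.max() * 10)
        _, std_out = retrieve(cab_model, crazy)
        assert np.all(std_out > np.median(std_in))

    def test_output_length_matches_rows(self, cab_model, toc_bands_lut):
        est, std = retrieve(cab_model, toc_bands_lut.Y[:13])
        assert est.shape == std.shape == (13,)


class TestSoilRows:
    def test_toc_and_toa_levels(self):
        toc = soil_band_rows(BANDS, level="toc", n=5, seed=1)
        toa = soil_band_rows(BANDS, level="toa", n=5, seed=1)
        assert toc.shape == toa.shape == (5, 9)
        assert np.all(toc >= 0) and np.all(toc <= 1)
        assert np.all(toa >= 0)


@pytest.fixture(scope="module")
def report():
    cfg = CFG_SMALL
    n = 200
    luts = {
        s: build_lut(s, n=n, seed=7, config=cfg, bands=BANDS)
        for s in ("retrieval_toc", "retrieval_toa", "reference_toc",
                  "reference_toa", "reference_atm")
    }
    models = {}
    for var in ("Cab", "Cw"):
        models[(var, "toc")] = train_retrieval(
            luts["retrieval_toc"], var, seed=7, config=cfg, max_iter=60
        )
        models[(var, "toa")] = train_retrieval(
            luts["retrieval_toa"], var, seed=7, config=cfg, max_iter=60
        )
    refs = {"TOC": luts["reference_toc"], "TOA": luts["reference_toa"],
            "TOC-ATM": luts["reference_atm"]}
    return evaluate_scenarios(models, refs)


class TestScenarios:
    def test_report_covers_variables_and_scenarios(self, report):
        assert set(s for _, s in report.entries) == {"TOC", "TOA", "TOC-ATM"}
        assert set(v for v, _ in report.entries) == {"Cab", "Cw"}

    def test_toc_beats_degraded_scenarios_for_cab(self, report):
        r2 = {s: report.entries[("Cab", s)].r2 for s in ("TOC", "TOA", "TOC-ATM")}
        assert r2["TOC"] >= r2["TOC-ATM"]

    def test_frame_layout(self, report):
        df = report.to_frame()
        assert df.shape == (4, 3)  # (R2, RMSE) x (Cab, Cw) rows, 3 scenarios

    def test_error_histogram(self, report):
        counts, edges = report.error_histogram("Cab", "TOC", bins=10)
        assert counts.sum() == report.errors[("Cab", "TOC")].size


class TestLaiSaturation:
    def test_deep_canopy_residuals_exceed_sparse_canopy(self):
        # canopy reflectance saturates for dense canopies, so retrieval
        # residuals in the deep regime (LAI > 5) exceed those in the sparse
        # regime (LAI < 1), where the soil-to-canopy transition is steep
        # (median over seeds)
        deep, sparse = [], []
        for seed in range(3):
            lut = build_lut("retrieval_toc", n=300, seed=seed, config=CFG_SMALL,
                            bands=BANDS)
            m = train_retrieval(lut, "LAI", seed=seed, config=CFG_SMALL,
                                max_iter=60)
            est, _ = retrieve(m, lut.Y)
            resid = np.abs(est - lut.column("LAI"))
            lai = lut.column("LAI")
            deep.append(np.median(resid[lai > 5]))
            sparse.append(np.median(resid[lai < 1]))
        assert np.median(deep) > np.median(sparse)


class TestApplyToCube:
    def test_constant_cube_gives_identical_estimates(self, cab_model, toc_bands_lut):
        row = toc_bands_lut.Y[0]
        cube = np.tile(row, (2, 2, 1))
        est, std = apply_to_cube(cab_model, cube, cab_model.band_ids)
        assert est.shape == std.shape == (2, 2)
        assert np.allclose(est, est[0, 0])

    def test_band_mismatch_names_missing_bands(self, cab_model):
        cube = np.zeros((1, 1, 9))
        with pytest.raises(ValueError, match="B12"):
            apply_to_cube(cab_model, cube, ["B2"] * 8 + ["B3"])

    def test_nan_pixels_propagate(self, cab_model, toc_bands_lut):
        cube = np.tile(toc_bands_lut.Y[0], (2, 2, 1))
        cube[0, 1, 4] = np.nan
        est, std = apply_to_cube(cab_model, cube, cab_model.band_ids)
        assert np.isnan(est[0, 1]) and np.isnan(std[0, 1])
        assert np.isfinite(est[1, 1])
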