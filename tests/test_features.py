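"""Distance/energy contrasts and similitude statistics, with brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import thermomimic as tm
from thermomimic import features as ft
from thermomimic.features import (
    build_descriptive_model,
    energy_difference,
    euclidean_distance,
    similitude_features,
)
from thermomimic.trc import DoubleExpFit


# -- independent brute-force oracles (plain loops, no shared code paths) -----

def _brute_distance(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return total**0.5 / len(a)


def _brute_energy(a, b):
    ua = [x - min(a) for x in a]
    ub = [x - min(b) for x in b]
    return sum(x * x for x in ua) - sum(x * x for x in ub)


def _brute_similitude(members, fm):
    projs, rhos, dists = [], [], []
    for fn in members:
        projs.append(sum(x * y for x, y in zip(fn, fm)))
        mean_n = sum(fn) / len(fn)
        mean_m = sum(fm) / len(fm)
        cov = sum((x - mean_m) * (y - mean_n) for x, y in zip(fm, fn)) / len(fm)
        sd_m = (sum((x - mean_m) ** 2 for x in fm) / len(fm)) ** 0.5
        sd_n = (sum((y - mean_n) ** 2 for y in fn) / len(fn)) ** 0.5
        rhos.append(cov / (sd_m * sd_n))
        dists.append(_brute_distance(fn, fm))

    def mean(v):
        return sum(v) / len(v)

    def sd(v):
        m = mean(v)
        return (sum((x - m) ** 2 for x in v) / len(v)) ** 0.5

    return {
        "proj_mean": mean(projs), "proj_sd": sd(projs),
        "rho_mean": mean(rhos), "rho_sd": sd(rhos),
        "dist_mean": mean(dists), "dist_sd": sd(dists),
    }


class TestEuclideanDistance:
    def test_identical_series_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert euclidean_distance(a, a) == 0.0

    def test_direct_formula(self):
        assert euclidean_distance(
            np.array([3.0, 0.0, 0.0, 0.0]), np.zeros(4)
        ) == pytest.approx(3.0 / 4.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(30, 2, (2, 37))
            assert euclidean_distance(a, b) == pytest.approx(
                _brute_distance(a, b), abs=1e-12
            )

    def test_metric_axioms(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c = rng.normal(0, 1, (3, 15))
            dab, dba = euclidean_distance(a, b), euclidean_distance(b, a)
            assert dab >= 0 and dab == pytest.approx(dba, abs=1e-15)
            assert euclidean_distance(a, c) <= dab + euclidean_distance(b, c) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(tm.ValidationError):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestEnergyDifference:
    def test_identical_series_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert energy_difference(a, a) == 0.0

    def test_offset_invariance_of_unbiasing(self):
        assert energy_difference(np.array([1.0, 2.0]), np.array([5.0, 6.0])) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = rng.normal(30, 2, (2, 41))
            assert energy_difference(a, b) == pytest.approx(_brute_energy(a, b), abs=1e-10)

    def test_sign_retained(self):
        big = np.array([0.0, 10.0])
        small = np.array([0.0, 1.0])
        assert energy_difference(big, small) > 0
        assert energy_difference(small, big) < 0


class TestDescriptiveModel:
    @staticmethod
    def _fit(theta):
        return DoubleExpFit(np.asarray(theta, dtype=float), 0.0, True)

    def test_single_cube_per_class(self):
        theta_m = [32.0, -3.0, -0.12, -1.0, -0.9]
        theta_b = [31.0, -2.5, -0.05, -1.0, -0.5]
        model = build_descriptive_model(
            [self._fit(theta_m)], [self._fit(theta_b)], K_IR=100, fps=2.0
        )
        t = np.arange(100) / 2.0
        expected = tm.double_exponential(theta_m, t)
        np.testing.assert_allclose(model.fM, expected / np.linalg.norm(expected), atol=1e-12)

    def test_parameters_averaged_not_curves(self):
        """Averaging θ differs from averaging curves when rates differ."""
        th1 = np.array([31.0, -2.0, -0.02, -1.0, -0.3])
        th2 = np.array([31.0, -2.0, -0.40, -1.0, -1.5])
        model = build_descriptive_model(
            [self._fit(th1), self._fit(th2)],
            [self._fit(th1)],
            K_IR=200,
            fps=2.0,
        )
        t = np.arange(200) / 2.0
        from_avg_theta = tm.double_exponential((th1 + th2) / 2, t)
        from_avg_theta /= np.linalg.norm(from_avg_theta)
        curve_avg = (tm.double_exponential(th1, t) + tm.double_exponential(th2, t)) / 2
        curve_avg /= np.linalg.norm(curve_avg)
        np.testing.assert_allclose(model.fM, from_avg_theta, atol=1e-12)
        assert np.abs(model.fM - curve_avg).max() > 1e-4

    def test_unit_norm_enforced(self):
        model = build_descriptive_model(
            [self._fit([32.0, -3.0, -0.12, -1.0, -0.9])],
            [self._fit([31.0, -2.5, -0.05, -1.0, -0.5])],
            K_IR=64,
            fps=2.0,
        )
        assert np.linalg.norm(model.fM) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(model.fB) == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(tm.ValidationError):
            build_descriptive_model([], [self._fit([31.0, -2.0, -0.05, -1.0, -0.5])], 64, 2.0)


class TestSimilitudeFeatures:
    @staticmethod
    def _model(K=60):
        curve = tm.generate_trc(np.array([31.0, -2.0, -0.05, -1.0, -0.5]), K, 2.0)
        return curve / np.linalg.norm(curve)

    def test_self_similarity(self):
        fm = self._model()
        stats = similitude_features(np.tile(fm, (10, 1)), fm)
        assert stats["proj_mean"] == pytest.approx(1.0, abs=1e-12)
        assert stats["proj_sd"] == pytest.approx(0.0, abs=1e-12)
        assert stats["rho_mean"] == pytest.approx(1.0, abs=1e-9)
        assert stats["dist_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        fm = self._model()
        stats = similitude_features(np.tile(-fm, (10, 1)), fm)
        assert stats["proj_mean"] == pytest.approx(-1.0, abs=1e-12)
        assert stats["rho_mean"] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        fm = self._model(K=25)
        members = rng.normal(0, 1, (12, 25))
        members /= np.linalg.norm(members, axis=1, keepdims=True)
        stats = similitude_features(members, fm)
        brute = _brute_similitude(members, fm)
        for key in brute:
            assert stats[key] == pytest.approx(brute[key], abs=1e-10), key

    def test_small_set_warns_but_proceeds(self):
        fm = self._model()
        with pytest.warns(UserWarning, match="similitude set"):
            stats = similitude_features(np.tile(fm, (3, 1)), fm)
        assert stats["proj_mean"] == pytest.approx(1.0)

    def test_rho_bounded(self):
        rng = np.random.default_rng(10)
        fm = self._model(K=30)
        members = rng.normal(0, 1, (40, 30))
        stats = similitude_features(members, fm)
        assert -1.0 <= stats["rho_mean"] <= 1.0


class TestExtractFeatures:
    @staticmethod
    def _pipeline(label, seed, shape=(14, 14)):
        from thermomimic import synthetic, trc as trc_mod

        scene = synthetic.SkinSceneConfig(
            shape=shape, fps_truth=2.0, duration_s=90.0, lesion_radius_px=4.0, seed=seed
        )
        record = synthetic.generate_acquisition(scene, label)
        fits = trc_mod.fit_cube(record.cube)
        lesion_fits = [fits[i, j] for (i, j) in np.argwhere(record.lesion_mask)]
        tref = trc_mod.compute_reference_temperature(lesion_fits)
        selection = trc_mod.select_trcs(fits, record.lesion_mask, tref, p=0.02)
        return record, fits, selection

    @staticmethod
    def _model_for(K, fps):
        m = DoubleExpFit(np.array([32.0, -3.0, -0.12, -1.0, -0.9]), 0.0, True)
        b = DoubleExpFit(np.array([31.5, -2.5, -0.05, -1.0, -0.5]), 0.0, True)
        return build_descriptive_model([m], [b], K, fps)

    def test_uniform_tissue_gives_near_zero_contrasts(self):
        """Lesion identical to surrounding skin: d and Ed vanish."""
        from thermomimic import synthetic, trc as trc_mod

        dist = synthetic.ThetaDistribution(
            mean=np.array([31.5, -2.5, -0.05, -1.0, -0.5]), sd=np.zeros(5)
        )
        scene = synthetic.SkinSceneConfig(
            shape=(14, 14), fps_truth=2.0, duration_s=90.0, lesion_radius_px=4.0,
            theta_benign=dist, theta_lesion_benign=dist, theta_lesion_malignant=dist,
            seed=21,
        )
        record = synthetic.generate_acquisition(scene, "benign")
        fits = trc_mod.fit_cube(record.cube)
        lesion_fits = [fits[i, j] for (i, j) in np.argwhere(record.lesion_mask)]
        tref = trc_mod.compute_reference_temperature(lesion_fits)
        selection = trc_mod.select_trcs(fits, record.lesion_mask, tref, p=0.02)
        model = self._model_for(record.cube.n_frames, record.cube.fps)
        fv = ft.extract_features(record, selection, model, fits)
        assert fv.d == pytest.approx(0.0, abs=1e-9)
        assert fv.Ed == pytest.approx(0.0, abs=1e-6)

    def test_full_vector_deterministic_across_runs(self):
        r1 = self._pipeline("MM", seed=22)
        r2 = self._pipeline("MM", seed=22)
        model = self._model_for(r1[0].cube.n_frames, r1[0].cube.fps)
        fv1 = ft.extract_features(r1[0], r1[2], model, r1[1])
        fv2 = ft.extract_features(r2[0], r2[2], model, r2[1])
        assert fv1.as_dict() == fv2.as_dict()
        assert len(fv1.similitude) == 24

    def test_selected_vector_order(self):
        record, fits, selection = self._pipeline("MM", seed=23)
        model = self._model_for(record.cube.n_frames, record.cube.fps)
        fv = ft.extract_features(record, selection, model, fits)
        np.testing.assert_allclose(
            fv.selected,
            [
                abs(fv.Ed),
                fv.similitude["rho_sd_B_L"],
                fv.similitude["proj_sd_B_N"],
                fv.similitude["dist_sd_M_N"],
            ],
        )

    def test_invariant_to_pixel_enumeration_order(self):
        record, fits, selection = self._pipeline("MM", seed=24)
        model = self._model_for(record.cube.n_frames, record.cube.fps)
        fv1 = ft.extract_features(record, selection, model, fits)
        import dataclasses as dc

        shuffled = dc.replace(
            selection,
            L_star=set(reversed(sorted(selection.L_star))),
            N_star=set(reversed(sorted(selection.N_star))),
        )
        fv2 = ft.extract_features(record, shuffled, model, fits)
        np.testing.assert_allclose(fv1.selected, fv2.selected, atol=1e-12)
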