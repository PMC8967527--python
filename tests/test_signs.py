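"""Feature extraction, univariate screening and the sign model."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nodulekit import phantom, signs
from nodulekit.volio import CTVolume


def _uniform_sphere_volume(d_mm=8.0, hu=20.0, bg=-850.0):
    shape = (32, 32, 32)
    mask = phantom.sphere_mask(shape, (16, 16, 16), d_mm / 2, (1, 1, 1))
    vox = np.full(shape, bg, np.float32)
    vox[mask] = hu
    return CTVolume(vox, (1, 1, 1)), mask


class TestExtraction:
    def test_uniform_sphere_has_zero_variance_and_entropy(self):
        vol, mask = _uniform_sphere_volume()
        f = signs.extract_features(vol, mask)
        assert f["fo_variance"] == 0.0
        assert f["fo_entropy"] == 0.0
        assert f["fo_mean"] == 20.0
        assert not any(np.isnan(v) for v in f.values())

    def test_sphere_sphericity_near_ideal(self):
        vol, mask = _uniform_sphere_volume()
        f = signs.extract_features(vol, mask)
        assert f["sphericity"] >= 0.9
        assert abs(f["equivalent_diameter_mm"] - 8.0) < 1.0

    def test_spiculated_less_spherical_than_smooth_twin(self):
        vol, mask = _uniform_sphere_volume()
        spik = phantom.spiculate_boundary(mask, 8, 3.0, (1, 1, 1), seed=4)
        f_smooth = signs.extract_features(vol, mask)
        f_spik = signs.extract_features(vol, spik)
        assert f_spik["sphericity"] < f_smooth["sphericity"]
        assert (f_spik["axial_radial_var"] > f_smooth["axial_radial_var"])

    def test_translation_invariance(self):
        shape = (40, 40, 40)
        vox = np.full(shape, -850.0, np.float32)
        feats = []
        for c in ((14, 14, 14), (24, 22, 20)):
            mask = phantom.sphere_mask(shape, c, 3.5, (1, 1, 1))
            v = vox.copy()
            v[mask] = 20.0
            feats.append(signs.extract_features(CTVolume(v, (1, 1, 1)), mask))
        for k in feats[0]:
            assert abs(feats[0][k] - feats[1][k]) < 1e-9, k

    def test_single_voxel_candidate_rejected(self):
        vol, _ = _uniform_sphere_volume()
        m = np.zeros(vol.shape, bool)
        m[16, 16, 16] = True
        with pytest.raises(ValueError, match="degenerate"):
            signs.extract_features(vol, m)


class TestScreening:
    def test_zero_effect_feature_not_retained(self, rng):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"null": rng.standard_normal(40),
                          "same": np.tile([1.0, 2.0], 20)})
        kept = signs.screen_features(X, y, alpha=0.05)
        assert "same" not in kept

    def test_overwhelming_effect_retained(self, rng):
        y = np.repeat([0, 1], 20)
        x = rng.standard_normal(40)
        x[y == 1] += 10.0
        X = pd.DataFrame({"strong": x})
        assert signs.screen_features(X, y) == ["strong"]

    def test_constant_feature_warns_not_raises(self):
        y = np.repeat([0, 1], 3)
        X = pd.DataFrame({"const": np.ones(6)})
        with pytest.warns(UserWarning, match="constant"):
            assert signs.screen_features(X, y) == []

    def test_categorical_goes_through_chi_square(self, rng):
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame({"flag": (y == 1)})  # perfectly associated boolean
        assert signs.screen_features(X, y) == ["flag"]

    def test_type_one_error_rate_near_alpha(self):
        """1000 null features at α=0.05 retain ≈5% (Monte-Carlo check)."""
        r = np.random.default_rng(17)
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame(r.standard_normal((40, 1000)),
                         columns=[f"f{i}" for i in range(1000)])
        kept = signs.screen_features(X, y, alpha=0.05)
        assert abs(len(kept) / 1000 - 0.05) < 0.015

    def test_monotone_in_alpha(self, rng):
        y = np.repeat([0, 1], 15)
        X = pd.DataFrame(rng.standard_normal((30, 30)),
                         columns=[f"f{i}" for i in range(30)])
        X["inf"] = y + 0.3 * rng.standard_normal(30)
        loose = set(signs.screen_features(X, y, alpha=0.2))
        tight = set(signs.screen_features(X, y, alpha=0.01))
        assert tight <= loose


class TestSignModel:
    def test_perfectly_separable_data(self, rng):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({
            "gap": y * 10.0 + rng.standard_normal(40) * 0.1,
            "noise": rng.standard_normal(40),
        })
        res = signs.SpiculationSignModel(X, y).fit(folds=5, seed=0,
                                                   n_alphas=10)
        assert res.sen == 100.0 and res.spe == 100.0
        assert "gap" in res.selected

    def test_summary_mentions_cv_scores(self, rng):
        y = np.repeat([0, 1], 15)
        X = pd.DataFrame({"a": y + 0.2 * rng.standard_normal(30),
                          "b": rng.standard_normal(30)})
        res = signs.SpiculationSignModel(X, y).fit(folds=5, seed=1,
                                                   n_alphas=10)
        text = res.summary()
        assert "SEN" in text and "LASSO" in text
        assert len(res.cv_table) == 5

    def test_no_surviving_features_instructs_relaxing_alpha(self, rng):
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"n1": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="alpha"):
            signs.SpiculationSignModel(X, y, alpha=1e-12).fit(folds=3)

    def test_informative_features_recovered(self):
        """Logistic data, 3 informative + 17 noise: the screen+LASSO path
        keeps a superset of the informative set in ≥80% of replicates."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(100 + rep)
            X = pd.DataFrame(r.standard_normal((200, 20)),
                             columns=[f"f{i}" for i in range(20)])
            logit = 3.0 * X["f0"] - 3.0 * X["f1"] + 2.5 * X["f2"]
            y = (r.random(200) < 1 / (1 + np.exp(-logit))).astype(int)
            model = signs.SpiculationSignModel(X, y)
            selected = model.select_features(folds=5, seed=rep, n_alphas=20)
            hits += {"f0", "f1", "f2"} <= set(selected)
        assert hits >= 0.8 * n_rep

    def test_serialization_round_trip(self, rng, tmp_path):
        y = np.repeat([0, 1], 15)
        X = pd.DataFrame({"a": y + 0.1 * rng.standard_normal(30),
                          "b": rng.standard_normal(30)})
        res = signs.SpiculationSignModel(X, y).fit(folds=3, seed=0,
                                                   n_alphas=5)
        p = tmp_path / "model.json"
        res.save(p)
        back = signs.load_sign_model(p)
        np.testing.assert_allclose(back.predict_proba(X),
                                   res.predict_proba(X), atol=1e-12)


class TestFusion:
    @pytest.mark.parametrize("decisions,expected", [
        ((False, False, False), False),
        ((True, False, False), True),
        ((False, True, False), True),
        ((True, True, True), True),
    ])
    def test_or_rule(self, decisions, expected):
        assert signs.fuse_sign_decisions(decisions) is expected

    def test_monotone(self):
        for base in ([False, False, False], [True, False, False]):
            for i in range(3):
                flipped = list(base)
                flipped[i] = True
                assert (signs.fuse_sign_decisions(flipped)
                        >= signs.fuse_sign_decisions(base))

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            signs.fuse_sign_decisions([True, False])
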