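import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from oracles import permanova_f_brute
from rhythmomics.compositional import clr_transform
from rhythmomics.errors import InputError
from rhythmomics.simulate import SyntheticSpec, generate_dataset
from rhythmomics.structure import cage_means, cage_sensitivity, pca_scores, permanova


def _random_distance(rng, n):
    points = rng.normal(size=(n, 3))
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"u{i}" for i in range(n)])


class TestCageMeans:
    def _clr_and_meta(self, study_dataset):
        from rhythmomics.compositional import replace_zeros

        _, features, metadata, _ = study_dataset
        return clr_transform(replace_zeros(features)), metadata

    def test_unit_means_and_zero_sum(self, study_dataset):
        clr, meta = self._clr_and_meta(study_dataset)
        agg, units = cage_means(clr, meta)
        assert len(units) == units["unit_id"].nunique() == agg.shape[1]
        np.testing.assert_allclose(agg.sum(axis=0), 0.0, atol=1e-9)
        # spot-check one unit against the hand mean of its member samples
        unit = units.iloc[0]
        members = meta[(meta["cage_id"] == unit["cage_id"]) & (meta["zt_h"] == unit["zt_h"])]
        np.testing.assert_allclose(
            agg[unit["unit_id"]].to_numpy(),
            clr[members["sample_id"]].to_numpy().mean(axis=1),
            atol=1e-12,
        )

    def test_two_sample_mean_and_singleton_passthrough(self):
        clr = pd.DataFrame(
            [[1.0, 3.0, 5.0], [-1.0, -3.0, -5.0]],
            index=["f1", "f2"], columns=["s1", "s2", "s3"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "zt_h": [5.0, 5.0, 11.0],
                "group": ["CV", "CV", "CV"],
                "cage_id": ["c1", "c1", "c2"],
                "animal_id": ["a1", "a2", "a3"],
            }
        )
        agg, units = cage_means(clr, meta)
        assert agg.loc["f1", "c1@ZT5"] == pytest.approx(2.0)
        assert agg.loc["f1", "c2@ZT11"] == pytest.approx(5.0)  # mean of one

    def test_cage_straddling_groups_rejected(self):
        clr = pd.DataFrame([[0.0, 0.0]], index=["f1"], columns=["s1", "s2"])
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"], "zt_h": [5.0, 5.0],
                "group": ["CV", "ABX"], "cage_id": ["c1", "c1"],
                "animal_id": ["a1", "a2"],
            }
        )
        with pytest.raises(InputError, match="straddle"):
            cage_means(clr, meta)

    def test_sample_order_invariance(self, study_dataset):
        clr, meta = self._clr_and_meta(study_dataset)
        shuffled = clr.sample(frac=1.0, axis=1, random_state=1)
        a1, _ = cage_means(clr, meta)
        a2, _ = cage_means(shuffled, meta)
        pd.testing.assert_frame_equal(a1, a2)


class TestPermanova:
    def test_pseudo_f_matches_brute_force(self, rng):
        for trial in range(5):
            dm = _random_distance(rng, 8)
            labels = np.array(["A", "A", "A", "B", "B", "B", "B", "A"])
            res = permanova(dm, labels, n_perm=99, seed=trial)
            f_brute, r2_brute = permanova_f_brute(dm.data, labels)
            assert res.pseudo_f == pytest.approx(f_brute, abs=1e-10)
            assert res.r_squared == pytest.approx(r2_brute, abs=1e-10)

    def test_pseudo_f_matches_skbio(self, rng):
        dm = _random_distance(rng, 12)
        labels = np.array(["A"] * 6 + ["B"] * 6)
        res = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), abs=1e-10)

    def test_exhaustive_two_plus_two(self, rng):
        dm = _random_distance(rng, 4)
        res = permanova(dm, np.array(["A", "A", "B", "B"]), n_perm=999, seed=0)
        assert res.exhaustive
        assert res.n_perm == 6  # C(4,2) distinct assignments
        assert res.p_perm in {i / 6 for i in range(1, 7)}

    def test_perfect_separation(self):
        points = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0]])
        d = np.abs(points - points.T)
        dm = DistanceMatrix(d, ids=[f"u{i}" for i in range(6)])
        res = permanova(dm, np.array(["A"] * 3 + ["B"] * 3), n_perm=999, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        # 20 labeled assignments; only the observed one and its A/B swap
        # reach the observed F, so the enumerated minimum is 2/20
        assert res.exhaustive and res.p_perm == pytest.approx(2 / 20)

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        """16 units, 2 groups: MC p within 3 SE of the enumerated p."""
        dm = _random_distance(rng, 16)
        labels = np.array(["A"] * 8 + ["B"] * 8)
        exact = permanova(dm, labels, n_perm=13000, seed=0)  # C(16,8)=12870 -> exhaustive
        assert exact.exhaustive
        mc = permanova(dm, labels, n_perm=2000, seed=1)
        assert not mc.exhaustive
        se = np.sqrt(exact.p_perm * (1 - exact.p_perm) / 2000)
        assert abs(mc.p_perm - exact.p_perm) <= 3 * se + 1e-3

    def test_small_group_rejected(self, rng):
        dm = _random_distance(rng, 4)
        with pytest.raises(InputError):
            permanova(dm, np.array(["A", "B", "B", "B"]), n_perm=99, seed=0)


class TestPCA:
    def test_duplicated_samples_identical_scores(self, rng):
        base = rng.normal(size=(10, 1))
        clr = pd.DataFrame(
            np.hstack([base, base, rng.normal(size=(10, 3))]),
            index=[f"f{i}" for i in range(10)],
            columns=["dup1", "dup2", "s3", "s4", "s5"],
        )
        scores, ratios = pca_scores(clr, n_components=2)
        np.testing.assert_allclose(
            scores.loc["dup1"].to_numpy(), scores.loc["dup2"].to_numpy(), atol=1e-9
        )
        assert (np.diff(ratios) <= 1e-12).all()
        assert ratios.sum() <= 1.0 + 1e-12

    def test_full_rank_scores_preserve_distances(self, rng):
        clr = pd.DataFrame(rng.normal(size=(12, 6)),
                           columns=[f"s{j}" for j in range(6)])
        scores, _ = pca_scores(clr, n_components=5)
        X = clr.to_numpy().T
        Xc = X - X.mean(axis=0)
        orig = np.sqrt(((Xc[:, None] - Xc[None]) ** 2).sum(-1))
        s = scores.to_numpy()
        rotated = np.sqrt(((s[:, None] - s[None]) ** 2).sum(-1))
        np.testing.assert_allclose(orig, rotated, atol=1e-9)

    def test_three_sample_toy_matches_eigen_oracle(self):
        clr = pd.DataFrame(
            np.array([[0.0, 3.0, 6.0], [0.1, 0.0, -0.1], [-0.1, -3.0, -5.9]]),
            columns=["s1", "s2", "s3"],
        )
        _, ratios = pca_scores(clr, n_components=2)
        X = clr.to_numpy().T
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        expected = eigvals[0] / eigvals[eigvals > 1e-12].sum()
        assert ratios[0] == pytest.approx(expected, abs=1e-9)

    def test_rank_truncation_warns(self, rng):
        clr = pd.DataFrame(rng.normal(size=(8, 3)), columns=["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="truncat"):
            scores, ratios = pca_scores(clr, n_components=6)
        assert scores.shape[1] == 2


class TestCageSensitivity:
    def _feature(self, sigma_cage, cage_size=4, seed=2):
        spec = SyntheticSpec(
            n_features=10, frac_rhythmic=1.0, frac_shifted=0.5,
            amplitude_log=1.0, sigma_noise=0.3, sigma_cage=sigma_cage,
            cage_size=cage_size, zero_rate=0.0, seed=seed,
        )
        features, metadata, _ = generate_dataset(spec)
        clr = clr_transform(features)
        return clr.iloc[0].to_numpy(), metadata

    def test_zero_cage_variance_limit(self):
        y, meta = self._feature(sigma_cage=0.0)
        res = cage_sensitivity(y, meta)
        assert res.converged
        for name in res.ols_coef:
            assert res.abs_diff[name] < 0.05

    def test_balanced_equal_cages_coincide_exactly(self):
        """Equal cage sizes nested in group x time cells: every fixed-effect
        column is cage-constant, so REML and OLS point estimates coincide."""
        y, meta = self._feature(sigma_cage=0.5, cage_size=4)
        sizes = meta.groupby("cage_id").size()
        assert sizes.nunique() == 1  # 8 animals per cell in cages of 4
        res = cage_sensitivity(y, meta)
        for name in res.ols_coef:
            assert res.abs_diff[name] < 1e-5

    def test_large_cage_effect_report_is_finite(self):
        y, meta = self._feature(sigma_cage=1.0, cage_size=3)
        res = cage_sensitivity(y, meta)
        assert np.isfinite(list(res.ols_coef.values())).all()
        assert np.isfinite(list(res.mixed_coef.values())).all() or not res.converged

    def test_requires_two_cages_per_group(self):
        y = np.zeros(8)
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "zt_h": [5.0, 11.0, 17.0, 23.0] * 2,
                "group": ["CV"] * 4 + ["ABX"] * 4,
                "cage_id": ["c1"] * 4 + ["c2"] * 4,
                "animal_id": [f"a{i}" for i in range(8)],
            }
        )
        with pytest.raises(InputError):
            cage_sensitivity(y, meta)
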