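import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import bh_stepup_brute
from rhythmomics.cosinor import build_design
from rhythmomics.differential import (
    amplitude_difference_table,
    amplitude_difference_test,
    bh_adjust,
    combine_components,
    differential_rhythmicity,
    differential_table,
    select_features,
)
from rhythmomics.errors import InputError

ZT = np.array([5.0, 11.0, 17.0, 23.0])


def _two_group_design(reps=2):
    times = np.tile(ZT, 2 * reps)
    groups = np.array(["CV"] * 4 * reps + ["ABX"] * 4 * reps)
    return times, groups, build_design(times, groups)


def _cosine(times, amplitude, acrophase, period=24.0):
    return amplitude * np.cos(2 * np.pi * (times - acrophase) / period)


class TestCombineComponents:
    @pytest.mark.parametrize(
        "p_sin, p_cos, expected",
        [(0.01, 0.5, 0.02), (0.9, 0.8, 1.0), (0.03, 0.04, 0.06)],
    )
    def test_min_bonferroni(self, p_sin, p_cos, expected):
        assert combine_components(p_sin, p_cos) == pytest.approx(expected)

    def test_symmetric_and_never_decreasing(self, rng):
        p = rng.random((2, 500))
        q = combine_components(p[0], p[1])
        np.testing.assert_allclose(q, combine_components(p[1], p[0]))
        assert (q >= np.minimum(p[0], p[1]) - 1e-15).all()
        assert (q <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            combine_components(1.2, 0.5)


class TestBHAdjust:
    def test_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    @pytest.mark.parametrize("p, q", [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.37], [0.37])])
    def test_edge_cases(self, p, q):
        np.testing.assert_allclose(bh_adjust(p), q)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_brute_force_stepup(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_brute(p), atol=1e-12)

    def test_select_is_strict(self):
        flags = select_features([0.05, 0.1, 0.2], threshold=0.1)
        np.testing.assert_array_equal(flags, [True, False, False])


class TestInteractionContrasts:
    def test_noiseless_antiphase_pair(self):
        """12 h shift at equal amplitude flips both harmonic coefficients;
        with acrophase 0 the cosine component carries the contrast."""
        times, groups, design = _two_group_design()
        y = np.where(groups == "CV", _cosine(times, 1.0, 0.0), _cosine(times, 1.0, 12.0))
        res = differential_rhythmicity(y, design, ("CV", "ABX"))
        assert res.p_cos == 0.0  # degenerate noiseless limit
        assert res.degenerate
        # beta_cos is +1 in CV and -1 in ABX: recovered from per-group fits
        from rhythmomics.cosinor import fit_cosinor

        fits = {f.group: f for f in fit_cosinor(y, design)}
        assert fits["CV"].beta_cos == pytest.approx(1.0, abs=1e-10)
        assert fits["ABX"].beta_cos == pytest.approx(-1.0, abs=1e-10)

    def test_two_group_tukey_is_identity(self, rng):
        """With k=2 the Tukey-adjusted contrast p equals the plain t-test p."""
        times, groups, design = _two_group_design()
        y = rng.normal(size=len(times))
        res = differential_rhythmicity(y, design, ("CV", "ABX"))
        # independent oracle: explicit OLS contrast t-test
        X, cols = design.X, {c: i for i, c in enumerate(design.columns)}
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.inv(X.T @ X)
        for comp, observed in (("sin", res.p_sin), ("cos", res.p_cos)):
            c = np.zeros(X.shape[1])
            c[cols[f"CV:{comp}"]] = 1.0
            c[cols[f"ABX:{comp}"]] = -1.0
            t = c @ beta / np.sqrt(sigma2 * c @ XtX_inv @ c)
            assert observed == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-12)

    def test_three_group_tukey_never_smaller(self, rng):
        times = np.tile(ZT, 6)
        groups = np.array(["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        design = build_design(times, groups)
        y = rng.normal(size=len(times))
        res = differential_rhythmicity(y, design, ("A", "B"))
        X = design.X
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.inv(X.T @ X)
        cols = {c: i for i, c in enumerate(design.columns)}
        for comp, observed in (("sin", res.p_sin), ("cos", res.p_cos)):
            c = np.zeros(X.shape[1])
            c[cols[f"A:{comp}"]] = 1.0
            c[cols[f"B:{comp}"]] = -1.0
            t = c @ beta / np.sqrt(sigma2 * c @ XtX_inv @ c)
            assert observed >= 2 * stats.t.sf(abs(t), df) - 1e-12

    def test_missing_group_rejected(self, rng):
        _, _, design = _two_group_design()
        with pytest.raises(InputError):
            differential_rhythmicity(rng.normal(size=16), design, ("CV", "GF"))

    def test_null_interaction_pvalues_uniform(self, rng):
        """10,000 features with identical groups: p_sin and p_cos are U(0,1)."""
        times, groups, design = _two_group_design(reps=2)
        clr = pd.DataFrame(rng.normal(size=(10_000, len(times))),
                           index=[f"f{i}" for i in range(10_000)],
                           columns=[f"s{j}" for j in range(len(times))])
        table = differential_table(clr, design, ("CV", "ABX"))
        for col in ("p_sin", "p_cos"):
            assert stats.kstest(table[col], "uniform").statistic < 0.02

    def test_shift_effect_is_monotone_on_noiseless_grid(self):
        """The interaction contrast magnitude grows with the acrophase shift
        and peaks at half a period (2A sin(pi*shift/P))."""
        times, groups, design = _two_group_design()
        sizes = []
        for shift in (0.0, 3.0, 6.0, 12.0):
            y = np.where(
                groups == "CV", _cosine(times, 1.0, 2.0), _cosine(times, 1.0, 2.0 + shift)
            )
            from rhythmomics.cosinor import fit_cosinor

            fits = {f.group: f for f in fit_cosinor(y, design)}
            delta = np.hypot(
                fits["CV"].beta_sin - fits["ABX"].beta_sin,
                fits["CV"].beta_cos - fits["ABX"].beta_cos,
            )
            expected = 2.0 * np.sin(np.pi * shift / 24.0)
            assert delta == pytest.approx(expected, abs=1e-9)
            sizes.append(delta)
        assert all(a <= b + 1e-12 for a, b in zip(sizes, sizes[1:]))


class TestAmplitudePermutation:
    def test_noiseless_amplitude_gap_hits_floor(self):
        times, groups, design = _two_group_design()
        y = np.where(groups == "CV", _cosine(times, 2.0, 3.0), _cosine(times, 0.1, 3.0))
        p = amplitude_difference_test(y, design, ("CV", "ABX"), n_perm=999, seed=1)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_add_one_floor_and_bounds(self, rng):
        times, groups, design = _two_group_design()
        y = rng.normal(size=len(times))
        p = amplitude_difference_test(y, design, ("CV", "ABX"), n_perm=99, seed=0)
        assert 1.0 / 100.0 <= p <= 1.0

    def test_requires_enough_permutations_and_samples(self, rng):
        times, groups, design = _two_group_design()
        with pytest.raises(InputError):
            amplitude_difference_test(rng.normal(size=16), design, ("CV", "ABX"), n_perm=10)
        lone = build_design(np.array([5.0, 11.0, 17.0, 23.0, 5.0, 11.0, 17.0]),
                            np.array(["CV"] * 4 + ["ABX"] * 3))
        with pytest.raises(InputError):
            amplitude_difference_test(rng.normal(size=7), lone, ("CV", "ABX"), n_perm=99)

    def test_cage_blocks_travel_together(self, rng):
        """Blocked permutations keep cage-mates on the same group label."""
        from rhythmomics.differential import _strata_permutations

        from rhythmomics.simulate import SyntheticSpec, generate_dataset

        _, meta, _ = generate_dataset(SyntheticSpec(n_features=2, n_per_cell=4, cage_size=2, seed=0))
        times = meta["zt_h"].to_numpy()
        groups = meta["group"].to_numpy()
        cages = meta["cage_id"].to_numpy()
        perms = _strata_permutations(groups, times, 50, np.random.default_rng(0), blocks=cages)
        for row in perms:
            frame = pd.DataFrame({"cage": cages, "label": row})
            assert frame.groupby("cage")["label"].nunique().max() == 1

    def test_identical_groups_pvalues_not_concentrated(self, rng):
        """Exchangeable groups: permutation p's spread over (0, 1]."""
        times, groups, design = _two_group_design()
        clr = pd.DataFrame(rng.normal(size=(200, len(times))),
                           index=[f"f{i}" for i in range(200)],
                           columns=range(len(times)))
        table = amplitude_difference_table(clr, design, ("CV", "ABX"), n_perm=199, seed=3)
        p = table["amplitude_p"]
        assert (p <= 0.05).mean() <= 0.1  # near-nominal small-p mass
        assert p.mean() == pytest.approx(0.5, abs=0.1)
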