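"""Between-group differential-rhythmicity testing.

A rhythm difference between two groups shows up as a difference in the
sine and/or cosine coefficients of the shared-period cosinor. Each pairwise
comparison tests the two interaction contrasts (group difference in
``beta_sin`` and in ``beta_cos``) with t-statistics from the pooled
full-interaction OLS model; with three or more groups every contrast is
Tukey-adjusted over the k(k-1)/2 pairs via the studentized range
distribution (for k = 2 the Tukey adjustment reduces exactly to the
ordinary two-sided t-test).

Per feature, the two component p-values are Bonferroni-corrected (x2) and
the smaller corrected value is reported as the feature's differential-
rhythmicity measure; features are then selected across the panel by
Benjamini-Hochberg at q < 0.1 (strict). An optional stratified permutation
test compares fitted amplitudes directly, operationalising "the amplitudes
did not change" as a testable statement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import DesignMatrix
from .errors import InputError

__all__ = [
    "DifferentialResult",
    "differential_rhythmicity",
    "differential_table",
    "combine_components",
    "bh_adjust",
    "select_features",
    "amplitude_difference_test",
    "amplitude_difference_table",
]


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    group_a: str
    group_b: str
    p_sin: float
    p_cos: float
    q_component: float
    q_bh: float | None  # filled once the across-feature BH pass has run
    is_differential: bool | None
    degenerate: bool = False


def _pair_levels(design: DesignMatrix, pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    for g in (a, b):
        if g not in design.group_levels:
            raise InputError(f"group {g!r} not present in design")
    if a == b:
        raise InputError("pair must name two distinct groups")
    return a, b


def _interaction_pvalues(
    Y: np.ndarray, design: DesignMatrix, pair: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-model contrast tests for group differences in beta_sin/beta_cos.

    ``Y`` is features x samples; returns (p_sin, p_cos, degenerate) arrays.
    """
    a, b = _pair_levels(design, pair)
    k = len(design.group_levels)
    if k < 2:
        raise InputError("differential testing needs at least two groups")
    X = design.X
    n, p = X.shape
    df = n - p
    if df < 1:
        raise InputError("no residual degrees of freedom in pooled model")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # p x features
    resid = Y.T - X @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    degenerate = sigma2 <= 1e-12 * np.maximum(np.sum(Y.T**2, axis=0) / n, 1.0)

    cols = {name: i for i, name in enumerate(design.columns)}
    pvals = []
    for comp in ("sin", "cos"):
        contrast = np.zeros(p)
        contrast[cols[f"{a}:{comp}"]] = 1.0
        contrast[cols[f"{b}:{comp}"]] = -1.0
        est = contrast @ beta
        var_unit = float(contrast @ XtX_inv @ contrast)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(sigma2 * var_unit)
        t = np.where(np.isfinite(t), t, np.sign(est) * np.inf)
        if k == 2:
            p_comp = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            p_comp = stats.studentized_range.sf(np.abs(t) * np.sqrt(2.0), k, df)
        # exact zero residuals with a nonzero contrast -> limiting p of 0
        p_comp = np.where(degenerate & (np.abs(est) > 0), 0.0, p_comp)
        p_comp = np.where(degenerate & (np.abs(est) == 0), 1.0, p_comp)
        pvals.append(np.clip(p_comp, 0.0, 1.0))
    return pvals[0], pvals[1], degenerate


def differential_rhythmicity(
    y: Sequence[float],
    design: DesignMatrix,
    pair: Sequence[str],
    feature_id: str = "feature",
) -> DifferentialResult:
    """Pairwise differential-rhythmicity test for a single feature.

    ``q_bh`` and ``is_differential`` are None here: BH selection is defined
    across a feature panel (see :func:`differential_table`).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_samples,):
        raise InputError("y length does not match design")
    p_sin, p_cos, degenerate = _interaction_pvalues(y[None, :], design, pair)
    a, b = _pair_levels(design, pair)
    return DifferentialResult(
        feature_id=feature_id,
        group_a=a,
        group_b=b,
        p_sin=float(p_sin[0]),
        p_cos=float(p_cos[0]),
        q_component=float(combine_components(p_sin[0], p_cos[0])),
        q_bh=None,
        is_differential=None,
        degenerate=bool(degenerate[0]),
    )


def combine_components(p_sin, p_cos):
    """Bonferroni across the two harmonic components, keeping the minimum.

    ``q = min(min(2*p_sin, 1), min(2*p_cos, 1))``; symmetric in its
    arguments and never below ``min(p_sin, p_cos)``. Vectorised.
    """
    p_sin = np.asarray(p_sin, dtype=float)
    p_cos = np.asarray(p_cos, dtype=float)
    if ((p_sin < 0) | (p_sin > 1) | (p_cos < 0) | (p_cos > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    q = np.minimum(np.minimum(2.0 * p_sin, 1.0), np.minimum(2.0 * p_cos, 1.0))
    return float(q) if q.ndim == 0 else q


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(qvals: Sequence[float], threshold: float = 0.1) -> np.ndarray:
    """Boolean flags for q strictly below the FDR threshold."""
    q = np.asarray(qvals, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise InputError("q-values must lie in [0, 1]")
    return q < threshold


def differential_table(
    clr: pd.DataFrame,
    design: DesignMatrix,
    pair: Sequence[str],
    threshold: float = 0.1,
    correction_order: str = "bonferroni_then_bh",
) -> pd.DataFrame:
    """Panel-wide pairwise differential rhythmicity with BH selection.

    ``correction_order`` controls how the per-feature component Bonferroni
    and the across-feature BH pass compose:

    - ``"bonferroni_then_bh"`` (default): q_component = min Bonferroni-
      corrected component p per feature, then BH across features on
      q_component.
    - ``"bh_then_bonferroni"``: BH across features within each component,
      then the per-feature min of the two Bonferroni-doubled BH values.
    """
    if correction_order not in ("bonferroni_then_bh", "bh_then_bonferroni"):
        raise InputError(f"unknown correction_order {correction_order!r}")
    Y = clr.to_numpy(dtype=float)
    p_sin, p_cos, degenerate = _interaction_pvalues(Y, design, pair)
    q_component = combine_components(p_sin, p_cos)
    if correction_order == "bonferroni_then_bh":
        q_bh = bh_adjust(q_component)
    else:
        q_bh = np.minimum(
            np.minimum(2.0 * bh_adjust(p_sin), 1.0),
            np.minimum(2.0 * bh_adjust(p_cos), 1.0),
        )
    a, b = _pair_levels(design, pair)
    return pd.DataFrame(
        {
            "feature_id": clr.index,
            "group_a": a,
            "group_b": b,
            "p_sin": p_sin,
            "p_cos": p_cos,
            "q_component": q_component,
            "q_bh": q_bh,
            "is_differential": select_features(q_bh, threshold),
            "degenerate": degenerate,
        }
    )


def _strata_permutations(
    labels: np.ndarray,
    strata: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    blocks: np.ndarray | None = None,
) -> np.ndarray:
    """n_perm label vectors, each permuted independently within every stratum.

    With ``blocks`` (e.g. cage ids), whole blocks exchange labels inside a
    stratum instead of individual samples, preserving within-block
    correlation under the null.
    """
    perms = np.tile(labels, (n_perm, 1))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if idx.size < 2:
            raise InputError(f"stratum {s!r} has fewer than 2 samples")
        if blocks is None:
            for r in range(n_perm):
                perms[r, idx] = perms[r, idx[rng.permutation(idx.size)]]
            continue
        stratum_blocks = blocks[idx]
        uniq = np.unique(stratum_blocks)
        if uniq.size < 2:
            raise InputError(f"stratum {s!r} has fewer than 2 blocks")
        block_label = {b: labels[idx[stratum_blocks == b][0]] for b in uniq}
        member_rows = {b: idx[stratum_blocks == b] for b in uniq}
        base = np.array([block_label[b] for b in uniq])
        for r in range(n_perm):
            shuffled = base[rng.permutation(uniq.size)]
            for b, lab in zip(uniq, shuffled):
                perms[r, member_rows[b]] = lab
    return perms


def _group_amplitudes(Y: np.ndarray, X3: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Fitted cosinor amplitude per feature on a sample subset."""
    beta, *_ = np.linalg.lstsq(X3[rows], Y[:, rows].T, rcond=None)
    return np.hypot(beta[1], beta[2])


def amplitude_difference_table(
    clr: pd.DataFrame,
    design: DesignMatrix,
    pair: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    blocks: Sequence | None = None,
) -> pd.DataFrame:
    """Stratified permutation test of |A_a - A_b| for every feature.

    Group labels are permuted within timepoint strata (preserving the
    sampling design); when ``blocks`` (cage ids aligned with the design
    rows) are given, whole cages exchange group labels instead of
    individual animals, so shared-housing correlation survives into the
    permutation null. The permutation set is shared across features. The
    p-value uses the add-one estimator, so it is never below
    ``1/(1 + n_perm)``; that minimum is attained whenever the observed
    statistic strictly exceeds every permuted one (a re-drawn labeling that
    merely reproduces the observed grouping, hence its exact statistic,
    does not count as an exceedance).
    """
    if n_perm < 99:
        raise InputError("n_perm must be at least 99")
    a, b = _pair_levels(design, pair)
    in_pair = np.isin(design.group_labels, [a, b])
    labels = design.group_labels[in_pair]
    times = design.times_h[in_pair]
    block_arr = None
    if blocks is not None:
        block_arr = np.asarray(blocks)
        if block_arr.shape != design.group_labels.shape:
            raise InputError("blocks must align with the design rows")
        block_arr = block_arr[in_pair]
    Y = clr.to_numpy(dtype=float)[:, in_pair]
    omega = 2.0 * np.pi / design.period_h
    X3 = np.column_stack([np.ones(times.size), np.sin(omega * times), np.cos(omega * times)])

    def stat(lbl: np.ndarray) -> np.ndarray:
        amp_a = _group_amplitudes(Y, X3, np.flatnonzero(lbl == a))
        amp_b = _group_amplitudes(Y, X3, np.flatnonzero(lbl == b))
        return np.abs(amp_a - amp_b)

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    perms = _strata_permutations(labels, times, n_perm, rng, blocks=block_arr)
    exceed = np.zeros(Y.shape[0], dtype=int)
    tol = 1e-12 * np.maximum(observed, 1.0)
    for r in range(n_perm):
        exceed += stat(perms[r]) > observed + tol
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "feature_id": clr.index,
            "group_a": a,
            "group_b": b,
            "amplitude_diff": observed,
            "amplitude_p": p,
        }
    )


def amplitude_difference_test(
    y: Sequence[float],
    design: DesignMatrix,
    pair: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    blocks: Sequence | None = None,
) -> float:
    """Single-feature amplitude-difference permutation p-value."""
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_samples,):
        raise InputError("y length does not match design")
    table = amplitude_difference_table(
        pd.DataFrame(y[None, :], index=["feature"], columns=range(y.size)),
        design,
        pair,
        n_perm=n_perm,
        seed=seed,
        blocks=blocks,
    )
    return float(table["amplitude_p"].iloc[0])
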