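"""Cohort-level structure: cage-mean aggregation, PERMANOVA, PCA, cage sensitivity.

Animals sharing a cage share diet spillover, coprophagy and microbial
exchange, so cage — not animal — is the safer exchangeable unit for
metabolome-wide tests. :func:`cage_means` averages CLR profiles within
(cage, timepoint) units; :func:`permanova` runs a permutational
multivariate ANOVA (Anderson's pseudo-F on a distance matrix) over those
units, enumerating all distinct label assignments exactly when that is
cheaper than sampling. :func:`cage_sensitivity` refits the per-feature
group x time interaction with and without a cage random intercept (REML)
and reports how much the interaction coefficients move — a per-feature
check that cage structure is not driving the group contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from .errors import InputError

__all__ = [
    "PermanovaResult",
    "CageSensitivityResult",
    "cage_means",
    "permanova",
    "pca_scores",
    "cage_sensitivity",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_perm: float
    n_perm: int
    term: str
    exhaustive: bool


@dataclass(frozen=True)
class CageSensitivityResult:
    feature_id: str
    ols_coef: dict[str, float]
    mixed_coef: dict[str, float]
    abs_diff: dict[str, float]
    rel_diff: dict[str, float]  # NaN where the OLS coefficient is ~0
    cage_variance: float
    converged: bool


def cage_means(
    clr: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average CLR columns within each (cage_id, zt_h) unit.

    Means of zero-sum columns are zero-sum, so the output is still a valid
    CLR matrix. Returns the aggregated matrix (columns = unit ids) and a
    metadata table with ``unit_id, cage_id, zt_h, group, n_samples``.
    """
    meta = metadata.set_index("sample_id").loc[list(clr.columns)]
    if meta["cage_id"].isna().any():
        raise InputError("every sample needs a cage_id")
    group_of_cage = meta.groupby("cage_id")["group"].nunique()
    if (group_of_cage > 1).any():
        bad = group_of_cage[group_of_cage > 1].index.tolist()
        raise InputError(f"cages straddle groups: {bad}")

    units, columns, rows = [], [], []
    for (cage, zt), sub in meta.groupby(["cage_id", "zt_h"], sort=True):
        unit_id = f"{cage}@ZT{zt:g}"
        units.append(
            {
                "unit_id": unit_id,
                "cage_id": cage,
                "zt_h": float(zt),
                "group": sub["group"].iloc[0],
                "n_samples": len(sub),
            }
        )
        columns.append(unit_id)
        rows.append(clr[sub.index].to_numpy(dtype=float).mean(axis=1))
    aggregated = pd.DataFrame(
        np.column_stack(rows), index=clr.index, columns=columns
    )
    return aggregated, pd.DataFrame(units)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Anderson's pseudo-F and R^2 from squared distances and labels."""
    n = labels.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        mask = labels == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
        k += 1
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:
        # identical points within every group: F diverges, R^2 = 1
        return float("inf"), ss_between / ss_total
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
    term: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Significance by permuting labels; when the number of distinct label
    assignments is at most ``n_perm`` the null is enumerated exhaustively
    (p = fraction of assignments, observed included, whose pseudo-F reaches
    the observed one); otherwise ``n_perm`` Monte-Carlo permutations with
    the add-one estimator, so ``p >= 1/(1 + n_perm)``.
    """
    labels = np.asarray(labels)
    d = np.asarray(dist.data, dtype=float)
    if labels.size != d.shape[0]:
        raise InputError("labels must align with the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise InputError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise InputError(f"groups with fewer than 2 members: {small}")
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, labels)

    n_distinct = math.factorial(labels.size)
    for c in counts:
        n_distinct //= math.factorial(int(c))
    eps = 1e-12
    if n_distinct <= n_perm:
        hits = 0
        total = 0
        for perm in multiset_permutations(sorted(labels.tolist())):
            f_perm, _ = _pseudo_f(d2, np.asarray(perm))
            hits += f_perm >= f_obs - eps
            total += 1
        p = hits / total
        return PermanovaResult(f_obs, r2, p, total, term, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels))
        hits += f_perm >= f_obs - eps
    p = (1.0 + hits) / (1.0 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, term, False)


def pca_scores(
    clr: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in CLR space (features centred, SVD scores).

    Returns (scores DataFrame indexed by sample id, explained-variance
    fractions, non-increasing). ``n_components`` beyond the matrix rank is
    truncated with a warning.
    """
    from sklearn.decomposition import PCA

    X = clr.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise InputError("PCA needs at least 2 samples")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=clr.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_


def cage_sensitivity(
    y,
    metadata: pd.DataFrame,
    period_h: float = 24.0,
    feature_id: str = "feature",
) -> CageSensitivityResult:
    """Group x time interaction with vs without a cage random intercept.

    Fits ``y ~ group * (sin + cos)`` (treatment coding, first sorted group
    as reference) by OLS, then by linear mixed model with a cage random
    intercept (REML). Reports both interaction coefficient pairs and their
    absolute/relative differences. Non-convergence of the mixed fit is
    flagged; the OLS result is always returned.
    """
    y = np.asarray(y, dtype=float)
    meta = metadata.reset_index(drop=True)
    if y.size != len(meta):
        raise InputError("y length does not match metadata")
    if meta.groupby("group")["cage_id"].nunique().min() < 2:
        raise InputError("need at least 2 cages per group")
    omega = 2.0 * np.pi / period_h
    frame = pd.DataFrame(
        {
            "y": y,
            "group": pd.Categorical(
                meta["group"], categories=sorted(meta["group"].unique())
            ),
            "s": np.sin(omega * meta["zt_h"].to_numpy(dtype=float)),
            "c": np.cos(omega * meta["zt_h"].to_numpy(dtype=float)),
            "cage": meta["cage_id"].to_numpy(),
        }
    )
    formula = "y ~ group * (s + c)"
    ols_fit = smf.ols(formula, data=frame).fit()

    def interaction_terms(params: pd.Series) -> dict[str, float]:
        return {
            name: float(val)
            for name, val in params.items()
            if (":s" in name or ":c" in name) and name.startswith("group")
        }

    ols_coef = interaction_terms(ols_fit.params)

    converged = True
    cage_var = float("nan")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=frame, groups=frame["cage"])
            try:
                mixed = model.fit(reml=True, method="lbfgs")
            except np.linalg.LinAlgError:
                # boundary (zero cage variance) breaks the gradient path;
                # Powell is derivative-free and handles it
                mixed = model.fit(reml=True, method="powell")
        mixed_coef = interaction_terms(mixed.params)
        cage_var = float(np.asarray(mixed.cov_re).ravel()[0])
        converged = bool(getattr(mixed, "converged", True))
    except Exception:
        mixed_coef = {name: float("nan") for name in ols_coef}
        converged = False

    tol = 1e-10
    abs_diff = {k: abs(mixed_coef[k] - ols_coef[k]) for k in ols_coef}
    rel_diff = {
        k: (abs_diff[k] / abs(ols_coef[k]) if abs(ols_coef[k]) > tol else float("nan"))
        for k in ols_coef
    }
    return CageSensitivityResult(
        feature_id=feature_id,
        ols_coef=ols_coef,
        mixed_coef=mixed_coef,
        abs_diff=abs_diff,
        rel_diff=rel_diff,
        cage_variance=cage_var,
        converged=converged,
    )
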