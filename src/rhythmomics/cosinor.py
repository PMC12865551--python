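"""Single-harmonic cosinor fitting via ordinary least squares.

The rhythm model for one feature and one group is

    y(t) = M + beta_s * sin(2*pi*t/P) + beta_c * cos(2*pi*t/P) + eps
         = M + A * cos(2*pi*(t - phi)/P) + eps

with mesor M (rhythm-adjusted mean), amplitude A = sqrt(beta_s^2 + beta_c^2)
and acrophase phi = (P / 2*pi) * atan2(beta_s, beta_c) mod P, the time at
which the fitted curve peaks. The period P is fixed (24 h for a diurnal
design; four timepoints cannot identify a free period). Rhythmicity is the
joint F-test of beta_s = beta_c = 0 against the intercept-only model
(2 numerator degrees of freedom).

Multi-group designs use a cell-means parameterisation — per-group
intercept, sine and cosine columns — so per-group estimates from one full
interaction model coincide with separate per-group fits, while the pooled
model supplies the interaction contrasts tested by
:mod:`rhythmomics.differential`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IdentifiabilityError, InputError

__all__ = [
    "DesignMatrix",
    "CosinorFit",
    "build_design",
    "acrophase_amplitude",
    "fit_cosinor",
    "fit_cosinor_table",
]

#: amplitudes below this are treated as zero and the acrophase as undefined
AMPLITUDE_TOL = 1e-12

#: residual variance below this (relative to total variance) flags a
#: degenerate (numerically perfect) fit
DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class DesignMatrix:
    """Cosinor design: rows = samples, cell-means coding per group."""

    X: np.ndarray
    columns: tuple[str, ...]
    times_h: np.ndarray
    group_labels: np.ndarray  # per-row group label
    group_levels: tuple[str, ...]
    period_h: float

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def group_rows(self, group: str) -> np.ndarray:
        if group not in self.group_levels:
            raise InputError(f"group {group!r} not present in design")
        return np.flatnonzero(self.group_labels == group)


def build_design(
    times_h: Sequence[float],
    groups: Sequence[str] | None = None,
    period_h: float = 24.0,
) -> DesignMatrix:
    """Build the Fourier design for the given sampling times.

    With a single group the matrix has columns ``[intercept, sin, cos]``;
    with several groups each group gets its own intercept/sin/cos triple
    (cell-means coding, 3 parameters per group). Group levels are ordered by
    sorted label. Raises :class:`IdentifiabilityError` when any group has
    fewer than 3 distinct timepoints or the matrix is rank deficient.
    """
    if period_h <= 0:
        raise InputError("period_h must be positive")
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("times_h must be a non-empty 1-D sequence")
    if groups is None:
        labels = np.array(["_all"] * t.size)
    else:
        labels = np.asarray(groups)
        if labels.shape != t.shape:
            raise InputError("groups must align with times_h")
    levels = tuple(sorted(set(labels.tolist())))

    omega = 2.0 * np.pi / period_h
    s, c = np.sin(omega * t), np.cos(omega * t)

    blocks, names = [], []
    for g in levels:
        ind = (labels == g).astype(float)
        if len(np.unique(t[labels == g])) < 3:
            raise IdentifiabilityError(
                f"group {g!r} has fewer than 3 distinct timepoints; "
                "mesor, sine and cosine terms are not identifiable"
            )
        blocks.extend([ind, ind * s, ind * c])
        prefix = f"{g}:" if groups is not None else ""
        names.extend([f"{prefix}intercept", f"{prefix}sin", f"{prefix}cos"])
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError("cosinor design matrix is rank deficient")
    return DesignMatrix(
        X=X,
        columns=tuple(names),
        times_h=t,
        group_labels=labels,
        group_levels=levels,
        period_h=float(period_h),
    )


def acrophase_amplitude(
    beta_sin: float | np.ndarray,
    beta_cos: float | np.ndarray,
    period_h: float,
    atol: float = AMPLITUDE_TOL,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Convert sine/cosine coefficients to (acrophase in hours, amplitude).

    The acrophase is the peak time of ``A * cos(omega*(t - phi))`` on
    ``[0, period_h)``; it is NaN (undefined) when the amplitude falls below
    ``atol``. Vectorised over array inputs.
    """
    if period_h <= 0:
        raise InputError("period_h must be positive")
    bs = np.asarray(beta_sin, dtype=float)
    bc = np.asarray(beta_cos, dtype=float)
    amplitude = np.hypot(bs, bc)
    phi = np.mod(np.arctan2(bs, bc) * period_h / (2.0 * np.pi), period_h)
    phi = np.where(phi >= period_h, 0.0, phi)  # fold the float-rounded wrap point
    phi = np.where(amplitude < atol, np.nan, phi)
    if np.ndim(beta_sin) == 0 and np.ndim(beta_cos) == 0:
        return float(phi), float(amplitude)
    return phi, amplitude


@dataclass(frozen=True)
class CosinorFit:
    """Fitted rhythm parameters for one feature within one group."""

    feature_id: str
    group: str
    mesor: float
    beta_sin: float
    beta_cos: float
    amplitude: float
    acrophase_h: float  # NaN when undefined (amplitude ~ 0)
    p_rhythm: float
    residual_df: int
    period_h: float
    degenerate: bool = False


def _group_ols(y: np.ndarray, Xg: np.ndarray) -> tuple[np.ndarray, float, float, int]:
    """OLS of y on [1, sin, cos]; returns (beta, rss, rss0, residual df)."""
    beta, *_ = np.linalg.lstsq(Xg, y, rcond=None)
    resid = y - Xg @ beta
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return beta, rss, rss0, y.size - 3


def _rhythm_pvalue(rss: float, rss0: float, df_resid: int) -> tuple[float, bool]:
    """F-test of the sine/cosine pair (2 numerator df) vs intercept only."""
    scale = max(rss0, 1.0)
    degenerate = rss <= DEGENERATE_REL_TOL * scale
    if degenerate:
        # perfect fit: p is the limit 0 when the rhythm explains anything
        return (0.0 if rss0 > rss else 1.0), True
    f = ((rss0 - rss) / 2.0) / (rss / df_resid)
    return float(stats.f.sf(max(f, 0.0), 2, df_resid)), False


def fit_cosinor(
    y: Sequence[float],
    design: DesignMatrix,
    feature_id: str = "feature",
) -> list[CosinorFit]:
    """Fit the cosinor to one feature; one :class:`CosinorFit` per group.

    Estimates are ordinary least squares within each group (identical to
    the full interaction model's per-group parameters). ``p_rhythm`` uses
    the within-group residual variance. Perfect (zero-residual) fits are
    flagged ``degenerate`` rather than raising, so noiseless recovery runs.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_samples,):
        raise InputError(
            f"y has length {y.size}, design has {design.n_samples} rows"
        )
    fits = []
    for group in design.group_levels:
        rows = design.group_rows(group)
        if rows.size - 3 < 1:
            raise InputError(f"group {group!r} has no residual degrees of freedom")
        cols = [i for i, name in enumerate(design.columns) if name.split(":")[-1] in ("intercept", "sin", "cos") and (design.n_params == 3 or name.startswith(f"{group}:"))]
        Xg = design.X[np.ix_(rows, cols)]
        beta, rss, rss0, df = _group_ols(y[rows], Xg)
        p, degenerate = _rhythm_pvalue(rss, rss0, df)
        phi, amp = acrophase_amplitude(beta[1], beta[2], design.period_h)
        fits.append(
            CosinorFit(
                feature_id=feature_id,
                group=group if design.n_params > 3 else "_all",
                mesor=float(beta[0]),
                beta_sin=float(beta[1]),
                beta_cos=float(beta[2]),
                amplitude=float(amp),
                acrophase_h=float(phi),
                p_rhythm=p,
                residual_df=df,
                period_h=design.period_h,
                degenerate=degenerate,
            )
        )
    return fits


def fit_cosinor_table(
    clr: pd.DataFrame,
    metadata: pd.DataFrame,
    period_h: float = 24.0,
) -> pd.DataFrame:
    """Vectorised per-feature, per-group cosinor fits over a CLR table.

    ``metadata`` must align with the CLR columns by ``sample_id`` and carry
    ``zt_h`` and ``group``. Returns a long DataFrame with one row per
    feature x group holding mesor, coefficients, amplitude, acrophase,
    ``p_rhythm``, residual df and a degeneracy flag.
    """
    meta = metadata.set_index("sample_id").loc[list(clr.columns)]
    times = meta["zt_h"].to_numpy(dtype=float)
    labels = meta["group"].to_numpy()
    Y = clr.to_numpy(dtype=float)

    out = []
    omega = 2.0 * np.pi / period_h
    for group in sorted(set(labels.tolist())):
        rows = np.flatnonzero(labels == group)
        t = times[rows]
        if len(np.unique(t)) < 3:
            raise IdentifiabilityError(
                f"group {group!r} has fewer than 3 distinct timepoints"
            )
        Xg = np.column_stack([np.ones(rows.size), np.sin(omega * t), np.cos(omega * t)])
        Yg = Y[:, rows]
        beta, *_ = np.linalg.lstsq(Xg, Yg.T, rcond=None)  # 3 x features
        resid = Yg.T - Xg @ beta
        rss = np.sum(resid**2, axis=0)
        rss0 = np.sum((Yg - Yg.mean(axis=1, keepdims=True)) ** 2, axis=1)
        df = rows.size - 3
        scale = np.maximum(rss0, 1.0)
        degenerate = rss <= DEGENERATE_REL_TOL * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss0 - rss) / 2.0) / (rss / df)
        p = stats.f.sf(np.clip(f, 0.0, None), 2, df)
        p = np.where(degenerate, np.where(rss0 > rss, 0.0, 1.0), p)
        phi, amp = acrophase_amplitude(beta[1], beta[2], period_h)
        out.append(
            pd.DataFrame(
                {
                    "feature_id": clr.index,
                    "group": group,
                    "mesor": beta[0],
                    "beta_sin": beta[1],
                    "beta_cos": beta[2],
                    "amplitude": amp,
                    "acrophase_h": phi,
                    "p_rhythm": p,
                    "residual_df": df,
                    "period_h": period_h,
                    "degenerate": degenerate,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
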