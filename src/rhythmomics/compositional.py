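"""Compositional preprocessing: zero replacement, CLR transform, Aitchison distance.

Untargeted metabolomics intensities are compositional: the total signal per
sample is an instrument artefact, so only relative information is meaningful.
All downstream statistics therefore operate on centred log-ratio (CLR)
values, ``clr_i = ln(x_i) - mean_j ln(x_j)`` per sample, after replacing
zeros with a per-feature fraction of the smallest detected value (the
'const' detection-limit surrogate).

Tables are pandas DataFrames oriented features x samples (rows = features,
columns = samples). The CLR output of :func:`clr_transform` sums to zero
over features within every sample column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import InputError

__all__ = ["replace_zeros", "clr_transform", "aitchison_distance"]


def _check_table(table: pd.DataFrame) -> None:
    if not table.index.is_unique:
        raise InputError("feature ids are not unique")
    if not table.columns.is_unique:
        raise InputError("sample ids are not unique")
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("abundance table contains non-finite values")
    if (values < 0).any():
        raise InputError("abundance table contains negative values")


def replace_zeros(
    table: pd.DataFrame,
    strategy: str = "const",
    const_factor: float = 0.5,
) -> pd.DataFrame:
    """Replace exact zeros with ``const_factor`` x the feature's minimum positive value.

    Parameters
    ----------
    table
        Nonnegative feature x sample abundance table.
    strategy
        Only ``"const"`` is supported: each zero in a feature row is replaced
        by a fixed fraction of that feature's smallest observed positive
        value, a standard surrogate for values below the detection limit.
    const_factor
        Fraction of the per-feature minimum positive value, default 0.5
        (half-minimum).

    Returns
    -------
    A strictly positive copy of ``table``; positive entries are unchanged.
    A table with no zeros is returned as an identical copy, so the operation
    is idempotent on its own output.

    Raises
    ------
    InputError
        If a feature is entirely zero (no replacement constant exists), or
        the table is malformed.
    """
    if strategy != "const":
        raise InputError(f"unknown zero-replacement strategy {strategy!r}")
    if not const_factor > 0:
        raise InputError("const_factor must be positive")
    _check_table(table)

    values = table.to_numpy(dtype=float).copy()
    zero_mask = values == 0.0
    if not zero_mask.any():
        return table.astype(float).copy()

    rows_with_zero = np.flatnonzero(zero_mask.any(axis=1))
    for i in rows_with_zero:
        row = values[i]
        positive = row[row > 0]
        if positive.size == 0:
            raise InputError(
                f"feature {table.index[i]!r} is entirely zero; "
                "no replacement constant exists"
            )
        row[row == 0.0] = const_factor * positive.min()
    return pd.DataFrame(values, index=table.index, columns=table.columns)


def clr_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform, applied per sample (column).

    ``clr_{i,s} = ln(x_{i,s}) - mean_j ln(x_{j,s})``; every column of the
    result sums to zero. The transform is invariant to rescaling a sample by
    any positive constant, which is what makes compositional data amenable
    to ordinary Euclidean statistics.

    Raises
    ------
    InputError
        If any entry is zero or negative (run :func:`replace_zeros` first).
    """
    _check_table(table)
    values = table.to_numpy(dtype=float)
    if (values <= 0).any():
        raise InputError(
            "CLR requires strictly positive values; replace zeros first "
            "(rhythmomics.compositional.replace_zeros)"
        )
    log_values = np.log(values)
    clr = log_values - log_values.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def aitchison_distance(clr: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance between CLR columns (Aitchison distance).

    Returns a :class:`skbio.DistanceMatrix` keyed by sample id.
    """
    values = clr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("CLR matrix contains non-finite values")
    # Gram-based pairwise distances on columns; clip tiny negatives from
    # cancellation before the square root.
    gram = values.T @ values
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.fill_diagonal(d2, 0.0)
    dist = np.sqrt(np.clip(d2, 0.0, None))
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(dist, ids=[str(c) for c in clr.columns])
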