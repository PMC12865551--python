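"""Circular acrophase summaries and class tallies.

Acrophases live on a circle of circumference P (the period in hours), so
they are summarised with circular statistics: each phase maps to a unit
vector at angle 2*pi*phi/P, the circular mean is the angle of the mean
vector and the resultant length R in [0, 1] measures phase concentration
(R = 1: all phases identical; R ~ 0: phases spread around the clock).
Between-group phase shifts are circular differences reported on
[-P/2, P/2]. Undefined acrophases (amplitude ~ 0) are excluded and counted
separately, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "circular_mean_h",
    "resultant_length",
    "circular_difference_h",
    "AcrophaseGroupSummary",
    "AcrophaseSummary",
    "acrophase_summary",
    "classify_tally",
]


def _angles(phases_h: np.ndarray, period_h: float) -> np.ndarray:
    return 2.0 * np.pi * np.asarray(phases_h, dtype=float) / period_h


def circular_mean_h(phases_h, period_h: float = 24.0) -> float:
    """Circular mean of phases in hours on [0, period_h); NaN if undefined.

    Undefined when there are no phases or the mean resultant vector is
    (numerically) zero, e.g. two phases exactly half a period apart.
    """
    phases = np.asarray(phases_h, dtype=float)
    phases = phases[~np.isnan(phases)]
    if phases.size == 0:
        return float("nan")
    ang = _angles(phases, period_h)
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if np.hypot(s, c) < 1e-12:
        return float("nan")
    mean = float(np.mod(np.arctan2(s, c) * period_h / (2.0 * np.pi), period_h))
    return 0.0 if mean >= period_h else mean  # fold the float-rounded wrap point


def resultant_length(phases_h, period_h: float = 24.0) -> float:
    """Mean resultant length R in [0, 1] of phases in hours; NaN if empty."""
    phases = np.asarray(phases_h, dtype=float)
    phases = phases[~np.isnan(phases)]
    if phases.size == 0:
        return float("nan")
    ang = _angles(phases, period_h)
    return float(np.hypot(np.sin(ang).mean(), np.cos(ang).mean()))


def circular_difference_h(a_h: float, b_h: float, period_h: float = 24.0) -> float:
    """Signed circular difference a - b mapped to [-P/2, P/2)."""
    if np.isnan(a_h) or np.isnan(b_h):
        return float("nan")
    half = period_h / 2.0
    return float(np.mod(a_h - b_h + half, period_h) - half)


@dataclass(frozen=True)
class AcrophaseGroupSummary:
    group: str
    n_defined: int
    n_undefined: int
    bin_edges_h: tuple[float, ...]
    bin_counts: tuple[int, ...]
    circular_mean_h: float
    resultant_r: float
    modal_bin_h: float  # left edge of the fullest bin; NaN if no phases


@dataclass(frozen=True)
class AcrophaseSummary:
    period_h: float
    bin_width_h: float
    groups: dict[str, AcrophaseGroupSummary]
    shifts_h: dict[str, float] = field(default_factory=dict)  # "A|B" -> shift

    def to_dict(self) -> dict:
        return {
            "period_h": self.period_h,
            "bin_width_h": self.bin_width_h,
            "groups": {
                g: {
                    "n_defined": s.n_defined,
                    "n_undefined": s.n_undefined,
                    "bin_edges_h": list(s.bin_edges_h),
                    "bin_counts": list(s.bin_counts),
                    "circular_mean_h": s.circular_mean_h,
                    "resultant_r": s.resultant_r,
                    "modal_bin_h": s.modal_bin_h,
                }
                for g, s in self.groups.items()
            },
            "shifts_h": dict(self.shifts_h),
        }


def acrophase_summary(
    fits: pd.DataFrame,
    bin_width_h: float = 2.0,
    restrict_to=None,
    period_h: float = 24.0,
) -> AcrophaseSummary:
    """Binned/circular summary of per-group acrophases from a fits table.

    ``fits`` is the long table from
    :func:`rhythmomics.cosinor.fit_cosinor_table` (needs columns
    ``feature_id, group, acrophase_h``). ``restrict_to`` optionally limits
    the summary to a feature subset (e.g. amino acids, or features called
    rhythmic). Between-group shifts are circular differences of group
    circular means, one entry per unordered pair, keyed ``"A|B"`` (mean of
    A minus mean of B).
    """
    n_bins = period_h / bin_width_h
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InputError("bin_width_h must divide the period")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, period_h, n_bins + 1)

    table = fits
    if restrict_to is not None:
        table = fits[fits["feature_id"].isin(set(restrict_to))]

    groups: dict[str, AcrophaseGroupSummary] = {}
    for g, sub in table.groupby("group", sort=True):
        phases = sub["acrophase_h"].to_numpy(dtype=float)
        defined = phases[~np.isnan(phases)]
        counts, _ = np.histogram(defined, bins=edges)
        modal = float(edges[int(np.argmax(counts))]) if defined.size else float("nan")
        groups[str(g)] = AcrophaseGroupSummary(
            group=str(g),
            n_defined=int(defined.size),
            n_undefined=int(phases.size - defined.size),
            bin_edges_h=tuple(edges.tolist()),
            bin_counts=tuple(int(c) for c in counts),
            circular_mean_h=circular_mean_h(defined, period_h),
            resultant_r=resultant_length(defined, period_h),
            modal_bin_h=modal,
        )

    names = sorted(groups)
    shifts = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shifts[f"{a}|{b}"] = circular_difference_h(
                groups[a].circular_mean_h, groups[b].circular_mean_h, period_h
            )
    return AcrophaseSummary(
        period_h=period_h, bin_width_h=bin_width_h, groups=groups, shifts_h=shifts
    )


def classify_tally(flags: pd.Series, class_map) -> pd.DataFrame:
    """Count flagged (differentially rhythmic) features per chemical class.

    ``flags`` is a boolean Series indexed by feature id; ``class_map`` maps
    feature id -> class label (dict or Series). Unmapped flagged features
    are tallied as ``"unclassified"``. Returns a DataFrame with ``class_``,
    ``count`` and ``fraction`` (of flagged features); counts sum to the
    number of flagged features.
    """
    if not isinstance(class_map, pd.Series):
        class_map = pd.Series(dict(class_map), dtype=object)
    flagged = flags[flags.astype(bool)].index
    labels = [
        str(class_map[f]) if f in class_map.index and pd.notna(class_map.get(f)) else "unclassified"
        for f in flagged
    ]
    counts = pd.Series(labels, dtype=object).value_counts()
    total = int(len(flagged))
    out = pd.DataFrame(
        {
            "class_": counts.index,
            "count": counts.to_numpy(dtype=int),
            "fraction": (counts / total).to_numpy() if total else np.array([]),
        }
    )
    return out.reset_index(drop=True)
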