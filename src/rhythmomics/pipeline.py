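"""End-to-end analysis pipeline over a feature table + sample metadata.

Stages: zero replacement -> CLR -> per-feature per-group cosinor fits ->
pairwise differential rhythmicity with BH selection -> circular acrophase
summaries -> optional amplitude permutation tests and PERMANOVA on cage
means. Deterministic given the config (including its seed); every
threshold and seed is echoed into the run log.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
import pandas as pd

from . import compositional, cosinor, differential, structure, summaries
from .errors import InputError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    period_h: float = 24.0
    const_factor: float = 0.5
    q_threshold: float = 0.1
    correction_order: str = "bonferroni_then_bh"
    bin_width_h: float = 2.0
    restrict_summary_to_rhythmic: bool = False
    rhythm_alpha: float = 0.05  # marginal-rhythmicity cut used only for restriction
    pair: tuple[str, str] | None = None  # default: first two sorted group labels
    amplitude_test: bool = False
    amplitude_n_perm: int = 999
    permanova: bool = True
    permanova_term: str = "group"  # group | time | group_time
    n_perm: int = 9999
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}


@dataclass
class PipelineResult:
    results_table: pd.DataFrame
    fits: pd.DataFrame
    differential: pd.DataFrame
    acrophase_summary: summaries.AcrophaseSummary
    permanova: structure.PermanovaResult | None
    log: list[str] = field(default_factory=list)


def _wide_results(
    fits: pd.DataFrame, diff: pd.DataFrame, amp: pd.DataFrame | None
) -> pd.DataFrame:
    wide = None
    for g, sub in fits.groupby("group", sort=True):
        cols = sub.set_index("feature_id")[
            ["mesor", "amplitude", "acrophase_h", "p_rhythm"]
        ].rename(columns=lambda c: f"{c}_{g}")
        wide = cols if wide is None else wide.join(cols)
    table = wide.join(
        diff.set_index("feature_id")[
            ["p_sin", "p_cos", "q_component", "q_bh", "is_differential"]
        ]
    )
    if amp is not None:
        table = table.join(
            amp.set_index("feature_id")[["amplitude_diff", "amplitude_p"]]
        )
    return table.reset_index()


def run_pipeline(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    class_map: pd.Series | None = None,
) -> PipelineResult:
    """Run every stage on a feature x sample table; see module docstring."""
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(f"{_dt.datetime.now().isoformat(timespec='seconds')} {msg}")

    note(f"config: {config.to_dict()}")
    missing = set(features.columns) - set(metadata["sample_id"])
    if missing:
        raise InputError(f"samples missing from metadata: {sorted(missing)[:5]}")
    meta = metadata.set_index("sample_id").loc[list(features.columns)].reset_index()

    group_levels = sorted(meta["group"].unique())
    if len(group_levels) < 2:
        raise InputError("pipeline needs at least two groups")
    pair = tuple(config.pair) if config.pair else tuple(group_levels[:2])

    n_zero = int((features.to_numpy() == 0).sum())
    positive = compositional.replace_zeros(features, const_factor=config.const_factor)
    note(f"replaced {n_zero} zeros (const, factor {config.const_factor})")
    clr = compositional.clr_transform(positive)
    note(f"CLR transform: {clr.shape[0]} features x {clr.shape[1]} samples")

    fits = cosinor.fit_cosinor_table(clr, meta, period_h=config.period_h)
    note(f"cosinor fits at period {config.period_h} h for groups {group_levels}")

    design = cosinor.build_design(
        meta["zt_h"].to_numpy(dtype=float),
        meta["group"].to_numpy(),
        period_h=config.period_h,
    )
    diff = differential.differential_table(
        clr,
        design,
        pair,
        threshold=config.q_threshold,
        correction_order=config.correction_order,
    )
    n_called = int(diff["is_differential"].sum())
    note(
        f"differential rhythmicity {pair[0]} vs {pair[1]}: {n_called} of "
        f"{len(diff)} features at q < {config.q_threshold} "
        f"({config.correction_order})"
    )

    amp = None
    if config.amplitude_test:
        amp = differential.amplitude_difference_table(
            clr, design, pair, n_perm=config.amplitude_n_perm, seed=config.seed,
            blocks=meta["cage_id"].to_numpy(),
        )
        note(
            f"amplitude permutation test: n_perm={config.amplitude_n_perm}, "
            f"seed={config.seed}"
        )

    restrict = None
    if config.restrict_summary_to_rhythmic:
        rhythmic = fits.loc[fits["p_rhythm"] < config.rhythm_alpha, "feature_id"]
        restrict = sorted(set(rhythmic))
        note(
            f"acrophase summary restricted to {len(restrict)} features with "
            f"p_rhythm < {config.rhythm_alpha} in some group"
        )
    acro = summaries.acrophase_summary(
        fits,
        bin_width_h=config.bin_width_h,
        restrict_to=restrict,
        period_h=config.period_h,
    )
    note(f"acrophase summary: shifts {acro.shifts_h}")

    perm = None
    if config.permanova:
        agg, units = structure.cage_means(clr, meta)
        if config.permanova_term == "group":
            labels = units["group"].to_numpy()
        elif config.permanova_term == "time":
            labels = units["zt_h"].astype(str).to_numpy()
        elif config.permanova_term == "group_time":
            labels = (units["group"] + "@" + units["zt_h"].astype(str)).to_numpy()
        else:
            raise InputError(f"unknown permanova_term {config.permanova_term!r}")
        dist = compositional.aitchison_distance(agg)
        perm = structure.permanova(
            dist, labels, n_perm=config.n_perm, seed=config.seed,
            term=config.permanova_term,
        )
        note(
            f"PERMANOVA on {len(units)} cage-mean units, term="
            f"{config.permanova_term}: F={perm.pseudo_f:.4g} R2="
            f"{perm.r_squared:.4g} p={perm.p_perm:.4g} "
            f"(n_perm={perm.n_perm}, exhaustive={perm.exhaustive}, seed={config.seed})"
        )

    table = _wide_results(fits, diff, amp)
    if class_map is not None:
        table["class_"] = table["feature_id"].map(class_map)
        tally = summaries.classify_tally(
            diff.set_index("feature_id")["is_differential"], class_map
        )
        note(f"class tally of differential features:\n{tally.to_string(index=False)}")

    return PipelineResult(
        results_table=table,
        fits=fits,
        differential=diff,
        acrophase_summary=acro,
        permanova=perm,
        log=log,
    )
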