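"""Synthetic compositional metabolomics time courses with known rhythm structure.

The generator emulates a two-group diurnal sampling design: animals housed
in small cages, culled at a handful of zeitgeber times (ZT), one tissue
sample per animal, ~120 annotated metabolites per sample. Feature
abundances follow a log-scale single-harmonic cosinor,

    log y = mesor + A * cos(2*pi*(t - phi)/P) + u_cage + eps,

with i.i.d. Gaussian residual noise ``eps`` and an additive cage random
intercept ``u_cage`` drawn independently per (feature, cage). A configurable
subset of rhythmic features carries a between-group acrophase shift with
preserved amplitude — the ground-truth analogue of a microbiota-dependent
phase inversion — and a fraction of entries is zeroed out to exercise
detection-limit zero replacement downstream.

Every run is fully reproducible from ``spec.seed``; equal seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["SyntheticSpec", "generate_dataset", "generate_null_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one synthetic dataset.

    Defaults mirror the emulated study design: 120 features, conventional
    (CV) vs microbiota-depleted (ABX) groups, samples at ZT 5/11/17/23 with
    8 animals per group per timepoint housed in cages of up to 3, a 24 h
    period, and a 12 h acrophase shift in the shifted subset.

    Parameters on the log-abundance scale: ``mesor_log``/``mesor_sd`` give
    the across-feature distribution of mean log abundance; ``amplitude_log``
    is either one amplitude for every rhythmic feature or a ``(lo, hi)``
    uniform range; ``sigma_noise`` and ``sigma_cage`` are residual and
    cage-intercept SDs.
    """

    n_features: int = 120
    frac_rhythmic: float = 0.5
    frac_shifted: float | None = None  # default: min(1/3, frac_rhythmic)
    groups: Sequence[str] = ("CV", "ABX")
    timepoints_h: Sequence[float] = (5.0, 11.0, 17.0, 23.0)
    n_per_cell: int = 8
    cage_size: int = 3
    period_h: float = 24.0
    mesor_log: float = 8.0
    mesor_sd: float = 1.0
    amplitude_log: float | tuple[float, float] = 1.0
    acrophase_shift_h: float = 12.0
    sigma_noise: float = 0.5
    sigma_cage: float = 0.2
    zero_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise InputError("n_features must be >= 1")
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise InputError("frac_rhythmic must lie in [0, 1]")
        if self.frac_shifted is not None and not (
            0.0 <= self.frac_shifted <= self.frac_rhythmic
        ):
            raise InputError("frac_shifted must lie in [0, frac_rhythmic]")
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise InputError("groups must be a non-empty list of unique labels")
        if self.period_h <= 0:
            raise InputError("period_h must be positive")
        if len(self.timepoints_h) == 0 or any(
            not 0.0 <= t < self.period_h for t in self.timepoints_h
        ):
            raise InputError("timepoints must lie in [0, period_h)")
        if len(set(self.timepoints_h)) != len(self.timepoints_h):
            raise InputError("timepoints must be distinct")
        if self.n_per_cell < 2:
            raise InputError("n_per_cell must be >= 2")
        if self.cage_size < 2:
            raise InputError("cage_size must be >= 2 (cages house 2-4 animals)")
        if self.sigma_noise <= 0:
            raise InputError("sigma_noise must be > 0")
        if self.sigma_cage < 0:
            raise InputError("sigma_cage must be >= 0")
        if not 0.0 <= self.zero_rate < 1.0:
            raise InputError("zero_rate must lie in [0, 1)")

    @property
    def resolved_frac_shifted(self) -> float:
        """Shifted fraction actually used; the default takes a third of the
        panel, capped by the rhythmic fraction."""
        if self.frac_shifted is None:
            return min(1.0 / 3.0, self.frac_rhythmic)
        return self.frac_shifted

    @property
    def n_samples(self) -> int:
        return len(self.groups) * len(self.timepoints_h) * self.n_per_cell


def _amplitudes(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    amp = spec.amplitude_log
    if isinstance(amp, (tuple, list)):
        lo, hi = float(amp[0]), float(amp[1])
        if lo < 0 or hi < lo:
            raise InputError("amplitude_log range must satisfy 0 <= lo <= hi")
        return rng.uniform(lo, hi, size=n)
    if amp < 0:
        raise InputError("amplitude_log must be nonnegative")
    return np.full(n, float(amp))


def _build_metadata(spec: SyntheticSpec) -> pd.DataFrame:
    """One row per sample; cages are nested within group x timepoint cells."""
    rows = []
    animal = 0
    for group in spec.groups:
        for zt in spec.timepoints_h:
            n_cages = -(-spec.n_per_cell // spec.cage_size)  # ceil
            for a in range(spec.n_per_cell):
                cage_idx = min(a // spec.cage_size, n_cages - 1)
                rows.append(
                    {
                        "sample_id": f"{group}_ZT{zt:g}_a{a + 1}",
                        "zt_h": float(zt),
                        "group": group,
                        "cage_id": f"cage_{group}_ZT{zt:g}_{cage_idx + 1}",
                        "animal_id": f"animal_{animal + 1}",
                    }
                )
                animal += 1
    return pd.DataFrame(rows)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one dataset: abundance table, sample metadata and ground truth.

    Returns
    -------
    features : DataFrame, features x samples
        Strictly positive abundances, except for a ``zero_rate`` fraction of
        entries set to exact 0 (completely at random).
    metadata : DataFrame
        Columns ``sample_id, zt_h, group, cage_id, animal_id``.
    truth : DataFrame (long)
        One row per feature x group with the generating ``mesor``,
        ``amplitude``, ``acrophase_h`` (NaN when amplitude is 0) and flags
        ``is_rhythmic``, ``is_shifted``.
    """
    rng = np.random.default_rng(spec.seed)
    n_feat = spec.n_features
    groups = list(spec.groups)
    period = spec.period_h

    metadata = _build_metadata(spec)
    n_samples = len(metadata)

    n_rhythmic = int(round(spec.frac_rhythmic * n_feat))
    n_shifted = int(round(spec.resolved_frac_shifted * n_feat))
    order = rng.permutation(n_feat)
    rhythmic_idx = order[:n_rhythmic]
    shifted_idx = order[:n_shifted]  # shifted features are rhythmic by construction
    is_rhythmic = np.zeros(n_feat, dtype=bool)
    is_rhythmic[rhythmic_idx] = True
    is_shifted = np.zeros(n_feat, dtype=bool)
    is_shifted[shifted_idx] = True

    mesor = rng.normal(spec.mesor_log, spec.mesor_sd, size=n_feat)
    amplitude = np.zeros(n_feat)
    amplitude[is_rhythmic] = _amplitudes(spec, rng, n_rhythmic)
    base_phase = np.full(n_feat, np.nan)
    base_phase[is_rhythmic] = rng.uniform(0.0, period, size=n_rhythmic)

    # Per-group acrophase: first group carries the base phase; later groups
    # are offset by acrophase_shift_h on shifted features only.
    phase = np.tile(base_phase, (len(groups), 1))  # groups x features
    for gi in range(1, len(groups)):
        phase[gi, is_shifted] = np.mod(
            base_phase[is_shifted] + spec.acrophase_shift_h, period
        )

    group_index = {g: i for i, g in enumerate(groups)}
    g_of_sample = metadata["group"].map(group_index).to_numpy()
    t_of_sample = metadata["zt_h"].to_numpy()

    cage_ids = metadata["cage_id"].to_numpy()
    cage_levels, cage_of_sample = np.unique(cage_ids, return_inverse=True)
    u_cage = rng.normal(0.0, spec.sigma_cage, size=(n_feat, len(cage_levels)))
    eps = rng.normal(0.0, spec.sigma_noise, size=(n_feat, n_samples))

    omega = 2.0 * np.pi / period
    phi = phase[g_of_sample, :].T  # features x samples
    rhythm = np.where(
        np.isnan(phi), 0.0, amplitude[:, None] * np.cos(omega * (t_of_sample[None, :] - phi))
    )
    log_y = mesor[:, None] + rhythm + u_cage[:, cage_of_sample] + eps
    values = np.exp(log_y)

    n_zero = int(round(spec.zero_rate * values.size))
    if n_zero > 0:
        flat = rng.choice(values.size, size=n_zero, replace=False)
        values.flat[flat] = 0.0

    feature_ids = [f"feature_{i + 1:04d}" for i in range(n_feat)]
    features = pd.DataFrame(
        values, index=pd.Index(feature_ids, name="feature_id"),
        columns=metadata["sample_id"].to_numpy(),
    )

    truth_rows = []
    for gi, g in enumerate(groups):
        truth_rows.append(
            pd.DataFrame(
                {
                    "feature_id": feature_ids,
                    "group": g,
                    "mesor": mesor,
                    "amplitude": amplitude,
                    "acrophase_h": phase[gi],
                    "is_rhythmic": is_rhythmic,
                    "is_shifted": is_shifted,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return features, metadata, truth


def generate_null_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A dataset with identical generating parameters in every group.

    Features may still be rhythmic (shared phase and amplitude across
    groups) but nothing is differentially rhythmic; ``is_shifted`` is False
    everywhere. Used as the type-I-error harness.
    """
    null_spec = replace(spec, frac_shifted=0.0, acrophase_shift_h=0.0)
    return generate_dataset(null_spec)
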