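#!/usr/bin/env python
"""Call differentially rhythmic features and score them against truth.

Tests the group x sine and group x cosine interaction contrasts per
feature, Bonferroni-corrects across the two components, selects features
by Benjamini-Hochberg at q < 0.1, and runs the cage-blocked amplitude
permutation test. Prints sensitivity/false-discovery against the known
generating truth, the recovered per-feature acrophase shift, and a class
tally using the ground-truth shift flag as a synthetic class map.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rhythmomics.cosinor import build_design
from rhythmomics.differential import amplitude_difference_table, differential_table
from rhythmomics.io import read_feature_table, read_metadata
from rhythmomics.summaries import circular_difference_h, circular_mean_h, classify_tally

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    clr = read_feature_table(BASE / "study_clr.tsv", allow_negative=True)
    metadata = read_metadata(BASE / "sim" / "study_metadata.tsv")
    truth = pd.read_csv(BASE / "sim" / "study_truth.tsv", sep="\t")
    meta = metadata.set_index("sample_id").loc[list(clr.columns)].reset_index()
    design = build_design(
        meta["zt_h"].to_numpy(dtype=float), meta["group"].to_numpy(), period_h=24.0
    )

    diff = differential_table(clr, design, ("ABX", "CV"), threshold=0.1)
    diff.to_csv(BASE / "study_differential.tsv", sep="\t", index=False)

    amp = amplitude_difference_table(
        clr, design, ("ABX", "CV"), n_perm=999, seed=1,
        blocks=meta["cage_id"].to_numpy(),
    )
    amp.to_csv(BASE / "study_amplitude_test.tsv", sep="\t", index=False)

    called = diff.set_index("feature_id")["is_differential"]
    flags = truth.drop_duplicates("feature_id").set_index("feature_id")["is_shifted"]
    shifted_ids = flags[flags].index
    sensitivity = called[shifted_ids].mean()
    n_called = int(called.sum())
    fdr = (called & ~flags).sum() / max(n_called, 1)
    print(f"{n_called} of {len(called)} features differential at q < 0.1")
    print(f"sensitivity on the {len(shifted_ids)} truly shifted: {sensitivity:.2f}; "
          f"empirical FDR {fdr:.2f}")

    fits = pd.read_csv(BASE / "study_fits.tsv", sep="\t")
    acro = fits.pivot(index="feature_id", columns="group", values="acrophase_h")
    shifts = [
        circular_difference_h(acro.loc[f, "ABX"], acro.loc[f, "CV"]) % 24.0
        for f in called[called].index.intersection(shifted_ids)
        if not np.isnan(acro.loc[f]).any()
    ]
    print(f"per-feature circular-mean shift of called shifted features: "
          f"{circular_mean_h(shifts):.2f} h (true 12 h)")

    frac_amp = float((amp["amplitude_p"] <= 0.05).mean())
    print(f"amplitude difference flagged in {frac_amp:.1%} of features "
          f"(generating amplitudes equal; nominal 5%)")

    class_map = flags.map({True: "shifted (synthetic)", False: "stable (synthetic)"})
    tally = classify_tally(called, class_map)
    tally.to_csv(BASE / "study_class_tally.tsv", sep="\t", index=False)
    print(tally.to_string(index=False))


if __name__ == "__main__":
    main()
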