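#!/usr/bin/env python
"""CLR-transform the study cohort and fit per-feature cosinor rhythms.

Zeros are replaced by half the per-feature minimum positive value, the
table is centred-log-ratio transformed, and a 24 h single-harmonic cosinor
is fitted per feature within each group. Writes the per-group fits table
and the circular acrophase summary; prints the between-group shift of the
acrophase distribution.
"""

from pathlib import Path

from rhythmomics.compositional import clr_transform, replace_zeros
from rhythmomics.cosinor import fit_cosinor_table
from rhythmomics.io import read_feature_table, read_metadata, write_feature_table, write_json
from rhythmomics.summaries import acrophase_summary

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    features = read_feature_table(BASE / "sim" / "study_features.tsv")
    metadata = read_metadata(BASE / "sim" / "study_metadata.tsv")

    clr = clr_transform(replace_zeros(features, const_factor=0.5))
    write_feature_table(clr, BASE / "study_clr.tsv")

    fits = fit_cosinor_table(clr, metadata, period_h=24.0)
    fits.to_csv(BASE / "study_fits.tsv", sep="\t", index=False)

    rhythmic = fits.loc[fits["p_rhythm"] < 0.05, "feature_id"].unique()
    summary = acrophase_summary(fits, bin_width_h=2.0, restrict_to=rhythmic)
    write_json(summary.to_dict(), BASE / "study_acrophase.json")

    for group, s in summary.groups.items():
        print(
            f"{group}: {s.n_defined} acrophases, circular mean "
            f"{s.circular_mean_h:.2f} h (R={s.resultant_r:.2f}), modal bin "
            f"ZT{s.modal_bin_h:g}"
        )
    for pair, shift in summary.shifts_h.items():
        print(f"group circular-mean shift {pair}: {shift:+.2f} h")
    print(
        "note: generating acrophases are uniform on the clock, so group "
        "means are weakly concentrated; the per-feature shift is scored in "
        "step 03"
    )


if __name__ == "__main__":
    main()
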