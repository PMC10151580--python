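"""Outlier QC: Dixon's Q test at Q99% on every factor of the cohort.

Each factor's 6 pooled values are tested with the r10 gap/range statistic
against the two-tailed critical value (0.740 at n = 6). Flagged cells are
excluded from later correlation stages as missing values (drop-value
policy), which reduces that factor's available sample count rather than
discarding the factor.

Reads results/study/cohort/; writes results/study/qc_dixon.tsv.
"""

from pathlib import Path

from transomics import harmonize, read_layer, read_metadata
from transomics.pipeline import _dixon_frame, _dixon_screen

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "study" / "cohort"
LAYERS = ("lipidomics", "transcriptomics", "proteomics")


def load_dataset():
    layers = [read_layer(COHORT / f"layer_{n}.tsv", name=n) for n in LAYERS]
    return harmonize(layers, read_metadata(COHORT / "metadata.tsv"))


def main() -> None:
    ds = load_dataset()
    flags = _dixon_screen(ds, confidence=0.99)
    frame = _dixon_frame(flags)
    out = ROOT / "results" / "study" / "qc_dixon.tsv"
    frame.to_csv(out, sep="\t", index=False, lineterminator="\n")
    flagged = frame[frame["is_outlier"]]
    print(f"{len(frame)} factors tested at Q99%; {len(flagged)} flagged")
    for _, row in flagged.iterrows():
        print(f"  {row['layer']}/{row['factor']}: sample "
              f"{row['outlier_sample']} "
              f"(Q = {max(row['q_low'], row['q_high']):.3f} >= "
              f"{row['q_crit']:.3f})")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
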