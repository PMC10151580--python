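"""Covariate check: antipsychotic dose (CPeq) and age at death (AoD).

For each triad factor, its marginal correlation with the chlorpromazine-
equivalent dose (controls are 0 mg/day by convention) and with age at
death; then each triad factor pair re-examined with one covariate
partialled out. If the cross-layer correlations merely reflected dose or
age, the covariate-adjusted partials would collapse; partials that stay
near the marginals argue the triad is not a medication or age artifact.

Reads results/study/; writes results/study/covariates.tsv and report.md
for the whole study via the pipeline report writer.
"""

import itertools
from pathlib import Path

import pandas as pd

from transomics import (
    PipelineConfig,
    cross_layer_screen,
    covariate_analysis,
    find_triads,
    run_pipeline,
)
from transomics.mediation import covariates_to_frame

ROOT = Path(__file__).resolve().parents[1]

import importlib.util


def _load(name):
    spec = importlib.util.spec_from_file_location(
        name, Path(__file__).parent / f"{name}.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


screenmod = _load("03_screen_correlations")


def main() -> None:
    ds = screenmod.screened_dataset()
    screens = [cross_layer_screen(ds, a, b, alpha=0.01)
               for a, b in itertools.combinations(screenmod.qc.LAYERS, 2)]
    frames = [covariates_to_frame(covariate_analysis(ds, t))
              for t in find_triads(screens)]
    frame = (pd.concat(frames, ignore_index=True) if frames
             else covariates_to_frame([]))
    out = ROOT / "results" / "study" / "covariates.tsv"
    frame.to_csv(out, sep="\t", index=False, lineterminator="\n")
    if frame.empty:
        print("no triads -> no covariate analysis")
    for _, row in frame.iterrows():
        print(f"  {row['factor']} ~ {row['covariate']}: "
              f"r = {row['r_marginal']:.2f}; "
              f"{row['factor']}-{row['partner_factor']} | "
              f"{row['covariate']}: r = {row['r_partial_pair']:.2f}")
    print(f"table -> {out}")

    # consolidated report over all stages
    cohort = ROOT / "results" / "study" / "cohort"
    outputs = run_pipeline(PipelineConfig(
        layers={n: str(cohort / f"layer_{n}.tsv")
                for n in screenmod.qc.LAYERS},
        metadata=str(cohort / "metadata.tsv"),
        outdir=str(ROOT / "results" / "study"),
        seed=11,
    ))
    print(f"consolidated report -> {outputs.outdir / 'report.md'}")


if __name__ == "__main__":
    main()
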