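"""End-to-end pipeline: read -> harmonize -> QC -> screens -> triads -> covariates.

One call runs every stage in order and writes a deterministic output
bundle: per-stage TSVs, a human-readable ``report.md`` and a ``run.log``
echoing every effective parameter and per-stage counts. Identical inputs
and configuration produce byte-identical bundles (log lines carry no
timestamps for this reason).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .exceptions import PipelineError, TransomicsError
from .io import (
    HarmonizedDataset,
    apply_outlier_policy,
    harmonize,
    read_layer,
    read_metadata,
)
from .mediation import (
    DROP_THRESHOLD,
    RETAIN_THRESHOLD,
    TriadReport,
    covariate_analysis,
    covariates_to_frame,
    find_triads,
    mediation_profile,
    triads_to_frame,
)
from .screening import ScreenResult, cross_layer_screen, export_heatmap_matrix
from .stats import DixonResult, critical_thresholds, dixon_q

__all__ = ["PipelineConfig", "PipelineOutputs", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run.

    ``layers`` maps layer label to file path, in analysis order. Alpha is
    the two-sided per-pair significance level; ``q_confidence`` the Dixon
    confidence level; ``outlier_policy`` one of drop-value / drop-factor /
    keep; ``precision`` the number of decimals for coefficients quoted in
    the report (TSVs always carry 5).
    """

    layers: dict[str, str]
    metadata: str
    outdir: str
    alpha: float = 0.01
    q_confidence: float = 0.99
    outlier_policy: str = "drop-value"
    covariates: tuple[str, ...] = ("CPeq", "AoD")
    drop_threshold: float = DROP_THRESHOLD
    retain_threshold: float = RETAIN_THRESHOLD
    seed: int = 0
    precision: int = 2
    delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.q_confidence not in (0.90, 0.95, 0.99):
            raise ValueError(
                f"q_confidence must be 0.90/0.95/0.99, got {self.q_confidence}"
            )


@dataclass
class PipelineOutputs:
    """Everything a run produced, in memory plus on disk."""

    config: PipelineConfig
    dataset: HarmonizedDataset          # after the outlier policy
    dataset_raw: HarmonizedDataset      # before the outlier policy
    dixon_flags: list[DixonResult]
    screens: list[ScreenResult]
    screens_raw: list[ScreenResult]     # same screens with outliers kept
    triad_reports: list[TriadReport]
    covariate_frame: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    @property
    def outdir(self) -> Path:
        return Path(self.config.outdir)


def run_pipeline(config: PipelineConfig) -> PipelineOutputs:
    """Run every stage and write the output bundle under ``config.outdir``.

    Stage failures are re-raised as :class:`PipelineError` carrying the
    stage name; outputs written before the failure are retained together
    with a ``FAILED`` marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note(f"transomics {__version__} pipeline")
    note(f"parameters: alpha={config.alpha} q_confidence={config.q_confidence} "
         f"outlier_policy={config.outlier_policy} "
         f"covariates={','.join(config.covariates) or '(none)'} "
         f"drop_threshold={config.drop_threshold} "
         f"retain_threshold={config.retain_threshold} seed={config.seed}")

    stage = "read"
    try:
        layers = []
        for label, path in config.layers.items():
            lay = read_layer(path, name=label, delimiter=config.delimiter)
            note(f"read: layer {label!r} from {path}: "
                 f"{len(lay.factors)} factors x {len(lay.samples)} samples")
            layers.append(lay)
        metadata = read_metadata(config.metadata, delimiter=config.delimiter)
        note(f"read: metadata from {config.metadata}: {len(metadata)} samples "
             f"({(metadata['diagnosis'] == 'SCZ').sum()} SCZ / "
             f"{(metadata['diagnosis'] == 'CON').sum()} CON)")

        stage = "harmonize"
        dataset_raw = harmonize(layers, metadata)
        note(f"harmonize: {len(dataset_raw.common_samples)} common samples: "
             f"{', '.join(dataset_raw.common_samples)}")

        stage = "qc-dixon"
        flags = _dixon_screen(dataset_raw, config.q_confidence)
        n_out = sum(f.is_outlier for f in flags)
        note(f"qc-dixon: {len(flags)} factors tested at "
             f"Q{int(config.q_confidence * 100)}%, {n_out} outlier(s) flagged")
        _dixon_frame(flags).to_csv(outdir / "qc_dixon.tsv", sep="\t",
                                   index=False, lineterminator="\n")

        stage = "outlier-policy"
        dataset = apply_outlier_policy(dataset_raw, flags, config.outlier_policy)
        note(f"outlier-policy: {config.outlier_policy} applied to "
             f"{n_out} flagged cell(s)")

        stage = "screen"
        screens, screens_raw = [], []
        for la, lb in itertools.combinations(config.layers, 2):
            s = cross_layer_screen(dataset, la, lb, alpha=config.alpha)
            screens.append(s)
            screens_raw.append(
                cross_layer_screen(dataset_raw, la, lb, alpha=config.alpha)
            )
            note(f"screen: {la} x {lb}: {s.n_tests} pairs tested, "
                 f"{len(s.significant_pairs())} significant at "
                 f"alpha={config.alpha}, {len(s.skipped)} skipped")
            s.to_frame().to_csv(outdir / f"correlations_{la}_{lb}.tsv",
                                sep="\t", index=False, lineterminator="\n")
            export_heatmap_matrix(s, outdir / f"heatmap_{la}_{lb}.tsv")

        stage = "triads"
        triad_reports: list[TriadReport] = []
        if len(config.layers) == 3:
            triads = find_triads(screens)
            note(f"triads: {len(triads)} mutually significant triad(s)")
            for t in triads:
                rep = mediation_profile(
                    dataset, t,
                    drop_threshold=config.drop_threshold,
                    retain_threshold=config.retain_threshold,
                )
                triad_reports.append(rep)
                note(f"triads: {_triad_label(rep)} -> {rep.classification}")
        else:
            note("triads: skipped (need exactly 3 layers)")
        triads_to_frame(triad_reports).to_csv(
            outdir / "triads.tsv", sep="\t", index=False, lineterminator="\n"
        )

        stage = "covariates"
        cov_rows = []
        if config.covariates and triad_reports:
            for rep in triad_reports:
                cov_rows.append(covariates_to_frame(
                    covariate_analysis(dataset, rep.triad, config.covariates)
                ))
            note(f"covariates: {','.join(config.covariates)} against "
                 f"{len(triad_reports)} triad(s)")
        else:
            note("covariates: skipped (no triads or no covariates requested)")
        cov_frame = (pd.concat(cov_rows, ignore_index=True) if cov_rows
                     else covariates_to_frame([]))
        cov_frame.to_csv(outdir / "covariates.tsv", sep="\t", index=False,
                         lineterminator="\n")

        stage = "report"
        outputs = PipelineOutputs(
            config=config, dataset=dataset, dataset_raw=dataset_raw,
            dixon_flags=flags, screens=screens, screens_raw=screens_raw,
            triad_reports=triad_reports, covariate_frame=cov_frame,
            log_lines=log,
        )
        (outdir / "report.md").write_text(write_report(outputs))
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        return outputs
    except Exception as e:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        (outdir / "run.log").write_text(
            "\n".join(log + [f"FAILED at {stage}: {e}"]) + "\n")
        if isinstance(e, TransomicsError):
            raise PipelineError(stage, str(e)) from e
        raise


def _dixon_screen(
    dataset: HarmonizedDataset, confidence: float
) -> list[DixonResult]:
    """Dixon's Q per factor, pooled over all common samples."""
    flags = []
    for name, lay in dataset.layers.items():
        for factor in lay.factors:
            vals = lay.values.loc[factor].dropna()
            if len(vals) < 3 or vals.max() == vals.min():
                continue  # untestable factor; screening will handle it
            flags.append(dixon_q(vals, confidence=confidence,
                                 factor=factor, layer=name))
    return flags


def _dixon_frame(flags: list[DixonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "layer": f.layer, "factor": f.factor, "n": f.n,
            "q_low": round(f.q_low, 5), "q_high": round(f.q_high, 5),
            "q_crit": f.q_crit, "outlier_sample": f.outlier_sample or "NA",
            "is_outlier": f.is_outlier,
        } for f in flags],
        columns=["layer", "factor", "n", "q_low", "q_high", "q_crit",
                 "outlier_sample", "is_outlier"],
    )


def _triad_label(rep: TriadReport) -> str:
    return " / ".join(f"{f} ({l})" for l, f in rep.triad.members())


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(outputs: PipelineOutputs) -> str:
    """Render the deterministic markdown analysis report."""
    cfg = outputs.config
    p = cfg.precision
    lines: list[str] = []
    add = lines.append

    add("# Trans-omics correlation analysis report")
    add("")
    add("## Parameters")
    add("")
    add(f"- layers: {', '.join(cfg.layers)}")
    add(f"- samples (common): {len(outputs.dataset.common_samples)} "
        f"({', '.join(outputs.dataset.common_samples)})")
    add(f"- alpha (two-sided): {cfg.alpha}")
    add(f"- Dixon confidence: Q{int(cfg.q_confidence * 100)}%")
    add(f"- outlier policy: {cfg.outlier_policy}")
    add(f"- covariates: {', '.join(cfg.covariates) or '(none)'}")
    add(f"- mediation thresholds: drop < {cfg.drop_threshold}, "
        f"retain >= {cfg.retain_threshold}")
    add("")

    add("## Significance thresholds by degrees of freedom")
    add("")
    dfs = sorted({r.df for s in outputs.screens for r in s.results})
    add("| df | n | t_crit | r_crit |")
    add("|---:|--:|-------:|-------:|")
    for df in dfs:
        t_crit, r_crit = critical_thresholds(cfg.alpha, df)
        # quote the minimum significant |r| truncated at the 5th decimal
        # (the conservative direction; tests use full precision)
        r_shown = math.floor(r_crit * 1e5) / 1e5
        add(f"| {df} | {df + 2} | {t_crit:.3f} | {r_shown:.5f} |")
    add("")

    add("## Outlier QC (Dixon's Q)")
    add("")
    flagged = [f for f in outputs.dixon_flags if f.is_outlier]
    add(f"{len(outputs.dixon_flags)} factors tested; "
        f"{len(flagged)} outlier(s) flagged.")
    if flagged:
        add("")
        add("| layer | factor | sample | Q | Q_crit |")
        add("|-------|--------|--------|--:|-------:|")
        for f in flagged:
            add(f"| {f.layer} | {f.factor} | {f.outlier_sample} "
                f"| {max(f.q_low, f.q_high):.3f} | {f.q_crit:.3f} |")
    add("")

    add("## Cross-layer screens")
    add("")
    for s in outputs.screens:
        sig = s.significant_pairs()
        add(f"### {s.layer_a} x {s.layer_b}")
        add("")
        add(f"{s.n_tests} pairs tested at alpha = {s.alpha}; "
            f"{len(sig)} significant; {len(s.skipped)} skipped.")
        if sig:
            add("")
            add("| factor_a | factor_b | n | r | r_crit |")
            add("|----------|----------|--:|--:|-------:|")
            for r in sig:
                add(f"| {r.factor_a} | {r.factor_b} | {r.n} "
                    f"| {r.r:.{p}f} | {r.r_crit:.5f} |")
        if s.skipped:
            add("")
            for fa, fb, reason in s.skipped:
                add(f"- skipped {fa} x {fb}: {reason}")
        add("")

    if flagged:
        add("## Flagged factors: correlations with vs. without outliers")
        add("")
        add("| factor | partner | r (with outlier) | r (policy applied) |")
        add("|--------|---------|-----------------:|-------------------:|")
        flagged_ids = {(f.layer, f.factor) for f in flagged}
        for s_raw, s_pol in zip(outputs.screens_raw, outputs.screens):
            for r_raw in s_raw.results:
                if ((r_raw.layer_a, r_raw.factor_a) in flagged_ids
                        or (r_raw.layer_b, r_raw.factor_b) in flagged_ids):
                    r_pol = s_pol.lookup(r_raw.factor_a, r_raw.factor_b)
                    after = f"{r_pol.r:.{p}f}" if r_pol else "NA"
                    add(f"| {r_raw.factor_a} | {r_raw.factor_b} "
                        f"| {r_raw.r:.{p}f} | {after} |")
        add("")

    add("## Triads and mediation")
    add("")
    if not outputs.triad_reports:
        add("No mutually significant cross-layer triads were found.")
    else:
        add("| x | y | z | n | r_xy | r_xz | r_yz "
            "| r_xy.z | r_xz.y | r_yz.x | classification |")
        add("|---|---|---|--:|-----:|-----:|-----:"
            "|-------:|-------:|-------:|----------------|")
        for rep in outputs.triad_reports:
            (lx, fx), (ly, fy), (lz, fz) = rep.triad.members()
            add(f"| {fx} | {fy} | {fz} | {rep.n} "
                f"| {rep.r_xy:.{p}f} | {rep.r_xz:.{p}f} | {rep.r_yz:.{p}f} "
                f"| {rep.partial_xy_z:.{p}f} | {rep.partial_xz_y:.{p}f} "
                f"| {rep.partial_yz_x:.{p}f} | {rep.classification} |")
    add("")

    add("## Covariate analysis")
    add("")
    if outputs.covariate_frame.empty:
        add("No covariate analysis was run.")
    else:
        add("| factor | covariate | r (factor, covariate) "
            "| partner | r_partial (pair | covariate) |")
        add("|--------|-----------|----------------------:"
            "|---------|----------------------------:|")
        for _, row in outputs.covariate_frame.iterrows():
            add(f"| {row['factor']} | {row['covariate']} "
                f"| {row['r_marginal']:.{p}f} | {row['partner_factor']} "
                f"| {row['r_partial_pair']:.{p}f} |")
    add("")

    add("## Reproduction")
    add("")
    add(f"- transomics version: {__version__}")
    add(f"- seed: {cfg.seed}")
    add(f"- layer files: "
        + "; ".join(f"{k}={v}" for k, v in cfg.layers.items()))
    add(f"- metadata file: {cfg.metadata}")
    add("")
    return "\n".join(lines)
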