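"""All-pairs cross-layer correlation screen with per-pair thresholds.

Every factor of one layer is correlated against every factor of another
on their pairwise-complete samples, and each pair is tested against the
critical |r| for its *own* degrees of freedom — a factor observed in only
4 of the 6 samples faces r_crit > 0.99 rather than the full-overlap
0.91719. No multiple-testing correction is applied; the error rate is
controlled by the strict per-pair two-sided alpha (default 0.01), and the
number of tests performed is reported so users can correct afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import (
    DegenerateDataError,
    InsufficientOverlapError,
)
from .io import HarmonizedDataset
from .stats import CorrelationResult, pearson_r

__all__ = ["ScreenResult", "cross_layer_screen", "export_heatmap_matrix"]

R_DECIMALS = 5  # precision of written coefficients


@dataclass
class ScreenResult:
    """Outcome of one layer-pair screen.

    ``results`` holds one :class:`CorrelationResult` per computable factor
    pair; ``skipped`` records pairs with no >= 3-sample overlap or a
    degenerate (zero-variance) factor, with the reason. Together they
    cover the full factor-pair grid.
    """

    layer_a: str
    layer_b: str
    alpha: float
    results: list[CorrelationResult] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)
    factors_a: list[str] = field(default_factory=list)
    factors_b: list[str] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.results)

    def significant_pairs(self) -> list[CorrelationResult]:
        return [r for r in self.results if r.significant]

    def lookup(self, factor_a: str, factor_b: str) -> CorrelationResult | None:
        for r in self.results:
            if r.factor_a == factor_a and r.factor_b == factor_b:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: factor_a, factor_b, n, df, r, t, r_crit, significant."""
        rows = [
            {
                "factor_a": r.factor_a, "factor_b": r.factor_b,
                "n": r.n, "df": r.df,
                "r": round(r.r, R_DECIMALS),
                "t": round(r.t, R_DECIMALS) if r.t != float("inf") else float("inf"),
                "r_crit": round(r.r_crit, R_DECIMALS),
                "significant": r.significant,
            }
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=["factor_a", "factor_b", "n", "df", "r", "t", "r_crit",
                     "significant"],
        )


def cross_layer_screen(
    dataset: HarmonizedDataset,
    layer_a: str,
    layer_b: str,
    alpha: float = 0.01,
) -> ScreenResult:
    """Correlate every factor of ``layer_a`` against every factor of ``layer_b``.

    Pairs with fewer than 3 complete samples or a constant factor are put
    into ``skipped`` rather than silently dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    la = dataset.layer(layer_a)
    lb = dataset.layer(layer_b)
    screen = ScreenResult(
        layer_a=layer_a, layer_b=layer_b, alpha=alpha,
        factors_a=list(la.factors), factors_b=list(lb.factors),
    )
    for fa in la.factors:
        xa = la.values.loc[fa].to_numpy(dtype=float)
        for fb in lb.factors:
            xb = lb.values.loc[fb].to_numpy(dtype=float)
            try:
                res = pearson_r(
                    xa, xb, alpha=alpha,
                    factor_a=fa, layer_a=layer_a,
                    factor_b=fb, layer_b=layer_b,
                )
            except InsufficientOverlapError:
                screen.skipped.append((fa, fb, "insufficient overlap"))
            except DegenerateDataError:
                screen.skipped.append((fa, fb, "degenerate factor"))
            else:
                screen.results.append(res)
    return screen


def export_heatmap_matrix(screen: ScreenResult, path) -> Path:
    """Write the screen as a wide r matrix (rows = layer_a factors).

    Skipped pairs are written as ``NA``. A companion ``*.flags.<ext>``
    file holds the significance booleans on the same grid. Output is
    deterministic: identical screens yield byte-identical files.
    """
    if not screen.results and not screen.skipped:
        raise ValueError("empty screen: nothing to export")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    seen_a = {r.factor_a for r in screen.results} | {fa for fa, _, _ in screen.skipped}
    seen_b = {r.factor_b for r in screen.results} | {fb for _, fb, _ in screen.skipped}
    if screen.factors_a and screen.factors_b:
        rows = [f for f in screen.factors_a if f in seen_a]
        cols = [f for f in screen.factors_b if f in seen_b]
    else:  # fall back to first-appearance order for hand-built screens
        rows = sorted(seen_a, key=lambda f: _first_index(screen, f, axis=0))
        cols = sorted(seen_b, key=lambda f: _first_index(screen, f, axis=1))
    rmat = pd.DataFrame(index=rows, columns=cols, dtype=object)
    fmat = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for r in screen.results:
        rmat.loc[r.factor_a, r.factor_b] = f"{r.r:.{R_DECIMALS}f}"
        fmat.loc[r.factor_a, r.factor_b] = str(bool(r.significant))
    for fa, fb, _reason in screen.skipped:
        rmat.loc[fa, fb] = "NA"
        fmat.loc[fa, fb] = "NA"
    rmat.index.name = "factor_id"
    fmat.index.name = "factor_id"
    rmat.to_csv(path, sep=sep, lineterminator="\n")
    flags_path = path.with_suffix(".flags" + path.suffix)
    fmat.to_csv(flags_path, sep=sep, lineterminator="\n")
    return path


def _first_index(screen: ScreenResult, factor: str, axis: int) -> int:
    """Original factor order: position of first appearance in the screen grid."""
    seq = [
        (r.factor_a if axis == 0 else r.factor_b) for r in screen.results
    ] + [
        (fa if axis == 0 else fb) for fa, fb, _ in screen.skipped
    ]
    return seq.index(factor)
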