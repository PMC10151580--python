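"""Triad finding, partial-correlation mediation profiles, covariate checks.

A triad is one factor per omics layer whose three cross-layer pairs are
all individually significant in the screens. For each triad the three
first-order partials are computed on the triple-complete samples; if the
partial between two factors collapses while both partials involving the
third stay strong, the third factor is called the mediator. Because no
significance test is attached to a partial at these sample sizes, the
classification compares magnitudes only: a partial below
``drop_threshold`` counts as collapsed and one at or above
``retain_threshold`` as retained.

The covariate stage plays the same game against clinical covariates —
antipsychotic dose in chlorpromazine equivalents (CPeq, mg/day; controls
are 0 by convention) and age at death (AoD, years): each triad factor is
correlated with each covariate, and each factor pair is re-examined with
the covariate partialled out, to check that the cross-layer correlations
are not mere dose or age artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    CollinearControlError,
    DegenerateDataError,
    InsufficientOverlapError,
)
from .io import HarmonizedDataset
from .screening import ScreenResult
from .stats import partial_r

__all__ = [
    "Triad",
    "TriadReport",
    "CovariateReport",
    "find_triads",
    "mediation_profile",
    "covariate_analysis",
    "DROP_THRESHOLD",
    "RETAIN_THRESHOLD",
]

# magnitude thresholds for the verbal mediation call: a partial below 0.30
# counts as collapsed, one at/above 0.50 as retained (configurable)
DROP_THRESHOLD = 0.30
RETAIN_THRESHOLD = 0.50

Factor = tuple[str, str]  # (layer, factor_id)


@dataclass(frozen=True)
class Triad:
    """One factor per layer, ordered lexicographically by layer name."""

    x: Factor
    y: Factor
    z: Factor

    def members(self) -> tuple[Factor, Factor, Factor]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class TriadReport:
    """Marginals, first-order partials and the mediation call for a triad.

    ``partial_xy_z`` is the partial correlation of x and y controlling z,
    and cyclically. ``classification`` is one of ``mediated-by-x``,
    ``mediated-by-y``, ``mediated-by-z``, ``direct``, ``indeterminate``.
    """

    triad: Triad
    n: int
    r_xy: float
    r_xz: float
    r_yz: float
    partial_xy_z: float
    partial_xz_y: float
    partial_yz_x: float
    classification: str


@dataclass(frozen=True)
class CovariateReport:
    """One triad factor against one clinical covariate.

    ``r_marginal`` is the factor-covariate correlation; ``partials`` maps
    each *other* triad factor to the factor-factor partial correlation
    with this covariate controlled.
    """

    factor: str
    layer: str
    covariate: str
    r_marginal: float
    partials: dict[Factor, float]


# ---------------------------------------------------------------------------
# triad enumeration
# ---------------------------------------------------------------------------

def find_triads(screens: list[ScreenResult]) -> list[Triad]:
    """All (x, y, z), one factor per layer, with three significant pairs.

    ``screens`` must cover the three distinct pairs of exactly three
    layers. Output order is deterministic: lexicographic by layer name,
    then by factor ID within each layer.
    """
    pair_index: dict[frozenset[str], ScreenResult] = {}
    layer_names: set[str] = set()
    for s in screens:
        key = frozenset((s.layer_a, s.layer_b))
        if len(key) != 2 or key in pair_index:
            raise ValueError("screens must cover three distinct layer pairs")
        pair_index[key] = s
        layer_names |= key
    if len(screens) != 3 or len(layer_names) != 3:
        raise ValueError(
            f"need 3 screens over 3 layers, got {len(screens)} screens "
            f"over {sorted(layer_names)}"
        )
    l1, l2, l3 = sorted(layer_names)

    def sig_pairs(la: str, lb: str) -> set[tuple[str, str]]:
        s = pair_index[frozenset((la, lb))]
        flip = s.layer_a != la
        return {
            ((r.factor_b, r.factor_a) if flip else (r.factor_a, r.factor_b))
            for r in s.significant_pairs()
        }

    sig12 = sig_pairs(l1, l2)
    sig13 = sig_pairs(l1, l3)
    sig23 = sig_pairs(l2, l3)
    f1s = sorted({a for a, _ in sig12} & {a for a, _ in sig13})
    triads = []
    for f1 in f1s:
        partners2 = sorted({b for a, b in sig12 if a == f1})
        partners3 = sorted({c for a, c in sig13 if a == f1})
        for f2, f3 in itertools.product(partners2, partners3):
            if (f2, f3) in sig23:
                triads.append(Triad(x=(l1, f1), y=(l2, f2), z=(l3, f3)))
    return triads


# ---------------------------------------------------------------------------
# mediation profile
# ---------------------------------------------------------------------------

def _triple_complete(dataset: HarmonizedDataset, triad: Triad):
    cols = []
    for layer, factor in triad.members():
        cols.append(dataset.factor_values(layer, factor).to_numpy(dtype=float))
    x, y, z = cols
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    return x[mask], y[mask], z[mask], int(mask.sum())


def classify_mediation(
    partial_xy_z: float,
    partial_xz_y: float,
    partial_yz_x: float,
    drop_threshold: float = DROP_THRESHOLD,
    retain_threshold: float = RETAIN_THRESHOLD,
) -> str:
    """Verbal mediation call from the three partial magnitudes.

    mediated-by-m: the partial *not* involving m collapses below
    ``drop_threshold`` while both partials involving m stay at or above
    ``retain_threshold``. ``direct`` when no mediator qualifies but some
    partial remains strong; ``indeterminate`` otherwise (including the
    ambiguous case of two qualifying mediators).
    """
    p = {
        "z": partial_xy_z,  # controlling z leaves the x-y partial
        "y": partial_xz_y,
        "x": partial_yz_x,
    }
    candidates = []
    for m in ("x", "y", "z"):
        others = [v for k, v in p.items() if k != m]
        if abs(p[m]) < drop_threshold and all(
            abs(v) >= retain_threshold for v in others
        ):
            candidates.append(m)
    if len(candidates) == 1:
        return f"mediated-by-{candidates[0]}"
    if len(candidates) > 1:
        return "indeterminate"
    if max(abs(v) for v in p.values()) >= retain_threshold:
        return "direct"
    return "indeterminate"


def mediation_profile(
    dataset: HarmonizedDataset,
    triad: Triad,
    drop_threshold: float = DROP_THRESHOLD,
    retain_threshold: float = RETAIN_THRESHOLD,
) -> TriadReport:
    """Marginals + first-order partials for a triad, on triple-complete samples.

    Needs >= 4 complete samples; a marginal of |r| = 1 among the
    controlled pairs makes a partial undefined (collinearity).
    """
    x, y, z, n = _triple_complete(dataset, triad)
    if n < 4:
        raise InsufficientOverlapError(
            f"triad {triad}: only {n} triple-complete samples (need >= 4)"
        )
    for v, (layer, factor) in zip((x, y, z), triad.members()):
        if np.ptp(v) == 0:
            raise DegenerateDataError(f"constant factor {factor!r} in {layer!r}")
    c = np.corrcoef(np.vstack([x, y, z]))
    r_xy, r_xz, r_yz = (float(c[0, 1]), float(c[0, 2]), float(c[1, 2]))
    try:
        p_xy_z = partial_r(r_xy, r_xz, r_yz)
        p_xz_y = partial_r(r_xz, r_xy, r_yz)
        p_yz_x = partial_r(r_yz, r_xy, r_xz)
    except CollinearControlError as e:
        raise CollinearControlError(f"triad {triad}: {e}") from None
    return TriadReport(
        triad=triad, n=n, r_xy=r_xy, r_xz=r_xz, r_yz=r_yz,
        partial_xy_z=p_xy_z, partial_xz_y=p_xz_y, partial_yz_x=p_yz_x,
        classification=classify_mediation(
            p_xy_z, p_xz_y, p_yz_x, drop_threshold, retain_threshold
        ),
    )


def triads_to_frame(reports: list[TriadReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        (lx, fx), (ly, fy), (lz, fz) = rep.triad.members()
        rows.append({
            "layer_x": lx, "factor_x": fx,
            "layer_y": ly, "factor_y": fy,
            "layer_z": lz, "factor_z": fz,
            "n": rep.n,
            "r_xy": round(rep.r_xy, 5), "r_xz": round(rep.r_xz, 5),
            "r_yz": round(rep.r_yz, 5),
            "partial_xy_z": round(rep.partial_xy_z, 5),
            "partial_xz_y": round(rep.partial_xz_y, 5),
            "partial_yz_x": round(rep.partial_yz_x, 5),
            "classification": rep.classification,
        })
    return pd.DataFrame(rows, columns=[
        "layer_x", "factor_x", "layer_y", "factor_y", "layer_z", "factor_z",
        "n", "r_xy", "r_xz", "r_yz", "partial_xy_z", "partial_xz_y",
        "partial_yz_x", "classification",
    ])


# ---------------------------------------------------------------------------
# covariate analysis
# ---------------------------------------------------------------------------

def covariate_analysis(
    dataset: HarmonizedDataset,
    triad: Triad,
    covariates: tuple[str, ...] = ("CPeq", "AoD"),
) -> list[CovariateReport]:
    """Correlate triad factors with covariates and partial the covariates out.

    For each (factor, covariate): the marginal r on pairwise-complete
    samples. For each factor pair of the triad: the partial correlation
    controlling the covariate, on samples complete in both factors and
    the covariate. A covariate constant over the analyzed samples is an
    error (degenerate covariate).
    """
    reports: list[CovariateReport] = []
    members = triad.members()
    values = {
        m: dataset.factor_values(*m).to_numpy(dtype=float) for m in members
    }
    for cov_name in covariates:
        cov = dataset.covariate(cov_name).to_numpy(dtype=float)
        for m in members:
            layer, factor = m
            v = values[m]
            mask = np.isfinite(v) & np.isfinite(cov)
            if mask.sum() < 3:
                raise InsufficientOverlapError(
                    f"{factor} vs {cov_name}: only {int(mask.sum())} samples"
                )
            if np.ptp(cov[mask]) == 0:
                raise DegenerateDataError(
                    f"degenerate covariate {cov_name!r}: constant over the "
                    "analyzed samples"
                )
            if np.ptp(v[mask]) == 0:
                raise DegenerateDataError(f"constant factor {factor!r}")
            r_marg = float(np.corrcoef(v[mask], cov[mask])[0, 1])
            partials: dict[Factor, float] = {}
            for other in members:
                if other == m:
                    continue
                w = values[other]
                tmask = np.isfinite(v) & np.isfinite(w) & np.isfinite(cov)
                if tmask.sum() < 4:
                    raise InsufficientOverlapError(
                        f"{factor}/{other[1]}/{cov_name}: "
                        f"only {int(tmask.sum())} complete samples"
                    )
                c = np.corrcoef(np.vstack([v[tmask], w[tmask], cov[tmask]]))
                partials[other] = partial_r(c[0, 1], c[0, 2], c[1, 2])
            reports.append(CovariateReport(
                factor=factor, layer=layer, covariate=cov_name,
                r_marginal=r_marg, partials=partials,
            ))
    return reports


def covariates_to_frame(reports: list[CovariateReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for (olayer, ofactor), p in rep.partials.items():
            rows.append({
                "layer": rep.layer, "factor": rep.factor,
                "covariate": rep.covariate,
                "r_marginal": round(rep.r_marginal, 5),
                "partner_layer": olayer, "partner_factor": ofactor,
                "r_partial_pair": round(p, 5),
            })
    return pd.DataFrame(rows, columns=[
        "layer", "factor", "covariate", "r_marginal",
        "partner_layer", "partner_factor", "r_partial_pair",
    ])
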