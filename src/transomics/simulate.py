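"""Synthetic multi-omics case-control cohorts with planted structure.

The generator emulates the shape of the study design the pipeline is
built for: a handful of case and control post-mortem samples (default
3 SCZ / 3 CON) measured on a small lipidomics layer (2 factors), a
transcriptomics layer (7 factors) and a proteomics layer (17 factors),
with per-sample clinical covariates. One factor per layer can carry a
planted relationship:

mediated
    x = a*z + e, y = b*z + e' with the driver z written into the third
    layer. All planted factors have unit population variance, so the
    loadings a, b are population correlations and recovery targets are
    analytic (r_xz -> a, r_yz -> b, r_xy -> a*b).
direct
    y = c*x + e with z an independent factor: a genuine x-y edge with no
    mediator.
confounded
    x and y both driven by the standardized CPeq dose, with no direct
    link: partialling out CPeq should collapse r_xy.
null
    every factor independent Gaussian noise.

Optional per-factor missing samples reproduce reduced-overlap situations
(a factor observed in only 4 of 6 samples), and a single-point outlier of
configurable magnitude exercises the Dixon QC stage. The truth record
stores every planted parameter so tests never reverse-engineer the
generator. One root seed drives deterministic per-layer substreams:
adding a layer does not perturb the draws of existing layers.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import UnknownReferenceError, ValidationError
from .io import HarmonizedDataset, OmicsLayer, harmonize, write_layer, write_metadata

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "inject_outlier"]

LAYER_NAMES = ("lipidomics", "transcriptomics", "proteomics")
LAYER_PREFIXES = {"lipidomics": "lipid", "transcriptomics": "gene",
                  "proteomics": "protein"}
STRUCTURES = ("mediated", "direct", "confounded", "null")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic cohort.

    ``loading_a``/``loading_b`` are the population correlations of the
    planted x and y factors with the latent driver (mediated/confounded)
    or the x->y coefficient (direct, via ``loading_a``). ``group_shift``
    is an additive offset (in population-SD units) applied to the planted
    factors of SCZ samples. ``noise_sd`` overrides the unit-variance
    normalization residual SD when set. ``missing_pattern`` maps factor ID
    to sample IDs to blank; ``outlier`` is (factor, sample, magnitude in
    residual SDs) applied after generation. The seed fully determines the
    output.
    """

    n_scz: int = 3
    n_con: int = 3
    layer_sizes: tuple[int, int, int] = (2, 7, 17)
    structure: str = "mediated"
    loading_a: float = 0.95
    loading_b: float = 0.95
    noise_sd: Optional[float] = None
    group_shift: float | tuple[float, float, float] = 0.0
    cpeq_range: tuple[float, float] = (200.0, 800.0)
    missing_pattern: dict[str, tuple[str, ...]] = field(default_factory=dict)
    outlier: Optional[tuple[str, str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scz < 0 or self.n_con < 0:
            raise ValidationError("group sizes must be >= 0")
        if self.structure not in STRUCTURES:
            raise ValidationError(
                f"structure must be one of {STRUCTURES}, got {self.structure!r}"
            )
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for name, v in (("loading_a", self.loading_a),
                        ("loading_b", self.loading_b)):
            if not -1 < v < 1 and self.noise_sd is None:
                raise ValidationError(
                    f"{name} must be in (-1, 1) under unit-variance "
                    f"normalization, got {v}"
                )
        if isinstance(self.group_shift, (tuple, list)) \
                and len(self.group_shift) != 3:
            raise ValidationError(
                "group_shift must be a scalar or one value per layer"
            )

    def shift_for(self, layer: str) -> float:
        """SCZ-vs-CON offset of the planted factor in ``layer``."""
        if isinstance(self.group_shift, (tuple, list)):
            return float(dict(zip(LAYER_NAMES, self.group_shift))[layer])
        return float(self.group_shift)


@dataclass
class SyntheticDataset:
    """Generated layers + metadata + the ground-truth record."""

    layers: dict[str, OmicsLayer]
    metadata: pd.DataFrame
    truth: dict

    def harmonized(self) -> HarmonizedDataset:
        return harmonize(self.layers.values(), self.metadata)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label substream of one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def _sample_ids(spec: SyntheticSpec) -> list[str]:
    return ([f"S{i + 1:02d}" for i in range(spec.n_scz)]
            + [f"C{i + 1:02d}" for i in range(spec.n_con)])


def _factor_ids(layer: str, size: int) -> list[str]:
    prefix = LAYER_PREFIXES.get(layer, layer)
    return [f"{prefix}_{i + 1:03d}" for i in range(size)]


def _make_metadata(spec: SyntheticSpec, samples: list[str]) -> pd.DataFrame:
    rng = _substream(spec.seed, "metadata")
    n = len(samples)
    is_scz = np.array([s.startswith("S") for s in samples])
    age = rng.integers(60, 91, size=n).astype(float)
    sex = rng.choice(["Male", "Female"], size=n)
    pmi = np.round(rng.uniform(4.0, 20.0, size=n), 1)
    doi = np.where(is_scz, rng.integers(20, 61, size=n), 0).astype(float)
    lo, hi = spec.cpeq_range
    cpeq = np.where(is_scz, np.round(rng.uniform(lo, hi, size=n), 0), 0.0)
    meta = pd.DataFrame({
        "diagnosis": np.where(is_scz, "SCZ", "CON"),
        "age": age, "sex": sex, "pmi": pmi, "doi": doi, "cpeq": cpeq,
        "cause_of_death": ["synthetic"] * n,
    }, index=pd.Index(samples, name="sample_id"))
    return meta


def generate_dataset(
    spec: SyntheticSpec, outdir: Optional[Path] = None
) -> SyntheticDataset:
    """Generate a cohort; optionally write layer/metadata/truth files.

    Written files (``layer_<name>.tsv``, ``metadata.tsv``, ``truth.json``)
    are byte-identical across calls with the same spec.
    """
    samples = _sample_ids(spec)
    n = len(samples)
    if n < 3:
        raise ValidationError("need at least 3 samples in total")
    meta = _make_metadata(spec, samples)
    is_scz = (meta["diagnosis"] == "SCZ").to_numpy()

    # latent driver shared across layers (own substream)
    driver = _substream(spec.seed, "latent-driver").standard_normal(n)

    layer_ids = {
        name: _factor_ids(name, size)
        for name, size in zip(LAYER_NAMES, spec.layer_sizes)
    }
    planted = {name: ids[0] if ids else None
               for name, ids in layer_ids.items()}
    x_layer, y_layer, z_layer = LAYER_NAMES

    def resid_sd(loading: float) -> float:
        if spec.noise_sd is not None:
            return spec.noise_sd
        return float(np.sqrt(1.0 - loading ** 2))

    # standardized confounder for the 'confounded' structure
    cpeq = meta["cpeq"].to_numpy(dtype=float)
    if spec.structure == "confounded":
        if np.ptp(cpeq) == 0:
            raise ValidationError("confounded structure needs varying CPeq")
        conf = (cpeq - cpeq.mean()) / cpeq.std()

    layers: dict[str, OmicsLayer] = {}
    for name in LAYER_NAMES:
        ids = layer_ids[name]
        rng = _substream(spec.seed, f"layer:{name}")
        mat = rng.standard_normal((len(ids), n))
        p = planted[name]
        if p is not None:
            noise = mat[0]  # reuse the planted row's iid draw as residual
            if spec.structure == "mediated":
                if name == z_layer:
                    mat[0] = driver
                elif name == x_layer:
                    mat[0] = spec.loading_a * driver + resid_sd(spec.loading_a) * noise
                else:
                    mat[0] = spec.loading_b * driver + resid_sd(spec.loading_b) * noise
            elif spec.structure == "direct":
                if name == x_layer:
                    mat[0] = driver
                elif name == y_layer:
                    mat[0] = spec.loading_a * driver + resid_sd(spec.loading_a) * noise
                # z stays independent noise
            elif spec.structure == "confounded":
                if name == x_layer:
                    mat[0] = spec.loading_a * conf + resid_sd(spec.loading_a) * noise
                elif name == y_layer:
                    mat[0] = spec.loading_b * conf + resid_sd(spec.loading_b) * noise
            # null: leave everything as independent noise
            shift = spec.shift_for(name)
            if shift:
                mat[0] = mat[0] + shift * is_scz
        values = pd.DataFrame(mat, index=ids, columns=samples)
        layers[name] = OmicsLayer(name=name, values=values, unit="synthetic a.u.")

    truth: dict = {
        "spec": _spec_to_jsonable(spec),
        "samples": samples,
        "planted": {
            "structure": spec.structure,
            "x": {"layer": x_layer, "factor": planted[x_layer],
                  "loading": spec.loading_a},
            "y": {"layer": y_layer, "factor": planted[y_layer],
                  "loading": spec.loading_b},
            "z": {"layer": z_layer, "factor": planted[z_layer]},
            "group_shift": {nm: spec.shift_for(nm) for nm in LAYER_NAMES},
        },
        "missing": {},
        "outlier": None,
    }

    for factor, withheld in spec.missing_pattern.items():
        hits = [nm for nm, ids in layer_ids.items() if factor in ids]
        if not hits:
            raise ValidationError(f"missing_pattern references absent factor {factor!r}")
        lay = layers[hits[0]]
        for s in withheld:
            if s not in samples:
                raise ValidationError(
                    f"missing_pattern references absent sample {s!r}"
                )
            lay.values.loc[factor, s] = np.nan
        truth["missing"][factor] = {"layer": hits[0], "samples": list(withheld)}

    if spec.outlier is not None:
        factor, sample, magnitude = spec.outlier
        hits = [nm for nm, ids in layer_ids.items() if factor in ids]
        if not hits:
            raise ValidationError(f"outlier references absent factor {factor!r}")
        original = inject_outlier(layers[hits[0]], factor, sample, magnitude)
        truth["outlier"] = {
            "layer": hits[0], "factor": factor, "sample": sample,
            "magnitude": magnitude, "original_value": original,
        }

    ds = SyntheticDataset(layers=layers, metadata=meta, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, lay in layers.items():
            write_layer(lay, outdir / f"layer_{name}.tsv")
        write_metadata(meta, outdir / "metadata.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )
    return ds


def inject_outlier(
    layer: OmicsLayer, factor: str, sample: str, magnitude: float
) -> float:
    """Replace one cell by mean + magnitude*SD of the factor's other values.

    Modifies the layer in place and returns the original cell value (for
    the truth record). The target cell must exist and be non-missing.
    """
    if factor not in layer.values.index:
        raise UnknownReferenceError(f"unknown factor {factor!r}")
    if sample not in layer.values.columns:
        raise UnknownReferenceError(f"unknown sample {sample!r}")
    original = float(layer.values.loc[factor, sample])
    if not np.isfinite(original):
        raise UnknownReferenceError(
            f"cell ({factor!r}, {sample!r}) is missing; cannot inject"
        )
    others = layer.values.loc[factor].drop(sample).to_numpy(dtype=float)
    others = others[np.isfinite(others)]
    if others.size < 2:
        raise UnknownReferenceError(
            f"factor {factor!r}: too few other values to scale the outlier"
        )
    layer.values.loc[factor, sample] = (
        others.mean() + magnitude * others.std(ddof=1)
    )
    return original


def _spec_to_jsonable(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["layer_sizes"] = list(spec.layer_sizes)
    d["cpeq_range"] = list(spec.cpeq_range)
    if isinstance(spec.group_shift, (tuple, list)):
        d["group_shift"] = list(spec.group_shift)
    d["missing_pattern"] = {k: list(v) for k, v in spec.missing_pattern.items()}
    d["outlier"] = list(spec.outlier) if spec.outlier else None
    return d
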