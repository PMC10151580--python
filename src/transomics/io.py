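"""Layer / metadata file reading, sample harmonization, outlier policy.

A layer file is a delimited table whose cell [0,0] is ``factor_id``, whose
remaining column headers are sample IDs, and whose cells are numbers or
``NA``. The metadata file carries one row per subject with diagnosis
(SCZ/CON), age at death, sex, post-mortem interval (h), duration of
illness (y), chlorpromazine-equivalent dose (mg/day; 0 for controls by
convention) and cause of death. Harmonization restricts every layer to
the samples common to all layers and the metadata, in metadata row order.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    NoCommonSamplesError,
    UnknownReferenceError,
    ValidationError,
)
from .stats import DixonResult

__all__ = [
    "OmicsLayer",
    "HarmonizedDataset",
    "read_layer",
    "read_metadata",
    "packaged_metadata",
    "harmonize",
    "apply_outlier_policy",
    "write_layer",
    "write_metadata",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = [
    "sample_id", "diagnosis", "age", "sex", "pmi", "doi", "cpeq",
    "cause_of_death",
]

_DIAGNOSIS_ALIASES = {
    "SCZ": "SCZ", "SCHIZOPHRENIA": "SCZ",
    "CON": "CON", "CONTROL": "CON", "CTRL": "CON",
}


@dataclass
class OmicsLayer:
    """One omics layer: a factor x sample matrix with a name and unit.

    ``values`` is a DataFrame indexed by factor ID with sample IDs as
    columns; NaN marks a missing measurement.
    """

    name: str
    values: pd.DataFrame
    unit: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError(f"layer {self.name!r}: duplicate factor IDs")
        if self.values.columns.has_duplicates:
            raise FormatError(f"layer {self.name!r}: duplicate sample IDs")
        self.values.index.name = "factor_id"

    @property
    def factors(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def availability(self) -> pd.Series:
        """Number of non-missing samples per factor."""
        return self.values.notna().sum(axis=1)


@dataclass
class HarmonizedDataset:
    """Layers restricted to a common sample set plus matching metadata."""

    layers: dict[str, OmicsLayer]
    metadata: pd.DataFrame
    common_samples: list[str] = field(default_factory=list)

    def layer(self, name: str) -> OmicsLayer:
        try:
            return self.layers[name]
        except KeyError:
            raise UnknownReferenceError(
                f"unknown layer {name!r}; have {sorted(self.layers)}"
            ) from None

    def factor_values(self, layer: str, factor: str) -> pd.Series:
        lay = self.layer(layer)
        if factor not in lay.values.index:
            raise UnknownReferenceError(
                f"unknown factor {factor!r} in layer {layer!r}"
            )
        return lay.values.loc[factor]

    def covariate(self, name: str) -> pd.Series:
        """Resolve a covariate vector over the common samples.

        ``CPeq``: chlorpromazine-equivalent dose; missing entries for CON
        samples are 0 by convention, missing for SCZ is an error.
        ``AoD``: age at death.
        """
        key = name.strip().lower()
        meta = self.metadata
        if key in ("aod", "age"):
            return meta["age"].astype(float)
        if key == "cpeq":
            vals = meta["cpeq"].astype(float).copy()
            con = meta["diagnosis"] == "CON"
            vals[con & vals.isna()] = 0.0
            bad = meta.index[(~con) & vals.isna()]
            if len(bad):
                raise ValidationError(
                    f"CPeq missing for SCZ sample(s) {list(bad)}; only CON "
                    "may be imputed as 0"
                )
            return vals
        raise UnknownReferenceError(f"unknown covariate {name!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_layer(
    path, name: str, unit: str = "", delimiter: Optional[str] = None
) -> OmicsLayer:
    """Read a factor x sample layer table (CSV/TSV, ``NA`` for missing)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: expected a header with >= 1 sample column")
    header = rows[0]
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample IDs in header")
    factors, data = [], []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(f"{path} line {i}: {len(row)} fields, "
                              f"expected {len(header)}")
        factors.append(row[0])
        parsed = []
        for j, cell in enumerate(row[1:], start=1):
            cell = cell.strip()
            if cell in ("NA", "", "NaN", "nan"):
                parsed.append(np.nan)
            else:
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path} line {i}, column {header[j]!r}: "
                        f"non-numeric cell {cell!r}"
                    ) from None
        data.append(parsed)
    if len(set(factors)) != len(factors):
        raise FormatError(f"{path}: duplicate factor IDs")
    values = pd.DataFrame(data, index=factors, columns=samples, dtype=float)
    return OmicsLayer(name=name, values=values, unit=unit)


def read_metadata(path, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read the sample metadata table; returns a frame indexed by sample_id.

    Diagnosis is normalized to {SCZ, CON}; age/pmi/doi/cpeq must be
    nonnegative. A CON row with cpeq > 0 violates the controls-as-0
    convention and triggers a warning (not an error).
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    meta = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")
    out = pd.DataFrame(index=pd.Index(meta["sample_id"], name="sample_id"))
    diag = meta["diagnosis"].str.strip().str.upper().map(_DIAGNOSIS_ALIASES)
    if diag.isna().any():
        bad = meta.loc[diag.isna().to_numpy(), "diagnosis"].tolist()
        raise ValidationError(f"{path}: unrecognized diagnosis value(s) {bad}")
    out["diagnosis"] = diag.to_numpy()
    for col in ("age", "pmi", "doi", "cpeq"):
        vals = pd.to_numeric(meta[col].replace({"NA": None, "": None}),
                             errors="coerce")
        raw_present = ~meta[col].isin(["NA", ""])
        if (vals.isna() & raw_present).any():
            raise FormatError(f"{path}: non-numeric value in column {col!r}")
        if (vals.dropna() < 0).any():
            raise ValidationError(f"{path}: negative value in column {col!r}")
        out[col] = vals.to_numpy()
    out["sex"] = meta["sex"].str.strip().to_numpy()
    out["cause_of_death"] = meta["cause_of_death"].to_numpy()
    con_dosed = (out["diagnosis"] == "CON") & (out["cpeq"].fillna(0) > 0)
    if con_dosed.any():
        warnings.warn(
            f"CON sample(s) {list(out.index[con_dosed])} have cpeq > 0; "
            "controls are conventionally 0 mg/day",
            stacklevel=2,
        )
    return out


def packaged_metadata() -> pd.DataFrame:
    """The packaged 6-subject metadata fixture (3 SCZ / 3 CON)."""
    ref = importlib.resources.files("transomics.data") / "subjects_metadata.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_metadata(p)


def write_layer(layer: OmicsLayer, path, delimiter: Optional[str] = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["factor_id"] + layer.samples)
        for fac in layer.factors:
            row = [fac] + [
                "NA" if not np.isfinite(v) else repr(float(v))
                for v in layer.values.loc[fac].to_numpy(dtype=float)
            ]
            w.writerow(row)


def write_metadata(meta: pd.DataFrame, path, delimiter: Optional[str] = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    out = meta.reset_index()[METADATA_COLUMNS]
    out.to_csv(path, sep=sep, index=False, na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# harmonization and the outlier policy
# ---------------------------------------------------------------------------

def harmonize(
    layers: Iterable[OmicsLayer], metadata: pd.DataFrame
) -> HarmonizedDataset:
    """Restrict all layers to their common samples, in metadata row order.

    Idempotent: harmonizing an already-harmonized dataset is a no-op.
    """
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError("harmonize needs at least 2 layers")
    names = [lay.name for lay in layers]
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate layer names: {names}")
    common = set(metadata.index)
    for lay in layers:
        common &= set(lay.samples)
    ordered = [s for s in metadata.index if s in common]
    if not ordered:
        raise NoCommonSamplesError(
            "no common samples across layers and metadata"
        )
    restricted = {
        lay.name: replace(lay, values=lay.values.loc[:, ordered].copy())
        for lay in layers
    }
    return HarmonizedDataset(
        layers=restricted,
        metadata=metadata.loc[ordered].copy(),
        common_samples=ordered,
    )


def apply_outlier_policy(
    dataset: HarmonizedDataset,
    flags: Iterable[DixonResult],
    policy: str = "drop-value",
) -> HarmonizedDataset:
    """Apply the outlier-exclusion policy for Dixon-flagged cells.

    drop-value
        flagged cells become missing; the factor stays with reduced
        availability (the default, mirroring a cell-level exclusion).
    drop-factor
        the whole flagged factor row is removed from its layer.
    keep
        data unchanged; flags are only carried for reporting.
    """
    if policy not in ("drop-value", "drop-factor", "keep"):
        raise ValueError(f"unknown outlier policy {policy!r}")
    flags = [f for f in flags if f.is_outlier]
    layers = {name: replace(lay, values=lay.values.copy())
              for name, lay in dataset.layers.items()}
    for f in flags:
        if f.layer not in layers:
            raise UnknownReferenceError(f"flag references unknown layer {f.layer!r}")
        lay = layers[f.layer]
        if f.factor not in lay.values.index:
            raise UnknownReferenceError(
                f"flag references unknown factor {f.factor!r} in {f.layer!r}"
            )
        if f.outlier_sample not in lay.values.columns:
            raise UnknownReferenceError(
                f"flag references unknown sample {f.outlier_sample!r}"
            )
        if policy == "drop-value":
            lay.values.loc[f.factor, f.outlier_sample] = np.nan
        elif policy == "drop-factor":
            layers[f.layer] = replace(
                lay, values=lay.values.drop(index=f.factor)
            )
    return HarmonizedDataset(
        layers=layers,
        metadata=dataset.metadata.copy(),
        common_samples=list(dataset.common_samples),
    )
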