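"""Delimited-text I/O for feature tables, sample metadata and fitted models.

A feature table is a dense samples x features matrix of non-negative peak
intensities; feature identifiers are by convention chemical-shift labels
such as ``d1.332``.  Sample metadata records the handling history of each
sample: donor, pre-centrifugation delay time in hours and pre-centrifugation
temperature in degrees Celsius.

Fitted models (drift models and handling-prediction models) are serialized
to a single human-inspectable JSON document with a mandatory format/version
header, rather than an opaque binary pickle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT = "plasmadrift-model"
MODEL_VERSION = 1

#: required columns of a sample-metadata table
META_COLUMNS = ("sample_id", "subject_id", "time_h", "temperature_c")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class FeatureTable:
    """Dense samples x features intensity matrix.

    Wraps a :class:`pandas.DataFrame` whose index holds unique sample ids and
    whose columns hold unique feature ids.  All intensities are finite,
    non-negative reals; missing values are rejected at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate feature ids: {dup[:5]}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"non-numeric intensity: {exc}") from exc
        if np.isnan(values).any():
            raise DataValidationError("missing intensities (NaN) in feature table")
        if not np.isfinite(values).all():
            raise DataValidationError("non-finite intensities in feature table")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative intensity at sample {df.index[i]!r}, "
                f"feature {df.columns[j]!r}"
            )
        if values.dtype != df.to_numpy().dtype:
            object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
    ) -> "FeatureTable":
        df = self.data
        if samples is not None:
            df = df.loc[list(samples)]
        if features is not None:
            df = df.loc[:, list(features)]
        return FeatureTable(df.copy())

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


def read_feature_table(
    path: str | Path,
    sep: str | None = None,
    orientation: str = "samples_rows",
    missing: str = "error",
) -> FeatureTable:
    """Read a delimited feature table.

    Parameters
    ----------
    path:
        Delimited text file; first row holds feature ids, first column sample
        ids (or transposed when ``orientation='features_rows'``).
    sep:
        Field delimiter; ``None`` auto-detects comma versus tab.
    orientation:
        ``'samples_rows'`` (canonical) or ``'features_rows'`` to transpose on
        load.
    missing:
        ``'error'`` (default) rejects empty cells; ``'impute_min'`` replaces
        each missing cell by the feature's minimum observed value.
    """
    path = Path(path)
    if orientation not in ("samples_rows", "features_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if missing not in ("error", "impute_min"):
        raise ValueError(f"unknown missing policy {missing!r}")
    resolved = _resolve_sep(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(resolved)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise DataValidationError(f"duplicate ids in header: {dup[:5]}")
    df = pd.read_csv(path, sep=resolved, index_col=0)
    if orientation == "features_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        if missing == "error":
            n = int(df.isna().sum().sum())
            raise DataValidationError(
                f"{n} missing cells in {path.name}; pass missing='impute_min' "
                "to impute by feature minima"
            )
        df = df.fillna(df.min(axis=0))
        if df.isna().any().any():
            raise DataValidationError("feature with no observed value cannot be imputed")
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a sample-metadata table.

    Requires columns ``sample_id, subject_id, time_h, temperature_c``; an
    optional ``group_label`` column carries coarse time levels (for legacy
    sample sets documented only as e.g. "same day" / "next day").
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_resolve_sep(path, sep))
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    meta.to_csv(path, sep=sep, index=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataValidationError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["subject_id"] = meta["subject_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"duplicate sample ids in metadata: {dup[:5]}")
    meta["time_h"] = pd.to_numeric(meta["time_h"], errors="raise").astype(float)
    meta["temperature_c"] = pd.to_numeric(meta["temperature_c"], errors="raise").astype(float)
    if (meta["time_h"] <= 0).any() or meta["time_h"].isna().any():
        bad = meta.loc[~(meta["time_h"] > 0), "sample_id"].tolist()
        raise DataValidationError(f"non-positive pre-centrifugation time for samples {bad[:5]}")
    if not np.isfinite(meta["temperature_c"]).all():
        raise DataValidationError("non-finite temperature in metadata")
    return meta


def match_samples(table: FeatureTable, meta: pd.DataFrame) -> dict[str, list[str]]:
    """Report the id overlap between a feature table and its metadata.

    Returns a dict with keys ``common``, ``table_only`` and ``meta_only``;
    a total join has both "only" lists empty.
    """
    t = set(table.sample_ids)
    m = set(meta["sample_id"])
    return {
        "common": sorted(t & m),
        "table_only": sorted(t - m),
        "meta_only": sorted(m - t),
    }


def join_samples(
    table: FeatureTable, meta: pd.DataFrame, strict: bool = True
) -> tuple[FeatureTable, pd.DataFrame]:
    """Align a feature table with metadata on sample id (table order).

    With ``strict=True`` any unmatched id on either side is an error; with
    ``strict=False`` the intersection is returned.
    """
    report = match_samples(table, meta)
    if strict and (report["table_only"] or report["meta_only"]):
        raise DataValidationError(
            "sample ids do not match: "
            f"table-only {report['table_only'][:5]}, "
            f"metadata-only {report['meta_only'][:5]}"
        )
    common = [s for s in table.sample_ids if s in set(report["common"])]
    sub = table.subset(samples=common)
    meta_idx = meta.set_index("sample_id", drop=False)
    return sub, meta_idx.loc[common].reset_index(drop=True)


# -- model serialization ------------------------------------------------------

class ModelFormatError(ValueError):
    """Raised on malformed or incompatible serialized model documents."""


def serialize_model(model, path: str | Path) -> None:
    """Write a fitted model to a structured JSON text document.

    Supports :class:`~plasmadrift.drift_model.DriftModel` and
    :class:`~plasmadrift.handling_predict.PredictionModel`.  The document is
    loss-free: deserialization restores fields and drift-function evaluations
    to within 1e-10 and prediction-model outputs exactly.
    """
    from .drift_model import DriftModel
    from .handling_predict import PredictionModel

    if isinstance(model, DriftModel):
        kind, payload = "drift", model.to_dict()
    elif isinstance(model, PredictionModel):
        kind, payload = "prediction", model.to_dict()
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    doc = {"format": MODEL_FORMAT, "version": MODEL_VERSION, "kind": kind, "payload": payload}
    Path(path).write_text(json.dumps(doc, indent=1))


def deserialize_model(path: str | Path):
    """Read a model document written by :func:`serialize_model`."""
    from .drift_model import DriftModel
    from .handling_predict import PredictionModel

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"not a valid model document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError("not a plasmadrift model document")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(f"unsupported model document version {doc.get('version')!r}")
    kind = doc.get("kind")
    if kind == "drift":
        return DriftModel.from_dict(doc["payload"])
    if kind == "prediction":
        return PredictionModel.from_dict(doc["payload"])
    raise ModelFormatError(f"unknown model kind {kind!r}")


def _resolve_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","
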