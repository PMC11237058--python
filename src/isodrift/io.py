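"""Reading and writing the package's table and spectrum formats.

Units are fixed package-wide: concentrations in µM, retention time in
minutes, chromatogram time in seconds, masses in Da, peak areas in
arbitrary counts. Feature tables round-trip losslessly (full float
precision) in either a tidy long CSV or a wide CSV with a two-row header
(sample id over group). MS2 spectra use MGF via pyteomics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .drift import FeatureMatrix
from .screen import MS2Record

__all__ = [
    "SchemaError",
    "load_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
]


class SchemaError(ValueError):
    """A required column or header is missing or malformed."""


_TIDY_REQUIRED = ("feature_id", "sample_id", "area")
_TIDY_SAMPLE_COLS = ("group", "injection_order", "time_hr")
_TIDY_FEATURE_COLS = ("mz", "rt_min")


def load_feature_table(path: str | Path, dialect: str = "tidy") -> FeatureMatrix:
    """Load a feature table CSV as a :class:`FeatureMatrix`.

    ``dialect="tidy"`` expects long form with at least feature_id,
    sample_id and area columns (sample metadata ``group``,
    ``injection_order``, ``time_hr`` and feature metadata ``mz``,
    ``rt_min`` are picked up when present). ``dialect="wide"`` expects
    features as rows and a two-row header: sample id over group.
    """
    path = Path(path)
    if dialect == "tidy":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _TIDY_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"tidy feature table is missing column(s): {', '.join(missing)}")
        values = df.pivot(index="feature_id", columns="sample_id", values="area")
        sample_meta_cols = [c for c in _TIDY_SAMPLE_COLS if c in df.columns]
        sample_meta = None
        if sample_meta_cols:
            sample_meta = (
                df.drop_duplicates("sample_id").set_index("sample_id")[sample_meta_cols]
            ).reindex(values.columns)
        feature_meta_cols = [c for c in _TIDY_FEATURE_COLS if c in df.columns]
        feature_meta = None
        if feature_meta_cols:
            feature_meta = (
                df.drop_duplicates("feature_id").set_index("feature_id")[feature_meta_cols]
            ).reindex(values.index)
        return FeatureMatrix(values=values, sample_meta=sample_meta, feature_meta=feature_meta)
    if dialect == "wide":
        try:
            df = pd.read_csv(path, header=[0, 1], index_col=0, float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as exc:
            raise SchemaError(f"malformed wide feature table header: {exc}") from exc
        if df.columns.nlevels != 2:
            raise SchemaError("wide feature table needs a two-row header (sample id, group)")
        values = df.copy()
        sample_ids = df.columns.get_level_values(0)
        groups = df.columns.get_level_values(1)
        values.columns = sample_ids
        values.index.name = "feature_id"
        sample_meta = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))
        sample_meta["injection_order"] = (
            sample_meta.groupby("group").cumcount().to_numpy()
        )
        return FeatureMatrix(values=values, sample_meta=sample_meta)
    raise SchemaError(f"unknown dialect {dialect!r} (expected 'tidy' or 'wide')")


def write_feature_table(matrix: FeatureMatrix, path: str | Path, dialect: str = "tidy") -> Path:
    """Write a :class:`FeatureMatrix` to CSV (inverse of load_feature_table)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "tidy":
        long = (
            matrix.values.rename_axis(index="feature_id", columns="sample_id")
            .stack()
            .rename("area")
            .reset_index()
        )
        if matrix.sample_meta is not None:
            long = long.merge(
                matrix.sample_meta.reset_index(names="sample_id"), on="sample_id", how="left"
            )
        if matrix.feature_meta is not None:
            long = long.merge(
                matrix.feature_meta.reset_index(names="feature_id"), on="feature_id", how="left"
            )
        long.to_csv(path, index=False, float_format="%.17g")
        return path
    if dialect == "wide":
        out = matrix.values.copy()
        if matrix.sample_meta is not None and "group" in matrix.sample_meta.columns:
            groups = matrix.sample_meta.loc[out.columns, "group"]
        else:
            groups = pd.Series("all", index=out.columns)
        out.columns = pd.MultiIndex.from_arrays([out.columns, groups.to_numpy()])
        out.to_csv(path, float_format="%.17g")
        return path
    raise SchemaError(f"unknown dialect {dialect!r} (expected 'tidy' or 'wide')")


def write_mgf(records: Sequence[MS2Record], path: str | Path) -> Path:
    """Write MS2 records as MGF (PEPMASS, RTINSECONDS, fragment peak list)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spectra = []
    for rec in records:
        spectra.append(
            {
                "m/z array": np.asarray(rec.fragments_mz),
                "intensity array": np.asarray(rec.fragments_intensity),
                "params": {
                    "title": rec.id or f"precursor_{rec.precursor_mz:.4f}",
                    "pepmass": (rec.precursor_mz, None),
                    "rtinseconds": rec.rt_min * 60.0,
                },
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")
    return path


def read_mgf(path: str | Path) -> list[MS2Record]:
    """Read an MGF file into MS2 records (RT converted back to minutes)."""
    records = []
    with _mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pepmass = params.get("pepmass", (float("nan"),))[0]
            rt_s = float(params.get("rtinseconds", 0.0))
            records.append(
                MS2Record(
                    precursor_mz=float(pepmass),
                    rt_min=rt_s / 60.0,
                    fragments_mz=spec["m/z array"],
                    fragments_intensity=spec["intensity array"],
                    id=str(params.get("title", "")),
                )
            )
    return records
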