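"""CSV/TSV readers and writers for every pipeline table.

All on-disk formats are plain delimited text with a header row; the
delimiter is inferred from the extension (``.tsv`` -> tab, otherwise
comma).  Readers validate against a light schema and raise
:class:`~catechoflux.errors.ValidationError` naming the offending column.
Write -> read round trips are lossless to 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bioenergetics import MediaTimecourse, RUN_COLUMNS, PHASES
from .errors import ValidationError
from .preprocess import META_COLUMNS, FoldChangeTable, SampleTable

FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class TableSchema:
    """Column contract for a delimited table."""

    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    unique: tuple[str, ...] = field(default=())


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_table(path, schema: TableSchema, index_col=None) -> pd.DataFrame:
    """Read a delimited table and validate it against ``schema``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing input file: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=index_col)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing}")
    for col in schema.numeric:
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"{path.name}: non-numeric values in column {col!r}")
    for col in schema.unique:
        if col in df.columns and df[col].duplicated().any():
            dup = df[col][df[col].duplicated()].iloc[0]
            raise ValidationError(f"{path.name}: duplicated {col} {dup!r}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep=_sep(path), index=index, float_format=FLOAT_FORMAT)


def write_sample_table(table: SampleTable, path) -> None:
    """One wide row per sample: metadata columns then feature columns."""
    wide = pd.concat([table.meta[list(META_COLUMNS)], table.intensities], axis=1)
    write_table(wide, path)


def read_sample_table(path) -> SampleTable:
    if not Path(path).exists():
        raise ValidationError(f"missing input file: {path}")
    # pandas silently renames duplicated header fields, so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))
    seen = set()
    for name in header:
        if name in seen:
            raise ValidationError(f"{Path(path).name}: duplicated feature id {name!r}")
        seen.add(name)
    schema = TableSchema(required=META_COLUMNS, numeric=("dose_uM", "time_h"))
    df = read_table(path, schema, index_col=0)
    meta = df[list(META_COLUMNS)]
    feats = df.drop(columns=list(META_COLUMNS))
    bad = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if bad:
        raise ValidationError(
            f"{Path(path).name}: non-numeric intensity cells in column {bad[0]!r}"
        )
    return SampleTable(intensities=feats.astype(float), meta=meta)


def write_fold_change(fc: FoldChangeTable, path) -> None:
    write_table(fc.lfc.reset_index(), path, index=False)


def read_fold_change(path) -> FoldChangeTable:
    schema = TableSchema(required=("dose_uM", "time_h"), numeric=("dose_uM", "time_h"))
    df = read_table(path, schema)
    lfc = df.set_index(["dose_uM", "time_h"]).sort_index()
    return FoldChangeTable(lfc=lfc)


def read_seahorse_run(path) -> pd.DataFrame:
    schema = TableSchema(
        required=RUN_COLUMNS, numeric=("cycle", "ocr", "ecar", "cells")
    )
    df = read_table(path, schema)
    unknown = set(df["phase"]) - set(PHASES)
    if unknown:
        raise ValidationError(
            f"{Path(path).name}: unknown phase labels {sorted(unknown)}"
        )
    return df.astype({"cycle": int, "ocr": float, "ecar": float, "cells": float})


def write_seahorse_run(run: pd.DataFrame, path) -> None:
    write_table(run, path, index=False)


MEDIA_COLUMNS = (
    "metabolite",
    "time_h",
    "concentration_mM",
    "volume_ml",
    "cells_start",
    "cells_end",
)


def write_media_timecourses(courses: dict[str, MediaTimecourse], path) -> None:
    rows = []
    for tc in courses.values():
        for t, c in zip(tc.times_h, tc.concentrations_mM):
            rows.append(
                {
                    "metabolite": tc.metabolite,
                    "time_h": t,
                    "concentration_mM": c,
                    "volume_ml": tc.volume_ml,
                    "cells_start": tc.cells_start,
                    "cells_end": tc.cells_end,
                }
            )
    write_table(pd.DataFrame(rows, columns=list(MEDIA_COLUMNS)), path, index=False)


def read_media_timecourses(path) -> dict[str, MediaTimecourse]:
    schema = TableSchema(
        required=MEDIA_COLUMNS,
        numeric=("time_h", "concentration_mM", "volume_ml", "cells_start", "cells_end"),
    )
    df = read_table(path, schema)
    out = {}
    for metabolite, grp in df.groupby("metabolite", sort=True):
        grp = grp.sort_values("time_h")
        out[str(metabolite)] = MediaTimecourse(
            metabolite=str(metabolite),
            times_h=grp["time_h"].to_numpy(),
            concentrations_mM=grp["concentration_mM"].to_numpy(),
            volume_ml=float(grp["volume_ml"].iloc[0]),
            cells_start=float(grp["cells_start"].iloc[0]),
            cells_end=float(grp["cells_end"].iloc[0]),
        )
    return out


def write_isotopologues(vectors: dict, path) -> None:
    """Rows of (sample, metabolite, m0..mn); shorter vectors NaN-padded."""
    n_max = max(v.n for v in vectors.values())
    rows = []
    for (sample, metabolite), vec in vectors.items():
        row = {"sample": sample, "metabolite": metabolite}
        for i in range(n_max + 1):
            row[f"m{i}"] = vec.m[i] if i <= vec.n else np.nan
        rows.append(row)
    write_table(pd.DataFrame(rows), path, index=False)


def read_isotopologues(path) -> dict:
    from .isotopes import IsotopologueVector

    schema = TableSchema(required=("sample", "metabolite", "m0", "m1"))
    df = read_table(path, schema)
    mcols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    out = {}
    for _, row in df.iterrows():
        m = row[mcols].to_numpy(dtype=float)
        m = m[~np.isnan(m)]
        out[(row["sample"], row["metabolite"])] = IsotopologueVector(m)
    return out
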