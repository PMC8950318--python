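"""Feature-table containers, quantile normalization and fold changes.

The central container is :class:`SampleTable`: a samples x features intensity
matrix from untargeted LC-MS, joined to per-sample metadata (catecholamine
dose in uM, exposure time in h, donor and batch identifiers).  Batch-to-batch
intensity shifts are removed by quantile normalization across all samples
jointly; treatment effects are then summarised as log2 fold changes of each
(dose, time) condition against the matched unstimulated (dose 0, same time)
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

META_COLUMNS = ("dose_uM", "time_h", "donor", "batch")


@dataclass
class SampleTable:
    """Samples x features intensity matrix with aligned sample metadata.

    Parameters
    ----------
    intensities
        Non-negative intensity matrix, one row per sample, one column per
        feature; column labels are the stable feature identifiers.
    meta
        Per-sample metadata with columns ``dose_uM``, ``time_h``, ``donor``
        and ``batch``, sharing the row index of ``intensities``.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape[0] != self.meta.shape[0]:
            raise ValidationError(
                f"metadata rows ({self.meta.shape[0]}) do not match "
                f"intensity rows ({self.intensities.shape[0]})"
            )
        if not self.intensities.index.equals(self.meta.index):
            raise ValidationError("intensities and meta must share a row index")
        dup = self.intensities.columns[self.intensities.columns.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated feature id: {dup[0]!r}")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns {missing}")
        vals = self.intensities.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = self.intensities.columns[
                [not np.issubdtype(d, np.number) for d in self.intensities.dtypes]
            ]
            raise ValidationError(f"non-numeric intensity column: {bad[0]!r}")
        if (vals < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def subset_samples(self, mask) -> "SampleTable":
        return SampleTable(self.intensities.loc[mask], self.meta.loc[mask])


@dataclass
class FoldChangeTable:
    """log2 fold changes of each (dose, time) condition vs dose-0 same time.

    ``lfc`` is indexed by a (dose_uM, time_h) MultiIndex with one column per
    feature; the reference conditions (dose 0) carry exact zeros.
    """

    lfc: pd.DataFrame
    pseudo: float = field(default=0.0)

    def at_time(self, time_h: float, treated_only: bool = True) -> pd.DataFrame:
        sub = self.lfc.xs(time_h, level="time_h", drop_level=False)
        if treated_only:
            sub = sub[sub.index.get_level_values("dose_uM") > 0]
        return sub


def default_pseudo(table: SampleTable) -> float:
    """Half the smallest nonzero intensity in the table (0 if all zero)."""
    vals = table.intensities.to_numpy(dtype=float)
    nz = vals[vals > 0]
    return float(nz.min() / 2.0) if nz.size else 0.0


def quantile_normalize(table: SampleTable) -> SampleTable:
    """Force every sample onto the mean empirical intensity distribution.

    Each sample's sorted intensity vector is replaced by the across-sample
    mean of sorted vectors; tied intensities receive the mean of the
    reference values at their tied ranks.  Applied across all samples
    jointly, this removes monotone per-sample (batch, donor) distortions.
    """
    vals = table.intensities.to_numpy(dtype=float)
    if vals.shape[0] < 1 or vals.shape[1] < 1:
        raise ValidationError("empty intensity matrix")
    if (vals.sum(axis=1) == 0).any():
        raise ValidationError("a sample is entirely zero; cannot normalize")
    reference = np.sort(vals, axis=1).mean(axis=0)
    out = np.empty_like(vals)
    n = vals.shape[1]
    for row_i in range(vals.shape[0]):
        row = vals[row_i]
        order = np.argsort(row, kind="stable")
        sorted_row = row[order]
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sorted_row[j + 1] == sorted_row[i]:
                j += 1
            out[row_i, order[i : j + 1]] = reference[i : j + 1].mean()
            i = j + 1
    normd = pd.DataFrame(
        out, index=table.intensities.index, columns=table.intensities.columns
    )
    return SampleTable(normd, table.meta.copy())


def log2_fold_change(table: SampleTable, pseudo: float | None = None) -> FoldChangeTable:
    """log2 of (mean treated + pseudo) / (mean dose-0 same-time + pseudo).

    Means are taken across donors within each (dose, time) condition; the
    reference is the unstimulated (dose 0) condition at the same time point.
    ``pseudo`` keeps the ratio finite in the presence of zeros and defaults
    to half the smallest nonzero intensity in the table.
    """
    if pseudo is None:
        pseudo = default_pseudo(table)
    if pseudo < 0:
        raise ValidationError("pseudo-intensity must be non-negative")
    meta = table.meta
    grouped = table.intensities.groupby(
        [meta["dose_uM"], meta["time_h"]]
    ).mean()
    grouped.index = grouped.index.set_names(["dose_uM", "time_h"])
    times = grouped.index.get_level_values("time_h").unique()
    doses0 = grouped.index.get_level_values("dose_uM") == 0
    for t in times:
        at_t = grouped.index.get_level_values("time_h") == t
        if not (at_t & doses0).any():
            raise ValidationError(f"missing dose-0 reference at time {t} h")
    dose_level = grouped.index.get_level_values("dose_uM")
    time_level = grouped.index.get_level_values("time_h")
    refs = {
        t: grouped.loc[(dose_level == 0) & (time_level == t)].iloc[0] for t in times
    }
    rows = {}
    for (dose, t), cond_mean in grouped.iterrows():
        rows[(dose, t)] = np.log2((cond_mean + pseudo) / (refs[t] + pseudo))
    lfc = pd.DataFrame.from_dict(rows, orient="index")
    lfc.index = pd.MultiIndex.from_tuples(lfc.index, names=["dose_uM", "time_h"])
    lfc = lfc.sort_index()
    # the reference condition against itself is exactly zero, not fp noise
    ref_rows = lfc.index.get_level_values("dose_uM") == 0
    lfc.loc[ref_rows, :] = 0.0
    return FoldChangeTable(lfc=lfc, pseudo=float(pseudo))
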