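"""Extracellular-flux (Seahorse-style) metrics and media exchange rates.

A mitochondrial stress test cycles through four phases: basal respiration,
then sequential injections of oligomycin (ATP-synthase inhibitor), FCCP
(uncoupler) and rotenone + antimycin A (complex I/III inhibitors).  From the
per-phase OCR plateaus the standard bioenergetic metrics follow:

    atp_linked  = basal - oligomycin        (respiration-based ATP production)
    maximal     = FCCP plateau              (uncoupled respiratory capacity)
    non_mito    = rotenone/antimycin plateau
    proton_leak = oligomycin - non_mito
    spare       = maximal - basal
    atp_fraction = atp_linked / basal

All rates are normalised to cell counts (pmol min^-1 cell^-1 for OCR,
mpH min^-1 cell^-1 for ECAR).  Media exchange rates are computed from
start/end metabolite concentrations, culture volume and the mean cell
count; positive rates denote secretion, negative rates uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import mann_whitney_u
from .errors import ValidationError

PHASES = ("basal", "oligomycin", "fccp", "rotaa")
RUN_COLUMNS = ("well", "condition", "cycle", "phase", "ocr", "ecar", "cells")
PHASE_SUMMARIES = ("mean", "last", "extremum")

METRIC_COLUMNS = (
    "basal_ecar",
    "basal_ocr",
    "atp_linked_ocr",
    "maximal_ocr",
    "non_mito_ocr",
    "proton_leak",
    "spare_capacity",
    "atp_fraction",
)


@dataclass
class MediaTimecourse:
    """Extracellular concentration time course of one metabolite.

    Concentrations in mM at timestamps in hours, with the culture volume
    (mL) and the cell counts at the first and last timestamp.
    """

    metabolite: str
    times_h: np.ndarray
    concentrations_mM: np.ndarray
    volume_ml: float
    cells_start: float
    cells_end: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        if self.times_h.size < 2:
            raise ValidationError("a time course needs at least 2 timestamps")
        if self.times_h.size != self.concentrations_mM.size:
            raise ValidationError("times and concentrations must align")
        if self.volume_ml <= 0:
            raise ValidationError("culture volume must be positive")
        if self.cells_start <= 0 or self.cells_end <= 0:
            raise ValidationError("cell counts must be positive")


def _validate_run(run: pd.DataFrame) -> None:
    missing = [c for c in RUN_COLUMNS if c not in run.columns]
    if missing:
        raise ValidationError(f"run table is missing columns {missing}")
    unknown = set(run["phase"]) - set(PHASES)
    if unknown:
        raise ValidationError(f"unknown phase labels {sorted(unknown)}")
    if (run["cells"] <= 0).any():
        raise ValidationError("cell counts must be positive")


def _summarise_phase(values: np.ndarray, phase: str, how: str) -> float:
    if how == "mean":
        return float(values.mean())
    if how == "last":
        return float(values[-1])
    if how == "extremum":
        # FCCP is a stimulation (take the peak); the inhibitor phases and
        # basal are summarised by their extreme suppression / plateau
        return float(values.max() if phase == "fccp" else values.min())
    raise ValidationError(f"unknown phase summary {how!r}")


def well_profiles(
    run: pd.DataFrame,
    phase_summary: str = "mean",
    subtract_non_mito: bool = False,
) -> pd.DataFrame:
    """Per-well bioenergetic metrics, normalised to the well's cell count.

    ``phase_summary`` selects how the 3 post-injection cycles of a phase
    collapse to one value ('mean' default, 'last', 'extremum'); the 6 basal
    cycles are always averaged.  With ``subtract_non_mito`` the maximal
    respiration is reported net of the non-mitochondrial OCR.
    """
    _validate_run(run)
    rows = {}
    for well, grp in run.groupby("well", sort=True):
        grp = grp.sort_values("cycle")
        cells = float(grp["cells"].iloc[0])
        phase_ocr = {}
        for phase in PHASES:
            sel = grp[grp["phase"] == phase]
            if sel.empty:
                raise ValidationError(f"well {well!r} is missing phase {phase!r}")
            how = "mean" if phase == "basal" else phase_summary
            phase_ocr[phase] = _summarise_phase(
                sel["ocr"].to_numpy(dtype=float), phase, how
            )
        basal_ecar = float(
            grp.loc[grp["phase"] == "basal", "ecar"].to_numpy(dtype=float).mean()
        )
        basal = phase_ocr["basal"]
        non_mito = phase_ocr["rotaa"]
        maximal = phase_ocr["fccp"] - (non_mito if subtract_non_mito else 0.0)
        atp_linked = basal - phase_ocr["oligomycin"]
        leak = phase_ocr["oligomycin"] - non_mito
        if maximal < basal:
            warnings.warn(f"well {well!r}: maximal OCR below basal")
        rows[well] = {
            "condition": grp["condition"].iloc[0],
            "basal_ecar": basal_ecar / cells,
            "basal_ocr": basal / cells,
            "atp_linked_ocr": atp_linked / cells,
            "maximal_ocr": maximal / cells,
            "non_mito_ocr": non_mito / cells,
            "proton_leak": leak / cells,
            "spare_capacity": (maximal - basal) / cells,
            "atp_fraction": atp_linked / basal if basal != 0 else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "well"
    return out


def extract_profile(
    run: pd.DataFrame,
    phase_summary: str = "mean",
    subtract_non_mito: bool = False,
) -> pd.DataFrame:
    """Per-condition bioenergetic profile: mean of the per-well metrics."""
    wells = well_profiles(run, phase_summary, subtract_non_mito)
    return wells.groupby("condition", sort=True)[list(METRIC_COLUMNS)].mean()


def fold_change(metric_treated: float, metric_control: float) -> float:
    """Plain treated/control ratio of a bioenergetic metric."""
    if metric_control <= 0:
        raise ValidationError("control metric must be positive")
    return float(metric_treated / metric_control)


def exchange_rate(tc: MediaTimecourse) -> float:
    """Per-cell exchange rate in umol (1e6 cells)^-1 h^-1.

    rate = (C_end - C_start) * volume / (mean cells * dt); the mean of the
    start/end cell counts stands in for the growing culture.  Positive
    rates are secretion, negative uptake.
    """
    dt = tc.times_h[-1] - tc.times_h[0]
    if dt == 0:
        raise ValidationError("time course spans zero time")
    dC = tc.concentrations_mM[-1] - tc.concentrations_mM[0]  # mM == umol/mL
    mean_cells = 0.5 * (tc.cells_start + tc.cells_end)
    return float(dC * tc.volume_ml / ((mean_cells / 1e6) * dt))


def condition_compare(
    profiles_a, profiles_b, alternative: str = "two-sided"
) -> dict[str, float]:
    """Mann-Whitney U comparison of a metric between two condition groups."""
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    u, p = mann_whitney_u(a, b, alternative=alternative)
    return {
        "U": u,
        "p": p,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
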