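"""Synthetic-data generators emulating the study design, with ground truth.

Every input the pipeline consumes can be generated here with known planted
parameters: LC-MS feature tables over a 4-dose x 3-time x 3-donor design
with a minority of dose-responding features following seven temporal
archetypes; isotopologue vectors under a tracer design; mitochondrial
stress-test (Seahorse) cycle series; and media concentration time courses
that integrate planted per-cell exchange rates.

The defaults reproduce the study conditions: equimolar catecholamine doses
0, 0.5, 5 and 50 uM; sampling at 0, 4 and 24 h; 3 donors; multiplicative
lognormal measurement noise on intensities and a per-donor multiplicative
offset shared across features (the batch effect quantile normalization is
meant to remove).  Identical configurations give bit-identical output: each
generator draws from its own ``numpy.random.default_rng`` stream seeded
from its config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .bioenergetics import MediaTimecourse, PHASES
from .errors import ValidationError
from .isotopes import (
    AtomTransferModel,
    IsotopologueVector,
    TracerDesign,
    correction_matrix,
    theoretical_max_enrichment,
)
from .preprocess import SampleTable

#: The seven temporal response archetypes as (early, late) direction pairs:
#: the largest observed cluster dips at 4 h and rebounds by 24 h; others
#: rise at both times, invert between times, or move at one time only.
ARCHETYPES: dict[str, tuple[float, float]] = {
    "transient_down": (-1.0, 0.0),  # down at 4 h, back to baseline at 24 h
    "sustained_up": (1.0, 1.0),
    "up_then_down": (1.0, -1.0),
    "down_then_up": (-1.0, 1.0),
    "early_up": (1.0, 0.0),
    "late_down": (0.0, -1.0),
    "late_up": (0.0, 1.0),
}

DEFAULT_ARCHETYPE_WEIGHTS = (0.25, 0.20, 0.15, 0.15, 0.10, 0.08, 0.07)


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters for the feature-table generator.

    Noise magnitudes (noise_sd, donor_sd: sigmas of multiplicative
    lognormal factors) are package defaults chosen as plausible for LC-MS
    intensity data, not values asserted by any study; tune them freely.
    """

    doses: tuple[float, ...] = (0.0, 0.5, 5.0, 50.0)
    times: tuple[float, ...] = (0.0, 4.0, 24.0)
    n_donors: int = 3
    n_features: int = 500
    n_responders: int = 40
    archetype_weights: tuple[float, ...] = DEFAULT_ARCHETYPE_WEIGHTS
    effect_size: float = 2.0
    noise_sd: float = 0.1
    donor_sd: float = 0.1
    baseline_log_mean: float = 11.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValidationError("n_features must be positive")
        if not 0 <= self.n_responders <= self.n_features:
            raise ValidationError("n_responders must lie in [0, n_features]")
        if 0.0 not in self.doses:
            raise ValidationError("doses must include 0 (the FC reference)")
        if len(set(self.doses)) != len(self.doses):
            raise ValidationError("doses must be distinct")
        positive_times = [t for t in self.times if t > 0]
        if len(positive_times) < 2:
            raise ValidationError(
                "need at least two positive times (early and late archetype anchors)"
            )
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")
        if len(self.archetype_weights) != len(ARCHETYPES):
            raise ValidationError(
                f"archetype_weights must have {len(ARCHETYPES)} entries"
            )
        if any(w < 0 for w in self.archetype_weights):
            raise ValidationError("archetype weights must be non-negative")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValidationError("archetype weights must sum to 1")
        for name in ("noise_sd", "donor_sd", "effect_size", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def early_time(self) -> float:
        return min(t for t in self.times if t > 0)

    @property
    def late_time(self) -> float:
        return max(t for t in self.times if t > 0)


@dataclass
class GroundTruth:
    """Planted truth of a simulated feature table."""

    responder_ids: list[str]
    archetype_of: dict[str, str]
    planted_lfc: pd.DataFrame  # (dose_uM, time_h) MultiIndex x features

    def lfc_of(self, feature: str, dose: float, time: float) -> float:
        return float(self.planted_lfc.loc[(dose, time), feature])

    def to_json(self, path) -> None:
        payload = {
            "responder_ids": self.responder_ids,
            "archetype_of": self.archetype_of,
            "planted_lfc": {
                f"{dose:g}|{time:g}": row.to_dict()
                for (dose, time), row in self.planted_lfc.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        records = {}
        for key, row in payload["planted_lfc"].items():
            dose, time = (float(v) for v in key.split("|"))
            records[(dose, time)] = row
        lfc = pd.DataFrame.from_dict(records, orient="index").sort_index()
        lfc.index = pd.MultiIndex.from_tuples(lfc.index, names=["dose_uM", "time_h"])
        return cls(
            responder_ids=payload["responder_ids"],
            archetype_of=payload["archetype_of"],
            planted_lfc=lfc,
        )


def _archetype_shape(
    archetype: str, time: float, early: float, late: float
) -> float:
    """Direction of a planted effect at a positive time point.

    Anchored at the early and late sampling times; any intermediate time
    interpolates linearly between the anchors.
    """
    s_early, s_late = ARCHETYPES[archetype]
    if time <= early:
        return s_early
    if time >= late:
        return s_late
    w = (time - early) / (late - early)
    return (1 - w) * s_early + w * s_late


def planted_log2_fc(
    config: SimulationConfig, archetype: str, dose: float, time: float
) -> float:
    """Planted log2 FC: log-linear in ordinal dose, archetype-shaped in time.

    The magnitude ramps linearly with the ordinal dose index (0..D-1),
    reaching ``effect_size`` at the highest dose of the archetype's active
    time point; dose 0 and time 0 are exactly 0.
    """
    if dose == 0 or time == 0:
        return 0.0
    levels = sorted(config.doses)
    d = levels.index(dose)
    ramp = d / (len(levels) - 1)
    shape = _archetype_shape(archetype, time, config.early_time, config.late_time)
    return config.effect_size * shape * ramp


def simulate_feature_table(
    config: SimulationConfig,
) -> tuple[SampleTable, GroundTruth]:
    """Simulate an LC-MS feature table with planted dose-responders.

    One sample per (dose, time, donor).  Responder intensities follow
    baseline * 2^planted_lfc * donor offset * lognormal noise; the
    remaining features are flat up to noise.  Donors double as batches.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features
    width = len(str(n_feat - 1))
    features = [f"F{i:0{width}d}" for i in range(n_feat)]
    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_feat)
    )
    responder_idx = rng.choice(n_feat, size=config.n_responders, replace=False)
    responder_idx.sort()
    archetype_names = list(ARCHETYPES)
    assigned = rng.choice(
        len(archetype_names), size=config.n_responders, p=config.archetype_weights
    )
    archetype_of = {
        features[fi]: archetype_names[ai]
        for fi, ai in zip(responder_idx, assigned)
    }
    donor_offsets = np.exp(rng.normal(0.0, config.donor_sd, config.n_donors))

    conditions = [(d, t) for d in sorted(config.doses) for t in sorted(config.times)]
    lfc = pd.DataFrame(
        0.0,
        index=pd.MultiIndex.from_tuples(conditions, names=["dose_uM", "time_h"]),
        columns=features,
    )
    for feat, arch in archetype_of.items():
        for dose, t in conditions:
            lfc.loc[(dose, t), feat] = planted_log2_fc(config, arch, dose, t)

    sample_rows = []
    meta_rows = []
    intens = []
    for dose, t in conditions:
        for donor in range(1, config.n_donors + 1):
            sample_rows.append(f"d{dose:g}_t{t:g}_r{donor}")
            meta_rows.append(
                {
                    "dose_uM": dose,
                    "time_h": t,
                    "donor": f"donor{donor}",
                    "batch": f"batch{donor}",
                }
            )
            noise = np.exp(rng.normal(0.0, config.noise_sd, n_feat))
            values = (
                baselines
                * np.exp2(lfc.loc[(dose, t)].to_numpy())
                * donor_offsets[donor - 1]
                * noise
            )
            intens.append(values)
    index = pd.Index(sample_rows, name="sample")
    table = SampleTable(
        intensities=pd.DataFrame(intens, index=index, columns=features),
        meta=pd.DataFrame(meta_rows, index=index),
    )
    truth = GroundTruth(
        responder_ids=[features[i] for i in responder_idx],
        archetype_of=archetype_of,
        planted_lfc=lfc,
    )
    return table, truth


def simulate_isotopologues(
    design: TracerDesign,
    model: AtomTransferModel,
    contribution: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    apply_purity: bool | None = None,
) -> IsotopologueVector:
    """Simulate a measured (natural-abundance-convolved) isotopologue vector.

    The underlying biological vector is Binomial(n, p) with per-atom label
    probability p = contribution * E_max, so its corrected mean enrichment
    is exactly contribution * theoretical_max_enrichment.  The vector is
    then convolved with natural abundance and, if requested, perturbed by
    multiplicative lognormal noise and renormalised.
    """
    if not 0 <= contribution <= 1:
        raise ValidationError("contribution must lie in [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    n = model.product_atoms
    p = contribution * theoretical_max_enrichment(model, design, apply_purity)
    true = scipy.stats.binom.pmf(np.arange(n + 1), n, p)
    measured = correction_matrix(n, design.natural_abundance) @ true
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        measured = measured * np.exp(rng.normal(0.0, noise_sd, n + 1))
        measured = measured / measured.sum()
    return IsotopologueVector(measured)


def simulate_seahorse(
    condition_effects: Mapping[str, Mapping[str, float]],
    n_wells: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_ocr: float = 200.0,
    baseline_ecar: float = 5.0,
    cells_per_well: float = 60_000.0,
    n_basal: int = 6,
    n_post: int = 3,
) -> pd.DataFrame:
    """Simulate a mitochondrial stress-test run.

    Each well records ``n_basal`` basal cycles then ``n_post`` cycles after
    each injection (oligomycin, FCCP, rotenone/antimycin A).  Per condition,
    ``condition_effects`` scales the phase means: keys 'basal',
    'oligomycin', 'fccp', 'rotaa' multiply the baseline OCR, and 'ecar'
    multiplies the baseline ECAR (missing keys default to 1).  Readings get
    multiplicative lognormal noise of sigma ``noise_sd``.
    """
    if n_wells < 1:
        raise ValidationError("n_wells must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cycles_per_phase = {"basal": n_basal, "oligomycin": n_post, "fccp": n_post, "rotaa": n_post}
    rows = []
    for condition in condition_effects:
        effects = dict(condition_effects[condition])
        unknown = set(effects) - set(PHASES) - {"ecar"}
        if unknown:
            raise ValidationError(f"unknown effect keys {sorted(unknown)}")
        if any(v <= 0 for v in effects.values()):
            raise ValidationError("phase multipliers must be positive")
        ecar_level = baseline_ecar * effects.get("ecar", 1.0)
        for w in range(1, n_wells + 1):
            well = f"{condition}_w{w}"
            cycle = 0
            for phase in PHASES:
                ocr_level = baseline_ocr * effects.get(phase, 1.0)
                for _ in range(cycles_per_phase[phase]):
                    cycle += 1
                    ocr = ocr_level
                    ecar = ecar_level
                    if noise_sd > 0:
                        ocr *= np.exp(rng.normal(0.0, noise_sd))
                        ecar *= np.exp(rng.normal(0.0, noise_sd))
                    rows.append(
                        {
                            "well": well,
                            "condition": condition,
                            "cycle": cycle,
                            "phase": phase,
                            "ocr": ocr,
                            "ecar": ecar,
                            "cells": cells_per_well,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_media_timecourse(
    rates: Mapping[str, float],
    cells0: float,
    growth: float = 0.0,
    volume_ml: float = 2.0,
    times: tuple[float, ...] = (0.0, 24.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    initial_concentrations: Mapping[str, float] | float = 5.0,
) -> dict[str, MediaTimecourse]:
    """Integrate planted per-cell exchange rates into media concentrations.

    ``rates`` are umol (1e6 cells)^-1 h^-1 (positive = secretion); the cell
    count grows exponentially from ``cells0`` at rate ``growth`` (h^-1).
    C(t) = C0 + rate * integral(N) / (1e6 * volume).  Negative
    concentrations are clipped to 0 with a warning.
    """
    times = np.asarray(sorted(times), dtype=float)
    if times.size == 0:
        raise ValidationError("times must be nonempty")
    if times.size < 2:
        raise ValidationError("need at least two timestamps")
    if volume_ml <= 0:
        raise ValidationError("volume must be positive")
    if cells0 <= 0:
        raise ValidationError("initial cell count must be positive")
    rng = np.random.default_rng(seed)
    t0 = times[0]
    if growth == 0.0:
        cum_cell_hours = cells0 * (times - t0)
    else:
        cum_cell_hours = cells0 * (np.exp(growth * (times - t0)) - 1.0) / growth
    cells_end = cells0 * np.exp(growth * (times[-1] - t0))
    out = {}
    for metabolite, rate in rates.items():
        if isinstance(initial_concentrations, Mapping):
            c0 = float(initial_concentrations[metabolite])
        else:
            c0 = float(initial_concentrations)
        conc = c0 + rate * cum_cell_hours / (1e6 * volume_ml)
        if noise_sd > 0:
            conc = conc * np.exp(rng.normal(0.0, noise_sd, conc.size))
        if (conc < 0).any():
            warnings.warn(
                f"{metabolite}: concentration went negative; clipped to 0 "
                "(pool exhausted before the last timestamp)"
            )
            conc = np.clip(conc, 0.0, None)
        out[metabolite] = MediaTimecourse(
            metabolite=metabolite,
            times_h=times.copy(),
            concentrations_mM=conc,
            volume_ml=volume_ml,
            cells_start=cells0,
            cells_end=cells_end,
        )
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serialisable echo of a simulation config (for manifests)."""
    d = asdict(config)
    for key in ("doses", "times", "archetype_weights"):
        d[key] = list(d[key])
    return d
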