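"""End-to-end driver: configuration, stage wiring, manifest, logging.

A single :class:`PipelineConfig` (flat YAML/JSON mapping, unknown keys
rejected) drives simulate -> normalize -> fold change -> select -> cluster,
plus the optional isotope-enrichment, bioenergetics and exchange-rate
stages.  Every run writes a ``manifest.json`` with the config echo, SHA-256
hashes of the inputs and package versions, so a rerun of the same config on
the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, io
from .bioenergetics import condition_compare, exchange_rate, extract_profile, fold_change
from .doseresponse import (
    SelectionThresholds,
    optimal_partition,
    responder_profiles,
    select_responders,
)
from .errors import ValidationError
from .isotopes import (
    ATOM_TRANSFER_MODELS,
    GLUCOSE_12C2_TRACER,
    TracerDesign,
    enrichment_result,
)
from .preprocess import log2_fold_change, quantile_normalize
from .synthetic import (
    SimulationConfig,
    config_to_dict,
    simulate_feature_table,
    simulate_isotopologues,
    simulate_media_timecourse,
    simulate_seahorse,
)

log = logging.getLogger("catechoflux")

#: Metabolites with a preset atom-transfer model for the contribution step.
DEFAULT_MODELS = {
    "lactate": "lactate_from_[1,2-13C2]glucose",
    "glutamate": "glutamate_from_[1,2-13C2]glucose_complete_turnover",
}


@dataclass
class PipelineConfig:
    """Flat configuration for a full pipeline run."""

    out_dir: str = "catechoflux_out"
    seed: int = 0
    log_level: str = "INFO"
    # feature-table stage
    simulate: bool = True
    sample_table: str | None = None
    simulation: dict = field(default_factory=dict)
    lfc_threshold: float = 1.0
    r_threshold: float = 0.8
    alpha: float = 0.05
    dose_encoding: str = "ordinal"
    pseudo: float | None = None
    k_min: int = 2
    k_max: int = 12
    # isotope stage
    enrich: bool = False
    isotopologues: str | None = None
    tracer_element: str = "C"
    tracer_fraction: float = 0.5
    purity: float = 0.99
    abundance: float | None = None
    phi: float = 0.0
    models: dict = field(default_factory=lambda: dict(DEFAULT_MODELS))
    # bioenergetics / rates stages
    bioenergetics: bool = False
    seahorse: str | None = None
    phase_summary: str = "mean"
    subtract_non_mito: bool = False
    rates: bool = False
    media: str | None = None

    def __post_init__(self) -> None:
        # range checks delegate to the stage objects where possible
        SelectionThresholds(
            lfc=self.lfc_threshold,
            r=self.r_threshold,
            alpha=self.alpha,
            dose_encoding=self.dose_encoding,
        )
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError("need 2 <= k_min <= k_max")
        if not 0 <= self.phi < 1:
            raise ValidationError("phi must lie in [0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"missing config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


class _Stage:
    """Context manager logging a stage name and its elapsed time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the result bundle.

    Returns a dict of in-memory results keyed by stage; files are written
    under ``config.out_dir`` together with ``manifest.json``.
    """
    _setup_logging(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    results: dict = {}

    with _Stage("features"):
        if config.simulate:
            sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
            table, truth = simulate_feature_table(sim)
            io.write_sample_table(table, out_dir / "samples.csv")
            truth.to_json(out_dir / "ground_truth.json")
            results["ground_truth"] = truth
            results["simulation_config"] = sim
        else:
            if config.sample_table is None:
                raise ValidationError("simulate is false and no sample_table given")
            path = Path(config.sample_table)
            table = io.read_sample_table(path)
            inputs[str(path)] = _sha256(path)
        results["samples"] = table

    with _Stage("normalize"):
        normed = quantile_normalize(table)
        io.write_sample_table(normed, out_dir / "normalized.csv")
        results["normalized"] = normed

    with _Stage("foldchange"):
        fc = log2_fold_change(normed, pseudo=config.pseudo)
        io.write_fold_change(fc, out_dir / "fold_change.csv")
        results["fold_change"] = fc

    with _Stage("select"):
        thresholds = SelectionThresholds(
            lfc=config.lfc_threshold,
            r=config.r_threshold,
            alpha=config.alpha,
            dose_encoding=config.dose_encoding,
        )
        result = select_responders(fc, normed, thresholds, pseudo=config.pseudo)
        io.write_table(result.stats, out_dir / "responders.tsv")
        results["responders"] = result
        log.info("selected %d dose-responding features", len(result.selected))

    with _Stage("cluster"):
        selected = list(result.selected)
        k_max = min(config.k_max, max(len(selected) - 1, 0))
        if len(selected) >= 3 and k_max >= config.k_min:
            profiles = responder_profiles(fc, selected)
            partition = optimal_partition(profiles, range(config.k_min, k_max + 1))
            payload = {
                "k": partition.k,
                "db_index": partition.db_index,
                "db_by_k": {str(k): v for k, v in sorted(partition.db_by_k.items())},
                "labels": {f: int(l) for f, l in partition.labels.items()},
            }
            (out_dir / "partition.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True)
            )
            results["partition"] = partition
        else:
            log.warning("too few selected features to cluster; stage skipped")

    if config.enrich:
        with _Stage("enrich"):
            results["enrichment"] = _run_enrich(config, out_dir, inputs)

    if config.bioenergetics:
        with _Stage("bioenergetics"):
            results["bioenergetics"] = _run_bioenergetics(config, out_dir, inputs)

    if config.rates:
        with _Stage("rates"):
            results["rates"] = _run_rates(config, out_dir, inputs)

    manifest = {
        "config": config.to_dict(),
        "inputs": inputs,
        "versions": {
            "catechoflux": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if "simulation_config" in results:
        manifest["simulation"] = config_to_dict(results["simulation_config"])
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results


def _tracer(config: PipelineConfig) -> TracerDesign:
    kwargs = dict(
        element=config.tracer_element,
        tracer_fraction=config.tracer_fraction,
        purity=config.purity,
    )
    if config.abundance is not None:
        kwargs["natural_abundance"] = config.abundance
    return TracerDesign(**kwargs)


def _run_enrich(config: PipelineConfig, out_dir: Path, inputs: dict) -> dict:
    design = _tracer(config)
    if config.isotopologues is not None:
        path = Path(config.isotopologues)
        vectors = io.read_isotopologues(path)
        inputs[str(path)] = _sha256(path)
    elif config.simulate:
        # demo vectors with known contributions, seeded from the run seed
        vectors = {
            ("sim", "lactate"): simulate_isotopologues(
                design,
                ATOM_TRANSFER_MODELS[DEFAULT_MODELS["lactate"]],
                contribution=0.8,
                noise_sd=0.01,
                seed=config.seed,
            ),
            ("sim", "glutamate"): simulate_isotopologues(
                design,
                ATOM_TRANSFER_MODELS[DEFAULT_MODELS["glutamate"]],
                contribution=0.18,
                noise_sd=0.01,
                seed=config.seed + 1,
            ),
        }
        io.write_isotopologues(vectors, out_dir / "isotopologues.csv")
    else:
        raise ValidationError("enrich stage needs an isotopologues input file")
    payload = {}
    for (sample, metabolite), vec in vectors.items():
        model_name = config.models.get(metabolite)
        if model_name is None:
            continue
        if model_name not in ATOM_TRANSFER_MODELS:
            raise ValidationError(f"unknown atom-transfer model {model_name!r}")
        res = enrichment_result(
            vec, ATOM_TRANSFER_MODELS[model_name], design, phi=config.phi
        )
        payload[f"{sample}/{metabolite}"] = {
            "mean_enrichment": res.mean_enrichment,
            "theoretical_max": res.theoretical_max,
            "contribution": res.contribution,
            "preexisting_fraction": res.preexisting_fraction,
        }
    (out_dir / "enrichment.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )
    return payload


#: Study-like default condition effects for the simulated stress test:
#: dose-dependent rises in glycolysis and respiration, ATP fraction ~49%.
DEFAULT_SEAHORSE_EFFECTS = {
    "control": {"oligomycin": 0.51, "fccp": 2.3, "rotaa": 0.25},
    "0.5uM": {"basal": 1.6, "oligomycin": 0.82, "fccp": 3.7, "rotaa": 0.28, "ecar": 1.95},
    "5uM": {"basal": 2.2, "oligomycin": 1.12, "fccp": 5.2, "rotaa": 0.3, "ecar": 2.79},
}


def _run_bioenergetics(config: PipelineConfig, out_dir: Path, inputs: dict):
    if config.seahorse is not None:
        path = Path(config.seahorse)
        run = io.read_seahorse_run(path)
        inputs[str(path)] = _sha256(path)
    elif config.simulate:
        run = simulate_seahorse(
            DEFAULT_SEAHORSE_EFFECTS, noise_sd=0.02, seed=config.seed
        )
        io.write_seahorse_run(run, out_dir / "seahorse.csv")
    else:
        raise ValidationError("bioenergetics stage needs a seahorse input file")
    profiles = extract_profile(
        run,
        phase_summary=config.phase_summary,
        subtract_non_mito=config.subtract_non_mito,
    )
    io.write_table(profiles, out_dir / "bioenergetics.tsv")
    conditions = list(profiles.index)
    rows = []
    ref = conditions[0]
    for cond in conditions[1:]:
        for metric in ("basal_ecar", "basal_ocr", "maximal_ocr", "atp_linked_ocr"):
            rows.append(
                {
                    "condition": cond,
                    "reference": ref,
                    "metric": metric,
                    "fold_change": fold_change(
                        profiles.loc[cond, metric], profiles.loc[ref, metric]
                    ),
                }
            )
    io.write_table(pd.DataFrame(rows), out_dir / "bioenergetic_folds.tsv", index=False)
    return profiles


def _run_rates(config: PipelineConfig, out_dir: Path, inputs: dict):
    if config.media is not None:
        path = Path(config.media)
        courses = io.read_media_timecourses(path)
        inputs[str(path)] = _sha256(path)
    elif config.simulate:
        courses = simulate_media_timecourse(
            {"glucose": -0.0833, "lactate": 0.15},
            cells0=1e6,
            times=(0.0, 24.0),
            noise_sd=0.0,
            seed=config.seed,
        )
        io.write_media_timecourses(courses, out_dir / "media.csv")
    else:
        raise ValidationError("rates stage needs a media input file")
    rows = [
        {"metabolite": name, "rate_umol_per_1e6cells_per_h": exchange_rate(tc)}
        for name, tc in sorted(courses.items())
    ]
    df = pd.DataFrame(rows)
    io.write_table(df, out_dir / "exchange_rates.tsv", index=False)
    return df


__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "condition_compare",
    "DEFAULT_SEAHORSE_EFFECTS",
]
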