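"""Seed-reproducible orchestration: simulate -> gate -> screen -> cluster.

Each stage reads/writes plain files under an output directory so stages
can be run separately or end-to-end.  Every tabular output begins with a
``#`` comment line carrying the config hash and master seed; two runs
with identical config and seed produce byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs
from .gating import GateConfig, QCError, fmo_threshold, gate_well, percent_positive
from .panel import Antibody, PanelPlateMap, demo_plate_map, load_plate_map
from .presets import default_noise, default_populations, digestion_treatment
from .profiling import export_dendrogram, hcluster, knn_impute, pearson_distance
from .screening import (
    ScreenCriteria,
    assemble_matrix,
    replicate_reproducibility,
    screen_summary,
    screen_treatment,
)
from .simulate import EventTable, simulate_screen_plate

log = logging.getLogger("htfc")

__all__ = ["PipelineConfig", "run_simulate", "run_gate", "run_screen", "run_cluster", "run_all"]


@dataclass
class PipelineConfig:
    """One YAML-loadable configuration for the whole pipeline."""

    plate_map: str = "demo"          # "demo" or a path to a plate-map CSV
    out_dir: str = "htfc_out"
    seed: int = 1
    samples: list[dict] = field(
        default_factory=lambda: [
            {"id": "untreated", "treatment": None},
            {"id": "digested", "treatment": "digestion"},
        ]
    )
    gate: dict = field(default_factory=dict)       # GateConfig overrides
    criteria: dict = field(default_factory=dict)   # ScreenCriteria overrides
    noise: dict = field(default_factory=dict)      # TechnicalNoiseModel overrides
    k_clusters: int = 2
    knn_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def load_map(self) -> PanelPlateMap:
        return demo_plate_map() if self.plate_map == "demo" else load_plate_map(self.plate_map)

    def gate_config(self) -> GateConfig:
        return GateConfig(**self.gate)

    def screen_criteria(self) -> ScreenCriteria:
        return ScreenCriteria(**self.criteria)

    def stamp(self) -> str:
        return f"# config_hash={self.config_hash()} seed={self.seed}\n"


def _treatment_by_name(name: str | None):
    if name is None:
        return None
    if name == "digestion":
        return digestion_treatment()
    raise ValueError(f"unknown treatment {name!r} (available: digestion)")


def _events_dir(config: PipelineConfig, sample_id: str) -> Path:
    return Path(config.out_dir) / "events" / sample_id


def run_simulate(config: PipelineConfig) -> Path:
    """Simulate every configured sample over the plate map; write events + manifest.

    Events go to ``out/events/<sample>/<plate>_<well>.csv.gz`` (tabular
    dialect); the manifest records per-well seeds and the planted pooled
    positive fraction per antigen so recovery tests have ground truth.
    """
    pmap = config.load_map()
    noise = default_noise(**config.noise)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "samples": {},
    }
    for k, sample in enumerate(config.samples):
        sid = sample["id"]
        treatment = _treatment_by_name(sample.get("treatment"))
        pops = default_populations()
        planted = treatment.apply(pops) if treatment else pops
        pooled = {
            ag: float(sum(p.abundance * p.positive_fraction.get(ag, 0.0) for p in planted))
            for ag in pmap.antigens
        }
        master = config.seed + k
        wells = simulate_screen_plate(pmap, pops, noise, treatment, master, sample_id=sid)
        d = _events_dir(config, sid)
        d.mkdir(parents=True, exist_ok=True)
        for (plate, well), events in wells.items():
            fcs.write_tabular(events, d / f"{plate}_{well}.csv.gz")
        manifest["samples"][sid] = {
            "master_seed": master,
            "treatment": sample.get("treatment"),
            "planted_pooled_positive_fraction": pooled,
        }
        log.info("simulated %s: %d wells (seed %d)", sid, len(wells), master)
    out = Path(config.out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def gate_sample_wells(
    wells: dict[tuple[str, str], EventTable],
    pmap: PanelPlateMap,
    gate_config: GateConfig,
    sample_id: str,
) -> list[dict]:
    """Gate every antibody well of one sample against its plate's pooled controls."""
    controls_by_plate: dict[str, list[EventTable]] = {}
    for key, entry in pmap.wells.items():
        if not isinstance(entry, Antibody) and key in wells:
            controls_by_plate.setdefault(key[0], []).append(wells[key])
    summaries = []
    for (plate, well), entry in pmap.wells.items():
        if not isinstance(entry, Antibody):
            continue
        if (plate, well) not in wells:
            raise FileNotFoundError(f"no events for well {plate}/{well}")
        ctrls = controls_by_plate.get(plate)
        if not ctrls:
            raise QCError(
                f"no FMO control events on plate {plate!r} for channel {entry.channel_name!r}"
            )
        control = EventTable(
            data=pd.concat([c.data for c in ctrls], ignore_index=True),
            metadata={"plate": plate, "well": "pooled-controls"},
        )
        events = wells[(plate, well)]
        result = gate_well(events, control, gate_config, channel=entry.channel_name)
        counts = result.counts
        try:
            pct = percent_positive(
                events, result, entry.channel_name, result.thresholds[entry.channel_name]
            )
        except QCError:
            pct = np.nan
        summaries.append(
            {
                "sample_id": sample_id,
                "plate": plate,
                "well": well,
                "antigen": entry.antigen_name,
                "channel": entry.channel_name,
                "total": events.n_events,
                "viable": counts["viable"],
                "singlet": counts["singlet"],
                "analysis": counts["analysis"],
                "threshold": result.thresholds[entry.channel_name],
                "percent_positive": pct,
                "qc_pass": result.qc_pass,
            }
        )
    return summaries


def _load_sample_wells(config: PipelineConfig, sample_id: str) -> dict[tuple[str, str], EventTable]:
    d = _events_dir(config, sample_id)
    if not d.is_dir():
        raise FileNotFoundError(f"no simulated events for sample {sample_id!r} under {d}")
    wells = {}
    for f in sorted(d.glob("*.csv.gz")):
        plate, well = f.name.removesuffix(".csv.gz").split("_", 1)
        wells[(plate, well)] = fcs.read_tabular(f)
    return wells


def run_gate(config: PipelineConfig) -> Path:
    """Gate all samples; write per-well gate summaries CSV."""
    pmap = config.load_map()
    gc = config.gate_config()
    rows: list[dict] = []
    for sample in config.samples:
        wells = _load_sample_wells(config, sample["id"])
        rows.extend(gate_sample_wells(wells, pmap, gc, sample["id"]))
    out = Path(config.out_dir) / "gate_summaries.csv"
    df = pd.DataFrame(rows)
    with open(out, "w", newline="") as fh:
        fh.write(config.stamp())
        df.to_csv(fh, index=False, float_format="%.6f")
    log.info("gated %d wells -> %s", len(df), out)
    return out


def run_screen(config: PipelineConfig) -> dict:
    """Assemble the percent-positive matrix, run the treatment screen, write outputs."""
    out_dir = Path(config.out_dir)
    summaries_path = out_dir / "gate_summaries.csv"
    if not summaries_path.exists():
        run_gate(config)
    summaries = pd.read_csv(summaries_path, comment="#").to_dict("records")
    pmap = config.load_map()
    matrix = assemble_matrix(summaries, pmap)
    with open(out_dir / "percent_positive_matrix.csv", "w", newline="") as fh:
        fh.write(config.stamp())
        matrix.to_csv(fh, float_format="%.6f")

    outputs: dict = {"matrix": matrix}
    untreated = [s["id"] for s in config.samples if s.get("treatment") is None]
    treated = [s["id"] for s in config.samples if s.get("treatment") is not None]
    if untreated and treated:
        criteria = config.screen_criteria()
        results = screen_treatment(
            matrix.loc[untreated[0]], matrix.loc[treated[0]], criteria
        )
        with open(out_dir / "screen_results.csv", "w", newline="") as fh:
            fh.write(config.stamp())
            results.to_csv(fh, float_format="%.6f")
        summary = screen_summary(results)
        summary["config_hash"] = config.config_hash()
        summary["seed"] = config.seed
        summary["untreated_sample"] = untreated[0]
        summary["treated_sample"] = treated[0]
        (out_dir / "screen_summary.json").write_text(json.dumps(summary, indent=1))
        outputs["results"] = results
        outputs["summary"] = summary
    if len(untreated) >= 2:
        rep = replicate_reproducibility(matrix.loc[untreated[0]], matrix.loc[untreated[1]])
        outputs["replicate"] = rep
    qc_fail = [s for s in summaries if not s["qc_pass"]]
    (out_dir / "qc_report.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_wells": len(summaries),
                "n_qc_fail": len(qc_fail),
                "qc_fail_wells": [
                    {"sample_id": s["sample_id"], "plate": s["plate"], "well": s["well"]}
                    for s in qc_fail
                ],
            },
            indent=1,
        )
    )
    return outputs


def run_cluster(config: PipelineConfig) -> Path:
    """Cluster sample profiles (k-NN impute -> Pearson distance -> complete linkage)."""
    out_dir = Path(config.out_dir)
    matrix_path = out_dir / "percent_positive_matrix.csv"
    if not matrix_path.exists():
        raise FileNotFoundError(f"run the screen stage first: {matrix_path} missing")
    matrix = pd.read_csv(matrix_path, comment="#", index_col="sample")
    if len(matrix) < 2:
        raise ValueError("clustering needs >= 2 sample rows")
    complete = knn_impute(matrix, k=min(config.knn_k, max(1, len(matrix) - 1)))
    tree = hcluster(pearson_distance(complete))
    out = out_dir / "dendrogram.nwk"
    export_dendrogram(tree, out)
    return out


def run_all(config: PipelineConfig) -> dict:
    run_simulate(config)
    run_gate(config)
    outputs = run_screen(config)
    if len(outputs["matrix"]) >= 2:
        outputs["dendrogram"] = run_cluster(config)
    return outputs
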