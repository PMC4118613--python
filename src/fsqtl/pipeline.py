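"""End-to-end orchestration: simulate, scan, and report runs.

These functions are the library-level backing of the command-line
interface: each consumes a plain config object, writes its artifacts into
an output directory, and returns the in-memory results so Python callers
can keep working with them.  A run log (config echo, seed, per-trait
counts) is written alongside the artifacts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as fio
from . import scan as fscan
from .report import summarize_report
from .simulate import (
    QTLSpec,
    SimulatedFamily,
    SimulationConfig,
    simulate_study,
)
from .traits import average_leaf_replicates, derive_traits
from .types import Effects, QTLRecord, SegType

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_scan_pipeline",
    "run_simulate_pipeline",
    "run_report_pipeline",
    "simulation_config_from_dict",
]


@dataclass
class PipelineConfig:
    """Configuration of a scan run (file paths + analysis knobs)."""

    map_path: str
    genotype_path: str
    phenotype_path: str
    traits: Sequence[str] = ()  # empty = every phenotype column
    q_level: float = 0.05
    min_class_n: int = 5
    collapse_peaks: bool = False
    orthogonal_dominance: bool = False
    derive: bool = True
    out_dir: str = "fsqtl_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_level < 1.0:
            raise ValueError("q_level must lie in (0, 1)")


def _config_hash(cfg) -> str:
    payload = json.dumps(
        dataclasses.asdict(cfg), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _safe(name: str) -> str:
    return name.replace(" ", "_").replace("/", "-")


def run_scan_pipeline(
    config: PipelineConfig,
) -> tuple[list[QTLRecord], dict[str, fscan.ScanResult]]:
    """Run the marker-by-trait scan end to end and write all artifacts.

    Writes per-trait LR-profile TSVs, a combined QTL report, a per-trait
    joint-variance summary, a cross-trait pleiotropy table and a run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lmap = fio.read_map(config.map_path)
    genotypes = fio.read_genotypes(config.genotype_path, lmap)
    table = fio.read_phenotypes(config.phenotype_path)
    table = average_leaf_replicates(table)
    if config.derive:
        table = derive_traits(table)
    traits = list(config.traits) or [str(c) for c in table.columns]
    records: list[QTLRecord] = []
    scans: dict[str, fscan.ScanResult] = {}
    log_lines = [
        f"config_hash: {_config_hash(config)}",
        f"seed: {config.seed}",
        f"markers: {len(lmap)} on {len(lmap.groups)} groups "
        f"({lmap.total_length_cm:.1f} cM)",
        f"individuals: {genotypes.n_individuals}",
    ]
    for trait in traits:
        result = fscan.genome_scan(
            genotypes,
            table,
            trait,
            min_class_n=config.min_class_n,
            orthogonal_dominance=config.orthogonal_dominance,
        )
        result = fscan.fdr_threshold(result, q=config.q_level)
        scans[trait] = result
        recs = fscan.call_qtls(result, collapse_peaks=config.collapse_peaks)
        records.extend(recs)
        fscan.export_lr_profile(result, out / f"lr_profile_{_safe(trait)}.tsv")
        log_lines.append(
            f"trait {trait}: {len(result)} usable markers, "
            f"{len(result.skipped)} skipped, {len(recs)} significant QTLs, "
            f"threshold_LR="
            + (
                f"{result.threshold_lr:.3f}"
                if result.threshold_lr is not None
                else "none"
            )
        )
    fio.write_qtl_report(records, out / "qtl_report.tsv")
    summaries = summarize_report(records)
    summaries["joint_variance"].to_csv(
        out / "joint_variance.tsv", sep="\t", index=False
    )
    summaries["pleiotropy"].to_csv(
        out / "pleiotropy.tsv", sep="\t", index=False
    )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return records, scans


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON mapping."""
    raw = dict(raw)
    qtls = []
    for q in raw.pop("qtls", []):
        st = SegType.parse(q["seg_type"])
        qtls.append(
            QTLSpec(
                marker=q["marker"],
                trait=q["trait"],
                effects=Effects(
                    seg_type=st,
                    mu=float(q.get("mu", 0.0)),
                    a1=float(q["a1"]),
                    a2=float(q["a2"]) if st is SegType.ABXCD else None,
                    d=(
                        float(q["d"])
                        if st in (SegType.ABXCD, SegType.HKXHK)
                        else None
                    ),
                ),
            )
        )
    if "seg_type_mix" in raw:
        raw["seg_type_mix"] = {
            SegType.parse(k): float(v) for k, v in raw["seg_type_mix"].items()
        }
    return SimulationConfig(qtls=qtls, **raw)


def run_simulate_pipeline(
    config: SimulationConfig, out_dir: str | os.PathLike
) -> SimulatedFamily:
    """Simulate a family and write map/genotype/phenotype files + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fam = simulate_study(config)
    fio.write_map(fam.map, out / "map.tsv")
    fio.write_genotypes(fam.genotypes, out / "genotypes.tsv")
    fio.write_phenotypes(fam.phenotypes, out / "phenotypes.csv")
    truth = {
        "seed": config.seed,
        "residual_sd": fam.truth.residual_sd,
        "qtls": [
            {
                "marker": q.marker,
                "trait": q.trait,
                "seg_type": q.effects.seg_type.value,
                "mu": q.effects.mu,
                "a1": q.effects.a1,
                "a2": q.effects.a2,
                "d": q.effects.d,
            }
            for q in fam.truth.qtls
        ],
        "p_alleles": {
            m: fam.truth.p_alleles.loc[m].tolist()
            for m in fam.truth.p_alleles.index
        },
        "q_alleles": {
            m: fam.truth.q_alleles.loc[m].tolist()
            for m in fam.truth.q_alleles.index
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    (out / "run_log.txt").write_text(
        f"config_hash: {_config_hash(config)}\nseed: {config.seed}\n"
        f"progeny: {config.n_progeny}\nmarkers: {len(fam.map)}\n"
    )
    return fam


def run_report_pipeline(
    records: Sequence[QTLRecord], out_dir: str | os.PathLike | None = None
) -> dict[str, pd.DataFrame]:
    """Report-only mode: summarize an existing QTL report."""
    summaries = summarize_report(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in summaries.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return summaries
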