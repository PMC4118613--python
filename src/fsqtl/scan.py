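"""Genome-wide single-marker scan, FDR thresholds and QTL reporting.

Each usable marker is fitted against the trait with the cross-type-specific
likelihood model and tested against the no-QTL null; genome-wide
significance is declared by applying Benjamini–Hochberg FDR control to the
per-marker p-values of a trait's scan.  The "threshold line" of an LR
profile is operationalized as the smallest LR among BH-rejected markers.
Adjacent linked markers flanking one causal locus typically all pass, and
all are reported; an optional peak-collapsing mode keeps only the maximum-LR
marker per contiguous significant run.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import models
from .errors import DegenerateFitError, MarkerNotUsable
from .types import Effects, GenotypeMatrix, LinkageMap, Marker, QTLRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRow",
    "ScanResult",
    "genome_scan",
    "fdr_threshold",
    "call_qtls",
    "joint_variance",
    "pleiotropy_summary",
    "export_lr_profile",
    "read_lr_profile",
]


@dataclass(frozen=True)
class ScanRow:
    """Per-marker scan outcome."""

    marker: Marker
    n: int
    lr: float
    df: int
    p: float
    r2: float
    effects: Effects
    significant: bool = False


@dataclass
class ScanResult:
    """A trait's genome scan: rows ordered by (linkage group, position)."""

    trait: str
    rows: list[ScanRow]
    q_level: float | None = None
    threshold_lr: float | None = None
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = sorted(
            self.rows,
            key=lambda r: (r.marker.linkage_group, r.marker.position_cm),
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [r.marker.name for r in self.rows],
                "group": [r.marker.linkage_group for r in self.rows],
                "position_cM": [r.marker.position_cm for r in self.rows],
                "n_genotypes": [r.marker.seg_type.n_classes for r in self.rows],
                "n": [r.n for r in self.rows],
                "LR": [r.lr for r in self.rows],
                "df": [r.df for r in self.rows],
                "p": [r.p for r in self.rows],
                "R2": [r.r2 for r in self.rows],
                "significant": [r.significant for r in self.rows],
            }
        )


def genome_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    *,
    min_class_n: int = 5,
    orthogonal_dominance: bool = False,
) -> ScanResult:
    """Fit and test every usable marker against one trait.

    Markers that are monomorphic in the usable individuals, have a sparse
    genotype class, or give a degenerate fit are logged and omitted.  For
    each marker the null fit is recomputed on exactly the individuals with
    both a genotype call and a phenotype there, so the likelihood ratio
    compares nested models on identical data.
    """
    if trait not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not present in the phenotype table")
    y = phenotypes[trait]
    shared = [i for i in genotypes.individuals if i in y.index]
    if not shared:
        raise ValueError("no individuals shared between genotypes and phenotypes")
    rows: list[ScanRow] = []
    skipped: dict[str, str] = {}
    for marker in genotypes.map:
        if marker.name not in genotypes.calls.index:
            skipped[marker.name] = "no genotype calls"
            continue
        calls = genotypes.marker_calls(marker.name).reindex(shared)
        try:
            full = models.fit_marker(
                marker,
                calls.tolist(),
                y.reindex(shared).to_numpy(dtype=float),
                min_class_n=min_class_n,
                index=shared,
            )
            null = models.fit_null(
                y.reindex(list(full.individual_index)).to_numpy(dtype=float),
                index=full.individual_index,
            )
            lr, df, p = models.likelihood_ratio(null, full)
            r2 = models.variance_explained(null, full)
            effects = models.decompose_effects(
                full, orthogonal_dominance=orthogonal_dominance
            )
        except (MarkerNotUsable, DegenerateFitError) as exc:
            skipped[marker.name] = str(exc)
            logger.info("skipping marker %s: %s", marker.name, exc)
            continue
        rows.append(
            ScanRow(
                marker=marker, n=full.n, lr=lr, df=df, p=p, r2=r2,
                effects=effects,
            )
        )
    if not rows:
        raise ValueError(f"trait {trait!r}: no usable markers")
    logger.info(
        "trait %s: %d usable markers, %d skipped", trait, len(rows), len(skipped)
    )
    return ScanResult(trait=trait, rows=rows, skipped=skipped)


def fdr_threshold(scan: ScanResult, q: float = 0.05) -> ScanResult:
    """Apply Benjamini–Hochberg FDR control across the scan's markers.

    Marks BH-rejected rows significant and sets ``threshold_lr`` to the
    minimum LR among them (the horizontal line of an LR-profile plot), or
    ``None`` when nothing is rejected.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if not scan.rows:
        raise ValueError("scan has no rows")
    reject, *_ = multipletests([r.p for r in scan.rows], alpha=q, method="fdr_bh")
    rows = [replace(r, significant=bool(s)) for r, s in zip(scan.rows, reject)]
    sig_lrs = [r.lr for r in rows if r.significant]
    return ScanResult(
        trait=scan.trait,
        rows=rows,
        q_level=q,
        threshold_lr=min(sig_lrs) if sig_lrs else None,
        skipped=dict(scan.skipped),
    )


def _records_from_rows(trait: str, rows: Iterable[ScanRow]) -> list[QTLRecord]:
    out = []
    for r in rows:
        e = r.effects
        out.append(
            QTLRecord(
                trait=trait,
                marker=r.marker.name,
                linkage_group=r.marker.linkage_group,
                n_genotypes=r.marker.seg_type.n_classes,
                a1=e.a1,
                a2=e.a2,
                d=e.d,
                r2=r.r2,
            )
        )
    return out


def call_qtls(scan: ScanResult, *, collapse_peaks: bool = False) -> list[QTLRecord]:
    """Turn the BH-significant markers of a thresholded scan into records.

    By default every significant marker is reported.  With
    ``collapse_peaks`` only the maximum-LR marker of each contiguous run of
    significant markers within a linkage group is kept.
    """
    if scan.q_level is None:
        raise ValueError("apply fdr_threshold before calling QTLs")
    sig = [r for r in scan.rows if r.significant]
    if not collapse_peaks:
        return _records_from_rows(scan.trait, sig)
    peaks: list[ScanRow] = []
    run: list[ScanRow] = []
    prev_key: tuple[int, int] | None = None
    index_in_group: dict[str, tuple[int, int]] = {}
    counter: dict[int, int] = {}
    for r in scan.rows:
        g = r.marker.linkage_group
        counter[g] = counter.get(g, -1) + 1
        index_in_group[r.marker.name] = (g, counter[g])
    for r in sig:
        key = index_in_group[r.marker.name]
        if run and (key[0] != prev_key[0] or key[1] != prev_key[1] + 1):
            peaks.append(max(run, key=lambda x: x.lr))
            run = []
        run.append(r)
        prev_key = key
    if run:
        peaks.append(max(run, key=lambda x: x.lr))
    return _records_from_rows(scan.trait, peaks)


def joint_variance(records: Sequence[QTLRecord], trait: str) -> float:
    """Joint phenotypic variance attributed to a trait's QTLs: Σ R²."""
    return float(sum(r.r2 for r in records if r.trait == trait))


def pleiotropy_summary(records: Sequence[QTLRecord]) -> pd.DataFrame:
    """Markers significant for two or more traits, with their trait sets."""
    by_marker: dict[str, list[str]] = {}
    for r in records:
        traits = by_marker.setdefault(r.marker, [])
        if r.trait not in traits:
            traits.append(r.trait)
    shared = {m: ts for m, ts in by_marker.items() if len(ts) >= 2}
    return pd.DataFrame(
        {
            "marker": list(shared),
            "n_traits": [len(ts) for ts in shared.values()],
            "traits": [", ".join(ts) for ts in shared.values()],
        }
    )


def export_lr_profile(scan: ScanResult, path: os.PathLike | str) -> None:
    """Write the per-marker LR track of a scan as a TSV.

    Columns: ``group  position_cM  marker  n_genotypes  LR  significant`` —
    the data behind a per-group LR-profile figure.
    """
    df = scan.to_frame()[
        ["group", "position_cM", "marker", "n_genotypes", "LR", "significant"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_lr_profile(path: os.PathLike | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
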