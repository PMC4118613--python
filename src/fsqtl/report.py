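"""Report-only analysis of a significant-QTL table.

Operates on a finished QTL report (such as the packaged reference table of
significant QTLs for juvenile growth and architecture traits in a mei
F1 full-sib family) without re-running any scan: per-trait joint variance
explained, dominance ratios, and cross-trait pleiotropy.
"""

from __future__ import annotations

import os
from importlib import resources
from typing import Sequence

import pandas as pd

from .io import read_qtl_report
from .models import dominance_ratio
from .scan import joint_variance, pleiotropy_summary
from .types import Effects, QTLRecord, SegType

__all__ = [
    "reference_qtl_table",
    "record_effects",
    "record_dominance_ratio",
    "joint_variance_table",
    "dominance_table",
    "summarize_report",
]

_REFERENCE_RESOURCE = "mei_f1_qtl_table.tsv"


def reference_qtl_table() -> list[QTLRecord]:
    """The packaged reference table of published significant QTLs for the
    mei full-sib family (effects and R² per trait × marker)."""
    with resources.as_file(
        resources.files("fsqtl.data").joinpath(_REFERENCE_RESOURCE)
    ) as path:
        return read_qtl_report(path)


_SEG_BY_NCLASS = {2: SegType.LMXLL, 3: SegType.HKXHK, 4: SegType.ABXCD}


def record_effects(record: QTLRecord) -> Effects:
    """Reconstruct an Effects object from a report row.

    The overall mean is not part of a report and is set to 0; everything
    the ratio and variance summaries need (a1, a2, d) is preserved.  A
    2-class row maps onto the testcross parameterization, a 3-class row
    onto the biallelic intercross, a 4-class row onto the multiallelic
    intercross.
    """
    st = _SEG_BY_NCLASS[record.n_genotypes]
    d = record.d if st is not SegType.LMXLL else None
    if st is SegType.HKXHK and d is None:
        d = 0.0  # table omitted the estimate; treat as no dominance
    return Effects(seg_type=st, mu=0.0, a1=record.a1, a2=record.a2, d=d)


def record_dominance_ratio(record: QTLRecord) -> float | None:
    """d/a ratio of a report row; None for testcross (2-class) rows."""
    if record.n_genotypes == 2:
        return None
    return dominance_ratio(record_effects(record))


def joint_variance_table(records: Sequence[QTLRecord]) -> pd.DataFrame:
    """Per-trait QTL counts and joint variance explained (Σ R²)."""
    traits: list[str] = []
    for r in records:
        if r.trait not in traits:
            traits.append(r.trait)
    return pd.DataFrame(
        {
            "trait": traits,
            "n_qtls": [
                sum(1 for r in records if r.trait == t) for t in traits
            ],
            "joint_R2": [joint_variance(records, t) for t in traits],
        }
    )


def dominance_table(records: Sequence[QTLRecord]) -> pd.DataFrame:
    """d/a ratios for every row where dominance is estimated."""
    rows = [
        (r.trait, r.marker, r.linkage_group, r.d, record_dominance_ratio(r))
        for r in records
        if r.n_genotypes >= 3 and r.d is not None
    ]
    return pd.DataFrame(
        rows, columns=["trait", "marker", "linkage_group", "d", "d_over_a"]
    )


def summarize_report(
    records: Sequence[QTLRecord],
) -> dict[str, pd.DataFrame]:
    """All report-mode summaries keyed by name."""
    return {
        "joint_variance": joint_variance_table(records),
        "pleiotropy": pleiotropy_summary(records),
        "dominance": dominance_table(records),
    }
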