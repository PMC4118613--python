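"""Readers and writers for the pipeline's plain-text file dialects.

Map file
    TSV with header ``marker  group  position_cM  seg_type``; seg_type is
    one of the CP codes abxcd / hkxhk / lmxll / nnxnp.

Genotype file
    TSV, one row per marker: first column the marker name, remaining
    columns one per individual (header row gives the individual ids).
    Missing calls are ``--`` or ``.``.

Phenotype file
    CSV, one row per individual, first column ``id``; leaf traits may come
    as up-to-three per-leaf replicate columns (``LL1 LL2 LL3`` ...).

QTL report
    TSV with columns ``trait  marker  linkage_group  n_genotypes  a1  a2  d
    R2``; effects a marker's cross type cannot estimate are written ``-``.
"""

from __future__ import annotations

import io as _io
import os
from typing import Sequence

import pandas as pd

from .errors import ParseError
from .types import (
    MISSING,
    MISSING_TOKENS,
    GenotypeMatrix,
    LinkageMap,
    Marker,
    QTLRecord,
    SegType,
)

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_qtl_report",
    "write_qtl_report",
]

_MAP_COLUMNS = ["marker", "group", "position_cM", "seg_type"]
_REPORT_COLUMNS = [
    "trait",
    "marker",
    "linkage_group",
    "n_genotypes",
    "a1",
    "a2",
    "d",
    "R2",
]
#: token written for an effect the cross type cannot estimate
_ABSENT = "-"


def read_map(path: os.PathLike | str) -> LinkageMap:
    """Read a linkage-map TSV into a validated :class:`LinkageMap`."""
    markers: list[Marker] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MAP_COLUMNS:
            raise ParseError(
                f"expected header {_MAP_COLUMNS}, got {header}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"expected 4 fields, got {len(fields)}", lineno)
            name, group, pos, seg = fields
            if name in seen:
                raise ParseError(f"duplicate marker name {name!r}", lineno)
            seen.add(name)
            try:
                seg_type = SegType.parse(seg)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            try:
                marker = Marker(
                    name=name,
                    seg_type=seg_type,
                    linkage_group=int(group),
                    position_cm=float(pos),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            markers.append(marker)
    return LinkageMap(markers)


def write_map(linkage_map: LinkageMap, path: os.PathLike | str) -> None:
    linkage_map.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(
    path: os.PathLike | str, linkage_map: LinkageMap
) -> GenotypeMatrix:
    """Read a genotype TSV, validating every call against the map."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str)
    calls = df.map(lambda t: MISSING if t.strip() in MISSING_TOKENS else t.strip())
    try:
        return GenotypeMatrix(calls, linkage_map)
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def write_genotypes(genotypes: GenotypeMatrix, path: os.PathLike | str) -> None:
    out = genotypes.calls.map(lambda c: "--" if c is MISSING else c)
    out.index.name = "marker"
    out.to_csv(path, sep="\t")


#: measured botanical traits, which must be strictly positive where present
_MEASURED_BASES = frozenset({"HT", "DIA", "LL", "LW", "LA", "PET", "VN"})


def read_phenotypes(path: os.PathLike | str) -> pd.DataFrame:
    """Read the phenotype CSV; index = individual id, one column per trait
    or per-leaf replicate.

    Measured botanical columns (HT, DIA and the leaf traits, replicated or
    not) must be strictly positive where present; other columns (e.g.
    simulated traits on an arbitrary scale) are only required to be numeric.
    """
    df = pd.read_csv(path, index_col="id")
    df.index = df.index.astype(str)
    bad = df.select_dtypes(exclude="number").columns.tolist()
    if bad:
        raise ParseError(f"non-numeric phenotype column(s): {bad}")
    measured = [
        c for c in df.columns if str(c).rstrip("123") in _MEASURED_BASES
    ]
    if measured and (df[measured] <= 0).any().any():
        neg = [c for c in measured if (df[c] <= 0).any()]
        raise ParseError(f"non-positive measured value(s) in column(s): {neg}")
    return df


def write_phenotypes(table: pd.DataFrame, path: os.PathLike | str) -> None:
    out = table.copy()
    out.index.name = "id"
    out.to_csv(path)


def _fmt(x: float | None) -> str:
    return _ABSENT if x is None else format(x, "g")


def write_qtl_report(
    records: Sequence[QTLRecord], path: os.PathLike | str
) -> None:
    """Write a significant-QTL report TSV (one row per trait × marker)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.trait,
                        r.marker,
                        str(r.linkage_group),
                        str(r.n_genotypes),
                        _fmt(r.a1),
                        _fmt(r.a2),
                        _fmt(r.d),
                        format(r.r2, "g"),
                    ]
                )
                + "\n"
            )


def _parse_effect(token: str, lineno: int) -> float | None:
    token = token.strip()
    if token in (_ABSENT, ""):
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"bad effect value {token!r}", lineno) from None


def read_qtl_report(path: os.PathLike | str) -> list[QTLRecord]:
    """Read a QTL report TSV back into :class:`QTLRecord` objects."""
    records: list[QTLRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REPORT_COLUMNS:
            raise ParseError(
                f"expected header {_REPORT_COLUMNS}, got {header}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_REPORT_COLUMNS):
                raise ParseError(
                    f"expected {len(_REPORT_COLUMNS)} fields, got {len(fields)}",
                    lineno,
                )
            trait, marker, lg, ngeno, a1, a2, d, r2 = fields
            try:
                records.append(
                    QTLRecord(
                        trait=trait,
                        marker=marker,
                        linkage_group=int(lg),
                        n_genotypes=int(ngeno),
                        a1=float(a1),
                        a2=_parse_effect(a2, lineno),
                        d=_parse_effect(d, lineno),
                        r2=float(r2),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
    return records
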