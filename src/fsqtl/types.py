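"""Domain types for outcrossed full-sib (CP) QTL mapping.

A full-sib F1 family from two outbred parents segregates differently from
locus to locus.  Four cross types occur, coded as in CP-population genotype
files:

======== ================================ ======================== =========
code     parental cross                   progeny classes          ratio
======== ================================ ======================== =========
abxcd    multiallelic intercross (P ab,   ac, ad, bc, bd           1:1:1:1
         Q cd)
hkxhk    biallelic intercross             hh, hk, kk               1:2:1
lmxll    testcross, P heterozygous        ll, lm                   1:1
nnxnp    testcross, Q heterozygous        nn, np                   1:1
======== ================================ ======================== =========

The class count determines how many genetic effects are estimable at a
marker: one additive effect for a testcross, additive + dominance for a
biallelic intercross, and two parent-specific additive effects plus a
dominance effect for a multiallelic intercross.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd

#: Sentinel used internally for a missing genotype call.
MISSING: None = None

#: Tokens accepted in genotype files for a missing call.
MISSING_TOKENS = frozenset({"--", ".", ""})


class SegType(str, enum.Enum):
    """Segregation type of a marker in the full-sib family."""

    ABXCD = "abxcd"
    HKXHK = "hkxhk"
    LMXLL = "lmxll"
    NNXNP = "nnxnp"

    @property
    def classes(self) -> tuple[str, ...]:
        """Legal progeny genotype-class labels, in canonical order."""
        return _CLASSES[self]

    @property
    def n_classes(self) -> int:
        return len(_CLASSES[self])

    @property
    def class_frequencies(self) -> dict[str, float]:
        """Expected Mendelian class frequencies in the progeny."""
        return dict(_FREQS[self])

    @property
    def is_testcross(self) -> bool:
        return self in (SegType.LMXLL, SegType.NNXNP)

    @classmethod
    def parse(cls, token: str) -> "SegType":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown segregation type {token!r}; expected one of "
                f"{', '.join(t.value for t in cls)}"
            ) from None


_CLASSES: dict[SegType, tuple[str, ...]] = {
    SegType.ABXCD: ("ac", "ad", "bc", "bd"),
    SegType.HKXHK: ("hh", "hk", "kk"),
    SegType.LMXLL: ("ll", "lm"),
    SegType.NNXNP: ("nn", "np"),
}

_FREQS: dict[SegType, dict[str, float]] = {
    SegType.ABXCD: {"ac": 0.25, "ad": 0.25, "bc": 0.25, "bd": 0.25},
    SegType.HKXHK: {"hh": 0.25, "hk": 0.5, "kk": 0.25},
    SegType.LMXLL: {"ll": 0.5, "lm": 0.5},
    SegType.NNXNP: {"nn": 0.5, "np": 0.5},
}


@dataclass(frozen=True)
class Marker:
    """A mapped marker: identity, cross type and map location."""

    name: str
    seg_type: SegType
    linkage_group: int
    position_cm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.position_cm) and self.position_cm >= 0):
            raise ValueError(
                f"marker {self.name}: position must be a finite non-negative "
                f"cM value, got {self.position_cm!r}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        return self.seg_type.classes


class LinkageMap:
    """An ordered collection of markers grouped into linkage groups.

    Markers within a group are kept sorted by cM position; names are unique
    map-wide.  Positions are cumulative within a group and may start at an
    arbitrary offset — only differences matter downstream.
    """

    def __init__(self, markers: list[Marker]):
        groups: dict[int, list[Marker]] = {}
        seen: set[str] = set()
        for m in markers:
            if m.name in seen:
                raise ValueError(f"duplicate marker name {m.name!r}")
            seen.add(m.name)
            groups.setdefault(m.linkage_group, []).append(m)
        self.groups: dict[int, list[Marker]] = {
            g: sorted(ms, key=lambda m: m.position_cm)
            for g, ms in sorted(groups.items())
        }
        self._by_name: dict[str, Marker] = {m.name: m for m in self}

    def __iter__(self) -> Iterator[Marker]:
        for ms in self.groups.values():
            yield from ms

    def __len__(self) -> int:
        return sum(len(ms) for ms in self.groups.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def marker(self, name: str) -> Marker:
        return self._by_name[name]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self]

    @property
    def total_length_cm(self) -> float:
        """Sum over groups of (last − first) marker position."""
        return float(
            sum(
                ms[-1].position_cm - ms[0].position_cm
                for ms in self.groups.values()
                if ms
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.name for m in self],
                "group": [m.linkage_group for m in self],
                "position_cM": [m.position_cm for m in self],
                "seg_type": [m.seg_type.value for m in self],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkageMap):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return (
            f"<LinkageMap: {len(self)} markers on {len(self.groups)} groups, "
            f"{self.total_length_cm:.1f} cM>"
        )


class GenotypeMatrix:
    """Progeny genotype calls: markers × individuals, CP class labels.

    Stored as a pandas DataFrame of strings with ``None`` for missing calls.
    Every non-missing call is validated against the owning marker's legal
    class set on construction.
    """

    def __init__(self, calls: pd.DataFrame, linkage_map: LinkageMap):
        if calls.columns.duplicated().any():
            dup = calls.columns[calls.columns.duplicated()][0]
            raise ValueError(f"duplicate individual id {dup!r}")
        calls = calls.astype(object).where(pd.notna(calls), MISSING)
        for name in calls.index:
            if name not in linkage_map:
                raise ValueError(f"marker {name!r} not present in the linkage map")
            legal = set(linkage_map.marker(name).classes)
            row = calls.loc[name]
            observed = {v for v in pd.unique(row.to_numpy(dtype=object)) if v is not MISSING}
            if not observed <= legal:
                bad = sorted(observed - legal)[0]
                ind = row[row == bad].index[0]
                raise ValueError(
                    f"illegal genotype class {bad!r} for marker {name!r} "
                    f"({linkage_map.marker(name).seg_type.value}) in "
                    f"individual {ind!r}"
                )
        self.calls = calls
        self.map = linkage_map

    @property
    def individuals(self) -> list[str]:
        return [str(c) for c in self.calls.columns]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def marker_calls(self, name: str) -> pd.Series:
        """Calls for one marker, indexed by individual id."""
        return self.calls.loc[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.calls.equals(other.calls) and self.map == other.map


@dataclass(frozen=True)
class Effects:
    """Decomposed genetic effects at a marker.

    ``a1`` is the additive effect contributed by parent P; ``a2`` the one
    from parent Q (estimable only for abxcd); ``d`` the dominance effect
    (absent for testcross types).  ``mu`` is the model's overall mean.
    """

    seg_type: SegType
    mu: float
    a1: float
    a2: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        st = self.seg_type
        if st is SegType.ABXCD:
            ok = self.a2 is not None and self.d is not None
        elif st is SegType.HKXHK:
            ok = self.a2 is None and self.d is not None
        else:
            ok = self.a2 is None and self.d is None
        if not ok:
            raise ValueError(
                f"effects inconsistent with {st.value}: a2={self.a2}, d={self.d}"
            )


@dataclass(frozen=True)
class QTLRecord:
    """One row of the significant-QTL report.

    ``n_genotypes`` is the number of progeny classes at the marker (2, 3 or
    4), which fixes which effects are estimable: 4 → a1, a2, d; 3 → a1, d;
    2 → a1 only.  A dominance estimate may be absent from a 3-genotype row
    (published tables occasionally omit it) but never present where the
    cross type cannot estimate it.
    """

    trait: str
    marker: str
    linkage_group: int
    n_genotypes: int
    a1: float
    a2: float | None = None
    d: float | None = None
    r2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genotypes not in (2, 3, 4):
            raise ValueError(f"{self.marker}: n_genotypes must be 2, 3 or 4")
        bad_a2 = (self.a2 is not None) != (self.n_genotypes == 4)
        bad_d = self.d is not None and self.n_genotypes < 3
        if bad_a2 or bad_d:
            raise ValueError(
                f"{self.marker}: a2/d presence inconsistent with "
                f"{self.n_genotypes} genotype classes"
            )


@dataclass(frozen=True)
class ModelFit:
    """A maximum-likelihood single-marker fit (or the null, no-QTL fit).

    Under the normal model the class means are the MLEs, the residual
    variance is rss/n (the ML, not unbiased, estimator) and
    loglik = −(n/2)·(ln(2π·σ²) + 1).
    """

    marker: Marker | None
    class_means: Mapping[str, float]
    class_counts: Mapping[str, int]
    n: int
    rss: float
    sigma2: float
    loglik: float
    #: ids of the individuals used, in order — fits are only comparable
    #: when computed on the identical subset
    individual_index: tuple = field(default=(), repr=False, compare=False)

    @property
    def n_classes(self) -> int:
        return len(self.class_means)

    @property
    def is_null(self) -> bool:
        return self.marker is None
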