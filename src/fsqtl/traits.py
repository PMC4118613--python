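"""Replicate averaging and derived botanical traits.

Measured traits are the height (HT, cm) and basal diameter (DIA, mm) of the
main stem, and the per-leaf traits leaf length (LL, cm), leaf width (LW,
cm), leaf area (LA, cm²), petiole length (PET, cm) and vein count (VN),
each scored on up to three representative leaves per seedling.  Replicate
means (over the available leaves) feed the QTL scan.

Three form/anatomy traits are derived as ratios:

* ``stem_taper``   = DIA / HT — stem slenderness (mm/cm as measured);
* ``leaf_shape``   = LW / LL — blade width-to-length ratio (dimensionless);
* ``vein_density`` = VN / LA — veins per unit blade area (cm⁻²).

Ratios are formed from the replicate-averaged columns (ratio of averages).
QTL inference is invariant to a constant unit factor within a trait, so no
unit conversion is applied to the taper ratio.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitDefinition",
    "LEAF_TRAITS",
    "DERIVED_TRAITS",
    "average_leaf_replicates",
    "derive_traits",
]


@dataclass(frozen=True)
class TraitDefinition:
    """A trait: either measured directly or a declared ratio of two others."""

    name: str
    kind: str  # "measured" | "derived"
    numerator: str | None = None
    denominator: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "derived"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "derived" and not (self.numerator and self.denominator):
            raise ValueError(f"derived trait {self.name!r} needs a ratio formula")


#: leaf traits scored per leaf, replicated up to three times
LEAF_TRAITS: tuple[str, ...] = ("LL", "LW", "LA", "PET", "VN")

DERIVED_TRAITS: tuple[TraitDefinition, ...] = (
    TraitDefinition("stem_taper", "derived", numerator="DIA", denominator="HT"),
    TraitDefinition("leaf_shape", "derived", numerator="LW", denominator="LL"),
    TraitDefinition("vein_density", "derived", numerator="VN", denominator="LA"),
)

_REP_RE = re.compile(r"^([A-Za-z_]+?)([123])$")


def average_leaf_replicates(
    table: pd.DataFrame, leaf_traits: tuple[str, ...] = LEAF_TRAITS
) -> pd.DataFrame:
    """Collapse per-leaf replicate columns to their arithmetic mean.

    ``LL1 LL2 LL3`` → ``LL`` etc.  The mean is taken over the non-missing
    replicates; an individual with all replicates missing gets a missing
    trait value.  Columns without replicate structure pass through.
    """
    out = pd.DataFrame(index=table.index)
    handled: set[str] = set()
    for col in table.columns:
        m = _REP_RE.match(str(col))
        base = m.group(1) if m else None
        if base in leaf_traits:
            if base in handled:
                continue
            reps = [
                c
                for c in table.columns
                if (mm := _REP_RE.match(str(c))) and mm.group(1) == base
            ]
            if len(reps) > 3:
                raise ValueError(f"trait {base}: more than 3 replicate columns")
            out[base] = table[reps].mean(axis=1, skipna=True)
            handled.add(base)
        else:
            out[col] = table[col]
    return out


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append the derived ratio traits to a replicate-averaged table.

    A zero, negative or missing denominator yields a missing derived value
    (with a warning in the log) rather than an error; measured columns are
    never altered, and re-deriving is idempotent.
    """
    out = table.copy()
    for t in DERIVED_TRAITS:
        if t.numerator not in out.columns or t.denominator not in out.columns:
            logger.warning(
                "derived trait %s skipped: needs columns %s and %s",
                t.name,
                t.numerator,
                t.denominator,
            )
            continue
        num = out[t.numerator].astype(float)
        den = out[t.denominator].astype(float)
        bad = den.notna() & (den <= 0)
        if bad.any():
            logger.warning(
                "derived trait %s: %d individual(s) with non-positive %s "
                "set to missing",
                t.name,
                int(bad.sum()),
                t.denominator,
            )
        out[t.name] = (num / den.where(~bad)).replace(
            [np.inf, -np.inf], np.nan
        )
    return out
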