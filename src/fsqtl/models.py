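"""Per-marker likelihood models, effect decomposition and test statistics.

The single-marker model treats the phenotype within each genotype class as
normal with a class-specific mean and a common residual variance.  The MLEs
are then the per-class arithmetic means and sigma² = RSS/n, so the maximized
log-likelihood is −(n/2)·(ln(2π·σ²)+1) and the likelihood-ratio statistic
against the one-mean null reduces to n·ln(RSS₀/RSS₁).  It is referred to a
chi-square with (number of genotype classes − 1) degrees of freedom — the
number of genetic effect parameters the cross type supports.

Genotypic values for the multiallelic intercross (abxcd) follow the
four-equation parameterization

    μ11 = μ + a1 + a2 + d        μ12 = μ + a1 − a2 − d
    μ21 = μ − a1 + a2 − d        μ22 = μ − a1 − a2 − d

with progeny classes mapped (ac, ad, bc, bd) → (P1Q1, P1Q2, P2Q1, P2Q2).
This system is nonsingular but non-orthogonal: its d equals twice the
textbook orthogonal dominance contrast.  ``orthogonal_dominance=True``
switches the fourth equation to μ22 = μ − a1 − a2 + d, giving the orthogonal
variant in which (a1, a2, d) are the usual contrasts of the four means.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFitError,
    IncompleteClassesError,
    NotSegregatingError,
    SparseClassError,
)
from .types import MISSING, Effects, Marker, ModelFit, SegType

__all__ = [
    "fit_marker",
    "fit_null",
    "decompose_effects",
    "effects_to_class_means",
    "genotypic_value",
    "likelihood_ratio",
    "variance_explained",
    "dominance_ratio",
]

#: abxcd progeny class → (P-allele index, Q-allele index), 1-based.
ABXCD_ROLE = {"ac": (1, 1), "ad": (1, 2), "bc": (2, 1), "bd": (2, 2)}

_SIGMA2_FLOOR = 1e-300


def _gaussian_loglik(n: int, sigma2: float) -> float:
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _clean(
    calls: Sequence, phenotypes: Sequence[float], index: Iterable | None
) -> tuple[list, np.ndarray, tuple]:
    calls = list(calls)
    y = np.asarray(phenotypes, dtype=float)
    if len(calls) != len(y):
        raise ValueError(
            f"calls ({len(calls)}) and phenotypes ({len(y)}) must be aligned"
        )
    idx = tuple(index) if index is not None else tuple(range(len(y)))
    keep = [
        i
        for i in range(len(y))
        if calls[i] is not MISSING and not _is_na(calls[i]) and np.isfinite(y[i])
    ]
    return [calls[i] for i in keep], y[keep], tuple(idx[i] for i in keep)


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def fit_marker(
    marker: Marker,
    calls: Sequence,
    phenotypes: Sequence[float],
    *,
    min_class_n: int = 5,
    index: Iterable | None = None,
) -> ModelFit:
    """ML fit of per-genotype-class means at one marker.

    Individuals with a missing genotype or non-finite phenotype are dropped.
    Raises :class:`NotSegregatingError` if fewer than two classes are
    observed, :class:`SparseClassError` if any observed class has fewer than
    ``min_class_n`` observations, and :class:`DegenerateFitError` on zero
    residual variance.  A legal class that is entirely unobserved leaves the
    fit valid (with df reduced accordingly) but makes the effect
    decomposition unavailable.
    """
    calls, y, idx = _clean(calls, phenotypes, index)
    counts = {c: 0 for c in marker.classes}
    for c in calls:
        if c not in counts:
            raise ValueError(
                f"illegal class {c!r} for {marker.seg_type.value} marker "
                f"{marker.name}"
            )
        counts[c] += 1
    observed = [c for c in marker.classes if counts[c] > 0]
    if len(observed) < 2:
        raise NotSegregatingError(
            f"marker {marker.name}: {len(observed)} genotype class(es) observed"
        )
    sparse = [c for c in observed if counts[c] < min_class_n]
    if sparse:
        raise SparseClassError(
            f"marker {marker.name}: classes {sparse} have fewer than "
            f"{min_class_n} observations"
        )
    arr = np.asarray(calls, dtype=object)
    means = {c: float(y[arr == c].mean()) for c in observed}
    fitted = np.array([means[c] for c in calls])
    rss = float(((y - fitted) ** 2).sum())
    n = len(y)
    sigma2 = rss / n
    if sigma2 <= _SIGMA2_FLOOR:
        raise DegenerateFitError(
            f"marker {marker.name}: zero residual variance (all phenotypes "
            "equal within classes)"
        )
    return ModelFit(
        marker=marker,
        class_means=means,
        class_counts={c: counts[c] for c in observed},
        n=n,
        rss=rss,
        sigma2=sigma2,
        loglik=_gaussian_loglik(n, sigma2),
        individual_index=idx,
    )


def fit_null(
    phenotypes: Sequence[float], *, index: Iterable | None = None
) -> ModelFit:
    """Null (no-QTL) fit: a single grand mean for all individuals."""
    y = np.asarray(phenotypes, dtype=float)
    idx = tuple(index) if index is not None else tuple(range(len(y)))
    keep = np.isfinite(y)
    y = y[keep]
    idx = tuple(i for i, k in zip(idx, keep) if k)
    if len(y) < 2:
        raise ValueError("null fit requires at least two non-missing phenotypes")
    mean = float(y.mean())
    rss = float(((y - mean) ** 2).sum())
    n = len(y)
    sigma2 = rss / n
    if sigma2 <= _SIGMA2_FLOOR:
        raise DegenerateFitError("constant phenotype: zero total variance")
    return ModelFit(
        marker=None,
        class_means={"all": mean},
        class_counts={"all": n},
        n=n,
        rss=rss,
        sigma2=sigma2,
        loglik=_gaussian_loglik(n, sigma2),
        individual_index=idx,
    )


def effects_to_class_means(
    effects: Effects, *, orthogonal_dominance: bool = False
) -> dict[str, float]:
    """Forward genotypic-value equations: effects → per-class means."""
    st = effects.seg_type
    mu, a1 = effects.mu, effects.a1
    if st is SegType.ABXCD:
        a2, d = effects.a2, effects.d
        mu22 = mu - a1 - a2 + d if orthogonal_dominance else mu - a1 - a2 - d
        return {
            "ac": mu + a1 + a2 + d,
            "ad": mu + a1 - a2 - d,
            "bc": mu - a1 + a2 - d,
            "bd": mu22,
        }
    if st is SegType.HKXHK:
        return {"hh": mu + a1, "hk": mu + effects.d, "kk": mu - a1}
    if st is SegType.LMXLL:
        return {"lm": mu + a1, "ll": mu - a1}
    return {"np": mu + a1, "nn": mu - a1}


def genotypic_value(
    effects: Effects, klass: str, *, orthogonal_dominance: bool = False
) -> float:
    """Genotypic value of one progeny class under the forward equations."""
    means = effects_to_class_means(
        effects, orthogonal_dominance=orthogonal_dominance
    )
    if klass not in means:
        raise ValueError(
            f"class {klass!r} is not legal for {effects.seg_type.value}"
        )
    return means[klass]


def decompose_effects(
    fit: ModelFit, *, orthogonal_dominance: bool = False
) -> Effects:
    """Invert the genotypic-value equations: fitted class means → effects.

    Requires the full class set for the marker's cross type; otherwise the
    system is underdetermined and :class:`IncompleteClassesError` is raised.
    """
    if fit.marker is None:
        raise ValueError("cannot decompose a null fit")
    st = fit.marker.seg_type
    means = fit.class_means
    missing = [c for c in st.classes if c not in means]
    if missing:
        raise IncompleteClassesError(
            f"marker {fit.marker.name}: class means missing for {missing}"
        )
    if st is SegType.ABXCD:
        m11, m12, m21, m22 = (means[c] for c in ("ac", "ad", "bc", "bd"))
        if orthogonal_dominance:
            mu = (m11 + m12 + m21 + m22) / 4.0
            a1 = (m11 + m12 - m21 - m22) / 4.0
            a2 = (m11 - m12 + m21 - m22) / 4.0
            d = (m11 - m12 - m21 + m22) / 4.0
        else:
            a2 = (m21 - m22) / 2.0
            d = ((m11 - m12) - (m21 - m22)) / 2.0
            a1 = ((m11 + m12) - (m21 + m22) - 2.0 * d) / 4.0
            mu = m11 - a1 - a2 - d
        return Effects(seg_type=st, mu=mu, a1=a1, a2=a2, d=d)
    if st is SegType.HKXHK:
        mu = (means["hh"] + means["kk"]) / 2.0
        a1 = (means["hh"] - means["kk"]) / 2.0
        d = means["hk"] - mu
        return Effects(seg_type=st, mu=mu, a1=a1, d=d)
    het, hom = ("lm", "ll") if st is SegType.LMXLL else ("np", "nn")
    mu = (means[het] + means[hom]) / 2.0
    a1 = (means[het] - means[hom]) / 2.0
    return Effects(seg_type=st, mu=mu, a1=a1)


def likelihood_ratio(null: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """LR statistic, degrees of freedom and chi-square p-value.

    LR = 2·(ℓ_full − ℓ_null) = n·ln(RSS₀/RSS₁); df = observed classes − 1.
    Both fits must have been computed on the identical individual subset.
    """
    if null.individual_index != full.individual_index:
        raise ValueError(
            "null and full fits were computed on different individual subsets"
        )
    lr = max(0.0, full.n * math.log(null.rss / full.rss))
    df = full.n_classes - 1
    if df == 0:  # full model adds no parameters; nothing to test
        return lr, 0, 1.0 if lr <= 0.0 else 0.0
    p = float(stats.chi2.sf(lr, df))
    return lr, df, p


def variance_explained(null: ModelFit, full: ModelFit) -> float:
    """Proportion of phenotypic variance explained: R² = 1 − RSS₁/RSS₀."""
    if null.individual_index != full.individual_index:
        raise ValueError(
            "null and full fits were computed on different individual subsets"
        )
    if null.rss <= 0:
        raise DegenerateFitError("null RSS is zero; R² undefined")
    return min(1.0, max(0.0, 1.0 - full.rss / null.rss))


def dominance_ratio(effects: Effects) -> float | None:
    """Dominance-to-additive ratio d/a; None for testcross types.

    For abxcd, where two additive effects exist, the denominator is the mean
    of |a1| and |a2|.  |d/a| > 1 indicates overdominance.
    """
    if effects.d is None:
        return None
    denom = (
        abs(effects.a1)
        if effects.a2 is None
        else (abs(effects.a1) + abs(effects.a2)) / 2.0
    )
    if denom == 0.0:
        warnings.warn(
            "additive effect is zero; dominance ratio reported as infinite",
            stacklevel=2,
        )
        return math.inf if effects.d > 0 else (-math.inf if effects.d < 0 else 0.0)
    return effects.d / denom
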