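"""Synthetic full-sib F1 families with known, planted QTLs.

The generator emulates the statistical structure the single-marker scan
assumes: two phased heterozygous parents, gametes produced by a Markov
crossover process whose adjacent-interval recombination fractions come from
the inverse Kosambi map function r = ½·tanh(2d) (d in Morgans), the four CP
marker types in a configurable mix, genotypic values added at designated
QTL markers, and i.i.d. Gaussian residual noise.  Defaults mirror the mei
mapping family: 190 progeny, eight linkage groups totalling 670 cM at 5-cM
mean marker spacing, with the marker-type mix in the observed proportions
(~7% multiallelic intercross, ~26% biallelic intercross, the rest testcross
split evenly between the two orientations).

Crossover interference beyond the adjacent-interval recombination fraction
is not modelled; a single-marker scan is only sensitive to pairwise
marker–QTL recombination, for which the Markov process is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import effects_to_class_means, genotypic_value
from .types import Effects, GenotypeMatrix, LinkageMap, Marker, SegType

__all__ = [
    "QTLSpec",
    "SimulationConfig",
    "ParentalHaplotypes",
    "SimTruth",
    "SimulatedFamily",
    "kosambi_r",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_family",
    "simulate_phenotypes",
    "simulate_study",
    "expected_qtl_variance",
]

#: parental allele pairs (parent P, parent Q) per cross type
_PARENT_ALLELES: dict[SegType, tuple[tuple[str, str], tuple[str, str]]] = {
    SegType.ABXCD: (("a", "b"), ("c", "d")),
    SegType.HKXHK: (("h", "k"), ("h", "k")),
    SegType.LMXLL: (("l", "m"), ("l", "l")),
    SegType.NNXNP: (("n", "n"), ("n", "p")),
}

_DEFAULT_MIX: dict[SegType, float] = {
    SegType.ABXCD: 0.07,
    SegType.HKXHK: 0.26,
    SegType.LMXLL: 0.335,
    SegType.NNXNP: 0.335,
}


def kosambi_r(distance_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance via the inverse Kosambi
    function, r = ½·tanh(2d) with d in Morgans; r ∈ [0, ½)."""
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(distance_cm) else r


@dataclass(frozen=True)
class QTLSpec:
    """A QTL planted at a marker for one trait, with its genetic effects."""

    marker: str
    trait: str
    effects: Effects


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated full-sib family."""

    n_progeny: int = 190
    n_groups: int = 8
    group_lengths_cm: Sequence[float] | None = None  # default: 670/8 each
    marker_spacing_cm: float = 5.0
    seg_type_mix: Mapping[SegType, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    qtls: Sequence[QTLSpec] = ()
    #: per-trait residual SD; ignored for traits listed in ``target_r2``
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    #: per-trait total variance fraction the planted QTLs should explain;
    #: the residual variance is solved from the expected genetic variance
    target_r2: Mapping[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    orthogonal_dominance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_lengths_cm is None:
            self.group_lengths_cm = [670.0 / self.n_groups] * self.n_groups
        if len(self.group_lengths_cm) != self.n_groups:
            raise ValueError("group_lengths_cm must have n_groups entries")
        if any(l <= 0 for l in self.group_lengths_cm):
            raise ValueError("group lengths must be positive")
        total = sum(self.seg_type_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"seg_type_mix must sum to 1, got {total}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for q in self.qtls:
            if not 0.0 < self.target_r2.get(q.trait, 0.5) < 1.0:
                raise ValueError(
                    f"target R² for trait {q.trait!r} must lie in (0, 1)"
                )

    @property
    def traits(self) -> list[str]:
        seen: list[str] = []
        for q in self.qtls:
            if q.trait not in seen:
                seen.append(q.trait)
        for t in list(self.residual_sd) + list(self.target_r2):
            if t not in seen:
                seen.append(t)
        return seen


@dataclass
class ParentalHaplotypes:
    """Phased two-haplotype allele sequences for both parents.

    ``p`` and ``q`` map linkage group → (2, n_markers) allele array, rows
    being the two homologs, columns following the map's marker order.
    """

    p: dict[int, np.ndarray]
    q: dict[int, np.ndarray]


@dataclass
class SimTruth:
    """What the simulator knows that the scan does not."""

    parents: ParentalHaplotypes
    #: inherited allele identity per marker × individual, e.g. ("a", "d")
    p_alleles: pd.DataFrame
    q_alleles: pd.DataFrame
    qtls: tuple[QTLSpec, ...]
    #: residual SD actually used per trait
    residual_sd: dict[str, float]


@dataclass
class SimulatedFamily:
    map: LinkageMap
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth


def _marker_name(group: int, idx: int) -> str:
    return f"M{group:02d}_{idx:03d}"


def simulate_parents(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[LinkageMap, ParentalHaplotypes]:
    """Lay out the map and draw phased parental haplotypes.

    Markers are placed at the configured spacing along each group; each
    marker's cross type is drawn from ``seg_type_mix`` (markers named by a
    planted QTL are forced to that QTL's cross type so its effects are
    estimable there).  Within each parent the two alleles are assigned to
    homologs at random per marker, giving random linkage phase.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    qtl_types = {q.marker: q.effects.seg_type for q in config.qtls}
    types = list(config.seg_type_mix)
    probs = np.array([config.seg_type_mix[t] for t in types], dtype=float)
    markers: list[Marker] = []
    for g, length in enumerate(config.group_lengths_cm, start=1):
        n_even = int(math.floor(length / config.marker_spacing_cm)) + 1
        positions = [i * config.marker_spacing_cm for i in range(n_even)]
        if positions[-1] < length - 1e-9:  # terminal marker at the group end
            positions.append(float(length))
        for i, pos in enumerate(positions):
            name = _marker_name(g, i)
            st = qtl_types.get(name, types[rng.choice(len(types), p=probs)])
            markers.append(
                Marker(
                    name=name, seg_type=st, linkage_group=g, position_cm=pos
                )
            )
    lmap = LinkageMap(markers)
    unknown = set(qtl_types) - {m.name for m in lmap}
    if unknown:
        raise ValueError(f"planted QTL markers not on the map: {sorted(unknown)}")
    hap_p: dict[int, np.ndarray] = {}
    hap_q: dict[int, np.ndarray] = {}
    for g, ms in lmap.groups.items():
        p = np.empty((2, len(ms)), dtype=object)
        q = np.empty((2, len(ms)), dtype=object)
        for j, m in enumerate(ms):
            pa, qa = _PARENT_ALLELES[m.seg_type]
            flip_p, flip_q = rng.integers(0, 2, size=2)
            p[:, j] = (pa[flip_p], pa[1 - flip_p])
            q[:, j] = (qa[flip_q], qa[1 - flip_q])
        hap_p[g] = p
        hap_q[g] = q
    return lmap, ParentalHaplotypes(p=hap_p, q=hap_q)


def _gametes(
    haps: np.ndarray, r: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n gametes from one parent's (2, m) phased group.

    Returns (alleles (n, m) object array, haplotype index (n, m)).  The
    crossover process is Markov: the transmitted homolog starts uniformly
    and switches between adjacent markers with probability r_j.
    """
    m = haps.shape[1]
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switches = (rng.random((n, m - 1)) < r).astype(int)
        hap_idx = (start[:, None] + np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        hap_idx = start[:, None]
    return haps[hap_idx, np.arange(m)[None, :]], hap_idx


def simulate_meiosis(
    haplotypes: dict[int, np.ndarray],
    linkage_map: LinkageMap,
    rng: np.random.Generator,
) -> dict[str, str]:
    """One gamete from a phased parent: marker name → transmitted allele."""
    out: dict[str, str] = {}
    for g, ms in linkage_map.groups.items():
        pos = np.array([m.position_cm for m in ms])
        r = kosambi_r(np.diff(pos))
        alleles, _ = _gametes(haplotypes[g], r, 1, rng)
        out.update({m.name: alleles[0, j] for j, m in enumerate(ms)})
    return out


def _class_label(seg_type: SegType, p_allele: str, q_allele: str) -> str:
    if seg_type is SegType.ABXCD:
        return p_allele + q_allele
    return "".join(sorted((p_allele, q_allele)))


def simulate_family(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[LinkageMap, GenotypeMatrix, SimTruth]:
    """Simulate the map, parents and full progeny genotype matrix.

    Each progeny receives one gamete from each parent; the unordered allele
    pair is collapsed to the CP class label (an hk×hk offspring carrying
    h/k is recorded as "hk" regardless of parental origin).  The truth
    record keeps the ordered (P-allele, Q-allele) identities.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lmap, parents = simulate_parents(config, rng)
    individuals = [f"ind{i + 1:04d}" for i in range(config.n_progeny)]
    marker_names = lmap.marker_names
    p_all = pd.DataFrame(index=marker_names, columns=individuals, dtype=object)
    q_all = pd.DataFrame(index=marker_names, columns=individuals, dtype=object)
    calls = pd.DataFrame(index=marker_names, columns=individuals, dtype=object)
    for g, ms in lmap.groups.items():
        pos = np.array([m.position_cm for m in ms])
        r = kosambi_r(np.diff(pos))
        pg, _ = _gametes(parents.p[g], r, config.n_progeny, rng)
        qg, _ = _gametes(parents.q[g], r, config.n_progeny, rng)
        for j, m in enumerate(ms):
            p_all.loc[m.name] = pg[:, j]
            q_all.loc[m.name] = qg[:, j]
            calls.loc[m.name] = [
                _class_label(m.seg_type, pa, qa)
                for pa, qa in zip(pg[:, j], qg[:, j])
            ]
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(mask, other=None)
    genotypes = GenotypeMatrix(calls, lmap)
    truth = SimTruth(
        parents=parents,
        p_alleles=p_all,
        q_alleles=q_all,
        qtls=tuple(config.qtls),
        residual_sd={},
    )
    return lmap, genotypes, truth


def expected_qtl_variance(
    effects: Effects, *, orthogonal_dominance: bool = False
) -> float:
    """Genetic variance of a QTL's genotypic values under Mendelian class
    frequencies (¼:¼:¼:¼, ¼:½:¼ or ½:½).  Expected scan R² is
    Vg / (Vg + σ²)."""
    freqs = effects.seg_type.class_frequencies
    means = effects_to_class_means(
        effects, orthogonal_dominance=orthogonal_dominance
    )
    mean = sum(freqs[c] * means[c] for c in freqs)
    return float(sum(freqs[c] * (means[c] - mean) ** 2 for c in freqs))


def _solve_residual_sd(config: SimulationConfig, trait: str) -> float:
    if trait in config.target_r2:
        r2 = config.target_r2[trait]
        if not 0.0 < r2 < 1.0:
            raise ValueError(f"target R² for {trait!r} must lie in (0, 1)")
        vg = sum(
            expected_qtl_variance(
                q.effects, orthogonal_dominance=config.orthogonal_dominance
            )
            for q in config.qtls
            if q.trait == trait
        )
        if vg == 0.0:
            raise ValueError(
                f"trait {trait!r} has a target R² but no planted QTL variance"
            )
        return math.sqrt(vg * (1.0 - r2) / r2)
    return float(config.residual_sd.get(trait, 1.0))


def simulate_phenotypes(
    truth_classes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    residual_out: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Phenotypes from true genotype classes: Σ genotypic values + N(0, σ²).

    ``truth_classes`` must be the complete (no-missing) class matrix so the
    genetic values are exact even when observed calls are masked.  With a
    per-trait ``target_r2`` the residual SD is solved from the planted
    QTLs' expected genetic variance.
    """
    individuals = list(truth_classes.columns)
    out = pd.DataFrame(index=pd.Index(individuals, name="id"), dtype=float)
    for trait in config.traits:
        sd = _solve_residual_sd(config, trait)
        if residual_out is not None:
            residual_out[trait] = sd
        y = np.zeros(len(individuals))
        for q in (q for q in config.qtls if q.trait == trait):
            classes = truth_classes.loc[q.marker]
            y += np.array(
                [
                    genotypic_value(
                        q.effects,
                        c,
                        orthogonal_dominance=config.orthogonal_dominance,
                    )
                    for c in classes
                ]
            )
        out[trait] = y + rng.normal(0.0, sd, size=len(individuals))
    return out


def simulate_study(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedFamily:
    """End-to-end simulation: map, genotypes, phenotypes and truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lmap, genotypes, truth = simulate_family(config, rng)
    # phenotypes are driven by the true classes, pre-masking
    if config.missing_rate == 0.0:
        true_calls = genotypes.calls
    else:
        true_calls = pd.DataFrame(
            {
                ind: [
                    _class_label(
                        lmap.marker(m).seg_type,
                        truth.p_alleles.at[m, ind],
                        truth.q_alleles.at[m, ind],
                    )
                    for m in lmap.marker_names
                ]
                for ind in genotypes.individuals
            },
            index=lmap.marker_names,
        )
    residual: dict[str, float] = {}
    phenotypes = simulate_phenotypes(
        true_calls, config, rng, residual_out=residual
    )
    truth.residual_sd = residual
    return SimulatedFamily(
        map=lmap, genotypes=genotypes, phenotypes=phenotypes, truth=truth
    )
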