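# Methods

## The mapping design and the per-marker model

`fsqtl` analyzes a single full-sib F1 family from two outbred parents (a
CP population).  Because each parent may be heterozygous or homozygous
locus by locus, markers fall into four segregation types — multiallelic
intercross (ab×cd), biallelic intercross (hk×hk) and the two testcross
orientations (lm×ll, nn×np) — producing four, three, two and two
distinguishable progeny genotypes respectively.  The scan is single-marker:
each marker's genotype classes are associated directly with the phenotype,
with no interval model between markers.  This is appropriate for a dense
map (~5 cM spacing), where a QTL is rarely far from the nearest marker; the
cost is that linked markers flanking one causal locus all show signal, so
significant markers arrive in runs (an optional `collapse_peaks` mode keeps
the maximum-LR marker per contiguous significant run).

At a marker with classes g = 1..k the phenotype is modelled as
y ~ N(μ_g, σ²), common σ².  The MLEs are the per-class arithmetic means
and σ̂² = RSS/n (the ML, not the unbiased, variance — chosen to match the
likelihood framing; the LR below is identical either way).  Against the
one-mean null, LR = 2(ℓ₁ − ℓ₀) = n·ln(RSS₀/RSS₁), referred to a chi-square
with k − 1 degrees of freedom, which equals the number of genetic effect
parameters the cross type supports (1, 2 or 3).  The variance explained is
R² = 1 − RSS₁/RSS₀, algebraically identical to 1 − exp(−LR/n); the test
suite asserts this identity to 1e-12.  The null fit is recomputed on
exactly the individuals usable at each marker (non-missing genotype and
phenotype), so the compared models are always nested on identical data.

## Effect decomposition

Multiallelic intercross (classes ac, ad, bc, bd mapped to parental allele
combinations P1Q1, P1Q2, P2Q1, P2Q2):

    μ11 = μ + a1 + a2 + d      μ12 = μ + a1 − a2 − d
    μ21 = μ − a1 + a2 − d      μ22 = μ − a1 − a2 − d

a₁ and a₂ are the additive effects contributed by parents P and Q, d the
dominance interaction.  This 4×4 system is nonsingular, so all four
parameters are identified, but it is not orthogonal: its d equals twice
the textbook orthogonal dominance contrast (μ11 − μ12 − μ21 + μ22)/4.
`orthogonal_dominance=True` switches the fourth equation to
μ22 = μ − a1 − a2 + d, under which the solution reduces to the usual
orthogonal contrasts.  The default is the non-orthogonal form, with the
orthogonal variant one flag away, because which parameterization produced
any given published d cannot generally be determined from a table alone.

Biallelic intercross: μ_hh = μ + a, μ_hk = μ + d, μ_kk = μ − a (this form
is already orthogonal-in-effect; the flag does not change it).  Testcross:
μ_het = μ + a, μ_hom = μ − a.  Decomposition requires every legal class to
be observed; otherwise the marker is reported unusable.  Sign conventions:
a₁ flips if the parental allele labels swap, so tests against simulated
truth use the simulator's fixed label assignment (P carries a/b, h/k, l/m
or n/n; Q carries c/d, h/k, l/l or n/p).

The dominance ratio d/a flags gene action (|d/a| > 1 = overdominance).
For the four-class type, where two additive effects exist, the denominator
is the mean of |a₁| and |a₂| — a documented convention, since no standard
definition exists there.

## Genome-wide significance

Per trait, Benjamini–Hochberg FDR is applied to the per-marker chi-square
p-values at q = 0.05 (ties kept at the boundary rank, the standard BH
step-up).  The plotted "genome-wide threshold" of an LR profile is
operationalized as the minimum LR among BH-rejected markers — with
monotone p↦LR within a df class this is the exact rejection boundary, and
across mixed df classes it is the natural single horizontal line.  BH is
applied across all markers of one trait's scan (one threshold per trait);
markers are heavily positively correlated through linkage, a dependence
regime in which BH remains conservative in practice — the acceptance suite
measures the empirical FDR of 500 null scans at ≈ 0.04–0.05.

## Derived traits

Leaf traits (length LL, width LW, area LA, petiole length PET, vein count
VN) are scored on up to three leaves per seedling and averaged over the
available non-missing replicates (requiring all three would discard usable
seedlings; the analysis is silent to which convention produced any given
published mean).  Derived ratios, computed from the replicate-averaged
columns (ratio of averages):

* `stem_taper` = DIA/HT — stem slenderness, in mm/cm as measured (QTL
  inference is invariant to a constant unit factor within a trait, so no
  conversion is applied);
* `leaf_shape` = LW/LL (dimensionless);
* `vein_density` = VN/LA (veins per cm²).

Non-positive denominators yield missing values with a logged warning.

## The simulator

The generator reproduces the statistical structure the scan assumes, with
defaults set to the mei study design: 190 progeny, 8 linkage groups of
equal length summing to 670 cM, markers every 5 cM (plus a terminal marker
at each group end, giving 17–18 per group), and a cross-type mix of 7%
ab×cd, 26% hk×hk and 67% testcross split evenly between orientations —
the proportions of the study's marker panel.

Parents are phased by assigning each marker's two alleles to homologs at
random.  A gamete per group starts on a uniformly chosen homolog and
switches between adjacent markers with probability r = ½·tanh(2d), the
inverse Kosambi map function of the adjacent interval (d in Morgans).
This Markov process matches Kosambi pairwise recombination fractions for
adjacent intervals only; true Kosambi crossover interference is not
modelled, which is immaterial to a single-marker scan since only pairwise
marker–QTL recombination enters its expectations.  Progeny classes are the
unordered union of inherited alleles collapsed to the CP label; the truth
record retains the ordered (P-allele, Q-allele) identities.

QTLs are planted at markers (off-marker QTLs would only attenuate effects
through recombination; the single-marker analysis has no position model to
exploit them).  Phenotypes are the sum of planted genotypic values plus
i.i.d. Gaussian noise; heavy-tailed or heteroscedastic noise is out of
scope.  Given a target R², the residual SD is solved from the QTLs'
exact Mendelian genetic variance: Vg = Var over class frequencies
(¼:¼:¼:¼, ¼:½:¼ or ½:½) of the genotypic values, σ² = Vg(1 − R²)/R².
All randomness flows through one seeded numpy Generator; equal seeds give
byte-identical output files.

What passing simulator-backed tests show — and what they do not: the
generator draws phenotypes from exactly the model the scan fits, so these
tests validate correctness and calibration of the machinery, not
robustness to the features of real field data it does not emulate
(non-normal residuals, segregation distortion, genotyping error,
shared environment, multi-QTL linkage on one group).

## Numerical and design choices

* Residual variance below 1e-300 raises a degenerate-fit error (the
  likelihood is unbounded); LR is floored at 0 against floating-point
  cancellation.
* `min_class_n` (default 5) flags markers with any observed class thinner
  than 5 individuals as unusable — group means with fewer observations
  make effect estimates erratic.  An entirely unobserved legal class
  leaves the fit valid (df = observed − 1) but blocks effect
  decomposition, so scans omit such markers too.
* Chi-square df = classes − 1 is a design decision (it matches the
  number of estimable effects per cross type); it is not forced by the
  single-marker likelihood itself, which is why it is documented here.
* Missing genotype tokens `--` and `.` are both accepted and normalized
  to one internal missing value.
* Map positions are cumulative cM within a group with arbitrary offset;
  only differences enter any computation.
* The packaged reference QTL table is transcribed as printed, including
  one 3-genotype row with no dominance estimate; its two internal
  inconsistencies (the overdominant diameter QTL's group, and a vein-count
  joint R² that sums to 0.25 against a narrative 20%) are preserved, not
  corrected — summaries report what the table implies.

## Problem sizes used in the test and acceptance runs

Chosen as the smallest sizes at which each check is statistically sharp:
segregation laws and recombination at 10,000 progeny/gametes (3-SE
binomial bands); null FDR over 500 families of 100 progeny × 50 markers;
effect recovery over 500 families of 190 progeny (the study's family
size); detection power over 200 replicates per planted R² on a two-group
map; localization over 200 replicates on the full default map, where the
maximum-LR marker falls within one marker of the planted QTL in ~94% of
replicates (the test asserts a conservative 90% floor).

## Known limitations

Single-marker association only: no interval mapping, no multi-QTL or
epistasis models, no permutation thresholds.  One family, two parents; no
multi-generation pedigrees.  The ef×eg CP type is not supported (absent
from the motivating panel).  Linked significant markers are reported as
separate records; `collapse_peaks` is a heuristic, not a QTL-position
estimator.
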