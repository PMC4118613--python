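"""Fit one marker by hand and decompose its genetic effects.

Shows the cross-type-aware model directly: a multiallelic intercross
(ab×cd) marker has four progeny classes, so two parent-specific additive
effects and a dominance effect are estimable from the four class means.
"""

import numpy as np

from fsqtl import (
    Marker,
    SegType,
    decompose_effects,
    fit_marker,
    fit_null,
    likelihood_ratio,
    variance_explained,
)

rng = np.random.default_rng(0)
marker = Marker("demo", SegType.ABXCD, linkage_group=1, position_cm=0.0)

# 40 progeny per class; true class means 4 / 2 / 1 / 0 plus unit noise
truth = {"ac": 4.0, "ad": 2.0, "bc": 1.0, "bd": 0.0}
calls = [c for c in truth for _ in range(40)]
y = np.array([truth[c] for c in calls]) + rng.normal(0, 1, len(calls))

full = fit_marker(marker, calls, y)
null = fit_null(y, index=full.individual_index)

lr, df, p = likelihood_ratio(null, full)
effects = decompose_effects(full)
print(f"class means: { {k: round(v, 2) for k, v in full.class_means.items()} }")
print(f"LR = {lr:.1f} on df={df}, p = {p:.2e}, "
      f"R2 = {variance_explained(null, full):.3f}")
print(f"mu = {effects.mu:+.2f}  a1 = {effects.a1:+.2f}  "
      f"a2 = {effects.a2:+.2f}  d = {effects.d:+.2f}")
# With true means (4, 2, 1, 0) the genotypic-value equations give
# (mu, a1, a2, d) = (2, 1, 0.5, 0.5); estimates land near these values and
# the chi-square(3) test is overwhelmingly significant.
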