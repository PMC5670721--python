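"""Pair coefficients, their induced gene coefficients, and peeling.

Builds the three-gene worked example, maps the pair coefficients to the
sum-to-zero gene coefficients, and peels the gene coefficients back into a
minimum-L1 pair set.
"""

import numpy as np

from pairzero import (
    PairCoefficients,
    beta_from_alpha,
    is_minimum_l1,
    peel,
    support_counts,
)

# two gene pairs: alpha_12 = 3, alpha_23 = -2 (0-based indices internally)
alpha = PairCoefficients(p=3, entries={(0, 1): 3.0, (1, 2): -2.0})
beta = beta_from_alpha(alpha)
print("pair coefficients:", dict(alpha.entries))
print("induced gene coefficients:", beta.values, "(sum:", beta.values.sum(), ")")
# beta = (3, -5, 2): gene 2 appears in both pairs, so its coefficient pools both.

recovered, trace = peel(beta)
print("peeled pairs:", dict(recovered.entries), "in", trace.iterations, "steps")
print("L1 norms: alpha", recovered.l1, "= beta/2 =", beta.l1 / 2)
# Peeling pairs the most positive with the most negative coefficient each
# step; the resulting pair set attains the smallest possible L1 norm.

flag, witness = is_minimum_l1(recovered)
print("minimum-L1 representation:", flag)
report = support_counts(recovered)
print(f"support counts: {report.n_pairs} pairs / {report.n_genes} active genes")
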