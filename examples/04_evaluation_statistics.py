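"""The evaluation statistics on their own: exact CIs, F-measure, kappa.

These are the same operations the evaluation report uses internally; here
they run on published-style counts so the arithmetic is easy to follow.
"""

from hfquality import (
    ConfusionCounts,
    clopper_pearson_ci,
    cohens_kappa,
    f_measure,
    percent_agreement,
    sensitivity,
)

# 469 of 474 patient classifications in agreement with an external review:
result = sensitivity(ConfusionCounts(tp=469, fp=0, tn=0, fn=5))
print(f"sensitivity: {result.display(2)}  (n={result.n})")

low, high = clopper_pearson_ci(469, 474)
print(f"exact 95% CI for 469/474: ({low:.2f}, {high:.2f})")

# F-measure from a sensitivity/PPV pair (percent scale):
print(f"F-measure of (98.9, 98.7): {f_measure(98.9, 98.7):.1f}")

# Cohen's kappa for a 2x2 concordance table [[20, 5], [10, 65]]:
a = [1] * 25 + [0] * 75
b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 65
print(f"kappa for the worked 2x2 table: {cohens_kappa(a, b):.3f}")
print(f"percent agreement for the same table: {percent_agreement(a, b):.1f}%")
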