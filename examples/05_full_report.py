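"""The orchestrated analysis: descriptives plus the triangular matrix.

Runs every univariate and pairwise bivariate fit for a subset of traits and
prints the conventional display — heritabilities on the diagonal, genetic
correlations above, phenotypic correlations below, each as value (SE).
At n = 147 the genetic-parameter SEs are large and some genetic variances
hit the zero boundary; those cells carry status flags instead of numbers.
"""

from apisqg import run_full_analysis

res = run_full_analysis({"seed": 1, "traits": ["bw", "tw", "aw", "sd", "sv"]})

print("h2 diagonal / r_g above / r_p below, value (SE):")
print(res.matrix.to_frame().to_string())
print("\nPer-cell status flags:")
for line in res.log:
    if line.startswith(("univariate", "bivariate")):
        print(" ", line)
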