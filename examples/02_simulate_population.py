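"""Generate the default two-season synthetic breeding population.

Reproduces the study structure — 147 phenotyped queens (70 + 77) in 17
maternal lines over two seasons, 15 week-of-year classes, 12-drone matings —
and prints descriptive statistics of the 12 simulated traits, which should
track the published means, SDs and CVs (spermatheca volume is derived from
the diameter by the sphere formula, not simulated independently).
"""

from apisqg import (
    BreedingDesign, compute_kinship, default_trait_model, defect_prevalence,
    generate_pedigree, inject_defect_flags, simulate_phenotypes, summarize,
)
from apisqg.report import descriptives_frame

design = BreedingDesign()  # the study defaults
ped = generate_pedigree(design, seed=42)
A = compute_kinship(ped)
pheno = simulate_phenotypes(ped, A, default_trait_model(), design, seed=43)
pheno = inject_defect_flags(pheno, seed=44)

print(f"{len(pheno)} phenotyped queens; per year:")
print(pheno["year"].value_counts().to_string())
print("\nDescriptives (compare with the published table):")
print(descriptives_frame(summarize(pheno)).to_string(index=False))
print("\nInternal defect prevalences (%):")
for name, pct in defect_prevalence(pheno).items():
    print(f"  {name:26s} {pct:5.1f}")
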