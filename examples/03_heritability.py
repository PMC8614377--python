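"""Estimate a heritability with the univariate REML animal model.

Simulates one population with a known true heritability (0.54, the
published body-weight estimate), fits y = mu + week + a + e with
Var(a) = sigma2_a A, and prints the estimate with its delta-method SE.
A single population of 500 queens carries limited information (SE ~ 0.1),
which is why recovery studies average over replicates.
"""

from apisqg import (
    compute_kinship, fit_univariate, generate_pedigree, heritability,
    recovery_design, simulate_phenotypes, single_trait_model,
)

design = recovery_design()  # 25 lines x 20 queens, 15 weeks, 12 DPQs, 12 drones
ped = generate_pedigree(design, seed=7)
A = compute_kinship(ped)
model = single_trait_model("bw", mean=195.9, sd=19.84, h2=0.54)
pheno = simulate_phenotypes(ped, A, model, design, seed=8)

fit = fit_univariate(pheno, A, "bw")
h2, se = heritability(fit)
print(f"n = {fit.n_used} queens, {fit.n_fixed} fixed-effect parameters")
print(f"sigma2_a = {fit.sigma2_a:8.2f}   sigma2_e = {fit.sigma2_e:8.2f}")
print(f"h2 = {h2:.3f} +- {se:.3f}   (true value 0.54)")
print(f"restricted logL = {fit.loglik:.3f}, converged = {fit.converged}")
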