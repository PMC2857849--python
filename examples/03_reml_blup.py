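"""Fit the animal model at each time point and predict breeding values.

For one relationship matrix, EM-REML estimates the additive and residual
variances per time point (the model is y = mu + a + e with var(a) = G
sigma2_a), then Henderson's mixed model equations return breeding values for
every animal — including the masked validation animals, which get theirs
purely through their relationships with phenotyped relatives.
"""

import snpblup as sb

pop = sb.simulate_population(sb.SimulationConfig(
    n_founders=12, n_generations=3, offspring_per_mating=6,
    n_chromosomes=3, snps_per_chromosome=40, n_qtl=12,
    n_validation_unphenotyped=108, seed=11,
))
A = sb.additive_relationship(pop.pedigree)

varcomp, ebv = sb.run_animal_model(pop.phenotypes, A)
print("variance components per time point (pedigree matrix):")
print(varcomp[["time", "sigma2_a", "sigma2_e", "h2", "n_iter", "converged"]]
      .round(3).to_string(index=False))
print("\nBoth variances grow with time, the pattern the generator builds")
print("in.  With only 48 phenotyped animals the h2 estimates are noisy;")
print("they tighten around the simulated 0.5 at larger sample sizes.")

masked = pop.masked_ids[:3]
print(f"\nEBVs of three validation animals (no phenotypes of their own):")
print(ebv.loc[masked].round(3).to_string())
print("\nTheir values are parent averages under the pedigree matrix —")
print("full sibs are indistinguishable until marker data enters.")
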