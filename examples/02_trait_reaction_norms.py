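"""Univariate reaction norms: the mixed-model species x site test.

Each trait is modelled as species + site + species:site fixed effects
with genotype-by-site and block random intercepts.  A significant
species x site interaction means the two species change their phenotype
differently across elevation — i.e. they differ in plasticity.
"""

from plastivec import synthdata, traits

design = synthdata.SimulationDesign(n_genotypes_per_species=15, seed=2)
table = synthdata.simulate_traits(design)

trait_names = sorted(table["trait"].unique())
print(f"{'trait':18s} {'chi2(3)':>9s} {'adj. p':>10s}  interaction?")
for name in trait_names:
    fit = traits.fit_trait_model(table, name, n_tests=len(trait_names))
    verdict = "yes" if fit.p_adjusted < 0.05 else "no"
    print(f"{name:18s} {fit.lrt_chi2:9.2f} {fit.p_adjusted:10.2e}  {verdict}")
print("^ likelihood-ratio tests of the species x site interaction, "
      "p multiplied by the number of traits (Bonferroni-style)")

fit = traits.fit_trait_model(table, "sla")
pairs = traits.pairwise_site_tests(fit)
letters = pairs.attrs["letters"]
print("\nSLA site groupings (sites sharing a letter do not differ):")
print(letters.pivot(index="species", columns="site", values="letters"))
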