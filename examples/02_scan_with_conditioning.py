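"""igeGWAS with and without conditioning on the direct genotype.

Plants a purely DIRECT effect (no social effect at all) at one variant
and tests that variant's social genotype both ways, over 25 phenotype
replicates. Because each mouse is both focal individual and cage mate,
the social genotype is (within cages) collinear with the direct
genotype, and the unconditioned social test picks up the direct effect;
conditioning removes it.
"""

import numpy as np

import socialgwas as sg

n = 600
rng = np.random.default_rng(3)
genotypes = sg.simulate_genotypes(n, 400, (0.1, 0.5), rng)
cages = sg.CageStructure.random(n, 3, rng)
A = sg.compute_grm(genotypes)
spec = sg.SimulationSpec(n_individuals=n, n_variants=400)
X = np.ones((n, 1))
causal = 200
one_variant = genotypes.subset_variants([causal])

nlp = {True: [], False: []}
for rep in range(25):
    y, realised = sg.simulate_phenotype(spec, genotypes, cages, A=A, rng=rng)
    g = genotypes.dosages[:, causal]
    y = y + np.sqrt(0.20 / 0.80 * realised["sv_C"] / np.var(g)) * g
    fit = sg.fit_varcomp(y, X, A, cages, n_restarts=0)
    for condition in (True, False):
        table = sg.scan(y, X, A, cages, one_variant, mode="ige", fit=fit,
                        condition=condition)
        nlp[condition].append(table.df["neg_log10_p"].iloc[0])

for condition in (True, False):
    vals = np.array(nlp[condition])
    label = "with conditioning   " if condition else "without conditioning"
    print(f"igeGWAS {label}: mean -log10 P at the DGE variant = "
          f"{vals.mean():.2f}  (share above 3.0: {(vals >= 3).mean():.2f})")

# The variant has no social effect. Under the null, mean -log10 P is
# ~0.43 and values above 3 occur once per thousand tests: the
# conditioned column should look like that, while the unconditioned test
# reports spurious social associations driven by the direct effect.
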