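"""Hierarchical population structure from SNP genotypes.

Simulates two species spread over three populations each under the nested
Balding-Nichols island model, then decomposes the molecular variance and
estimates pairwise F_ST.  The printed Φ_CT should sit near the simulated
between-species differentiation (0.30), with between-species pairwise
Φ_ST an order of magnitude above the within-species values.
"""

import numpy as np

from skyisland import popgen, synthdata

spec = synthdata.SimGenotypeSpec(
    n_groups=2, pops_per_group=3, inds_per_pop=20, n_loci=2000,
    fct_target=0.30, fsc_target=0.02, seed=1,
)
g = synthdata.simulate_hierarchical_genotypes(spec)
print(f"simulated {g.n_individuals} diploids x {g.n_loci} SNPs "
      f"({len(g.groups)} species, {len(g.populations)} populations)")

stats = popgen.locus_statistics(g)
print(f"mean He = {stats.he.mean():.4f}, mean Ho = {stats.ho.mean():.4f}, "
      f"loci out of HWE at 5%: {(stats.hwe_p < 0.05).mean():.2%}")

res = popgen.amova(g, "groups/pops", n_permutations=999, seed=1)
print("\nhierarchical AMOVA:")
print(res.to_frame().to_string(index=False))
print(f"Phi_CT = {res.phi_ct:.4f} (p = {res.p_values['phi_ct']:.4f}), "
      f"Phi_SC = {res.phi_sc:.4f}, Phi_ST = {res.phi_st:.4f}")

fst = popgen.pairwise_phi_st(g, n_permutations=0)
pops = np.asarray(fst.populations)
between = [fst.fst[i, j] for i in range(6) for j in range(i + 1, 6)
           if pops[i][:2] != pops[j][:2]]
within = [fst.fst[i, j] for i in range(6) for j in range(i + 1, 6)
          if pops[i][:2] == pops[j][:2]]
print(f"\npairwise Phi_ST: between species {np.mean(between):.3f}, "
      f"within species {np.mean(within):.3f}")
print("most variance lies between species and within populations — the "
      "signature of two well-differentiated montane species.")
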