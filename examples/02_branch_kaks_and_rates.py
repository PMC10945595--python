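"""Per-branch dN/dS and absolute silent-site divergence rates.

Simulates a 4-taxon codon alignment, reconstructs ancestral sequences by
Fitch parsimony, estimates dS/dN/omega on every terminal branch, and
converts the mean dS into a per-site per-year rate via mu = dS / (2 T).
"""

import numpy as np

from matrisome.io import read_newick
from matrisome.kaks import branch_estimates, silent_rate
from matrisome.simulate import CodonSimSpec, simulate_codon_alignment

tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
spec = CodonSimSpec(tree=tree, omega=0.5, kappa=2.0, n_codons=400, seed=7)
aln, _ = simulate_codon_alignment(spec)

ests = branch_estimates(aln, tree)
print("terminal-branch estimates (tip vs reconstructed ancestor):")
for e in ests:
    print(f"  {e.id_a}: dS={e.dS:.4f}  dN={e.dN:.4f}  omega={e.omega:.3f}")

ds_mean = float(np.mean([e.dS for e in ests]))
rate = silent_rate(ds_mean, T_years=2.0e6, group_id="demo-clade")
print(f"mean terminal dS = {ds_mean:.4f}")
print(f"mu = dS/(2T) = {rate.mu:.3e} substitutions per silent site per year")
# with T = 2 Myr the rate lands in the 1e-8 range typical of plant
# nuclear genes; per-branch omega should scatter around the planted 0.5.
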