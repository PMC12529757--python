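# stresspath

Force-distribution analysis of allosteric signalling in proteins:
pairwise residue-force matrices, punctual-stress perturbation profiles,
and maximin (widest-path) pathway extraction — with an exactly-sampled
elastic-network ensemble generator that plants known allosteric pathways
for validation.

## The problem

When a cofactor or ligand binds a protein, the perturbation can travel far
from the binding site — in dimeric enzymes such as the human
sulfotransferase SULT1A1, all the way into the *other* subunit, a candidate
mechanism for half-site reactivity. Structural metrics (RMSD, RMSF,
loop-gate distances) show *where* flexibility changes; force-distribution
analysis shows *how the mechanical signal gets there*.

For each condition (apo, cofactor-bound, …) the mean pairwise force matrix
is

    F_ij = ⟨ −k_ij (|r_i − r_j| − r0_ij) ⟩  (pN, signed; + repulsive)

averaged over an ensemble. Two conditions are compared by
**ΔF = |F_A − F_B|**, and the per-residue **punctual stress**
S_i = Σ_j ΔF_ij localises residues that sense the perturbation. Pathways
are read off a graph weighted by ΔF: the **maximum connectivity cutoff** is
the largest force-change threshold at which the source region (e.g. the
cofactor site) still reaches the sink region (e.g. the dimer interface) —
exactly the maximin/widest-path bottleneck — and the surviving subgraph
yields ranked widest paths.

Because these signals are statistical, the package ships a synthetic
generator: elastic-network "proteins" (one or two chains) sampled *exactly*
from their equilibrium Gaussian N(x0, kT·H⁺), plus a planted perturbation
(a ligand node tethered to a binding site and a stiffened spring chain
crossing the dimer interface) whose pathway is ground truth. Every
statistical claim in the test suite is checked against the closed-form
elastic-network answer.

## Worked example

```python
import stresspath as sp
from stresspath.synthetic import default_plant_spec

structure = sp.make_toy_structure(32, n_chains=2, seed=0)
apo_net = sp.build_enm(structure)              # k=100 pN/Å, 8 Å cutoff
spec = default_plant_spec(32)                  # ligand site + stiffened chain
bound_net = sp.plant_perturbation(apo_net, spec)

apo = sp.sample_ensemble(apo_net, 10_000, seed=1)
bound = sp.sample_ensemble(bound_net, 10_000, seed=2)

fa, fb = sp.align_force_matrices(sp.mean_force_matrix(apo, apo_net),
                                 sp.mean_force_matrix(bound, bound_net))
dF = sp.force_difference(fa, fb)
stress = sp.punctual_stress(dF)
for v, (ch, rid) in sorted(((v, k) for k, v in stress.items()
                            if k[0] != "X"), reverse=True)[:5]:
    print(f"{ch}{rid:<3d} punctual stress {v:7.1f} pN")

g = sp.build_graph(dF, floor=0.0, source=spec.site_residues,
                   sink=[("B", 31)])
cutoff = sp.max_connectivity_cutoff(g)
path = sp.extract_pathways(g, cutoff, max_paths=1).paths[0]
print(f"maximin cutoff {cutoff:.1f} pN")
print("pathway " + " -> ".join(f"{c}{r}" for c, r in path))
```

prints

```
A30  punctual stress   146.8 pN
A31  punctual stress   140.0 pN
B32  punctual stress   130.7 pN
A32  punctual stress    92.4 pN
A29  punctual stress    78.3 pN
maximin cutoff 37.9 pN
pathway A30 -> A31 -> A32 -> B32 -> B31
```

The five highest-stress residues are the planted ligand site (A29, A30) and
the stiffened pathway into chain B; the extracted widest path runs from the
site across the designated interface bridge (A32–B32) into the second
subunit — the binding perturbation is "felt" across the dimer interface,
the signature the method is designed to detect. The 37.9 pN cutoff is the
strongest force-change threshold that still connects site to sink.

The same analysis runs from the shell:

```sh
stresspath compare --seed 1 --n-frames 2000 --out results/
```

writing per-condition RMSD/RMSF/gate tables, the force matrices, ΔF, the
stress profile (TSV and B-factor-coded PDB), the pathway graph (GraphML +
edge TSV), the ranked pathway report and a run manifest. Subcommands
`simulate`, `metrics`, `fda`, `stress`, `pathways`, `validate` expose the
individual stages; configs are TOML (see `stresspath.config`, which also
ships the canonical SULT1A1 gate/loop/region profile in 2D06 numbering:
gates L1-L2 = P87Cα–V148Cα, L1-L3 = P87Cα–F247Cα, cL3 = K197Cα–M260Cα).

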