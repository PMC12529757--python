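# Methods

## Scope and model

`stresspath` analyses how a binding perturbation propagates mechanically
through a protein, using the force-distribution picture: instead of asking
where *structure* changes, it asks where *pairwise forces between residues*
change. The pipeline has four stages.

1. **Pairwise forces.** The system is described by an explicit harmonic
   spring network over residue nodes. For a spring `(i, j)` with stiffness
   `k` (pN/Å) and rest length `r0` (Å), the signed scalar pairwise force at a
   conformation is `f_ij = −k (|r_i − r_j| − r0)`, positive repulsive,
   negative attractive. Multiple springs joining one residue pair (ligand
   tethers mapped to the ligand pseudo-residue) are summed. Averaging each
   pair over all frames of an ensemble gives the mean force matrix `F` of
   one condition. The signed-scalar, average-then-difference convention is
   the default; averaging per-frame absolute forces is available via a flag
   (`signed=False`) because the convention in published force-distribution
   tools is not uniquely fixed.
2. **Perturbation difference.** Two conditions A and B (e.g. apo vs
   cofactor-bound) are compared entrywise: `ΔF = |F_A − F_B|` ≥ 0. When the
   conditions differ in their residue sets (a ligand exists only in the
   bound form), both matrices are first padded onto the union index map with
   zeros (`align_force_matrices`).
3. **Punctual stress.** `S_i = Σ_j ΔF_ij` (pN) is the total absolute force
   change residue `i` senses. It obeys the conservation identity
   `Σ_i S_i = 2 Σ_{i<j} ΔF_ij` on every input, which the tests assert
   exactly. Profiles can be written onto the PDB B-factor column (linear map
   of a chosen value window onto 0–99.99) for colour-coded 3D rendering.
4. **Pathways.** ΔF defines an undirected weighted graph (edges above a
   noise floor). For configured source and sink residue regions, the
   *maximum connectivity cutoff* is the largest threshold at which some
   source still reaches some sink through edges of weight ≥ cutoff. This is
   exactly the maximin (widest-path) bottleneck between the regions; it is
   computed by binary search over the sorted unique weights with union-find
   connectivity, and a brute-force threshold sweep is kept as the test
   oracle. Within the surviving subgraph, pathways are reported as ranked
   widest paths: ties on bottleneck weight are broken by fewer hops, then by
   lexicographically smallest residue sequence; after each extraction the
   path's interior nodes are removed, so successive paths prefer node
   disjointness and ranks are non-increasing in bottleneck. The published
   procedure fixes only the cutoff rule; the ranked-widest-path extraction
   and its tie-breaks are this package's own (documented) choice, and the
   full surviving subgraph is exported alongside the paths so either reading
   can be reproduced.

## Structural observables

* **Superposition** uses the Kabsch/quaternion solution
  (`scipy.spatial.transform.Rotation.align_vectors`); rotations are always
  proper, and degenerate (collinear, < 3 point) inputs are rejected because
  the optimum is not unique there. A dense rotation-grid search serves as an
  independent oracle in the tests.
* **RMSD** superposes each frame on an explicit reference over a *fit*
  selection (default: backbone heavy atoms) and reports over an independent
  *report* selection, so a backbone fit can report an all-atom value.
* **RMSF** uses the self-consistent mean-structure reference: frames are
  iteratively superposed on the running mean until it shifts by
  < 1e-6 Å (configurable to a fixed reference, or no superposition). A
  residue pools the mean squared fluctuations of its selected atoms.
* **Gate distances** are per-frame distances between two named atoms
  (for SULT1A1: L1–L2 = P87Cα–V148Cα, L1–L3 = P87Cα–F247Cα,
  cL3 = K197Cα–M260Cα, shipped as the default profile together with the
  loop windows L1 83–91, L2 141–158, L3 241–255, cL3 256–262, nL3 236–240,
  α14nL3 228–240, α3L4 66–78, KTVE 265–274). Histograms default to 0.5 Å
  bins over the data range; a configured gate pair also gets the joint 2D
  histogram whose marginals equal the 1D histograms by construction.

## Synthetic ensembles

The generator produces the statistical situation the difference analysis
assumes, with known ground truth:

* `make_toy_structure` grows compact self-avoiding Cα chains (3.8 Å steps,
  ≥ 3.4 Å self-separation, a drift toward the centroid for compactness).
  The two-chain form docks chain B so that the *last residue of each chain*
  forms a designated interface bridge at 4.5 Å, requires ≥ 10 inter-chain
  contacts within 8 Å so the dimer is mechanically rigid, and rejects any
  geometry whose contact network has more than the six rigid-body zero
  modes.
* `build_enm` joins all residue pairs within a cutoff (default 8 Å) by
  springs of k = 100 pN/Å with rest lengths equal to the input distances, so
  the input structure is the exact energy minimum.
* `sample_ensemble` draws frames *exactly* from the equilibrium Gaussian
  `N(x0, kT·H⁺)`, where `H` is the 3N×3N anisotropic-network Hessian and the
  pseudoinverse runs over non-rigid modes (eigenvalues below 1e-8 × the
  largest are treated as rigid and excluded, so the ensemble has no drift or
  tumble). kT defaults to 41.4 pN·Å (300 K). Exact sampling instead of
  Langevin integration removes integrator error: RMSF, covariance and
  equipartition all have closed forms the tests compare against (5%
  sampling tolerance at 20,000 frames).
* `plant_perturbation` emulates ligand binding: a ligand pseudo-node placed
  just outside the binding-site centroid, tethered by springs to three site
  residues, plus a designated chain of springs stiffened by λ = 4. The
  default scenario on the 2×32-residue dimer perturbs 7 residues: site
  A28–A30 and pathway A30–A31–A32–B32–B31 across the interface bridge
  (A32, B32). The perturbed set is deliberately about one decile of the
  64 protein residues so that "top decile of punctual stress captures the
  planted residues" is a sharp, achievable recovery criterion.

Defaults (k = 100 pN/Å, cutoff 8 Å, kT = 41.4 pN·Å, λ = 4) put planted ΔF
bottlenecks near 35–40 pN and peak punctual stress near 150 pN — the order
of magnitude reported for cofactor-binding force changes in sulfotransferase
simulations (hundreds of pN).

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes: Gaussian
equilibrium fluctuations, a localized force perturbation, propagation along
a known spring chain, two chains with an interface. It does not contain
side chains, solvent, anharmonic barriers, conformational switching, or
realistic secondary structure; passing recovery tests therefore shows the
*analysis* is correct and well-calibrated, not that real μs-scale MD of a
real dimer would yield equally clean signals.

## Numerical choices

* Mean signed forces on the sampled ensembles are not exactly zero even for
  the unperturbed network: forces are evaluated with the full nonlinear
  spring law on coordinates sampled from the *linearized* Gaussian, so the
  convexity of the distance function leaves O(kT/r0) residual attractions
  (tens of pN at the defaults). The difference analysis is unaffected —
  both conditions carry the same bias except where the perturbation acts —
  and tolerances in the tests account for it.
* Equipartition is asserted on the harmonic (quadratic-form) energy
  ½ δᵀHδ, which the sampled Gaussian satisfies exactly at kT/2 per mode;
  the full spring energy exceeds it by the anharmonic correction (~25% at
  the default kT), which is why the harmonic form is the right observable
  for this check.
* Spring evaluation rejects inter-node distances below 1e-6 Å (undefined
  axis).
* Maximin cutoff: binary search over unique sorted weights; exact equality
  with the sweep oracle is asserted, no floating-point slack needed since
  both compare the same weight values.
* B-factor export clips to the configured window and writes 2 decimals in
  columns 61–66; the linear map targets 0–99.99 (the PDB field maximum
  below 100).
* PDB reading keeps the highest-occupancy altloc (first on tie), rejects
  insertion codes with the offending line number, and reads only the first
  MODEL of a multi-model file as a structure.

## Problem sizes

Tests and the acceptance script use 16–64-residue networks, 2,000–20,000
frames, 5 replicas for the recovery experiment, and 200 random graphs for
the cutoff oracle — sizes at which every analytic comparison is sharp and
the whole suite runs in well under a minute on one core.

## Known limitations

* Only PDB v3.3 and a plain XYZ frame dialect are parsed; no mmCIF or
  binary trajectory formats.
* The force model is springs-only; it cannot ingest native output of
  all-atom force-distribution tools directly, though the documented
  force-matrix TSV schema makes external conversion trivial.
* Pathway extraction reports ranked widest paths; flow-based or
  betweenness-style allostery measures are out of scope.
* `robust_residues` is a plain intersection of pathway node sets; it is
  meaningful when the compared results' regions are chosen so their
  pathways can in fact share residues (e.g. several comparisons spanning
  the same interface), and an empty intersection is a valid outcome.
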