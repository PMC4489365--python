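# Methods

## The model

`qsfr` treats a protein conformation as a mechanical constraint network and
derives joint thermodynamic and mechanical ("stability/flexibility")
properties from the statistics of network rigidity — the minimal distance
constraint model (mDCM).

Atoms are rigid bodies with six degrees of freedom.  Interactions become
bars, each removing at most one relative degree of freedom:

* a non-rotatable covalent bond (peptide, double/aromatic, ring, or any
  bond to hydrogen) contributes **6 bars** — a weld;
* a rotatable single bond contributes **5 bars**, leaving exactly the
  dihedral degree of freedom;
* a hydrogen bond or salt bridge contributes **5 bars** between the donor
  heavy atom and the acceptor;
* every rotatable bond with heavy atoms on both sides carries one
  **torsion constraint** (a single bar between the dihedral's outer atoms)
  in either a *native* (well-packed, low-entropy) or *disordered* state.

A macrostate is the pair (N_hb, N_nat): the number of H-bonds present and
the number of torsion constraints in the native state.  Its free energy is

    G(N_hb, N_nat) = U(N_hb) − u_sol·N_hb + v_nat·N_nat
                     − T·[S_conf(N_hb, N_nat | δ_nat) + S_mix(N_hb, N_nat)]

with conformational entropy counted only over *independent* constraints,

    S_conf / R = ⟨ Σ_t q_t γ_t + Q_nat δ_nat + Q_dis δ_dis ⟩,

where q_t ∈ {0,…,5} is the number of independent bars of H-bond t, and
Q_nat/Q_dis count independent native/disordered torsion constraints.
Independence is decided by the (6,6) body-bar pebble game with constraints
inserted in **preferential order** (ascending component entropy), which
makes the entropy estimate the lowest upper bound attainable by constraint
exchange.  Entropy is therefore strongly non-additive: a constraint that is
redundant contributes nothing, which is how enthalpy–entropy compensation
arises mechanically.

### Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| u_sol | solvent H-bond energy credited when an intramolecular H-bond breaks | kcal/mol | −1.0 |
| v_nat | energy of a native-like torsion (packing) | kcal/mol | −0.45 |
| δ_nat | component entropy of an independent native torsion | — | 2.4 |
| δ_dis − δ_nat | fixed disordered-torsion offset | — | 0.6 |
| γ_max | maximum H-bond component entropy | — | 2.0 |
| R | gas constant | kcal/(mol·K) | 1.987×10⁻³ |

Only {u_sol, v_nat, δ_nat} are fitted.  The defaults were chosen once so
that the 12-residue helical test peptide shows a clean two-basin landscape
with its heat-capacity peak near 328 K; they are starting values, not
physical claims.

H-bond component entropies use an affine map of the detected bond energy
onto [0, γ_max]: the strongest bond in an inventory anchors γ = 0, a bond
at the detection cutoff gets γ_max, so weaker bonds always carry at least
as much entropy as stronger ones.  The exact functional form of this map
(and of S_mix, realised as independent log-binomial placement counts,
S_mix/R = ln C(M_hb, N_hb) + ln C(M_nat, N_nat)) is an explicit design
choice; both are isolated behind single functions so an alternative can be
swapped in.

U(N_hb) is defined as the mean over sampled constraint topologies of the
summed energies of the present H-bonds.  Because subsets are drawn
uniformly, this equals N_hb/M_hb times the total inventory energy in
expectation; the Boltzmann factor acts only *across* macrostates.

## H-bond detection

The source structures must carry their polar hydrogens; no hydrogen
building is performed.  Donors are N/O/S atoms with a covalently bound
hydrogen; acceptors are any O/S plus nitrogens without hydrogens; pairs
within three covalent bonds are excluded.  Geometry gates: H···A ≤ 2.6 Å,
D···A ≤ 3.6 Å, D–H···A angle ≥ 100°.  The energy is a Mayo-style
distance–angle potential,

    E = D0 [5 (R0/d_DA)^12 − 6 (R0/d_DA)^10] cos² θ_DHA,

with D0 = 8 kcal/mol and R0 = 2.8 Å, and a cutoff of −0.1 kcal/mol.  Salt
bridges (Arg/Lys/His donors to Asp/Glu carboxylates) are flagged but
treated as ordinary 5-bar H-bonds.  All gates are configurable.

## Rigidity analysis and the two-network decomposition

A single pebble game over the full framework (covalent + H-bond + torsion
bars, preferential order) supplies the entropy counts q_t, Q_nat, Q_dis.

The *mechanical* decomposition deliberately distinguishes the structural
network from the torsion constraints: a torsion constraint is entropy
bookkeeping, not a weld — placing it on a hinge must not make that hinge
"locked".  A second pebble game over the structural bars alone (covalent
and H-bond) therefore decides:

* **locked** rotatable bonds — central-bond endpoint pairs on which 7
  pebbles cannot be gathered;
* **rigid clusters** — transitive closure of pairwise mutual rigidity over
  bonded and H-bonded pairs (equivalent to all-pairs testing on a
  connected framework);
* **over-constrained regions** — unions of the vertex sets visited by
  failed pebble searches, merged when overlapping, with B = redundant
  structural bars and L = locked rotatable bonds per region;
* **flexible regions** — connected components of unlocked torsion sites,
  two sites being adjacent when their central bonds share an atom, are
  covalently bonded, or are linked by a present H-bond; H counts the
  region's hinges, and A its independent *disordered* torsion constraints
  from the full-network game.

This reproduces the canonical loop-closure cases exactly: a free chain has
one flexible region with A = H (f = 1 everywhere); a six-membered ring of
rotatable bonds is isostatically rigid (B = 0, f = 0); an eight-membered
ring leaves two collective hinge degrees of freedom shared by eight bonds
(h = 2/8); a redundant crosslink creates a stressed region with f = −B/L.

The flexibility index is f_i = h_i − l_i (h = A/H in a flexible region,
l = B/L in an over-constrained region, 0 for isostatically locked bonds);
the cooperativity correlation matrix over backbone φ/ψ torsions is +h for
co-flexible pairs, −l for co-rigid pairs, 0 otherwise.  For the rare case
of two locked bonds sharing a rigid cluster but assigned to different
stressed regions, the CC entry uses −(l_i + l_j)/2 to preserve symmetry.
Both metrics are Boltzmann-averaged over the native basin at T = T_m, and
per-residue FI is the unweighted mean of that residue's φ/ψ sites.

An independent oracle — the rank of the generic body-bar rigidity matrix,
evaluated numerically at random generic placements with majority voting —
cross-checks the pebble game exactly on hundreds of random multigraphs.

## Monte Carlo sampling and parameter fitting

Each macrostate is sampled with 200 uniform random subsets by default
(spec-scale fixtures use fewer; see below).  Sampling is parameter-free:
subsets do not depend on {u_sol, v_nat, δ_nat}, and the pebble-game
outcome depends only on the insertion *order*.  The fit constrains δ_nat
to [γ_max, γ_max + 4], so every H-bond entropy (≤ γ_max) stays below every
torsion entropy and the preferential order — hence every sampled count —
is invariant across trial parameter sets.  One sampling pass therefore
serves the entire Nelder–Mead fit exactly, no approximation involved.

The fit minimises the squared difference between min–max-normalised model
and target heat-capacity curves (or the peak-location error when only a
melting temperature is given).  Because the normalised-shape misfit has
flat shoulders, the simplex is seeded from a coarse scan over u_sol (which
dominates the peak location) and restarted once after convergence; on the
helix fixture this recovers all three parameters to ~1% across sampling
seeds.  C_p is d⟨H⟩/dT by central differences on a 1 K grid; only the
normalised peak shape and location are fitted — calorimetric baselines are
not modelled.

The native basin at T_m is found by locating grid-local minima, taking the
highest-N_nat minimum as native, computing the minimax saddle to the
lowest remaining minimum (union-find over nodes sorted by G), and
flood-filling strictly below the saddle.  A single-minimum landscape
returns the whole grid, flagged.

Per-macrostate random streams are derived from (seed, N_hb, N_nat) so
grids are reproducible regardless of evaluation order.

## Representative structures and comparison

Ensembles are reduced by greedy centroid clustering on the all-heavy-atom
pairwise RMSD matrix (each pair superposed independently with the SVD
Kabsch solution, reflections rejected).  The radius is bisected until
about 20 clusters emerge; the centroids of the 10 largest clusters become
representatives, weighted by cluster size, and their coverage is reported,
not enforced.  The greedy scheme (promote the unassigned frame with the
most unassigned neighbours, ties to the lowest index) is deterministic.

Differences between two systems are per-residue Z-scores with
cluster-weighted means and standard deviations and the fixed divisor
n = number of representatives.  |Z| > 2.33 is a moderate change (one-sided
normal p = 0.01), |Z| > 3.33 a large change (p ≤ 0.0005); exact threshold
values are "none" (strict inequalities).  When both standard deviations
vanish with unequal means the Z-score saturates to ±inf and is flagged
rather than clipped.  The same formula applied per pixel gives the ΔCC
map, and per-residue H-bond propensity sums (fraction-of-frames occupancy
summed over a residue's atoms) give the H-bond difference profile.
Mobility (RMSF about the iteratively fitted ensemble mean) is paired with
the flexibility Z-scores via a Spearman rank correlation with a seeded
permutation p-value; no multiple-testing correction is applied anywhere.

## The synthetic generator

The generator emulates exactly the features of a solvated-protein MD
ensemble that this analysis consumes, and nothing more:

* idealised peptides (helix −57/−47, hairpin −119/113 with a two-residue
  turn, extended coil −75/150) with standard bond geometry and polar
  hydrogens, built by internal-coordinate chain extension; supported
  residues are Ala, Gly, Ser, Pro;
* metastable **substates**: frames hop between a few fixed per-atom offset
  fields with Dirichlet-distributed occupancies, which is what gives a
  trajectory its cluster structure — without substates, one cluster
  dominates and cluster-size-weighted statistics degenerate;
* isotropic Cartesian jitter (no torsional correlations, no solvent, no
  force field — occupancy is controlled explicitly rather than
  emergently);
* scheduled H-bond occupancy edits: a frame scheduled "present" has the
  donor hydrogen re-placed on the donor→acceptor line (acceptor pulled to
  2.9 Å when outside the gate), guaranteeing detection; "absent" frames
  swing the hydrogen to the far side, guaranteeing rejection.  Schedules
  are Bernoulli ("random") or evenly spaced ("even", exact to one frame).

Passing tests on these ensembles validates the machinery — detection,
clustering, rigidity, thermodynamics, statistics — under controlled truth.
They do not validate force-field realism, the H-bond energy model against
experiment, or behaviour on structures whose protonation is uncertain.

## Problem sizes and numerics

The standard fixtures are a 12-residue poly-Ala helix (8 candidate
H-bonds, 23 torsion sites, 216-node macrostate grid) and a 16-residue
hairpin pair (240 frames, 10 representatives, 30 samples/macrostate,
N_nat-axis stride 2); parameter-recovery runs use the full 200
samples/macrostate.  These sizes keep a complete two-system comparison in
the minutes range on one core while leaving every statistic comfortably
resolved.

Numerical choices worth knowing: superposition RMSDs below ~1e-6 Å are
numerically zero (trace-formula cancellation); RMSF mean-fitting iterates
to 1e-6 Å; bisection for the cluster radius stops within ±3 clusters or 40
iterations, returning the closest (smallest-radius) candidate; Nelder–Mead
uses xatol 1e-3 with one restart; T = 0 landscapes put all weight on the
ground state; ties everywhere break by ascending index, so every stage is
deterministic given its seed.

## Limitations

* Torsion inventories must agree between compared systems (same sequence
  and covalent topology) — variant pairs differing by actual mutations are
  out of scope; differences enter through the H-bond network.
* The decomposition conventions (failed-search region merging, flexible-
  region adjacency, locked-pair CC symmetrisation) are documented choices;
  other conventions would shift f values without changing the rank
  invariants.
* No nucleic acids, ligands, metals, π-stacking or hydrophobic tethers;
  packing enters only through native torsion constraints.
* Kabat numbering and region definitions are not built in; region masks
  are supplied as residue intervals in the configuration.
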