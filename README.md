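# qsfr

Network-rigidity thermodynamics and flexibility comparison of protein
conformational ensembles.

`qsfr` is for structural bioinformaticians who want to know not just *how
stable* a protein is but *where* that stability lives mechanically — which
backbone torsions are flexible, which are locked into over-constrained
regions, how those properties couple across the structure, and how they
shift between two closely related systems (a germline vs. affinity-matured
antibody, a wild type vs. a designed mutant).  It implements the minimal
distance constraint model (mDCM): atoms become rigid bodies, covalent
bonds, hydrogen bonds and torsions become distance constraints (bars), and
a (6,6) body-bar pebble game counts which constraints are independent.

The free energy of a macrostate with N_hb hydrogen bonds and N_nat
native-like torsions is

    G(N_hb, N_nat) = U(N_hb) − u_sol·N_hb + v_nat·N_nat − T·[S_conf + S_mix]

with the non-additive conformational entropy counted over independent
constraints only,

    S_conf / R = ⟨ Σ_t q_t γ_t + Q_nat δ_nat + Q_dis δ_dis ⟩ ,

sampled by Monte Carlo (200 constraint topologies per macrostate) under
preferential, lowest-entropy-first constraint placement.  Heat-capacity
curves C_p = d⟨H⟩/dT locate the melting temperature; the three
phenomenological parameters {u_sol, v_nat, δ_nat} are fitted to a target
C_p curve or T_m.  At T = T_m, native-basin Boltzmann averages yield the
backbone **flexibility index** FI = ⟨h − l⟩ (h = A/H the independent-DOF
density of a flexible region, l = B/L the redundant-constraint density of
an over-constrained region) and the **cooperativity correlation** matrix
CC over φ/ψ torsions (+h co-flexible, −l co-rigid, 0 uncoupled).

Two systems are compared across 10 cluster-weighted representative
structures with the Z-score

    Z = (x̄_B − x̄_A) / sqrt(σ²_B/10 + σ²_A/10),

calling |Z| > 2.33 a moderate change (one-sided p = 0.01) and |Z| > 3.33 a
large change (p ≤ 0.0005).  Per-residue H-bond propensity differences and
flexibility-vs-mobility (ΔRMSF) pairings complete the comparison.

A synthetic-data module generates every input the pipeline needs —
idealised peptides with polar hydrogens, multi-substate jittered ensembles
with exactly scheduled H-bond occupancies, paired variant systems with a
known ground truth, random body-bar graphs, and single-peak C_p targets —
so the whole analysis runs and is tested without any external data.

## Worked example

Compare a 16-residue β-hairpin against a variant in which two new
serine-hydroxyl-to-carbonyl hydrogen bonds crosslink the turn (the classic
rigidifying-mutation scenario):

```python
import dataclasses
from qsfr import HBondEdit, SyntheticSystemSpec
from qsfr.pipeline import PipelineConfig, run_pipeline

wild_type = SyntheticSystemSpec(
    sequence="AAAAAASAASAAAAAA", fold_template="hairpin",
    n_frames=240, jitter_sigma=0.25, seed=7,
)
mutant = dataclasses.replace(
    wild_type, seed=8,
    hbond_edits=[
        HBondEdit("add", donor=(7, "OG"), acceptor=(10, "O"), propensity=1.0),
        HBondEdit("add", donor=(10, "OG"), acceptor=(7, "O"), propensity=1.0),
    ],
)
config = PipelineConfig(
    system_a=wild_type, system_b=mutant,
    n_representatives=5, n_samples=30, stride=(1, 2), seed=1,
)
result = run_pipeline(config, outdir="comparison")
print(f"T_m = {result.t_m:.0f} K")
print("residue    Z  class")
for r, z, c in zip(result.system_a.residue_index, result.z, result.classes):
    print(f"{r:7d} {z:6.2f}  {c}")
```

Output:

```
T_m = 251 K
residue    Z  class
      1  -4.23  large_rigidity
      2  -4.23  large_rigidity
      3  -4.23  large_rigidity
      4  -4.23  large_rigidity
      5  -4.23  large_rigidity
      6  -4.23  large_rigidity
      7  -3.82  large_rigidity
      8  -3.83  large_rigidity
      9  -3.83  large_rigidity
     10  -3.83  large_rigidity
     11  -4.82  large_rigidity
     12  -4.82  large_rigidity
     13  -4.82  large_rigidity
     14  -4.82  large_rigidity
     15  -4.82  large_rigidity
     16  -4.82  large_rigidity
```

Every residue rigidifies (negative Z): the two crosslinks close the
hairpin's macrocycle, so rigidity percolates through the whole constraint
network rather than staying local to the edited turn — the long-range
character of network rigidity is the point of the method.  A null pair
(same recipe, different noise seeds) produces no calls at the 2.33
threshold.  The `comparison/` directory receives the full artifact set:
per-system FI/RMSF/propensity tables, the Z profile and class counts, the
ΔCC Z matrix, representative structures as multi-model PDB with weights,
fitted parameters, and a manifest with content hashes.

The same pipeline runs from the shell:

```sh
qsfr generate --spec system.yaml --out system      # synthetic ensemble
qsfr cluster  --ensemble system.pdb --out clusters # representatives
qsfr fit      --structure rep.pdb --target-tm 326 --out params.json
qsfr qsfr     --structure rep.pdb --params params.json --out qsfr_out
qsfr run-all  --config comparison.yaml --out results
```

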