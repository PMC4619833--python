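# pocketdyn

**Does binding-site flexibility explain protease substrate specificity?**
`pocketdyn` is a Python library and CLI that quantifies both sides of that
question and rank-correlates them, sub-pocket by sub-pocket:

* **Specificity** — from a table of known cleavage sites, the *cleavage
  entropy* of each substrate position Pn (Schechter–Berger nomenclature,
  non-prime side P6…P1):

  S(Pn) = −Σ_a f_a · ln f_a / ln 20 ∈ [0, 1]

  where f_a are the residue frequencies at Pn. 0 means absolute specificity
  (one residue type only), 1 means no preference.

* **Flexibility** — from a conformational ensemble (multi-model PDB, e.g.
  MD snapshots):
  * residue-wise Cα B-factors after a *single* global Kabsch alignment,
    B = (8π²/3)·MSF in Å²;
  * backbone dihedral entropies Sφ, Sψ by periodic Gaussian kernel density
    estimation of the torsion distribution and integration
    S_α = −R ∫ p(α) ln p(α) dα (degree measure, J/(mol·K)); a torsion locked
    into a 1°-wide peak scores ≈ 0, a fully disordered one R·ln 360 ≈ 48.94;
  * protease–peptide hydrogen-bond occupancy (heavy-atom distance ≤ 3.0 Å,
    D–H···A within 45° of linearity), reported as mean bonds per frame and
    per pocket (can exceed 1);
  * 2D-RMSD matrices and ten-block trajectory splitting as convergence
    diagnostics.

Sub-pockets Sn are defined from a complex structure as all protease residues
with any atom within 3.5 Å of the peptide residue at Pn; definitions from
several complexes can be merged. Residue-wise metrics are aggregated as
unweighted pocket means and compared to cleavage entropy by the Spearman
rank correlation coefficient ρ (midranks, optional exact permutation
p-value for the typical n = 6 pockets).

Because microsecond MD ensembles are rarely shareable, the package ships a
first-class synthetic-data generator (`pocketdyn.synthetic_data`) that
emulates every input with analytic ground truth — planted positional residue
distributions, von Mises torsion ensembles realised as Cartesian chains,
Gaussian Cα fluctuations under rigid-body jitter, and toy complexes with
hydrogen bonds present in a known fraction of frames.

## Worked example

The packaged "thrombin-like" scenario plants a specificity gradient
(S1 most specific → S6 promiscuous) with rank-concordant flexibility and a
deliberately discordant hydrogen-bond pattern:

```python
from pocketdyn.synthetic_data import ThrombinLikeScenario, analyze_scenario

data = ThrombinLikeScenario(seed=1).generate()   # 20,000 frames, 1,000 substrates
report = analyze_scenario(data, with_exact_p=True)
print(report.pocket_table.round(3))
print(report.summary())
```

```
        cleavage_entropy  bfactor_global_ca   s_phi   s_psi  hbond_occupancy
pocket
S1                 0.094              1.780  28.296  28.253            3.410
S2                 0.662              4.953  34.114  34.152            0.000
S3                 0.901             12.680  38.497  38.512            0.594
S4                 0.925             23.861  41.153  41.176            0.000
S5                 0.951             38.754  44.844  44.829            0.012
S6                 0.973             64.235  47.759  47.788            1.000
Specificity vs flexibility (Spearman rank correlation)
  bfactor_global_ca: rho=+1.000, n=6, p_exact=0.003
  s_phi: rho=+1.000, n=6, p_exact=0.003
  s_psi: rho=+1.000, n=6, p_exact=0.003
  hbond_occupancy: rho=-0.087, n=6, p_exact=0.861
```

Reading the output: cleavage entropy rises from a highly specific S1 (0.09)
to a nearly indifferent S6 (0.97); every flexibility metric rises in the
same rank order (ρ = 1), while hydrogen bonding — strong in S1, absent in
the similarly specific S2 — carries almost no rank information (ρ ≈ −0.09).
Rigid pockets read out their substrates specifically even without strong
polar contacts; that is the conformational-selection picture the pipeline
is built to test.

The same analysis is available from the shell on files:

```bash
pocketdyn simulate --seed 2 --frames 300 --interface-frames 200 \
    --substrates 200 --out demo/
pocketdyn cleavage-entropy --substrates demo/substrates.csv \
    --positions P6,P5,P4,P3,P2,P1 --out demo/spec
pocketdyn dihedral-entropy --traj demo/torsion_ensemble.pdb --out demo/dihed.csv
pocketdyn pockets-define --complex demo/interface_ensemble.pdb --peptide-chain P \
    --position-map "P:1=P6,P:2=P5,P:3=P4,P:4=P3,P:5=P2,P:6=P1" --out demo/pockets.json
pocketdyn hbonds --traj demo/interface_ensemble.pdb --pockets demo/pockets.json \
    --peptide-chain P --out demo/hbonds.csv
```

`simulate` always writes a `ground_truth.json` next to the data so recovery
can be checked against planted values rather than against the estimators
themselves.

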