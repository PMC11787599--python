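# trajcouple

Trajectory analysis for GPCR / G-protein molecular-dynamics studies:
conformational clustering, **key-lock conformational-coupling detection**,
center-to-center-distance (CCD) state classification, Boltzmann-inversion
free-energy surfaces, and ligand-contact hotspot extraction — with a
synthetic-data module that plants known ground truth so every stage is
verifiable without an MD engine.

## Who this is for

Researchers analysing simulations of receptor–transducer complexes (e.g.
β-adrenergic receptors coupled to the stimulatory G protein G_s, with an
agonist such as norepinephrine in the orthosteric pocket) who need the
post-processing layer between raw trajectories and biological statements:
which Gα conformational state dominates, whether ligand poses and receptor
conformations move in lock-step, what the free-energy surface over two
distance coordinates looks like, and which residues line a dissociation
pathway.

## What it computes

- **CCD series** — per-frame Euclidean distance between the *geometric*
  (unweighted) centers of two atom selections, e.g. between marker residues
  on the Gα α-helical domain (AHD) and Ras-like domain (RD).
- **Gα state classification** — open (CCD ≥ 55 Å), semi-open ([45, 55) Å),
  semi-closed ((35, 45) Å), closed (≤ 35 Å); ligand binding state — bound
  (< 12 Å), unbound (> 40 Å), intermediate otherwise. Both the per-frame
  occupancy convention and the mean-CCD convention are reported and named.
- **Conformational clustering** — pairwise RMSD matrix with per-pair Kabsch
  superposition, Ward agglomeration, elbow selection of the cluster count,
  medoid extraction (a deterministic k-medoids alternative is included).
- **Key-lock coupling** — for cluster *A_i* of one component and *B_j* of
  another sharing `n_common` frames, the overlap
  `|A_i ∩ B_j| / min(|A_i|, |B_j|)` (denominator selectable); a pair with
  overlap strictly above 0.5 is a *strong coupling pair*.
- **Free-energy surfaces** — 1D/2D potential of mean force by Boltzmann
  inversion, `W = −k_B T ln(n_bin / n_max)`, bin width 1.0 Å at 310 K, with
  a 10-configuration occupancy cutoff on 2D grids.
- **Contact hotspots** — residues within 4.0 Å heavy-atom minimum distance
  of the ligand, retained when in contact for strictly more than 20% of the
  pathway duration.
- **Series statistics** — Pearson correlation between motion series,
  block-average SEM, and the interaction entropy
  `−TΔS = k_B T ln⟨exp(β(E − ⟨E⟩))⟩` of an interaction-energy series.

## Worked example

```python
import numpy as np
import trajcouple as tc

# toy ligand/receptor ensemble with an 80% planted joint-state fraction
system = tc.gen_coupled(states_k=3, n_frames=300, f=0.8, noise_sigma=0.1, seed=42)

sel = tc.Selection("all", np.arange(5))
assignments = []
for traj in (system.trajectory_a, system.trajectory_b):
    matrix = tc.pairwise_rmsd_matrix(traj, sel, sel)
    linkage = tc.ward_linkage(matrix)
    k = tc.select_k_elbow(matrix, linkage, k_max=20)
    assignments.append(tc.cut_clusters(linkage, k, matrix))

pairs = tc.coupling_pairs(assignments[0], assignments[1])
report = tc.coupling_report(pairs, "ligand", "receptor")
print("clusters:", assignments[0].k, "x", assignments[1].k)
print("strong pairs:", report["strong_count"])
for p in pairs[:3]:
    print(f"  A{p.cluster_a} - B{p.cluster_b}: overlap {p.overlap_fraction:.3f} strong={p.strong}")

print("states:", [tc.classify_galpha(v) for v in (63.6, 42.3, 31.2)])
```

Output:

```
clusters: 3 x 3
strong pairs: 3
  A2 - B2: overlap 0.832 strong=True
  A3 - B3: overlap 0.832 strong=True
  A1 - B1: overlap 0.829 strong=True
states: ['open', 'semi-closed', 'closed']
```

The elbow rule recovers the three planted conformational states in each
component, and each matched cluster pair shares ≈83% of its frames —
detected as three strong key-lock pairs (the planted coupling fraction was
0.8). The three CCD values classify as open, semi-closed, and closed Gα.

## Command-line pipeline

Every stage also runs as a config-driven subcommand writing results plus a
`manifest.json` (config hash, package version, seed, effective parameters);
identical configs give byte-identical outputs:

```sh
trajcouple simulate --config sim.yaml     # synthetic dataset with ground truth
trajcouple couple   --config run.yaml     # clustering + key-lock coupling report
trajcouple states   --config run.yaml     # CCD -> state series + occupancy
trajcouple pmf      --config run.yaml     # 2D free-energy surface (CSV)
trajcouple hotspots --config run.yaml     # contact timeline + hotspot table
trajcouple corr x.csv y.csv               # Pearson r between two series
trajcouple entropy energies.csv           # interaction entropy
trajcouple sem series.csv --blocks 5      # block-average SEM
```

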