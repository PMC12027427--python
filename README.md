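# allopath

Post-simulation analysis of allosteric communication in protein ensembles,
built for multi-chain systems such as antibodies where signal has to travel
between distal sites (e.g. from an Fc-side ligand site to the Fab arms).

Given a static structure and a coordinate trajectory, the pipeline computes:

- **Backbone fluctuation metrics** — RMSD(t), radius of gyration Rg(t), and
  per-residue RMSF about the time-average structure, with optimal
  least-squares (Kabsch) superposition.
- **Essential dynamics** — PCA of the Cα Cartesian covariance and the
  free-energy landscape over the PC1/PC2 projection density by Boltzmann
  inversion, `G = −kT ln(P/P_max)`.
- **Residue coupling** — the dynamic cross-correlation matrix
  `C(i,j) = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^{1/2}` of Cα displacement
  vectors, and the residue contact matrix (fraction of frames a pair is
  within a distance cutoff, smallest-heavy-atom-distance convention).
- **Communication pathways** — fusion of the two matrices into a weighted
  residue graph: an edge joins residues in frequent contact
  (freq ≥ f_min) with coupled motions (|C| ≥ c_min), weighted by
  `−ln|C|`. Dijkstra shortest paths over all residue pairs score each edge
  by the number of co-optimal paths traversing it; edges above a normalised
  importance threshold form the shortest-path map, whose endpoints are the
  pathway "hotspot" residues. Hotspot sets from several simulation systems
  are intersected into the consensus communication residues.
- **Non-covalent interactions** — per-frame geometric detection of hydrogen
  bonds (donor–acceptor < 3 Å, D–H···A angle > 150°), hydrophobic contacts
  (Cα–Cα < 4 Å), cation–π (ring atom to cationic N < 6 Å) and π–π stacking
  (ring centroids < 5 Å), summarised as per-site occupancy percentages and
  per-frame pair-count statistics.

Residues are addressed by a single **global index**, numbered continuously
across chains in a caller-declared order (for an IgG the alternating
light–heavy–light′–heavy′ pattern), so one index names any residue of the
assembly in every matrix, graph and table.

Because production MD trajectories are expensive, the package ships a
first-class synthetic-ensemble generator with analytic ground truth:
multivariate-Gaussian Cα ensembles with a prescribed correlation matrix,
"planted" high-correlation communication chains between two distal lobes,
and single-interaction geometries placed exactly at or across each detector
threshold. Every stage of the pipeline is validated against these truths.

## Worked example

Generate a 30-residue, 2000-frame synthetic system with a 6-residue
communication chain planted between residues 13 and 18, then mine it:

```bash
allopath simulate --n-res 30 --n-frames 2000 --seed 42 \
    --planted-chain 13,14,15,16,17,18 --out sim
allopath pathway sim/structure.pdb sim/trajectory.pdb --out path
allopath pca-fel sim/structure.pdb sim/trajectory.pdb --out pca
allopath metrics sim/structure.pdb sim/trajectory.pdb --out met
```

prints

```
wrote structure.pdb and trajectory.pdb (2000 frames) in sim
11 hotspot residues; outputs in path
PC1+PC2 carry 11.85% of the variance; wrote pca_summary.tsv, fel.tsv in pca
wrote rmsd.tsv, rg.tsv, rmsf.tsv in met
```

`path/hotspots.tsv` then lists the hotspot residues `7, 11, 12, 13, 14, 15,
16, 17, 18, 19, 20` — the planted chain 13–18 is recovered in full, plus
the residues through which cross-lobe traffic enters the chain. The 11.85%
PC1+PC2 variance is what an isotropic-noise ensemble should give (no
dominant collective mode was planted here); `met/rmsf.tsv` shows per-residue
RMSF ≈ 0.8 Å, matching the generator's σ = 0.5 Å per axis (σ√3 ≈ 0.87 Å
before superposition shrinkage). A full per-system run —
`allopath run-all config.yaml` — writes all of the above plus DCCM/RCM
matrices, the edge list, interaction events and occupancy tables, and a
`manifest.json` with the effective configuration and a SHA-256 hash of
every output; `allopath compare run1/manifest.json run2/manifest.json`
emits the cross-system consensus table.

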