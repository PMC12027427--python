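# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `allopath` pipeline. It states no empirical numbers
beyond those the test suite and `scripts/acceptance.py` recompute.

## Residue model and renumbering

All analyses address residues by a global 1-based index that runs
continuously across chains in a caller-declared order. For a four-chain
antibody the conventional order is light, heavy, light′, heavy′, so a
pathway can name a residue deep in the second heavy chain with a single
number larger than any individual chain length. Offsets are always derived
from the actual input (author residue numbers per chain), never assumed.
Ligand and glycan chains are appended after all protein chains, keeping
protein-only matrices dense and contiguous; the mapping and its inverse are
exposed and written as a JSON sidecar with every run.

PDB input follows fixed-column conventions: the first MODEL only for the
static structure, highest-occupancy altloc retained (single-conformer
model), elements from columns 77–78 or inferred from the atom name, masses
from a built-in element table. Parse errors carry the 1-based line number;
trajectory frames with the wrong atom count name the offending frame. XYZ
input (one Cα per residue) requires a JSON sidecar declaring the chain
layout. Matrix TSV output uses 17 significant digits so write→read
round-trips are exact.

## Backbone metrics

Superposition minimises the least-squares RMSD over a selection via the
optimal-rotation solution (`scipy`'s `align_vectors`, Kabsch-equivalent);
selections with fewer than three non-collinear atoms are rejected because
the rotation is then not unique. Computations are in Å (nm emission is a
flag for tools that plot in GROMACS units); mass weighting is off for
Cα selections. RMSF is measured about the time-average structure after one
superposition pass (align to frame 0, average, re-align to the average) —
the convention of the standard `rmsf` tools. RMSF defaults to Cα atoms
only; the selection is configurable since backbone-atom variants exist in
the field.

## Covariance, DCCM, contacts

The displacement covariance is `c(i,j) = ⟨Δr_i·Δr_j⟩` with
`Δr_i = r_i − ⟨r_i⟩`, a full 3-vector dot product, frames superposed onto
the iterated mean structure. The denominator is F, not F−1: the choice
cancels in the normalised matrix. The DCCM is the Pearson-style
normalisation `C(i,j) = c(i,j)/√(c(i,i)c(j,j))`; one occasionally sees the
normaliser misprinted with `c(i,j)` inside the square root, but the
expanded form `⟨Δr_i·Δr_j⟩/⟨Δr_i²⟩^{1/2}⟨Δr_j²⟩^{1/2}` is the intended and
implemented quantity. The diagonal is set to exactly 1 and a residue with
zero positional variance raises an error naming it, since it cannot be
normalised.

The contact matrix records the fraction of frames with pair distance below
a cutoff. The default measure is the smallest distance between heavy atoms
of the two residues (the `mdmat` smallest-distance convention) with a
10 Å cutoff — the literature rarely prints this value, so it is an explicit
config key, as is a Cα–Cα mode. Whether a contact map should encode
frequency or mean distance is genuinely ambiguous in parts of the
literature; frequency is primary here and the per-pair mean smallest
distance is carried alongside.

## PCA and free-energy landscape

PCA eigen-decomposes the 3n×3n Cartesian covariance of the selected Cα
atoms after superposition; eigenvalues are reported in Å² descending with
variance fractions and the PC1+PC2 cumulative fraction. Projections of the
centred frames onto all eigenvectors reconstruct the input to numerical
precision (tested), and the eigenvalue sum equals the covariance trace to
1e-8 relative.

The landscape is the Boltzmann inversion `G_b = −kT ln(P_b/P_max)` over a
B×B histogram of the PC1/PC2 projections (default B = 50, edges at the
data extrema, T = 300 K, output in kJ/mol or kT). The form printed in some
sources, "−kT + ln P", is dimensionally inconsistent; the implemented
normalised form reproduces the standard basin-depth maps and pins the
global minimum at exactly G = 0. Empty bins are unvisited (+inf), and G
depends only on probability ratios, so rescaling all counts is a no-op.

A caveat that matters for validation: a bin whose *expected* count is of
order one estimates G at the Poisson floor (roughly the log of the maximum
bin count) rather than at the true landscape value, so the rim of an
extrema-spanning grid is systematically biased low. The quadratic-landscape
check therefore grids over robust 0.1–99.9% quantiles with 12 bins per
axis, keeping every occupied bin populated enough for the inversion to be
calibrated; the default exploratory grid is unchanged.

## Residue graph and shortest-path map

Contacts gate edges and correlations weight them: edge (i,j) exists iff
freq(i,j) ≥ f_min and |C(i,j)| ≥ c_min, with weight `−ln|C(i,j)|`
(alternative `1−|C|` behind config). Strong coupling means short edges, so
minimum-weight paths are maximum-correlation communication routes; c_min
must be positive because |C| = 0 corresponds to infinite weight. Defaults —
f_min = 0.5, c_min = 0.05, importance threshold 0.3 — are explicit package
defaults standing in for thresholds the methodology literature leaves
unstated, and every run's manifest echoes them.

Edge importance is the exact number of co-optimal shortest paths crossing
the edge, summed over all node pairs: per-source Dijkstra distances plus a
path-count recursion (σ of a node is the sum of σ over its shortest-path
predecessors), with float ties detected at 1e-9 relative tolerance and
zero-weight ties broken deterministically by settle order. All co-optimal
paths are counted — not one representative — so the result is independent
of adjacency iteration order. Importance is normalised by its maximum;
edges at or above the threshold form the shortest-path map and their
endpoints, in ascending global index, are the hotspot residues. Ligand and
glycan residues are excluded from the graph by default. Whether
normalisation should be by maximum importance or by per-pair path counts is
an open convention; maximum-normalisation is used here.

Cross-system consensus intersects hotspot sets, optionally within a ±window
of global positions (window 0 is exact intersection); runs of
window-equivalent indices report their smallest member.

## Non-covalent interaction criteria

All detection is geometric, per frame:

| type | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor distance, D–H···A angle at the hydrogen | < 3.0 Å and > 150° |
| hydrophobic | Cα–Cα distance between hydrophobic residues, non-neighbours | < 4.0 Å |
| cation–π | min distance, aromatic ring atom to cationic N | < 6.0 Å |
| π–π | aromatic ring centroid distance | < 5.0 Å |

Donors/acceptors are N/O/S; a donor's hydrogens are resolved by covalent
distance (< 1.25 Å, same residue) and donors with no resolvable hydrogen
are skipped with a logged count. The 150° threshold names no vertex in
some method descriptions; it is interpreted as the standard D–H···A angle.
The Cα–Cα < 4 Å hydrophobic criterion is geometrically very restrictive
for non-bonded residues — it is implemented exactly as stated, with a
side-chain-carbon minimum-distance mode behind config for users who want
the more permissive convention. His rings count as aromatic but His is not
a cation by default (protonation unknown without explicit charges); Lys NZ
and Arg NE/NH1/NH2 are cations, and every ligand nitrogen is treated as a
potential cation (a deliberate simplification — ligand formal charges are
not perceived). Periodic boundary conditions are not applied; inputs are
assumed whole.

Occupancy of a type at a site is the percentage of frames with at least
one event of that type touching the site ("any event at site", the less
ambiguous of the two possible readings), with min/max/mean per-frame pair
counts over all frames including empty ones.

## Synthetic ensembles and ground truth

`generate_ensemble` draws per-frame Cα displacements from a multivariate
Gaussian with covariance `σ_i σ_j ρ_ij`, independently and identically per
Cartesian axis. Isotropy makes the ground truth analytic: the DCCM's
3-vector dot-product correlation equals the generating ρ in expectation
exactly. Defaults: σ = 0.5 Å per axis (Cα RMSF ≈ 0.87 Å, typical of a
folded core at 300 K), an ideal α-helical trace (2.3 Å radius, 1.5 Å rise,
100°/residue → 3.81 Å Cα spacing) as the compact self-avoiding base
geometry, 5000 frames for convergence-sensitive checks, one RNG stream per
call with a mandatory seed; identical specs produce byte-identical files.
Correlation inputs are eigenvalue-clipped at a relative floor of −1e-8
(measurement-grade matrices only) and rejected beyond it.

`generate_planted_path` builds the geometry of an allosteric conduit: two
helical lobes joined by the planted chain as an extended linker, so every
cross-lobe shortest path must traverse every chain edge — this is what
makes "the chain is the unique low-weight route" well-posed under all-pairs
traffic scoring. The linker spacing is 5.5 Å so that only consecutive
linker residues are in contact at the 10 Å cutoff; at physical 3.8 Å
spacing, second-neighbour contacts exist and the AR(1) correlation profile
makes one skip edge and two consecutive edges tie *exactly*
(−ln ρ² = 2(−ln ρ)), leaving the optimal route undefined up to sampling
noise. On-chain correlation follows AR(1) in chain distance (0.9 by
default, PSD by construction); all residues also receive weak
sequence-local coupling (AR(1), ρ = 0.5, range 4) so the lobes are
internally connected in the graph the way a real backbone is; random
off-chain pairs get correlations capped at 0.2. The overlaid matrix is
projected back to the PSD cone if needed.

Validations that compare recovered correlations against planted values
compute the covariance with superposition disabled: these ensembles
contain no rigid-body motion by construction, and the least-squares fit
would otherwise remove an O(1/n_res) share of the planted signal,
measuring the fit rather than the estimator. Superposition remains the
default in every pipeline entry point and is exercised separately by
rigid-motion invariance tests.

`generate_interaction_fixture` places minimal atom groups at an exactly
parameterised distance (and D–H···A angle for hydrogen bonds) so each
detector can be probed just inside and just outside its criterion.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analyses consume —
prescribed correlations, contact geometry, planted communication routes,
exact interaction geometries — but not protein physics: no force field, no
side-chain rotamers beyond what detectors need, no anisotropic or
time-correlated dynamics, no solvent, no conformational transitions
(ensembles are unimodal Gaussians, so synthetic free-energy landscapes have
a single basin). Passing tests therefore demonstrate that the estimators
and graph algorithms are correct and well-calibrated, not that any
biological conclusion about a specific system is reproduced. Applying the
pipeline to real trajectories additionally depends on simulation quality,
sampling convergence, and threshold choices that should be reported with
the results (the run manifest exists for exactly that purpose).

## Problem sizes used in the validation suite

Convergence-sensitive checks use 50 residues × 5000 frames (correlation
recovery), 30 residues × 5000 frames (pathway recovery), 50 000 samples
(landscape inversion), and ≤ 10-node graphs for exhaustive-enumeration
oracles — sizes at which the relevant sampling errors are an order of
magnitude below the tolerances being checked while the whole suite stays
interactive.
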