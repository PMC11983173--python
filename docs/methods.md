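# Methods

This note documents the models and procedures implemented in `bindmodes`,
the defaults chosen where the underlying protocol leaves them open, and
what the synthetic benchmark does and does not establish.

## Trajectory model and units

Coordinates are Angstrom, times picoseconds, energies kcal/mol; every file
format (PDB topology, DCD/XTC coordinates) is converted on read via
MDAnalysis. Frames are 0-indexed internally; reports print 1-based frame
numbers and simulation times. The storage interval is read from the
trajectory file and can be overridden; `sample_frames` decimates to the
nearest achievable multiple of it. Sampling stride is deliberately a
configuration parameter with the native storage interval as default: a
production protocol may store coordinates at one interval (e.g. 0.1 ns)
and decorrelate at another (e.g. 10 ps), and the two need not be conflated
by the analysis code.

Selections use a small grammar (`backbone`, `ligand`, `protein`, `resid`
ranges, `name`/`resname`/`chain` sets, and/or/not, parentheses). The
backbone is the explicit atom-name list N, CA, C, O on protein residues.

## Geometry

**Superposition** is the closed-form Kabsch solution (SVD of the
covariance with a determinant correction to exclude reflections). Inputs
with fewer than three atoms or a collinear point cloud are rejected —
the optimal rotation is not unique there.

**RMSD conventions.** Ligand RMSD fits the protein backbone and measures
the ligand without re-fitting, so ligand motion relative to the receptor
is not absorbed by the fit. No symmetry correction is applied to ligand
atom mapping. **RMSF** aligns all frames to frame 0, forms the
time-averaged structure, re-aligns onto that mean (one iteration) and
reports per-atom root-mean-square displacement about the mean position;
per-residue values average over each residue's selected atoms. Note that
superposition absorbs six rigid-body degrees of freedom, biasing RMSF low
by a factor ≈ √(1 − 2/N) for N fitted atoms — negligible for protein-sized
selections.

**SASA** is Shrake–Rupley with Bondi van der Waals radii, probe 1.4 Å and
960 golden-spiral sphere points — standard settings. Coincident spheres
count their shared surface once. Accuracy at these settings is ~0.3 %
against the exact two-sphere cap formula.

## Hydrogen bonds and salt bridges

A donor–acceptor pair (N/O heavy atoms; donors carry a bonded hydrogen) is
bonded in a frame when the heavy-atom distance is ≤ 3.5 Å and the
donor–H–acceptor angle is ≥ 150° for some hydrogen on the donor — the
widely used geometric criterion of MD analysis toolkits. Salt bridges
(Arg/Lys/His side-chain N against Glu/Asp side-chain O) use a plain
N···O ≤ 4.0 Å criterion and are tracked as a separate interaction class
through the same occupancy machinery.

Occupancy is aggregated at the residue-pair level (a pair is present when
any of its atom pairs qualifies) because the scientifically meaningful
unit — and the format of cross-system comparison tables — is the residue
pair (e.g. R357−E460). Salt-bridge keys are canonically sorted so the pair
is direction-free. The stability threshold defaults to 60 % and is
*inclusive* (≥ 60 %); it is a parameter, not a constant. Occupancies below
the threshold are tracked continuously and only filtered at
classification/comparison time, so sub-threshold values remain reportable.
Cross-system comparison reports the shared stable core, per-system
differential sets, and "NOB" (not observed) for pairs a system never
exhibits.

## Binding-mode clustering

Feature columns: one ligand-COM-to-residue-COM distance per named residue,
plus backbone RMSD, ligand RMSD and interacting-residue RMSD, all relative
to the initial frame. Which residues go into the distance and
interacting-residue sets is system knowledge and must be named explicitly
per run; there is no automatic feature selection. Standardization uses the
population (n) denominator; constant columns are dropped with a warning
rather than divided by zero.

PCA retains the minimal component count whose cumulative explained
variance reaches the target fraction (default 0.90). Since the features
are standardized this is correlation-matrix PCA. Component signs are fixed
(largest-magnitude loading positive) for reproducibility.

K-means++ runs with `n_init = 10` restarts per k (best by WSS), k from 2
to 10, a fixed seed, and empty-cluster refits logged. The cluster-count
vote: SI, DI and pSF vote for their argmax over k; WSS votes for the elbow,
operationalized as the largest positive second difference of WSS(k) — the
discrete analogue of "the change in slope". A k with ≥ 3 votes wins;
otherwise the k with most votes, ties broken toward smaller k (parsimony).
The decision path (every criterion's vote) is part of the returned model.

W % is the rounded percentage of frames per cluster, reported in
descending order; rounded values may not sum to exactly 100, so the exact
fractions are kept internally and used for energy weighting. The centroid
frame of a cluster is the sampled frame whose reduced-space coordinates
are nearest (Euclidean) to the cluster mean — a real structure, exportable
as PDB, not a synthetic average.

## Energetics

The package never computes MM-GBSA/DFT/ANI energies; scorers are external
and their outputs enter as per-structure CSV tables. The difference form
ΔG_b = ΔG_complex − ΔG_ligand − ΔG_receptor and the linear combiner
α·ΔG_DFT + β·ΔG_ANI + γ are exact arithmetic; α/β/γ default to (1, 0, 0)
and require a provenance note, since meaningful values come from an
external optimization. The cluster-weighted mean uses exact cluster
fractions, renormalized to sum to one. More negative means stronger
binding; reports sort ascending.

## Free-energy surfaces

Grids are 1-D or 2-D with uniform spacing, normalized to min = 0.
`fes_from_hills` sums the deposited Gaussians and negates; with a
well-tempered bias factor γ the estimate is scaled by γ/(γ−1), the
long-time relation between accumulated bias and free energy. The bias
factor is never assumed — it must be supplied when scaling is wanted.
Replica averaging is a cell-wise mean followed by re-normalization;
engine-exported grids are accepted directly via CSV.

Minima are basins of topographic prominence ≥ `depth_cut` (default
0.5 kcal/mol), found by watershed flooding; plateau ties resolve
canonically so a flat-bottomed well yields one minimum. Labels A, B, C, …
follow depth order (global minimum first) — basin labeling carries no
other semantics. Convergence diagnostics window the hill heights (default
50 hills/window) and report a Kendall-type pairwise sign score in [−1, 1]
(strictly decreasing → −1) plus a `converging` flag when the last window's
mean height falls below half the first window's.

## Synthetic benchmark

The generator emulates the statistical structure the clustering protocol
assumes: a rigid helical receptor (5 backbone atoms per residue plus
side-chain donor/acceptor groups where scheduled), a rigid chain ligand
occupying one of up to five planted poses stepped along the
receptor–ligand axis (adjacent anchors exactly `mode_separation` = 5 Å
apart by default), and an induced-fit "lid" — the last quarter of the
receptor shifts with the binding mode (0.6·separation per mode index) so
the RMSD descriptor families carry mode information, as they do in real
binding-mode transitions.

Mode dwell times are ≥ 10 frames (quota-based blocks, shuffled), so modes
are contiguous metastable episodes rather than i.i.d. shuffles, and the
planted 61/23/16 frame split is reproduced exactly up to rounding.
Scheduled H-bonds toggle the acceptor between 2.9 Å/180° (inside the
criterion) and 5 Å (outside) with an exact-count frame mask, so target
occupancies are met to within one frame.

Thermal noise is AR(1)-correlated between frames (ρ = 0.7) with a slowly
wandering global amplitude (±35 %, AR(1) ρ = 0.95). Both features mimic
real trajectories sampled a few correlation times apart: uncorrelated
jitter would make the RMSD-to-initial-frame distribution collapse onto a
razor-thin plateau, turning the reference frame into an extreme
feature-space outlier that no real trajectory exhibits. Defaults give a
mode separation ≳ 5× the within-mode feature spread, the regime in which
end-to-end recovery (correct k, ARI ≥ 0.9) is the designed guarantee.

What passing these tests does **not** show: the generator has no force
field, solvent, realistic stereochemistry or overlapping mode basins, so
recovery here does not certify performance on marginally separated or
hierarchically structured binding modes in real data.

The double-well walker (overdamped Langevin, quartic well, barrier
3 kcal/mol, kT = 0.596 kcal/mol) deposits hills of initial height
0.4 kcal/mol every 100 steps with width 0.2 Å and well-tempered decay
(γ = 6); it supplies the analytic surface as oracle. Barrier recovery is
reliable to well within 15 % at the default 600 hills.

## Problem sizes and tolerances

Default verification sizes: 1000-frame / ~66-atom systems for end-to-end
recovery (10 seeds), 100 random 5-atom pairs for the superposition oracle
(tolerance 1e-3 Å against a rotation-search oracle), 960 sphere points for
SASA (2 % single-sphere, 3 % dimer), 60 000 walker steps / 600 hills for
the FES oracle (15 % barrier tolerance). Index arithmetic (silhouette,
Dunn, pseudo-F, WSS) is checked to 1e-9 on a four-point configuration;
energy combiners to 1e-9 kcal/mol. These sizes keep the full verification
run in the tens of seconds while leaving every tolerance comfortably met.

## Known limitations

- No periodic-boundary imaging: trajectories are assumed whole-molecule.
- Pairwise RMSD is O(n²) superpositions — fine for thousands of sampled
  frames, not for hundreds of thousands.
- H-bond detection requires explicit hydrogens; topologies without them
  are rejected rather than guessed.
- 2-D FES minima use 8-connected neighborhoods; no sub-grid interpolation
  of minimum positions.
- The vote among validation indices inherits their known biases (e.g. the
  pseudo-F can rise monotonically on very tight, low-dimensional
  clusters); the 3-of-4 rule plus the WSS elbow is what makes the
  selection robust, and the per-criterion votes are always reported.
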