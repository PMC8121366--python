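# Methods

This note records the models, conventions and numerical choices behind each
component, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible convention exists.

## Structure model and I/O

Structures are a plain chains → residues → atoms hierarchy with coordinates
in Å and author numbering kept untouched (reports refer to author residue
numbers, e.g. Ser79). Parsing and writing go through gemmi; the first model
of a file is used (no NMR ensemble averaging). Alternate locations are
collapsed at read time to the highest-occupancy conformer, ties broken by
the lexicographically first altloc — the common convention for deposited
X-ray entries. Hydrogens are kept in the model but excluded by default from
SASA and RMSD, since deposited crystal structures carry them inconsistently.

Biological assemblies are built by applying the deposited (BIOMT/assembly)
operators; no operators are derived from space-group symbols. Image chains
are renamed deterministically as `<chain id><operator index>` so interface
reports are reproducible regardless of whether a dimer is present in the
asymmetric unit or generated by a crystallographic two-fold — the assembly
builder handles either case without hard-coding.

Per-residue scores (e.g. conservation) are written into the PDB B-factor
column, clamped to its printable range [0, 999.99], with a sentinel
(default 0.00) for unscored residues. The column stores two decimals, so
scores round-trip to 0.01.

## Superposition and alignment

Superposition is the Kabsch least-squares fit: SVD of the weighted
covariance of centered point sets, with the sign of the smallest singular
value flipped when needed so only proper rotations are returned. Collinear
point sets are rejected (the rotation about the common axis is undefined).
"All-atom" RMSD means all shared heavy atoms of paired residues — hydrogens
excluded, altlocs resolved — because deposited entries do not support a
better-defined atom set. Cα RMSD is reported after the same all-atom fit.

Residue pairing uses either identical author numbers or the aligned columns
of a global sequence alignment. The aligner follows the EMBOSS Needle
conventions: BLOSUM62, gap open 10.0, gap extend 0.5, terminal gaps
penalized, a gap of length L costing `open + L·extend`, and percent
identity computed over the full alignment length (not the shorter
sequence). Remote capsid-domain homologies therefore land in the 10–20%
range typical of server output. The implementation delegates the dynamic
programming to Biopython's `PairwiseAligner` (with the open/extend scores
transformed to its first-position/continuation convention); tests verify
the scores against explicit enumeration of all gapped alignments of short
sequences.

## Surface areas and contacts

SASA uses the Shrake–Rupley method with a deterministic Fibonacci lattice
(default 960 points/atom; doubling the count changes areas by < 1%), probe
radius 1.4 Å, and the fixed heavy-atom radii C 1.70, N 1.55, O 1.52,
S 1.80 Å (Se 1.90, P 1.80); unknown elements fall back to 1.80 Å with a
warning. Neighbour occlusion is found with a k-d tree.

Buried surface area of a two-part complex is
`BSA_total = SASA(A) + SASA(B) − SASA(AB)`, which counts both faces; the
one-face "interface area" (what PISA-style servers print) is half of it.
Both are reported because published totals are quoted in either
convention. Interface residues are those losing more than 0.1 Ų of SASA
upon complexation.

Contacts are classified by distance only — deposited entries lack
hydrogens, so angle-aware criteria would require hydrogen placement and
break determinism. Inter-part N/O pairs within 3.5 Å count as hydrogen
bonds unless the pair belongs to the charged-group sets (Lys NZ,
Arg NE/NH1/NH2, His ND1/NE2 against Asp OD1/OD2, Glu OE1/OE2) within
4.0 Å, which are salt bridges; salt bridges take precedence so no pair is
double-counted. Carbon–carbon pairs within 4.0 Å are counted as nonpolar
contacts (π-π geometry is not detected separately). All cutoffs are
configurable; published hydrogen-bond counts from angle-aware tools may
require sweeping the H-bond cutoff over ~3.2–3.9 Å to reproduce, which
should be documented by the user rather than silently adopted.

## Helix axes and crossing angles

A helix axis is the principal eigenvector of the covariance of the
segment's Cα coordinates, through their centroid, sign-oriented from the
first to the last residue (N→C). The crossing angle is the angle between
two directed axes in [0°, 180°], so an obtuse packing (e.g. ~140°) is
distinguished from its supplement. The principal-component fit assumes a
straight helix; `fit_rms` (RMS perpendicular Cα distance, ~2.3 Å for an
ideal helix) is reported so kinked helices — e.g. a fused helix that bends
at a turn residue — can be detected and split before fitting. A local-axis
(per-turn) method was deliberately not used: for the long helices this
package targets, the PCA axis is adequate and easier to diagnose.

## Small-angle scattering

Model intensities use the Debye equation over point scatterers with the
q→0 limit handled analytically; granularity is either per heavy atom
(f = element electron count) or one center per residue at the Cα
(f = residue electron count) for large structures. No hydration shell or
excluded-volume correction is applied — curves are for shape-level
comparison and scale fitting, not absolute-scale prediction.

Rg is the second moment of the coordinate distribution (uniform or
mass-weighted). P(r) is the direct histogram of all pairwise distances
normalized to unit area (indirect Fourier inversion of I(q) is out of
scope); Dmax is the maximum pairwise distance, and the P(r) second moment
reproduces the coordinate Rg to ~2% at 1 Å bins. The Guinier fit is an
iterative linear fit of ln I vs q² on the largest low-q window with
q·Rg ≤ 1.3, erroring on non-decaying data. Model-to-data fitting solves
weighted linear least squares for a scale and optional constant background
and reports reduced χ². Internally everything is in Å; the reporting layer
also prints nm for solution-scattering summaries.

## Conservation pipeline

Pairwise distances are p-distances on the supplied alignment: 1 minus the
fraction of identical residues over mutually ungapped columns (pairs with
no comparable columns get distance 1.0 with a warning). This is a stand-in
for aligner-internal distance matrices, which have no published closed
form; for redundancy pruning only the ranking of small distances matters.

Pruning visits pairs in ascending distance (ties by lexicographic id pair)
and, while more than the target number survive, removes one member of each
still-intact pair. The removed member is the one with the smaller mean
distance to the other survivors — keeping outliers gives the most even
spread of sequences; ties remove the later input row, so exact duplicates
lose their second copy. Survivors keep input order and the result is
deterministic.

Column entropy is Shannon entropy in base 20, `S = −Σ pᵢ log₂₀ pᵢ`, over
the 20 standard residues; S ∈ [0, 1] with 0 = fully conserved and 1 = all
residues equally frequent, so larger S means more variable. (The sign is
chosen so S is non-negative; the base makes the fully-variable column
exactly 1.) Gaps and ambiguity codes (X/B/Z) are excluded and frequencies
renormalized rather than treated as a 21st symbol — absolute S values
therefore depend on this gap policy, which is why gap fractions are
reported per column and columns over 50% gaps are flagged (still
computed). A column with no standard residue gets S = NaN and a flag, not
an exception. Homologue retrieval is out of scope; the e-value thresholds
typical input sets were collected with (1e-10 single-pass; staged
1e-20/1e-10/1e-8 for iterative searches) ship as documented constants.

Mapping entropy onto a structure aligns the ungapped reference row to the
chain sequence (EMBOSS-convention global alignment, ≥ 80% identity required
by default) and writes each residue's column entropy into the B-factor
column, so the profile can be rendered as structure colouring.

## Oligomeric-state calling

The monomer mass is the sum of average-isotopic residue masses plus one
water (no modifications), in kDa. Envelope-volume masses use
MM [Da] = V [ų] / 1.21, the conventional bead-model packing density, with
the divisor configurable.

The consensus state pools the mass/monomer ratios of all estimates with a
Huber M-estimator of location (tuning constant 1.345, MAD scale, median
fallback for degenerate scale) and rounds to the nearest integer in
[1, max_states]. The design question is what should happen when one
estimate disagrees: mass panels for the same species routinely spread by
10–30% across techniques, and a plain mean of ratios lets a single outlier
pull the call to the wrong integer — e.g. a panel with ratios
(2.39, 2.28, 2.93) has a mean relative deviation that is actually smaller
at k = 3 than at k = 2, although two of three estimates clearly say dimer.
A robust pooled location behaves like the mean on concordant panels
(retaining the pooling needed to average down noise) and like the median
against an outlier, and calls that panel a dimer. Per-estimate nearest
states are always reported next to the consensus; the call is flagged
ambiguous when no estimate's own nearest state matches the consensus or
when a supporting estimate deviates from the consensus mass by more than
25% (configurable). The call is scale invariant.

The recovery study (`simulate_state_recovery`) draws panels of 5 estimates
with 8% multiplicative Gaussian noise per replicate. Five estimates is the
panel size used because the rounding boundary at k = 6 lies at ~1σ of a
single estimate: one estimate is misrounded ~30% of the time, three pooled
estimates still leave a ~7% error floor even for an optimal estimator, and
five put the pooled boundary past 2σ so recovery clears 95% for all states
up to hexamer.

## Synthetic generators

The generators produce the idealized inputs the estimators are tested on;
all take a mandatory seed and are bit-reproducible.

- Helices are Cα traces on an ideal cylinder (rise 1.5 Å/residue, twist
  100°/residue, radius 2.3 Å); dimers place a rotated copy at a prescribed
  axis separation and crossing angle and record the ground truth. They
  carry no side chains, so interface fixtures bury hundreds (not
  thousands) of Ų and contact-classification fixtures are built from
  explicitly placed N/O/C atoms instead.
- Synthetic alignments draw each column from the smallest residue mixture
  whose expected log₂₀ entropy equals the target (two residue types up to
  S ≈ 0.231, more types above), optionally with per-column gap fractions
  and redundancy clusters of point-mutated founder copies emulating the
  near-duplicates a database search returns. Cluster mutations add real
  variability, so measured entropy matches targets only for the
  no-redundancy case.
- Synthetic curves are Debye intensities with multiplicative Gaussian
  noise and σ = noise·I.

Passing tests on these fixtures demonstrates correctness of the estimators
under their stated models (rigid bodies, straight helices, independent
columns, Gaussian noise), not performance on real data with conformational
heterogeneity, hydration effects, or phylogenetic correlation.

## Problem sizes and tolerances

The test and reproduction runs use desk-scale inputs chosen to make the
statistical assertions sharp: 20-residue helices, 40–60-sequence
alignments, 500–4000-point sphere clouds, 400-point q grids, 1000
replicates per state for recovery rates, and a 1° global / 0.1° local
rotational grid for the superposition oracle. Numerical tolerances follow
the estimator's discretization: 1% for 960-point SASA closed forms, 1e-3 Å
for Kabsch vs grid search, 2–3% for Rg recovery, 1° for crossing angles.

## Known limitations

- Distance-only contact criteria overcount hydrogen bonds relative to
  angle-aware tools on some interfaces; counts should be compared under a
  stated cutoff.
- The PCA helix axis is biased for strongly kinked segments; use fit_rms
  to detect and split them.
- Debye curves ignore hydration; absolute I(0) comparisons across models
  with different granularity are not meaningful.
- p-distance pruning is a documented stand-in for aligner-internal
  distances; survivor sets may differ from pipelines using those.
- The entropy scale depends on the exclude-and-renormalize gap policy;
  profiles computed with a 21-symbol convention are not comparable.
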