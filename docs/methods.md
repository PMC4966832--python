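# Methods

This note records the models, numerical choices and open design decisions
behind cdrclust, and what the synthetic fixtures do and do not demonstrate.

## CDR definition and extraction

Loops are delimited in Chothia numbering: L1 24–34, L2 50–56, L3 89–97,
H1 26–32, H2 50–56 (the Chothia H2 pre-extended by two N-terminal
residues, which measurably improves sequence-based class prediction),
H3 95–102. Numbering is taken from the input files (the SAbDab-style
Chothia dialect, where insertion codes such as 30A are meaningful); no
numbering software is embedded, and un-numbered PDBs will simply fail the
range checks. The backbone atom set is {N, CA, C, O}; anchors are the five
residues immediately adjacent in chain order on each side of the loop.

Parsing is done directly over ATOM records rather than through a generic
PDB library: the extraction contract needs per-atom B-factors,
occupancy-resolved alternate locations (highest occupancy wins, ties going
to altloc 'A'), insertion-code ordering, parse errors that name the
offending line, and exact text round-trips, all of which are simpler to
guarantee over the raw records.

Quality filters: X-ray structures only; resolution ≤ 2.80 Å (the boundary
value is kept — the removal rule is "above 2.8"); complete backbone in
loop and anchors; every backbone B-factor b with 0 < b ≤ 80. The B-factor
rule is applied over loop *and* anchor backbone by default
(`include_anchor_bfactors=False` restricts it to the loop; the scope over
anchors is ambiguous in the literature, so it is a switch). Identical
sequences are deliberately not deduplicated: the same CDR sequence
crystallised repeatedly can adopt conformations more than 1.5 Å apart, and
removing redundancy would both hide that and bias medoids.

## Anchor superposition

Each loop is fitted once, by its 40 anchor backbone atoms, onto a single
per-CDR-type reference frame (least-squares rigid Kabsch fit, reflections
excluded; near-collinear anchor sets raise a degeneracy error because the
rotation about the line is unconstrained). The default reference is the
medoid anchor set — the loop whose anchors have the smallest summed fit
RMSD to all others; `first` and `mean` modes exist for small or controlled
inputs (`mean` averages coordinates as given and assumes a shared frame).
Superposing anchors rather than loops preserves each loop's orientation
relative to the framework, which is the geometrically meaningful
comparison for loops of different length. Whether published distances were
computed under a common frame or per-pair superposition is not knowable
from the text; the common frame is the default and a per-pair mode can be
emulated by fitting pairs with `mode="first"`.

## DTW structural distance

For superposed loops A (length n) and B (length m), the residue-pair cost
is the summed squared distance over the four backbone atoms. The
cumulative table D(i,j) = cost(i,j) + min(D(i−1,j−1), D(i−1,j), D(i,j−1))
with D(0,0) = cost(0,0) is the classic three-step DTW (no gap states:
every residue of both loops is matched at least once, the path runs from
(0,0) to (n−1,m−1)). Backtracking ties prefer the diagonal, then the step
in the longer loop. The reported score is the pooled RMSD over all matched
atom pairs, sqrt(Σ d² / 4·|path|); atoms matched many-to-one are counted
once per pair (no de-duplication in the denominator — a duplicated
residue genuinely participates in two matches). Equal lengths force the
diagonal, so the score reduces exactly to plain backbone RMSD. The measure
is symmetric and non-negative but not a metric (no triangle inequality is
claimed or used). The DP is verified against exhaustive path enumeration
for loops of ≤ 5 residues, and the whole construction is invariant (to
1e-6 Å) under arbitrary rigid pre-transforms of the inputs.

The structural insertion site of a cross-length pair is the residue(s) of
the longer loop matched many-to-one on the optimal path; its offset from
the declared Chothia insertion index measures whether the numbering scheme
places insertions where the geometry does.

## Clustering

Stage one is UPGMA (average linkage) on the precomputed DTW matrix, cut at
a cophenetic height of 1.5 Å; every loop is assigned. Stage two re-clusters
a cluster with DBSCAN only when it has more than 6 unique sequences *and*
fails both prediction gates (precision < 0.75 and recall < 0.25; an OR
mode is configurable). The 6-sequence gate uses "more than 6" while the
large-cluster report uses "at least 6", following the two source rules
literally. DBSCAN runs on the sub-matrix with a per-CDR-type radius
(L1 0.82 Å, L3 0.91 Å, H1 0.80 Å, H2 0.63 Å; L2 none — for L2 the UPGMA
stage is considered sufficient and no re-clustering occurs); `min_pts`
defaults to 3, the smallest value for which a core point is meaningful.
When no radius is configured, it can be chosen from the OPTICS
reachability profile: eps is placed at the largest drop in the sorted
reachability values — a deliberately simple heuristic, always overridable
by configuration. DBSCAN iterates points in id order, making border-point
assignment (first discovered core wins) deterministic.

Kappa and lambda light chains are clustered jointly; chain-class
composition is a reporting concern, not a pre-split. Cluster names are
`<type>-<lengths>-<letter>` with letters ranked within a length signature
by number of structures, then unique sequences; the summary table orders
clusters by length, then size. Medoids minimise the summed DTW distance to
the rest of the cluster, ties resolved lexicographically.

## Profile HMMs and prediction

Cluster sequences are aligned by Chothia position: columns are the
numbering-ordered union of (position, insertion code) labels in the
cluster, each sequence occupying its own positions with gaps elsewhere.
This replaces an aligner's internal heuristics with an explicit, testable
rule and makes mixed-length clusters well-defined (an insertion-code
column is gapped in the rows that lack it).

The HMM is a global match/insert/delete architecture — CDRs are scored end
to end, with no local-alignment or flanking states. Match emissions are
Laplace-smoothed column counts, (c + 1)/(n + 20) by default (the
pseudocount is configurable). Transition probabilities are counted from
the implied match/delete paths with a smaller pseudocount (0.1); insert
states are never observed in training (insertions are columns here), so
they keep uniform emissions and a fixed 0.1 extension probability. The
forward algorithm is computed in log space and verified against brute-force
path enumeration on toy models. Scores are natural-log likelihood
differences against a background model of identical architecture trained
on all out-of-cluster sequences of the CDR type — a "raw" log-odds against
an empirical background rather than a fixed residue composition. A
re-implementation was chosen over wrapping HMMER because the published
procedure required modifying HMMER's source to expose raw likelihoods;
pyhmmer serves as an independent ranking cross-check in the test suite,
never as the scorer.

Classification is one-vs-all among clusters containing at least one
training sequence of the query's length; ties go to the larger cluster.
The length-dependent comparison mode uses the same rule on the
length-split cluster set, so the two modes coincide whenever no cluster
spans multiple lengths. Leave-one-out cross-validation removes duplicate
sequences per cluster, then repeatedly holds out one random unclassified
sequence per cluster (seeded generator), retrains all models without the
held-out set, and classifies; a cluster reduced to a single unique
sequence is scored against the others only, and this is logged. ROC curves
macro-average per-cluster TPR/FPR over all observed score thresholds;
clusters without positives or negatives are excluded from the mean at that
sweep and logged. AUC comparison bootstraps the (FPR, TPR) point sets
(1,000 replicates by default) and uses a normal approximation for the
p-value.

## Calibration and repertoire classification

Expected precision as a function of the score threshold is estimated from
the cross-validation records pooled per CDR type (the single precision
axis used for repertoire work implies one global scale; per-cluster
calibration would also be computable but is not the default), then made
monotone by isotonic regression and interpolated linearly between observed
thresholds. Requested precisions above the calibration support yield no
assignments and a warning. Repertoires are deduplicated before counting;
raising the precision level can only shrink the assigned set.

A caveat the synthetic experiments surfaced: pooled calibration sets one
global threshold per mode, so comparing modes assumes their score scales
are comparable. When a length-split cluster's twin (same motif, other
length) remains in the background set, its log-odds shrink and the pooled
threshold moves; the mode comparison is therefore run with both modes
calibrated on their own cross-validation records.

## Synthetic fixtures

Loop families are smooth sine-bulge arcs between two fixed anchor
stretches shared by all families (the anchor trace carries a helical
wobble off its axis — a near-collinear anchor set would leave the rigid
fit rotationally unconstrained and noise would be amplified through the
lever arm of the loop). Families differ in bulge height and direction
(≥ 3 Å apart by construction; a warning fires if noise could bridge the
gap). Members are the base backbone plus iid Gaussian coordinate noise
(default sd 0.2 Å, roughly the coordinate uncertainty of a good crystal
structure); a configurable fraction carry one extra residue interpolated
locally into the arc, so a family spans two lengths while keeping its
shape — the planted analogue of a length-variable canonical class.
Sequences follow per-family motifs with per-position mutation (default
rate 0.05, enough variation to be realistic while keeping families
separable), wildcard positions and background sequences uniform over the
20 amino acids. All generators are seeded; there is no hidden global
randomness.

What passing tests show: the pipeline's machinery — superposition, DTW,
clustering, HMM scoring, calibration — behaves correctly on data whose
truth is known, including the headline case of a family spanning two
lengths being recovered as one cluster and yielding more assignable
repertoire sequences than its length-split counterpart. What they do not
show: real loops are not noisy arcs (no Ramachandran validity, no
physical minimisation), real sequence families are not iid-mutated motifs,
and real structural datasets carry redundancy and chain-class imbalances
the generator only mimics qualitatively. Quantities tied to a specific
historical structure snapshot (cluster tables, dataset-level fractions,
absolute assignment counts) are out of reach by construction and are not
claimed.

## Problem sizes

The default test and acceptance runs use three loop families of 8–10
members (26 loops, one family spanning lengths 11/12), three sequence
families of 20–30 members, and repertoires of ~240 sequences — sizes
chosen so planted separations (≥ 3 Å between arcs, mutation rate 0.05)
are comfortably resolvable and every run completes in seconds on one CPU.

## Known limitations

- The OPTICS eps heuristic (largest reachability drop) is one of several
  defensible extraction rules; configured radii always take precedence.
- Worked-example checks against published distances for named PDB entries
  require fetching Chothia-numbered structures at run time; no structure
  data is bundled.
- The CLI `classify` command trusts the model directory's sidecar metadata
  for training lengths; retrain rather than hand-edit models.
- Insert-state parameters of the profile HMM are priors, not estimates —
  with Chothia-position columns, training data never exercises inserts;
  queries of unseen greater length pay the fixed insert penalty.
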