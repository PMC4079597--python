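# Methods

This note documents the models, decision rules, numerical choices and
known limitations of `barcodegap`, in the spirit of the methods
documentation of established scientific Python packages.

## Scope and design

The package implements a distance-based barcode-gap workflow for
single-locus (COI-5P) species screening: K2P distances → neighbour
joining → reciprocal monophyly → per-taxon gap statistics at two
geographic scopes → threshold flagging of candidate splits and lumps →
evidence-based CCS/DCL resolution, plus diagnostic-site analysis of a
second (nuclear) alignment and a calibrated sequence simulator.  It
deliberately excludes model-based delimitation (GMYC/PTP), BIN-style
refined clustering, alignment computation, parsimony/likelihood tree
search, and any network access.

The computational stages are exposed both as functions (one per
operation) and as scikit-learn-style estimators (`K2PDistance`,
`NeighborJoining`, `BarcodeGapDelimiter`) so they compose with standard
tooling; `analyze` and the `barcodegap` CLI orchestrate the two-scope
survey run.

## Distance model

K2P (Kimura two-parameter) distance with pairwise deletion:

* Comparable sites for a pair are the positions where **both** sequences
  carry an unambiguous base (A/C/G/T).  Gaps, N and IUPAC ambiguity
  codes are treated as missing at that site for that pair; ambiguity
  codes do, however, count toward a record's informative length in the
  quality filter, because they are real base calls.
* d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), with P and Q the transition and
  transversion proportions.  When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the distance
  is undefined (saturation); such pairs are masked with the reason
  logged, never silently zeroed.
* `min_overlap` (default 300 comparable sites, half the standard
  658-base barcode) guards against distances estimated from tiny
  overlaps; more than 50% undefined pairs in a matrix is treated as a
  data problem and raised.
* Distances are stored as proportions (substitutions/site) and rendered
  as percentages with two decimals in every report.

The quality filter keeps records **strictly longer than** 500
informative sites by default.  The cutoff is applied to unaligned
(informative) length, not aligned length — the conservative reading for
gappy alignments — and is configurable.

## Trees and monophyly

Neighbour joining is the canonical Q-criterion agglomeration
(Q(i,j) = (n−2)d(i,j) − R_i − R_j) with the standard branch-length
formulas.  Two details are pinned down for reproducibility:

* ties on Q are broken by the lowest (row, column) index pair, so the
  output is deterministic for a given input order (and, absent ties,
  invariant under permutation);
* negative intermediate branch lengths are clamped to zero with the
  deficit moved to the sibling branch, so downstream logic always sees
  non-negative lengths.  On additive matrices NJ reproduces the
  generating topology exactly and its path lengths to 1e-9 (verified
  against randomly generated weighted trees and cross-checked against
  scikit-bio's and R ape's independent NJ implementations).

Trees are dendropy objects, stored arbitrarily rooted but treated as
unrooted: a taxon set is *reciprocally monophyletic* iff some edge
bipartition has one side exactly equal to it (either side of the edge —
the complement counts).  Singletons and the full tip set are
monophyletic by convention.

## Decision rules

With the operational threshold t (default 2%, strict inequalities on
both sides, following the "more than 2% divergence" convention of
Lepidoptera barcode surveys):

* **Split candidate**: δ > t and the species contains ≥ 2 reciprocally
  monophyletic clusters separated by more than t.  Clusters are
  single-linkage components of the ≤ t graph on the species' specimens.
  Because the criterion is an existential statement about cluster
  structure, the rule additionally searches coarser single-linkage cut
  levels ≥ t for the finest partition whose groups are all
  monophyletic: at a low threshold a tight cluster can fragment into
  chained, non-monophyletic pieces, and without the search a genuine
  deep split would paradoxically *lose* its flag as the threshold is
  lowered.  With the search, decreasing t never removes a split flag
  (monotonicity), and whenever the partition at t itself qualifies the
  two rules agree.  Between-cluster divergence is summarized by the
  minimum (used for the qualifying rule — a qualifying split has a
  genuine gap) and the maximum (for transparency).
* **Lump candidate**: Δsp < t.  Lump candidates carry no CCS/DCL
  resolution — their causes (misidentification, overlooked synonymy,
  introgression, mitogenome replacement) require case-by-case study —
  and are reported with every partner taxon within t.
* **CCS/DCL**: one positive line of independent evidence (morphology
  distinct, or a nuclear diagnostic difference) confirms a split (CCS);
  two explicit negatives demote it (DCL); anything else is unresolved.
  A disjunction is used for confirmation because either line alone is
  accepted in practice.
* **Watch list**: taxa with δ in [1%, t] that do not qualify as splits
  are marked report-only, since shallow clusters deserve attention when
  they match an existing taxonomic division.  There is no formal rule
  here; the band's lower edge is configurable.

Per-taxon statistics: for N ≥ 2 specimens in scope, δ = max, d̄ = mean
and sd over all N(N−1)/2 intraspecific pairwise distances; taxa with
N < 2 are reported N/A.  The sd is by default the population standard
deviation of the pairwise distances ("pair" mode); a standard error of
the mean mode ("sem") is available, since survey tables rarely state
which dispersion they print.  Within-species and within-genus grand
means are pair-weighted by default, with a taxon-weighted mode behind a
switch.  Δsp ties are broken alphabetically and logged.

## Diagnostic sites

A position of the nuclear alignment is diagnostic between two specimen
groups iff, among records with an unambiguous base there, within-group
states are uniform and the two groups' states are disjoint.  The strict
default (`allow_missing_fraction = 0`) also requires no missing data in
either group at that site — "diagnostic substitution" in the classical
fixed-difference sense.  Coordinates are 1-based on the provided
alignment and are therefore alignment-relative, not portable across
alignments.

## Simulator

The generator emulates the statistical structure the analysis assumes,
not real genealogies:

* **Substitution process**: sites evolve independently under K2P with
  closed-form transition probabilities — transition rate α = κ/(κ+2),
  per-transversion rate β = 1/(κ+2), so a branch length is the expected
  number of substitutions per site.  κ defaults to 4, a typical insect
  mitochondrial transition bias.  Base frequencies are equal (the K2P
  assumption), so the distance estimator downstream inverts exactly the
  generating process.
* **Design**: a star phylogeny — species roots radiate from a common
  ancestor at half the target between-species divergence (default 8%),
  specimens radiate from their species root at half the target
  within-species divergence (default 0.5%) — giving direct control of
  expected pairwise distances, which is what the analysis consumes.
  Planted splits place two sub-roots (split − intra)/2 apart around the
  species root so the expected between-subcluster distance equals the
  configured split divergence once tip branches are added; planted
  lumps emit one cluster under two species names; a stated fraction of
  records is truncated below the length-filter cutoff; region labels
  support two-scope analyses.  Defaults (8 species × 8 specimens,
  658 sites, intra 0.5%, inter 8%) mirror the divergence regimes of
  real continental barcode surveys: intraspecific means mostly below
  1%, candidate splits at 2–10%.
* A fixed seed reproduces the dataset byte-for-byte.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: coalescent genealogy shape and incomplete
lineage sorting, rate variation among sites and lineages, unequal base
composition, indel/alignment error, sequencing error, geographic
population structure within species, and uneven taxon sampling.
Truth-recovery results demonstrate correctness of the decision
machinery under a clean barcode gap, not the biological adequacy of a
2% threshold.

## Validation problem sizes and stochastic margins

The test-suite and acceptance-script problem sizes were chosen to make
each check decisive at desk scale: 1,000 random pairs for the K2P
closed-form oracle (agreement to 1e-12), 50 random additive matrices of
4–12 tips for NJ recovery, 200 random trees (≤ 10 tips, exhaustive
subsets up to 7 tips) for monophyly, 20 simulated datasets for the
statistic oracles, 20 seeded simulations (7 species × 6 specimens,
intra 0.8%, inter 8%, planted 6% and 4% splits, one lump) for truth
recovery, and 10 seeds at 8 species × 10 specimens for simulator
calibration (realized within-species divergence within ±20% relative of
target; note that per-species mean branch length has ~19% relative
Monte-Carlo sd at 0.8% × 658 sites, so calibration checks need several
species to average over).

One stochastic caveat: a planted split at exactly 4% keeps ~3.2%
expected separation between sub-roots, and with 658 sites the *minimum*
cross-cluster distance occasionally realizes below the 2% threshold; in
such replicates the dataset genuinely lacks a barcode gap and the
pipeline correctly — but "incorrectly" relative to the planted label —
reports the species cohesive.  Expect exact-recovery rates of 95–100%
across arbitrary seeds, and 100% for gaps ≥ 5%.

## Degenerate inputs and numerical notes

* 2-tip matrices produce a single edge with the distance split evenly;
  3-tip trees use the three-point formulas (a special case of the
  general step).
* Undefined distance pairs must be resolved before tree building;
  `DistanceMatrix.drop_undefined` greedily removes the records with the
  most undefined pairs (the pipeline does this automatically and logs
  the drops).
* Matrix symmetry is validated to 1e-9 relative tolerance; Newick
  output carries branch lengths at full double precision (`%.17g`) so
  write→read round-trips preserve path lengths to 1e-9.
* All randomness flows through `numpy.random.default_rng` seeded from
  the configuration; reports render percentages with two decimals, and
  report files are byte-deterministic for a given input.
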