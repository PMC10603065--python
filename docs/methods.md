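# Methods

`abselect` analyses NGS output of in-vitro antibody display campaigns: scFv
amplicons (VL-linker-VH) sequenced after two sort rounds at decreasing
antigen concentration (early = 10 nM, late = 1 nM), demultiplexed by inline
8-mer barcodes, annotated against fixed scaffolds, clustered into sequence
families, quantified for abundance and enrichment, and ranked. This note
records the models, conventions and numerical choices behind each stage, and
what the bundled simulator does and does not emulate.

## Read processing

**Quality filter.** A read is retained when the required fraction of its
bases (default 100%) reaches the Phred threshold (default Q >= 40, standard
relation Q = -10·log10(P); the threshold is inclusive). The filter is
order-preserving and idempotent; raising the threshold can only shrink the
retained set.

**Demultiplexing.** Barcodes are terminal 8-mers. The 5' barcode is compared
against the first eight bases; the stored 3' barcode is reverse-complemented
before comparison with the last eight bases, so the barcode table keeps both
barcodes in sense orientation (`bc3_as_given` disables this dialect). A read
is assigned when both ends match within the mismatch budget (default 2 of 8,
i.e. >= 70% identity per end) and one population uniquely minimises total
mismatches; equal-mismatch ties are deliberately left unassigned rather than
placed arbitrarily. Assignment trims both barcodes. Quality encoding is fixed
to Phred+33 — no autodetection.

## Annotation

The library is synthesised on a small set of fixed clinical scaffolds, so the
framework segments flanking each CDR are known per scaffold. Annotation
therefore translates each read (three forward frames; reverse complement only
on request, as amplicons are directional), rejects frames with internal stop
codons (`frameshift`), and locates the framework anchors sequentially — exact
substring search first, then a Hamming-tolerant scan over the plausible CDR
length window (2–40 residues; per-anchor mismatch cap of 30%). The scaffold
with the highest aggregate framework identity wins; below the identity floor
(default 70%) the read is rejected (`no_scaffold`). CDRs are the substrings
between located anchors, 0-based half-open on the translated chain, light
chain before heavy. This replaces germline-database alignment; it preserves
the semantics that matter downstream (a scaffold call standing in for the
V/J assignment, plus six CDRs) without an external database. Reads are
annotated once per unique nucleotide sequence and condensed into unique
full-length amino-acid clones with per-population read counts.

**Regions of interest (ROIs).** Counting and clustering operate on one of
four deterministic strings per clone: `HCDR3`; `HCDR3+LCDR3` (light first,
`|`-separated); `CDRs` (all six, light before heavy, CDR1 < CDR2 < CDR3);
`FULL` (the whole VL-linker-VH chain).

**Reduced alphabet.** Clustering distances are computed on an 11-group
physicochemical reduction of the 20 amino acids. The shipped default groups
aliphatics (LVIM), aromatics (FYW), acids (DE), amides (NQ), bases (KR) and
hydroxyls (ST), with A, C, G, H and P kept as singletons whose chemistry is
not shared. Group characters are lower-case so pseudo-sequences can never be
confused with amino-acid strings, and the mapping is a config input so any
published partition can be dropped in. The reduction is length-preserving
and contracts Levenshtein distance (a within-group substitution costs 0).

**Liabilities.** Developability-risk motifs are counted over the full
variable region with a user-overridable set (defaults: deamidation NG/NS,
isomerisation DG, N-glycosylation sequon N[^P][ST], cleavage-prone DP), plus
unpaired cysteines and oxidisable methionines inside CDRs — the conserved
cysteine pairs live in the frameworks, so any CDR cysteine is treated as
unpaired. Motifs are scanned independently and non-overlapping within each
motif.

## AbScan clustering

ROI strings (pooled across populations so cluster ids are comparable across
arms; per-population clustering is a flag) are clustered as follows.

1. **Distances.** Pairwise Levenshtein distance between reduced
   pseudo-sequences (edlib).
2. **Epsilon from the data.** Each point's core distance at `min_pts = 2`
   (distance to its nearest true neighbour, i.e. the k-th closest point
   counting itself) is sorted ascending and the knee located by maximum
   perpendicular distance to the chord joining the curve endpoints (ties to
   the smallest index). The result is floored at the smallest positive
   pairwise distance; an all-zero matrix falls back to a configured minimum
   (default 1.0). Two points use their own distance.
3. **Density clustering.** OPTICS (scikit-learn, precomputed metric) with
   `min_pts = 2`, reachability capped at `max_eps = 10 x eps_opt`, clusters
   extracted at steepness `xi = 0.01`, then **consolidated at the core
   scale**: with `min_pts = 2` every point with a neighbour within `eps_opt`
   is a core point, so any two points within `eps_opt` are density-connected
   — their xi clusters are unioned and xi-noise with an `eps_opt` neighbour
   is absorbed. Raw xi extraction fragments the dense halo of near-identical
   variants around dominant clones; consolidation restores the
   density-connectivity semantics that the brute-force reachability oracle
   and the family-recovery tests check. Points unreachable at `eps_opt` and
   unclaimed by xi stay noise. Input order is canonicalised (descending
   abundance, then lexicographic) so results are permutation-invariant.
4. **Abundance-seeded iterations.** The first iteration clusters all values
   at >= 0.005% pooled relative abundance; each later threshold of the
   schedule (default decade steps 0.005, 0.0005, 0.00005, 0) re-clusters one
   exemplar per existing cluster (its most abundant member, ties
   lexicographic) together with the unassigned values now above threshold.
   New values landing in an OPTICS cluster containing exemplars inherit the
   nearest exemplar's id (ties to the smaller id); clusters without an
   exemplar found new ids. Existing clusters are never merged — late
   iterations are dominated by exemplars whose spacing reflects
   between-family distance, and an elbow recomputed on that spacing would
   otherwise fuse the partition built from denser data. For the same reason
   an iteration whose candidates were all seen before is skipped. Epsilon is
   re-estimated on each executed iteration's point set (freezable by flag).
5. **Noise rescue.** After the final iteration, noise values are grouped by
   their reduced-space representation; groups with pooled count >= 2 become
   singleton clusters (`rescued_count`). Remaining noise matching an existing
   cluster member at equal length and >= 90% Hamming identity (amino-acid
   space) joins that cluster (`rescued_identity`; best identity, then
   smallest cluster id). Whatever is left is discarded as true noise.

**Baselines.** Traditional clonotyping joins two ROI values when they have
equal length, the same scaffold call and >= 90% positional identity, and
takes connected components (single linkage), with ids ordered by each
component's lexicographically smallest member. The 100%-identity method
assigns one cluster per distinct ROI string.

## Abundance and enrichment

Relative frequency of a ROI value in one population is
`100 * count / total`, after condensing identical ROI strings by summing the
read counts of all full-length clones that share them. Fold enrichment is
the late (1 nM) over early (10 nM) frequency ratio. A ROI absent from one
round receives a pseudo-count equal to that round's minimum observed count
divided by a correction factor — 2 when absent from the early round, 10 when
absent from the late round — so depletion is penalised five times more
heavily than new appearance is rewarded. Two deliberate conventions, both
covered by regression tests:

* Enrichment is reported as a plain fold ratio by default; the
  percent-scale variant (x100) is available by flag. Every downstream
  threshold ("tenfold", "< 0.01x") reads naturally on the fold scale.
* Pseudo-counts enter only the numerator of the absent side; the round
  totals stay sums of observed counts, leaving every observed ROI's
  frequency untouched. An alternative mode adds the pseudo-count to the
  denominator as well.
* The per-population minimum count is read as the global minimum of that
  round, the most literal reading of the correction rule.

Cumulative-abundance curves sort values by descending frequency (running sum
ends at 100); a representative mode keeps only the most abundant member per
cluster, in which case the curve ends at the representatives' summed share.

## Diversity and read-depth model

Accumulation curves subsample the pooled reads: per replicate one seeded
permutation is drawn and every depth is a prefix of it, so diversity is
non-decreasing within a replicate and the curve is bit-reproducible for a
fixed seed. Diversity is either the number of distinct ROI values or the
number of AbScan clusters after re-clustering the subsample (each subsample
is genuinely re-clustered; a fast mode mapping onto full-data labels exists
for exploration). The default depth grid is 10 log-spaced depths from 100 to
the dataset size with 5 replicates.

The read-depth model `reads = C * D^k` is fit by nonlinear least squares
with reads as the response, initialised from the log-log linear regression;
a failed fit returns the log-log estimate flagged as non-converged. At
least 3 distinct positive diversity values are required. Predictions for a
target diversity are rounded up. Note that when the cluster-unit curve has
already plateaued, the fitted `k` for clusters grows without bound — the
plateau itself, not the exponent, is the informative output in that regime.

## Ranking and models

Per-cluster representatives are the argmax of late-round FULL abundance (or
fold enrichment), ties broken by the lexicographically smallest full-length
sequence. Liability-reduced alternatives are members with strictly fewer
liabilities than the abundance representative, classed
improved/similar/worse at 2x and 5x KD fold thresholds when affinities are
available. Bin concordance calls a cluster consistent when all its
characterised members (>= 2 required) share one epitope bin. The binder
heuristic calls a clone positive when its late-round concatenated-CDRs
abundance is >= 0.005% (inclusive).

The feature matrix carries, per ROI, log10 early/late relative frequency and
log10 fold enrichment (each floored at the smallest positive observed value;
imputed rows are flagged), the AbScan cluster size, the liability count, and
one-hot framework residues over a fixed per-position vocabulary (21 symbols
including the pad; invariant positions are dropped). Binder labels use the
< 1 µM against-any-target definition; regression targets are log10 KD of the
best monomeric affinity (affinities span pM to µM, so the log scale is the
only sensible one).

`train_eval` splits the characterised set once (default 100/100, stratified
for classification), selects XGBoost hyperparameters by seeded random search
scored on bootstrap out-of-bag metrics of the training half (mean PR-AUC for
classification, Spearman for regression), refits on the full training half,
and reports test metrics plus their distribution over bootstrap refits
(default 100 reps). Single-class training labels are a hard error.

## The campaign simulator

The simulator provides the study conditions every stage is tested under:
50 clonal families on 4 scaffolds with Zipf(1.5) abundance; 1–4 true
sequence variants per family within 2 CDR edits of the prototype; CDR
lengths drawn from ranges typical of human repertoires (HCDR3 10–16);
substitution errors at 0.1% per base (PacBio-CCS-like; indels are off by
default because they break translation and exercise only the rejection
path); 50,000 reads per sort round; 2% of reads carry one sub-Q40 base;
barcode bases err at 0.1%. A latent per-family log10 KD ~ Normal(-8.5, 2.0)
matches the characterised-set structure of a real campaign (most binders
sub-10 nM, roughly a tenth non-binders at the 1 µM line) with clone-level
jitter of 0.2. Late-round family weights are the early weights tilted by
`exp(-beta * log10 KD)`; the default `beta = 0` encodes the empirical
finding that a single late selective step carries little affinity signal —
tests that need signal set `beta > 0` explicitly.

Characterisation defaults to one clone per family (the most abundant,
mirroring a non-redundant top-representative-per-cluster synthesis
strategy). With family-level affinities, characterising several clones per
family lets abundance features fingerprint families across a random
train/test split, and the regressor would beat the permuted null even with
`beta = 0`; the per-family cap is what makes the coupled/uncoupled contrast
a real test of the method rather than of leakage. The cap is configurable
for analyses that need redundant members (e.g. bin concordance).

Two simulator idealisations matter for interpreting green tests: family
prototypes are resampled until HCDR3s of different families are >= 5 edits
apart, and errors are substitution-only. Real campaigns contain somatic
lineages at intermediate distances, indels, chimeric PCR products and
context-dependent error hotspots; recovery numbers on simulated campaigns
(cluster counts near the family count, adjusted Rand index near 1) therefore
demonstrate correctness of the machinery under its stated model, not
expected field accuracy. Epitope bins are drawn at family level from a small
pool, so distinct families sharing a bin occur, as observed experimentally.

## Problem sizes

The test suite and the acceptance script run desk-scale campaigns chosen to
exercise every code path while keeping the default runs quick: the
full-scale recovery check uses the simulator defaults above (100,000 reads
total); ML checks use 150 families at 20,000 error-free reads per round with
a 75/75 split, 20 bootstrap reps and a 3–5 draw search; oracle suites use
hundreds of randomised instances of <= 10 points. All randomness flows from
explicit seeds.

## Known limitations

* Annotation assumes the fixed-scaffold library design; libraries with real
  germline diversity need an external annotator (AIRR-style tables can be
  imported directly, bypassing annotation).
* Consensus building, paired-end merging and adapter discovery are out of
  scope; inputs are assumed to be consensus reads.
* The OPTICS stage materialises the full pairwise distance matrix per
  iteration; campaigns with >~50k unique ROI values per iteration would need
  a blocked or indexed distance backend.
* Only two sort rounds are modelled; multi-round trajectories and
  replicate-based variance are not.
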