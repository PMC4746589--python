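# Methods

This note records the models, defaults and numerical conventions behind
each `madskit` module, what the simulator does and does not emulate, and the
design choices made where several reasonable options existed.

## Family mining (`madskit.mining`)

**Model.** The conserved domain is modeled as a log-odds position-specific
score matrix (PSSM) in bits, built from a gap-free seed alignment with
pseudocount τ against a background distribution *b*:

    S(j, a) = log2( ((c_j(a) + τ b_a) / (n + τ)) / b_a )

Defaults: τ = 0.5, uniform background (1/20).  A column whose residue
frequencies equal the background scores 0 bits for every residue; a fully
conserved column approaches log2(20) ≈ 4.32 bits as τ → 0.  Unknown residues
score 0 bits (a dedicated sentinel column).  This is deliberately a PSSM
with best-window scoring, not a match/insert/delete profile HMM: the
contract being tested is thresholded domain detection on gap-free planted
domains, for which the PSSM is exact, transparent, and fast; profile-HMM
Viterbi is a natural extension point if gapped domains ever matter.

**Significance.** Each protein's best profile-length window is compared
against windows of *shuffled copies of the same protein* (default 200
decoys), giving the empirical tail probability
e = (1 + #{decoy windows ≥ S}) / (1 + #decoy windows).  Membership requires
passing twice, with independent decoy streams, at e ≤ 1e-4.  Because 200
decoys resolve 1e-4 only coarsely (the floor is 1/(1 + 200·w) for w windows,
so proteins shorter than ~107 residues cannot reach it at all), confirmation
additionally requires a bit-score of at least 0.4 × the minimum self-score
of the seed alignment's own sequences.  The 0.4 factor is set so that
members at the simulator's stated divergence (0.15–0.2; mismatches cost
about −4 bits each under the default profile) pass with several standard
deviations of margin while background best windows — which score hundreds
of bits lower — cannot approach it.

**Orthologs and naming.** Best hits against a reference proteome use
Smith–Waterman local alignment (Bio.Align.PairwiseAligner, BLOSUM62, gap
open 10 + extend 1, so a length-k gap costs 11 + (k−1)).  Percent similarity
counts substitution-matrix-positive aligned pairs over alignment columns
(the BLASTP "positives" convention); query coverage is the aligned query
span over query length; "regular" orthologs require both strictly > 50%.
Ties on score break by subject id.  Positional names sort members by
(chromosome order, start coordinate) and number them densely, zero-padded;
unplaced members are appended in input order.

## Genome organization (`madskit.synteny`)

Homolog pairs come from all-vs-all Smith–Waterman with Karlin–Altschul
e-values E = K·m·n·e^(−λS) (gapped BLOSUM62 constants λ = 0.267, K = 0.041),
threshold 1e-10, at most 5 subjects per query, symmetric closure.  We do
not shell out to BLAST; on both synthetic and real protein pairs the
homolog/non-homolog decision at 1e-10 is separated by many orders of
magnitude, so the constants are not delicate.

Collinear blocks are maximal-scoring chains of anchors (homolog pairs
located by gene-order rank) found by DP: +1 per anchor, penalty 0.01 per
rank of gap on either axis, per-step gap ≤ 25 ranks, strict monotonicity in
both coordinates (both orientations tried), ≥ 5 anchors per block, iterated
extraction of disjoint chains, deterministic leftmost tie-break.  Rank
gaps, not bp, drive chaining — robust to gene-length variation.
Same-chromosome anchors closer than 30 ranks are treated as local
duplication arrays, not synteny, and excluded from chaining (MCScanX
likewise removes tandem pairs before chaining); without this, a run of
tandem/proximal arrays on one chromosome can masquerade as a "collinear
block" of local duplicates.

Duplication modes follow the duplicate-gene-classifier precedence —
segmental (block anchor) > tandem (adjacent rank, same chromosome) >
proximal (≤ 20 ranks) > dispersed (any other homolog) > singleton — so each
family gene gets exactly one mode and the mode counts partition the family.

Clusters: single-linkage along a chromosome, joining consecutive family
genes with ≤ 5 intervening genes *and* ≤ 250 kb bp gap; size ≥ 2; clusters
composed of a single subfamily are flagged.  Both knobs are arguments; the
defaults are a common tandem-array convention.

## Phylogenetics (`madskit.phylo`)

Distances: p-distance or Poisson correction d = −ln(1−p) with per-pair
deletion of gap columns; a saturated pair (p = 1) under Poisson raises an
error naming the pair rather than returning ∞.  Poisson is the default (the
usual protein-NJ default in MEGA-style workflows); p-distance is available.

NJ: Saitou–Nei Q-minimization with deterministic tie-break on the smallest
index pair; branch lengths l_i = d_ij/2 + (r_i − r_j)/(2(m−2)); negative
estimates clamped to 0 with the deficit transferred to the sister branch so
path lengths are preserved (MEGA-compatible convention).  The returned tree
is unrooted, represented rooted at the final three-way join.  NJ recovers
any additive matrix exactly — topology and branch lengths to 1e-9 — which
the tests exercise on random trees (dendropy path lengths as the
independent oracle) and against scikit-bio's NJ on non-additive matrices.

Bootstrap: columns resampled with replacement per replicate; distance + NJ
rebuilt; support = % of replicates whose tree contains each internal
bipartition of the *original* tree (no consensus tree is built).  Taxa are
canonically sorted before drawing, so supports are invariant to input
order at a fixed seed.  Replicates reuse the caller's distance model.

Clade assignment: every edge bounds two subtrees; a query takes the label
of the smallest edge-bounded subtree containing it and ≥ 1 reference taxon,
provided all minimal such subtrees agree on a single reference label
(ties across equally small subtrees with conflicting labels, and mixed
labels within one subtree, both yield "unassigned" — this also guarantees a
reference taxon always keeps its own label via its pendant edge).  A
functional DAM or FLC-like call is made when the chosen subtree contains a
functional anchor (SVP/DAM- or FLC-type taxon) and the subfamily label is
MIKC^C-type; anchors are a user-supplied table, since which peach DAM /
grape FLC-like sequences serve as anchors is a study-level choice.

## Expression (`madskit.expression`)

log2(FPKM + 1) with pseudocount 1 (zeros map to 0); expressed = FPKM ≥ 1 in
≥ 1 sample (the ≥ boundary is deliberate and documented); reciprocal pairs
are Pearson (or Spearman) correlations of log profiles over a stage window
— by convention the 10 dormancy-to-bloom stages — flagged at r ≤ −0.5.
ΔΔCt: ΔCt = Ct_target − Ct_control per sample, fold = 2^(−ΔΔCt).
Concordance between FPKM and qPCR fold changes is Pearson on log2 folds
(≥ 3 matched points).  The heat-map export is bit-identical to the log
transform, columns ordered by the stage design.  The expressed threshold
and reciprocal cutoff are arguments; "very low expression" has no standard
definition, so FPKM 1 is the default.

## Regulatory analysis (`madskit.regulatory`)

IUPAC scanning compiles each pattern to a regex of character classes inside
a lookahead, so overlapping occurrences are all counted; reverse-strand
hits scan the reverse-complement pattern on the forward sequence and report
forward coordinates.  Both-strand scanning is the default (whether a
single-strand convention was ever intended is unknowable; a flag disables
it).  Upstream windows: for + genes the [start − w, start) slice in 0-based
half-open coordinates; for − genes (end, end + w] reverse-complemented;
truncation at chromosome edges is flagged, 2000 bp for target search and
1500 bp for low-temperature-element counting.  Default LTRE patterns are
the CCGAC core with an RYCGAC variant and RCCGAC for CBF/DRE — the elements
are named in the literature but their exact strings vary, so the set is
overridable.

Phase filtering keeps a pattern iff it has ≥ 1 hit lying *wholly inside*
≥ 1 peak (peaks are the evidence unit; boundary-spanning matches do not
count).  A gene is a target iff ≥ 1 retained pattern hits its upstream
region; "unique motifs present" counts distinct patterns with ≥ 1 hit
anywhere in the region set.  Networks keep every interactome edge with ≥ 1
endpoint among the target orthologs, merge duplicate edges, drop
self-loops, and eliminate seeds without partners.  Degree distributions are
summarized by the discrete power-law MLE with x_min = 1 (bounded scalar
optimization, tolerance 1e-10, verified against grid search to 1e-6), a KS
distance between empirical and fitted CDFs, and a secondary log–log
least-squares slope with R².  Hubs are the top-k nodes of the largest
connected component by degree (ties by node id), reported with k as a
percentage of the component; k = 5 by default, with a quantile rule
available, since "hub" has no universal cutoff.  GO enrichment is the
hypergeometric upper tail per term over a flat annotation table (no
ontology propagation), BH-corrected, significant at FDR < 0.05 strictly.

## The simulator (`madskit.simulate`)

Each generator draws from its own seeded substream, so outputs are
byte-identical under a fixed seed and adding one stage never perturbs
another.  What is emulated, and what is not:

- **Proteomes.** Family proteins are random flanks around one planted copy
  of a random 58-residue consensus mutated per-site with probability equal
  to the divergence; background proteins are i.i.d. uniform over 20 amino
  acids.  Real proteomes have compositional bias and repeat families;
  passing recovery tests here shows threshold logic and calibration are
  correct, not that uniform-background e-values transfer to real data.
- **Genome layouts.** All genes have uniform length (300 bp) and random
  spacing; tandem duplicates sit at adjacent ranks, proximal within 20,
  segmental as blocks of ≥ 5 consecutive pairs copied across chromosomes
  (duplicate proteins mutated at 5%), dispersed as cross-chromosome pairs.
  Dispersed pairs avoid chromosome pairs hosting a segmental block (and at
  most 4 share any chromosome pair), so planted events are unambiguous by
  construction — the classifier is scored on clean labels, not on the
  genuinely ambiguous cases real genomes contain.  Infeasible placements
  raise rather than truncate.
- **Alignments.** Poisson substitutions along a tree (events ~
  Poisson(branch × rate × length), uniform sites, uniform replacement
  residue); no indels, no rate heterogeneity.
- **Expression.** 21 samples (3 apical-bud, 5 spur-bud, 6 flower, 7 fruit
  stages).  Planted pairs are linear on the log2(FPKM+1) scale across the
  first 10 samples (the dormancy-to-bloom window), repressors falling
  32 → 1 FPKM and activators mirror-rising, so a pair is exactly
  anti-correlated at zero noise; noise is multiplicative log-normal
  (σ = 0.2 by default, a typical FPKM replicate spread).  Defaults plant
  142 genes of which 63 are expressed — the family-scale split this kind of
  study reports — with 79 silent genes below FPKM 0.5.
- **Promoters and peaks.** Regions contain exactly the planted occurrences
  of library patterns and nothing else: accidental background hits are
  removed by resampling the offending window (rejection-repair), keeping
  true counts exact for recovery tests.  The default 8-pattern library is
  chosen pairwise non-nested and non-self-complementary so planted counts
  are well-defined under both-strand scanning.  Peaks carry a chosen
  subset (default 5) of the library, each instance wholly inside a peak,
  with no other library pattern inside any peak.
- **Interactomes.** Degrees are drawn from the discrete power law (Zipf) at
  the target exponent and realized exactly by Havel–Hakimi construction
  plus random relabeling; this is the cleanest way to hit an *arbitrary*
  target exponent (classic preferential attachment pins the exponent at 3).
  Hub planting adds edges until designated nodes exceed every other degree,
  which locally distorts the power law — exponent-recovery studies use
  n_hubs = 0.  One GO term is attached to 80% of a designated target set on
  top of a 2% background annotation rate; with the enriched fraction at 0
  the term appears only at background rate and type-I behaviour can be
  measured.

## Problem sizes and numerical conventions

Recovery studies run at: 50 family + 500 background proteins with 200
decoys each (mining); 10 planted events per duplication class on 7 × 60
gene chromosomes; 200 random trees of ≤ 8 taxa and 50 random 7-taxon
matrices (NJ); 200 bootstrap replicates on a 10-taxon, 300-column
alignment; 1000 random cases each for the motif-scan and (300 in the
acceptance script) chaining oracles; 20 × 1000-node graphs for exponent
recovery; 1000 null simulations for enrichment type-I control.  These sizes
give stable pass/fail behaviour at desk scale while exercising the same
code paths a full genome would.

Ties and degeneracies: NJ joins the smallest index pair among exact Q ties;
chaining prefers the leftmost chain and the + orientation at equal score;
hub ranking breaks degree ties by node id; BH significance is strict
(fdr < α); all intervals are 0-based half-open internally, with GFF3
converted on ingestion and BED read natively.

## Known limitations

- PSSM e-values are calibrated per protein by shuffling, so they are
  composition-conditional; they are not comparable across proteins the way
  database e-values are.
- The Karlin–Altschul constants are nominal; absolute homolog e-values
  should not be over-interpreted, only the thresholded decision.
- Bootstrap supports attach to the original tree's bipartitions; no
  majority-rule consensus is computed.
- The power-law fit fixes x_min = 1 and reports a KS distance without a
  resampled goodness-of-fit p-value.
- GO enrichment assumes a flat annotation table; no propagation up the
  ontology graph.
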