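# Methods

This note documents the models behind each `tomseek` module, the
parameters that matter, what the synthetic-data generators emulate, and
the numerical choices made where the design was genuinely open.

## Profile HMMs (`profile_hmm`)

A profile HMM is built from a gapped alignment: columns whose non-gap
fraction is at least the occupancy threshold (default 0.5, a
HMMER-like heuristic) become match states. Match emissions are observed
counts mixed with `pseudocount_weight` (default 1.0) times the background;
the background is the residue frequency over the whole alignment with a
small floor so log-odds stay finite. Insert emissions equal the
background; transitions are state-constant defaults (M→M 0.90, M→I 0.05,
M→D 0.05; I→M 0.60, I→I 0.40; D→M 0.70, D→D 0.30). Estimating transitions
from desk-scale alignments adds nothing to discrimination and was left
out; Dirichlet-mixture priors and glocal mode are likewise out of scope.

Scoring is local: a path enters at any match state (uniform entry
probability 1/n_match), walks M/I/D transitions, and may exit after any
match state at no cost. All dynamic programming is in log space; scores
are bits (log2-odds against the background null). Viterbi is the best
path, forward the log-sum over all paths; forward ≥ Viterbi is checked
everywhere and both are verified against exhaustive path enumeration on
toy models (≤ 3 match states, sequences ≤ 4 residues). Delete chains are
evaluated with a cumulative-max (or log-sum) scan, which requires the
state-constant transitions above.

**E-values.** The null is fitted explicitly: forward or Viterbi scores of
i.i.d. background decoys (default 200 decoys of length 150) are fitted by
maximum likelihood to a Gumbel distribution, and
E(s) = N·exp(−λ(s−μ)) clipped to [0, N]. Calibration and search default
to **Viterbi** scores: optimal-alignment scores of random sequences follow
a Gumbel law, and the self-consistency check (≈ 1 decoy in 200 at E ≤ 1)
holds for them, whereas forward (sum) scores have a visibly heavier right
tail (sample skewness ≈ 2.7) that a Gumbel fit underestimates several-fold.
The forward machinery remains available via `score_type="forward"`.

Iterative (jackhmmer-style) profile refinement is not implemented; a
single search round suffices to test best-candidate retrieval. HMM–HMM
comparison is out of scope; profile-to-sequence search stands in for it.

## β-signal scanning (`motif_scan`)

Patterns are degenerate residue-class strings (`PxGxxHxH`). The class
table is configurable; defaults are hydrophobic = {A,F,I,L,M,V,W},
polar = {C,D,E,H,K,N,Q,R,S,T,Y}, glycine fixed. Published figure legends
label the classes without enumerating them, so the split is explicit
configuration rather than a constant. Every window is tested (overlapping
hits all reported); a hit counts for classification when it lies entirely
inside the C-terminal window, default 40 residues — the motif sits in the
last β-strand, which has no fixed sequence coordinates, and 40 residues
cover a terminal strand plus the barrel's short C-tail. The scanner is
property-tested against a naive regex oracle.

## Hydropathy TMD prediction (`tmd_predict`)

Kyte–Doolittle values are averaged in a sliding window (default 19, the
canonical helix-spanning width; shrinking windows at the termini) and
affinely rescaled so −4.5 → 0 and +4.5 → 1. Spans are maximal runs at or
above the cutoff, with runs separated by ≤ 3 residues merged and runs
shorter than 15 residues discarded. The default cutoff is 0.8 with a
"relaxed" preset of 0.7; trained-predictor posterior cutoffs (e.g. 0.3)
live on a different scale and are recorded in configuration for
provenance only, not mapped numerically.

Window smoothing shifts span edges by up to half a window, so a
20-residue hydrophobic block yields an above-cutoff run of ≈ 13 residues —
below the minimum span length. Consequences: constructed test blocks use
25–30 residues, and the pipeline classifies the generator's 20–21-residue
anchors at the relaxed 0.7 preset. For positional motif checks (the Tom22
TMD motif) the span start is first snapped left to the beginning of the
contiguous run of residues with Kyte–Doolittle ≥ −2.0 containing the span
(keeps W/S/T/P inside, breaks at charged/strongly polar residues), which
undoes the smoothing shift deterministically.

Anchor topology: one span ending in the last 35 residues → tail-anchored
(checked first; TA proteins are the discovery focus); one span starting in
the first 35 → signal-anchored; ≥ 2 spans → polytopic; otherwise none.

## LFQ enrichment (`lfq_enrichment`)

Input: four bait and four control log2 intensities per protein; zero or
empty cells mean "not quantified". Means are taken over present replicates
only (no imputation). A protein is enriched if (a) present in ≥ 2 of 4
bait replicates and quantified in 0 control replicates ("presence only"),
or (b) fold change 2^(mean_test − mean_control) exceeds the threshold.
The published wording "fold change of > 1" is read literally as a linear
ratio (n > 0) by default. Under symmetric replicate noise that rule flags
~50 % of null proteins by construction (a coin flip on the sign of n), so
the recovery benchmark uses the stricter documented reading
`fc_scale="log2"` (n > 1); both readings are exposed and reported. The
presence knobs (min present in bait = 2, max present in control = 0) are
configuration, since the source legend defines neither.

## Triage and architectures (`candidate_triage`)

Venn decomposition is exact over membership signatures. Tiering follows
the discovery logic: tier 1 = enriched under both co-IP conditions and in
the membrane proteome, tier 2 = crosslink-only plus membrane. Domain
architectures are called by iterative best-hit excision with small
packaged profile HMMs for the Hsp20/α-crystallin domain and the 34-aa TPR
repeat (synthetic seed alignments, labelled as such), per-domain E-value
cutoff 0.01, greedy non-overlap resolution, TMD taken from the anchor
call. The Tom22 motif is anchored at the refined TMD start: position 2
must be W, ≥ 1 hydroxylated residue (S/T/Y) within three residues after
the W, serine at +4 counting the W as +1, and a proline anywhere in the
TMD. The "+4" origin is an interpretation (the source states no
coordinate system) and the anchor offset is configurable.

## Similarity networks (`similarity_network`)

All-vs-all Smith–Waterman (Bio.Align.PairwiseAligner, local mode) with
BLOSUM62 and gap costs 12 (first gapped position) / 1 (extension).
Significance: E = K·m·n·exp(−λS), p = 1 − exp(−E), with λ = 0.2533 and
K = 0.0501 — fitted by a Gumbel fit to 1,000 random-pair scores under this
exact configuration. The published gapped constants (0.267, 0.041)
understate this null (uniform-composition sequences, this gap model) and
admit ~2.5× the nominal number of spurious p < 0.1 edges. Both constants
are arguments.

Edges with p below the inclusion cutoff (default 0.1, mirroring the
single-query search heuristic) carry attraction min(−log10 p, 200). For
all-vs-all **cluster** analysis the package uses `CLUSTER_P_CUTOFF = 1e-4`:
at 0.1, roughly 10 % of unrelated pairs pass by construction and bridge
clusters to decoys, a multiple-testing effect that a database-scale
inclusion threshold never faces.

Layout: nodes start uniformly in the unit square (seeded); per iteration,
each edge pulls its endpoints together proportionally to
attraction × distance, every pair repels as 1/distance, the displacement
direction is unit-capped and scaled by a step that starts at 0.1 and
decays by 0.999 per iteration. Forces depend only on coordinate
differences, so the layout is translation-equivariant and deterministic
under a fixed seed. The separation benchmark (two planted 15-member
families, inter/intra mean distance ratio > 2) is run at 2,000 iterations
over 40 seeds — separation is far from marginal (typical ratios > 10), so
longer schedules add nothing; the CLI default remains 10,000 iterations.

## Dollo gain/loss profiling (`phyloprofile`)

Each component is assumed gained once — at the MRCA of the taxa carrying
it — and lost any number of times below that node (Dollo parsimony; the
package reasons about secondary loss, not repeated gain). The minimal loss
set consists of the maximal clades below the gain that contain no present
leaf and at least one absent leaf; all-uncertain clades resolve to the
event-free state. On a polytomy each lost child clade counts one edge.
Correctness is established against a brute-force oracle that minimises
losses over every gain placement and loss-edge subset: exhaustively for
all rooted binary topologies with ≤ 5 leaves × all presence patterns, and
for seeded random 6–8-leaf trees × all patterns (the full 8-leaf
enumeration — 135,135 topologies × 256 patterns — is far beyond a test
budget; per-tree the oracle remains exhaustive).

The packaged lineage tree and TOM-subunit profile under `tomseek/data/`
are hand-encoded illustrations (a consensus arrangement of eukaryote
lineages and an example presence/absence matrix), not data files from any
external source.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure of the study inputs:

- **Proteomes**: planted families are per-site substitutions of synthetic
  consensus templates — a β-barrel with a terminal β-signal (and a
  serine-substituted variant whose signal is broken at the last
  hydrophobic position), an Hsp20–TPR(3)–TMD tail-anchored receptor, and a
  short Tom22-like protein with the W/S/P motif in its TMD. Diagnostic
  positions are protected from mutation, and β-signal-negative members are
  rejection-sampled so mutation never plants an accidental in-window
  match: truth tables state motif status exactly. Decoys are i.i.d. from
  the background (uniform by default; Robinson–Robinson optional).
  Default mutation rates 0.05–0.10 per site keep family identity ~90 %,
  comfortably inside profile-HMM recovery range while far from identical.
- **LFQ tables**: protein-specific means uniform on [20, 30] log2 units,
  replicate noise SD 0.5, bait-complex members shifted by Δlog2 = 3 by
  default (the recovery benchmark uses Δlog2 = 2, the hardest condition
  the benchmark covers), control cells of members dropped with probability
  0.8, background cells with 0.02.
- **Tree profiles**: random rooted binary trees; each component gains at a
  random internal node with ≥ 4 descendant leaves and loses each edge
  below with probability 0.2–0.25, under two identifiability constraints —
  the gain node keeps ≥ 2 surviving child edges and every surviving
  internal node keeps ≥ 1 — so the simulated events are exactly the
  minimal Dollo explanation and recovery can be checked for equality.

What the generators do **not** emulate: indels and rate heterogeneity in
family evolution, correlated replicate structure or intensity-dependent
missingness in LFQ data, and homoplasy (repeated gain) in profiles.
Passing the recovery benchmarks therefore shows the methods are correct
and well-calibrated under their own model assumptions, not that they are
robust to every pathology of real data.

## Pore-class accounting (`reporting`)

Class-average statistics are consumed as given (no image processing).
Fractions are n/total; percents round to the nearest integer, half away
from zero. Raw fractions are always printed beside percents because
published rounding conventions vary — a 34.4 % class can appear as 35 % in
print. The pipeline orchestrator validates its YAML/dict configuration
against the known key set before executing, funnels all randomness through
one seed, and writes per-stage TSVs, a JSON summary and the resolved
configuration; reruns are byte-identical.

## Problem sizes

Defaults were chosen so the full test suite runs in ~1.5 minutes and the
acceptance script in ~1 minute: planted-family retrieval uses a 12-member
training family, 100 decoys of length 120 and 100 seeds; LFQ recovery 200
proteins × 100 seeds; network separation 30 sequences × 2,000 iterations
× 40 seeds; the Dollo oracle ~4,100 tree-pattern cases.
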