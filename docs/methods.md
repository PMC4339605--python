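# Methods

This note records the models, parameter choices, and numerical conventions
behind `covloss`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Problem and model

The package decides, per gene family, whether a query lineage (for which
only unassembled shotgun reads are available) has retained or lost the gene,
relative to reference species with complete CDS sets. The decision variable
is *horizontal coverage*: the fraction of a reference CDS covered by the
union of best-hit read alignment footprints. Under roughly uniform genome
sampling at depth C, a retained gene's CDS accumulates many overlapping read
footprints (expected per-base coverage follows the Poisson/Lander–Waterman
model, so the uncovered fraction decays as e^(−C·q), q the per-read mapping
probability), whereas a deleted locus yields no reads at all and its
ortholog's coverage stays near zero. Cross-species divergence attenuates q;
this is why the operating cut-offs are calibrated rather than assumed.

## Internal aligner

Reads (and whole CDSs) are aligned by exact-k-mer seeding (contiguous k=11
on both strands; an optional spaced-seed mask emulates discontiguous
megaBLAST templates, whose exact template is tool-specific) followed by
ungapped X-drop extension (X = 20 score units) with match +2 / mismatch −3.
Raw scores are converted with Karlin–Altschul statistics: λ solves
(1/4)e^(λ·2) + (3/4)e^(λ·(−3)) = 1 under uniform composition (solved with
Brent's method to 1e-12), K fixed at 0.41 (configurable); e-value =
K·m·n·e^(−λS) with m the query length and n the total database length,
cut at 1e-5. The aligner is deliberately ungapped: the generator introduces
substitutions only (an indel-rate option exists but defaults to 0), and at
the ≤ 20% pairwise divergence the method targets, ungapped extension keeps
the implementation tractable enough to verify read-by-read against a full
Smith–Waterman oracle. Real data contain indels; for faithful replication of
a BLAST-based protocol the package ingests external `outfmt 6` files
unchanged. 'N' bases never seed and always score as mismatches. Coordinates
follow BLAST conventions externally (1-based inclusive, minus strand encoded
by s_start > s_end) and are 0-based half-open, strand-normalized,
internally.

Ties in best-hit filtering resolve by lowest e-value, then highest bit
score, then lexicographically smallest subject id — deterministic under any
input order.

## Coverage degeneracy rule

A CDS with at most one mapped read, or with several reads all sharing an
identical (start, end) footprint, reports horizontal coverage exactly 0.
Footprint identity is evaluated on strand-normalized coordinates, so two
reads hitting opposite strands of one locus count as the same footprint;
the rule exists to suppress single-locus artifacts (e.g. one conserved motif
attracting a read pile-up) and its intent is strand-agnostic. Coverage is
computed per comparison-species database, not pooled, since each species is
searched independently.

## Calibration and cut-off choice

The discrepancy-rate curves compare read-based calls at every cut-off
against a full-length CDS-vs-CDS search on a species pair where both are
available. "Lost" is strict (`coverage < c`) and "conserved" inclusive
(`coverage ≥ c`) throughout, matching the strict `< 2%` operating rule;
cut-offs with an empty denominator report an undefined (missing) DR rather
than 0 — coercing to 0 would make automatic cut-off selection latch onto
degenerate extremes. `select_cutoffs` formalizes one defensible reading of
"choose cut-offs from the curves": the largest cut-off with DRL within
tolerance (default 0.05) and the smallest with DRC within tolerance. The
default grid is 0.01–0.99 in steps of 0.01.

The calibration benchmark draws per-family divergence from a Gamma(1, 1)
rate multiplier around a mean of 0.06 substitutions/site per branch
(≈ 0.12 between the species pair, comparable to moderately diverged
eudicot–eudicot ortholog pairs). Rate heterogeneity is essential here, not
cosmetic: with one uniform rate every family is either detectable by both
searches or by neither, the DR curves degenerate, and the characteristic
rise of DRL with the cut-off — the feature the 2%/50% operating points are
read from — disappears. Real ortholog sets are strongly rate-heterogeneous.
The homogeneous default (`rate_var_shape=None`) is kept for the loss-calling
benchmarks, where a single well-separated regime makes ground-truth
bookkeeping exact.

## Orthology

Reciprocal best hits with the bit-score tie window: per query, the hits
tied at the minimal e-value are considered; the maximal bit score among them
and every tied hit within 10 bits — inclusive at the boundary, since
"within" ordinarily includes it — are admitted, symmetrically in both
directions. E-value ties are exact-equality ties: the internal aligner
assigns identical e-values to identical scores, and externally produced
files quantize e-values coarsely enough that exact equality is the faithful
reading. Clusters are anchored on one pivot gene; the monocot flag marks
clusters with ≥ 1 member from a species tagged monocot (the OGCsM subset).

EST deduplication is greedy by decreasing length with a 0.99 identity
threshold; pairwise identity is computed end-gap-free (the shorter sequence
aligned into the longer with edlib's infix mode, edits charged against the
shorter length). This reproduces the intent, not the bit-exact heuristics,
of UCLUST. ORF extraction scans all six frames for ATG-to-stop spans (stop
required and excluded from the peptide), ties broken by frame order
+1, +2, +3, −1, −2, −3.

## Loss calling

Only OGCsM clusters are evaluable (a call needs the pivot gene plus at least
one monocot ortholog). The mean is taken over the pivot and the members
whose species is in the evaluation set (default: pivot + monocots; members
from outgroup species used only for cluster construction are excluded).
Members with zero mapped reads contribute 0.0 to the mean — skipping them
would bias calls toward conservation. Strict inequalities at both cut-offs
leave an explicit `undetermined` band, and a missing coverage record makes
the cluster `not_evaluable` with a reason rather than silently shrinking the
mean. Presence panels use the inclusive ≥ 2% rule, mirroring the worded
asymmetry between the absence (< 2%) and presence (≥ 2%) criteria. The
method cannot, by construction, discover genes newly evolved in the query
lineage — it only scores the reference gene space.

## K-mer genome size

Canonical (lexicographic minimum of k-mer and reverse complement) 21-mers;
k must be odd so canonicalization is unambiguous. The error valley is the
first local minimum of the spectrum along the sparse, sorted multiplicity
axis — sparse, because interpolating zeros into gaps would relocate the
valley into empty multiplicity ranges. The peak is the highest count at or
beyond the valley, and the size estimate divides the valley-trimmed k-mer
total (standard practice; whether to trim is the one free choice here and is
flagged as such) by the peak depth. Monotone spectra (insufficient coverage)
raise an error rather than guessing. The estimator ignores heterozygosity
and repeat structure; on repeat-free synthetic genomes it recovers size to
within a few percent at ≥ 20×, which bounds only the counting/peak logic,
not performance on real polymorphic genomes.

## Enrichment

Annotations are propagated to all is_a ancestors (true-path rule) after
dropping NR/ND evidence rows; part_of traversal is off by default. The
classic statistic is the one-sided hypergeometric tail (scipy), verified to
1e-10 against an exact integer-binomial summation. `elim` processes terms
children-first (topological order) and removes the genes of terms with
p < α (default 0.01) from their ancestors before testing them, decorrelating
nested terms; with α = 0 it reduces exactly to classic. Raw p-values are
reported; a Benjamini–Hochberg column is optional. topGO's `weight`
statistic is intentionally out of scope (its published description
underdetermines the implementation); outputs are labelled with the method
used.

## Synthetic generator

Each family starts from an ancestral CDS with uniform base composition
(GC configurable, default 0.5), length uniform in 400–800 bp (≥ 3 read
lengths, so several distinct footprints fit on one CDS). Every species
branch, including the query's, receives i.i.d. substitutions at the branch
rate (star phylogeny): read-vs-pivot identity therefore reflects two-branch
divergence, as it does between a real query and a reference. Exactly
round(loss_fraction · n_families) families — not a Bernoulli draw — are
deleted, keeping truth-table denominators deterministic. The query genome
concatenates the retained query-branch CDS copies in shuffled order with
uniform-random intergenic spacers (200–500 bp); lost loci simply do not
exist, so no read can come from them. Reads are wgsim-style: 100 bp pairs
from ~Normal(304, 30) fragments (insert geometry of a typical paired-end
library), read 2 reverse-complemented, i.i.d. substitution errors at 1%
by default, pair count = round(coverage · genome_length / (2 · read
length)). Read names carry the source fragment interval, which is what
makes the zero-divergence "best hit = source CDS" identity checkable.

Not emulated: repeats, paralogy, ploidy, indels (by default), quality-score
profiles, contamination, GC bias. Passing benchmarks therefore demonstrate
the correctness of the statistics and bookkeeping under the stated model,
and the self-consistency of the whole pipeline — not robustness to every
artifact of real sequencing data; for real data the external-BLAST ingestion
path exists precisely so the alignment step can be swapped out.

## Benchmark problem sizes

The default end-to-end benchmark uses 200 families (≈ 144 kb query genome,
≈ 21 500 reads at 15×) against three reference species; zero-divergence
identity checks use 60 families; calibration uses 250 families in a
two-species design; genome-size recovery uses a 100 kb genome at 30×.
These sizes give tight statistics (binomial noise on a 50-family sensitivity
estimate is ≈ ±4%) while keeping any single run in the tens of seconds.

## Known limitations

Ungapped extension understates coverage for indel-rich divergence; the
e-value model assumes uniform composition; RBB with a tie window can link
one pivot gene to several co-orthologs but performs no tree reconciliation;
`elim` order among equal-depth siblings follows the topological sort and can
matter when α is large; the genome-size valley rule assumes a unimodal
coverage peak (no heterozygosity shoulder).
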