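# covloss

Assembly-free detection of gene loss and conservation from unassembled
whole-genome shotgun reads.

Draft genome assemblies are expensive; for many non-model organisms only raw
short reads exist. `covloss` implements a comparative-genomics strategy that
skips assembly entirely: shotgun reads of a query species are mapped onto the
coding sequences (CDSs) of sequenced reference species, and each gene is
scored by its **horizontal coverage** — the fraction of the CDS length
covered by the union of best-hit read alignments. Genes whose ortholog
cluster shows almost no coverage are called *lost* in the query lineage;
genes with high coverage are called *conserved*. The approach was designed
for organisms such as seagrasses (e.g. *Zostera*), where it reveals lineage
wide losses like the ethylene biosynthesis and signalling pathway, but the
machinery is general.

## Method

For a query species Q with reads R and a pivot reference species (plus
comparison species) with CDS sets:

1. **Mapping** — R is aligned to each species' CDS database with a
   seed-and-extend local nucleotide aligner (exact 11-mer seeds on both
   strands, ungapped X-drop extension, Karlin–Altschul e-values; e-value
   cut-off 1e-5). External BLAST `outfmt 6` hit files are accepted anywhere
   internal hits are, so dc-megaBLAST can stand in for the built-in mapper.
   Only the best hit per read is retained.
2. **Horizontal coverage** — per CDS, footprints of best hits are unioned;
   coverage = covered bases / CDS length. A CDS with a single mapped read,
   or several reads all sharing one footprint, is assigned coverage 0
   (single-locus artifact guard).
3. **Calibration** — on a species pair where the full query CDS set is also
   available, read-based lost/conserved calls at each cut-off c are compared
   with a full-length CDS-vs-CDS search. Discrepancy rates
   `DRL(c) = |lost ∩ truth| / |lost|` and `DRC(c) = |conserved \ truth| /
   |conserved|` are tabulated over c; the operating cut-offs (2% for lost,
   50% for conserved) are read off these curves.
4. **Orthology** — reciprocal best hits between the pivot and every other
   species, with the bit-score tie window: among hits tied at the top
   e-value, the best bit score and everything within 10 bits (inclusive) is
   admitted. One cluster per pivot gene; clusters with ≥1 monocot member
   form the OGCsM subset used for calling.
5. **Calling** — mean horizontal coverage over the pivot gene and its
   monocot members: mean < 2% ⇒ lost, mean > 50% ⇒ conserved, otherwise
   undetermined. Presence panels for named gene lists use the inclusive
   ≥ 2% rule.
6. **Genome size** — canonical 21-mer spectrum of the reads; size ≈ (k-mers
   beyond the error valley) / (peak depth). The Lander–Waterman model
   P(Y=y) = C^y·e^(−C)/y! gives the expected unsequenced fraction e^(−C);
   at 30× coverage this is 9.4e-12 %, so missing genes are not sampling
   artifacts.
7. **Enrichment** — GO over-representation of the lost/conserved pivot
   genes against the OGCsM background: true-path propagated annotations
   (NR/ND evidence excluded), one-sided Fisher exact test, `classic` and
   `elim` algorithms.

A fully synthetic data generator (ortholog families diverged along a star
phylogeny, a query genome with a designated deleted-gene subset, wgsim-style
100 bp paired-end reads at configurable coverage and error rate) provides
ground truth for every stage.

## Worked example

Run the whole pipeline on synthetic data with known ground truth
(200 ortholog families, 25% deleted from the query genome, 0.10
substitutions/site per branch, 15× paired-end reads with 1% error):

```yaml
# run.yaml
sim:
  n_families: 200
  loss_fraction: 0.25
  divergence_per_branch: 0.10
  coverage: 15.0
  seq_error_rate: 0.01
  rng_seed: 1
```

```bash
covloss run --config run.yaml --out run_out
# calls: {'conserved': 150, 'lost': 50}
```

`run_out/summary.yaml` then contains:

```yaml
calls:
  conserved: 150
  lost: 50
confusion:
  lost_call_sensitivity: 1.0
  retained_called_lost: 0
n_clusters: 200
n_ogcm: 200
n_reads: 21538
```

All 50 truly deleted families are called lost and all 150 retained families
conserved (sensitivity 1.0, zero false losses); 200 reciprocal-best-hit
clusters are built, all containing a monocot member. Intermediate TSVs
(hits, per-CDS coverage, DR curve, clusters, calls) are written next to the
summary, and each stage is also exposed as its own subcommand
(`covloss simulate / map / coverage / calibrate / cluster / kmer /
genome-size / enrich`).

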