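"""End-to-end orchestration: simulate (or load) -> map -> coverage ->
calibrate -> cluster -> classify -> enrich, from one config.

Every stage writes a self-describing TSV so it can be re-run or inspected
independently, and the final summary (YAML) reports the lost / conserved /
undetermined counts plus, when ground truth is available (synthetic runs),
a confusion matrix of calls against the truth table.  The whole run is
deterministic given the config's ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from covloss import alignment, calibration, coverage, enrichment, kmer_genome, loss_calling, orthology
from covloss.seqio import read_fasta, read_fastq
from covloss.synthetic import SimConfig, TruthTable, simulate_reads, simulate_truth_set, write_fixture_bundle

logger = logging.getLogger("covloss.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``sim`` is set (fully synthetic run with ground truth) or the
    input paths are: ``reads_fastq`` plus ``cds_fasta`` per species.  The
    operating constants default to the calibrated values: e-value 1e-5 for
    every BLAST-style search, mean cluster coverage < 2% for lost, > 50%
    for conserved, >= 2% for presence.
    """

    sim: SimConfig | None = None
    reads_fastq: tuple[str, ...] = ()
    cds_fasta: dict[str, str] = field(default_factory=dict)   # species -> path
    query_cds_fasta: str | None = None                        # enables calibration
    pivot_species: str = "ath"
    monocot_species: tuple[str, ...] = ("osa", "spo")
    eval_species: tuple[str, ...] | None = None               # default: pivot + monocots
    evalue_max: float = 1e-5
    seed_len: int = 11
    tie_window: float = 10.0
    lost_cutoff: float = 0.02
    conserved_cutoff: float = 0.50
    present_cutoff: float = 0.02
    run_calibration: bool = True
    run_genome_size: bool = True
    kmer_k: int = 21
    obo_path: str | None = None
    gene2go_path: str | None = None
    enrichment_method: str = "classic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.lost_cutoff, self.conserved_cutoff, self.present_cutoff):
            if not 0.0 < c < 1.0:
                raise ValueError("cutoffs must lie in (0, 1)")
        if self.lost_cutoff >= self.conserved_cutoff:
            raise ValueError("lost_cutoff must be below conserved_cutoff")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            for key in ("cds_len_range", "intergenic_len_range", "species", "monocot_species"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        for key in ("reads_fastq", "monocot_species", "eval_species"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s %6.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage and return the summary report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    truth: TruthTable | None = None
    query_cds: dict[str, str] | None = None
    if cfg.sim is not None:
        cfg = dataclasses.replace(
            cfg,
            pivot_species=cfg.sim.pivot_species,
            monocot_species=cfg.sim.monocot_species,
        )
        cds_sets, genome, truth, reads = _simulate(cfg.sim, outdir)
        query_cds = cds_sets.pop(cfg.sim.query_species)
    else:
        if not cfg.reads_fastq or not cfg.cds_fasta:
            raise StageError("stage 'inputs' failed: need either sim or reads_fastq + cds_fasta")
        reads = []
        for p in cfg.reads_fastq:
            reads.extend(read_fastq(p))
        cds_sets = {sp: read_fasta(p) for sp, p in cfg.cds_fasta.items()}
        if cfg.query_cds_fasta:
            query_cds = read_fasta(cfg.query_cds_fasta)

    pivot = cfg.pivot_species
    if pivot not in cds_sets:
        raise StageError(f"stage 'inputs' failed: pivot species {pivot!r} has no CDS set")
    eval_species = set(cfg.eval_species or ((pivot,) + tuple(cfg.monocot_species)))

    # ---- map reads and compute coverage per species database --------------
    cov_records: dict[str, list[coverage.CoverageRecord]] = {}
    for sp, db in cds_sets.items():
        if sp not in eval_species:
            continue
        best = _map_species(reads, db, sp, cfg, outdir)
        cov_records[sp] = coverage.build_coverage_table(best, db, species_id=sp)
        coverage.coverage_table_to_tsv(cov_records[sp], outdir / f"coverage_{sp}.tsv")

    report: dict = {"n_reads": len(reads), "species_evaluated": sorted(cov_records)}

    # ---- calibration (needs the query species' full CDS set) --------------
    if cfg.run_calibration and query_cds is not None:
        curve = _calibrate(query_cds, cds_sets[pivot], cov_records[pivot], cfg, outdir)
        report["calibration"] = {
            "drl_at_lost_cutoff": _curve_value(curve, cfg.lost_cutoff, "drl"),
            "drc_at_conserved_cutoff": _curve_value(curve, cfg.conserved_cutoff, "drc"),
        }

    # ---- orthology --------------------------------------------------------
    clusters = _cluster(cds_sets, cfg, outdir)
    ogcm = [cl for cl in clusters if cl.has_monocot]
    report["n_clusters"] = len(clusters)
    report["n_ogcm"] = len(ogcm)

    # ---- classification ---------------------------------------------------
    cov_lookup = {
        (r.species_id, r.gene_id): r.horizontal_coverage
        for recs in cov_records.values()
        for r in recs
    }
    calls = loss_calling.classify_clusters(
        ogcm, cov_lookup, pivot, eval_species, cfg.lost_cutoff, cfg.conserved_cutoff
    )
    loss_calling.calls_to_tsv(calls, outdir / "calls.tsv")
    by_status: dict[str, int] = {}
    for c in calls:
        by_status[c.status] = by_status.get(c.status, 0) + 1
    report["calls"] = by_status

    if truth is not None:
        report["confusion"] = _confusion(calls, truth, pivot)

    # ---- genome size ------------------------------------------------------
    if cfg.run_genome_size:
        try:
            hist = kmer_genome.kmer_histogram(reads, k=cfg.kmer_k)
            hist.to_tsv(outdir / "kmer_histogram.tsv")
            est = kmer_genome.estimate_genome_size(hist)
            report["genome_size"] = {
                "size_bp": est.size_bp,
                "peak_depth": est.peak_depth,
                "error_valley": est.error_valley,
            }
        except ValueError as exc:
            report["genome_size"] = {"error": str(exc)}

    # ---- enrichment -------------------------------------------------------
    if cfg.obo_path and cfg.gene2go_path:
        report["enrichment"] = _enrich(calls, cfg, outdir)

    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report


@_stage("simulate")
def _simulate(sim: SimConfig, outdir: Path):
    cds_sets, genome, truth = simulate_truth_set(sim)
    reads1, reads2 = simulate_reads(genome, sim)
    write_fixture_bundle(cds_sets, genome, truth, (reads1, reads2), sim, outdir / "sim")
    return cds_sets, genome, truth, reads1 + reads2


@_stage("map")
def _map_species(reads, db, sp, cfg: PipelineConfig, outdir: Path):
    hits = alignment.map_reads_to_cds(
        reads, db, seed_len=cfg.seed_len, evalue_max=cfg.evalue_max
    )
    best = alignment.best_hit_filter(hits)
    alignment.write_tabular_hits(best, outdir / f"hits_{sp}.m6")
    return best


@_stage("calibrate")
def _calibrate(query_cds, pivot_cds, pivot_cov, cfg: PipelineConfig, outdir: Path):
    cds_hits = alignment.align_cds_sets(
        query_cds, pivot_cds, seed_len=cfg.seed_len, evalue_max=cfg.evalue_max
    )
    best = alignment.best_hit_filter(cds_hits)
    alignment.write_tabular_hits(best, outdir / "cds_vs_cds.m6")
    truth_ids = calibration.truth_hit_set(best)
    curve = calibration.compute_dr_curves(pivot_cov, truth_ids)
    curve.to_frame().to_csv(outdir / "dr_curve.tsv", sep="\t", index=False)
    return curve


@_stage("cluster")
def _cluster(cds_sets, cfg: PipelineConfig, outdir: Path):
    pivot = cfg.pivot_species
    rbb_maps = {}
    for sp, db in cds_sets.items():
        if sp == pivot:
            continue
        ab = alignment.align_cds_sets(
            cds_sets[pivot], db, seed_len=cfg.seed_len, evalue_max=cfg.evalue_max
        )
        ba = alignment.align_cds_sets(
            db, cds_sets[pivot], seed_len=cfg.seed_len, evalue_max=cfg.evalue_max
        )
        rbb_maps[sp] = orthology.rbb_pairs(ab, ba, tie_window=cfg.tie_window)
    clusters = orthology.build_clusters(pivot, rbb_maps, set(cfg.monocot_species))
    orthology.clusters_to_tsv(clusters, outdir / "ogc.tsv")
    return clusters


@_stage("enrich")
def _enrich(calls, cfg: PipelineConfig, outdir: Path):
    dag = enrichment.parse_obo_minimal(cfg.obo_path)
    rows = []
    with open(cfg.gene2go_path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                parts = line.rstrip("\n").split("\t")
                rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    annotations = enrichment.propagate_annotations(rows, dag)
    background = {c.pivot_gene_id for c in calls}
    out = {}
    for label in (loss_calling.LOST, loss_calling.CONSERVED):
        study = {c.pivot_gene_id for c in calls if c.status == label}
        if not study:
            out[label] = 0
            continue
        result = enrichment.fisher_enrichment(
            study, background, annotations, dag=dag, method=cfg.enrichment_method
        )
        enrichment.enrichment_to_tsv(result, outdir / f"enrichment_{label}.tsv")
        out[label] = sum(1 for r in result if r.p_value < 0.05)
    return out


def _curve_value(curve: calibration.DRCurve, cutoff: float, which: str):
    vals = curve.drl if which == "drl" else curve.drc
    diffs = [abs(c - cutoff) for c in curve.cutoffs]
    i = diffs.index(min(diffs))
    return vals[i]


def _confusion(calls, truth: TruthTable, pivot: str) -> dict:
    """Cross-tabulate call status against truth status, keyed per family."""
    call_by_family = {}
    for c in calls:
        fam = truth.family_of_gene(c.pivot_gene_id)
        call_by_family[fam] = c.status
    table: dict[str, dict[str, int]] = {"lost": {}, "retained": {}}
    for fam, status in truth.status.items():
        call = call_by_family.get(fam, "no_cluster")
        table[status][call] = table[status].get(call, 0) + 1
    n_lost_true = len(truth.lost_families)
    n_ret_true = len(truth.retained_families)
    sens = table["lost"].get("lost", 0) / n_lost_true if n_lost_true else float("nan")
    return {
        "truth_lost": table["lost"],
        "truth_retained": table["retained"],
        "lost_call_sensitivity": sens,
        "retained_called_lost": table["retained"].get("lost", 0),
    }
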