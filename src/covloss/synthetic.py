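"""Synthetic ortholog families, a query genome with known gene losses, and
wgsim-style paired-end reads.

The generator emulates the two study designs the pipeline is built for:

* a *calibration* setup — two species diverged from a common ancestor, no
  losses, shotgun reads of one compared against the CDSs of the other
  (tomato reads vs. Arabidopsis CDSs);
* a *query* setup — a pivot species plus monocot comparators, and a query
  genome from which a designated subset of gene families has been deleted
  outright (seagrass vs. the reference gene sets).

Each gene family starts as an ancestral CDS of uniform base composition;
every species (including the query branch) receives an independent copy
with i.i.d. substitutions at the branch rate.  The query genome is the
concatenation of the query branch's *retained* CDS copies separated by
random intergenic spacers — lost families have no locus at all, so no read
can originate from them.  Reads are 100 bp paired-end by default, drawn
from ~Normal(304, sd) fragments, read 2 reverse-complemented, with i.i.d.
substitution errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from covloss.seqio import revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

RETAINED = "retained"
LOST = "lost"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic truth set.

    ``divergence_per_branch`` is the expected substitutions/site applied
    independently on every species branch (star phylogeny), so two species
    sit at roughly twice that divergence from each other.  ``loss_fraction``
    of the families (exactly ``round(loss_fraction * n_families)`` of them)
    are deleted from the query genome.  ``rate_var_shape``, when set, draws
    a per-family Gamma(shape, 1/shape) rate multiplier (mean 1) so families
    differ in divergence the way real ortholog pairs do; ``None`` keeps one
    uniform rate.
    """

    n_families: int = 200
    cds_len_range: tuple[int, int] = (400, 800)
    divergence_per_branch: float = 0.10
    loss_fraction: float = 0.25
    intergenic_len_range: tuple[int, int] = (200, 500)
    read_len: int = 100
    insert_mean: float = 304.0
    insert_sd: float = 30.0
    seq_error_rate: float = 0.01
    coverage: float = 15.0
    indel_rate: float = 0.0
    gc_content: float = 0.5
    rate_var_shape: float | None = None
    species: tuple[str, ...] = ("ath", "osa", "spo")
    monocot_species: tuple[str, ...] = ("osa", "spo")
    query_species: str = "zmu"
    rng_seed: int = 0

    @property
    def pivot_species(self) -> str:
        return self.species[0]

    @property
    def n_lost(self) -> int:
        return int(round(self.loss_fraction * self.n_families))

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for frac, name in [
            (self.loss_fraction, "loss_fraction"),
            (self.seq_error_rate, "seq_error_rate"),
            (self.gc_content, "gc_content"),
            (self.indel_rate, "indel_rate"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.divergence_per_branch < 0:
            raise ValueError("divergence_per_branch must be >= 0")
        if self.cds_len_range[0] < 3 * self.read_len:
            raise ValueError(
                "cds_len_range minimum must be >= 3 * read_len so a CDS can "
                "carry several distinct read footprints"
            )
        if self.cds_len_range[0] > self.cds_len_range[1]:
            raise ValueError("cds_len_range must be (lo, hi) with lo <= hi")
        if self.n_families - self.n_lost <= 0:
            raise ValueError(
                "loss_fraction leaves zero retained families; the query genome "
                "would be empty"
            )
        if self.query_species in self.species:
            raise ValueError("query_species must not collide with comparison species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if not set(self.monocot_species) <= set(self.species):
            raise ValueError("monocot_species must be a subset of species")


@dataclass
class TruthTable:
    """Ground truth of one simulation: per-family status and gene ids."""

    status: dict[str, str]                      # family_id -> retained|lost
    genes: dict[str, dict[str, str]]            # family_id -> species -> gene_id
    query_loci: dict[str, tuple[int, int]]      # retained family -> genome interval
    family_rates: dict[str, float] = field(default_factory=dict)

    @property
    def lost_families(self) -> set[str]:
        return {f for f, s in self.status.items() if s == LOST}

    @property
    def retained_families(self) -> set[str]:
        return {f for f, s in self.status.items() if s == RETAINED}

    def gene_of(self, family_id: str, species: str) -> str:
        return self.genes[family_id][species]

    def family_of_gene(self, gene_id: str) -> str:
        # gene ids are "<species>_<family>"; keep a parse-free reverse map
        if not hasattr(self, "_gene2fam"):
            self._gene2fam = {
                g: f for f, per_sp in self.genes.items() for g in per_sp.values()
            }
        return self._gene2fam[gene_id]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    # index order A,C,G,T; GC split evenly between C and G
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions at `rate`, each to one of the three other bases."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def simulate_truth_set(
    cfg: SimConfig,
) -> tuple[dict[str, dict[str, str]], tuple[str, str], TruthTable]:
    """Generate species CDS sets, the query genome, and the truth table.

    Returns ``(cds_sets, (genome_id, genome_seq), truth)`` where
    ``cds_sets`` maps species id (comparison species plus the query species)
    to an ordered ``{gene_id: sequence}`` dict.  The query species' CDS set
    contains only retained families — lost genes do not exist in that
    lineage.  Deterministic given ``cfg.rng_seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    fams = [f"fam{idx:04d}" for idx in range(cfg.n_families)]
    lost = set(rng.choice(cfg.n_families, size=cfg.n_lost, replace=False).tolist())

    if cfg.rate_var_shape is not None:
        mult = rng.gamma(cfg.rate_var_shape, 1.0 / cfg.rate_var_shape, size=cfg.n_families)
    else:
        mult = np.ones(cfg.n_families)

    all_species = list(cfg.species) + [cfg.query_species]
    cds_sets: dict[str, dict[str, str]] = {sp: {} for sp in all_species}
    status: dict[str, str] = {}
    genes: dict[str, dict[str, str]] = {}
    rates: dict[str, float] = {}
    query_copies: dict[str, str] = {}

    for idx, fam in enumerate(fams):
        length = int(rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1))
        ancestor = _random_seq(rng, length, cfg.gc_content)
        branch_rate = min(cfg.divergence_per_branch * float(mult[idx]), 0.95)
        rates[fam] = branch_rate
        status[fam] = LOST if idx in lost else RETAINED
        genes[fam] = {}
        for sp in all_species:
            gid = f"{sp}_{fam}"
            seq = _decode(_mutate(ancestor, branch_rate, rng))
            if sp == cfg.query_species:
                if status[fam] == RETAINED:
                    cds_sets[sp][gid] = seq
                    query_copies[fam] = seq
                # lost families simply have no gene in the query lineage
                else:
                    continue
            else:
                cds_sets[sp][gid] = seq
            genes[fam][sp] = gid

    # Genome: retained query CDS copies in shuffled order, spaced by random
    # intergenic sequence (spacers also flank the ends).
    retained = [f for f in fams if status[f] == RETAINED]
    order = [retained[i] for i in rng.permutation(len(retained))]
    parts: list[str] = []
    loci: dict[str, tuple[int, int]] = {}
    pos = 0

    def _spacer() -> str:
        n = int(rng.integers(cfg.intergenic_len_range[0], cfg.intergenic_len_range[1] + 1))
        return _decode(_random_seq(rng, n, cfg.gc_content))

    for fam in order:
        sp = _spacer()
        parts.append(sp)
        pos += len(sp)
        seq = query_copies[fam]
        loci[fam] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    tail = _spacer()
    parts.append(tail)

    genome = ("".join(parts))
    truth = TruthTable(status=status, genes=genes, query_loci=loci, family_rates=rates)
    return cds_sets, (f"{cfg.query_species}_genome", genome), truth


def simulate_reads(
    genome: tuple[str, str] | str, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate paired-end shotgun reads from a genome sequence.

    The number of pairs is ``round(coverage * genome_len / (2 * read_len))``.
    Each pair comes from a uniformly placed fragment of length
    ~Normal(insert_mean, insert_sd) (clipped to [read_len, genome_len]);
    read 1 is the fragment's 5' end on the forward strand, read 2 the
    reverse complement of its 3' end.  Substitution errors are i.i.d. at
    ``seq_error_rate``.  Read names encode the fragment's source interval
    (``frag<i>:<start>-<end>``) for traceability.
    """
    if isinstance(genome, tuple):
        genome = genome[1]
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    glen = len(genome)
    if glen <= cfg.insert_mean + 4 * cfg.insert_sd:
        raise ValueError("genome too short for the configured insert size distribution")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)

    L = cfg.read_len
    n_pairs = int(round(cfg.coverage * glen / (2 * L)))
    flens = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)).astype(int),
        L,
        glen,
    )
    starts = (rng.random(n_pairs) * (glen - flens + 1)).astype(int)

    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    for i in range(n_pairs):
        s, fl = int(starts[i]), int(flens[i])
        e = s + fl
        r1 = genome[s : s + L] if fl >= L else genome[s:e]
        r2 = revcomp(genome[e - L : e]) if fl >= L else revcomp(genome[s:e])
        if cfg.seq_error_rate > 0:
            r1 = _with_errors(r1, cfg.seq_error_rate, rng, code)
            r2 = _with_errors(r2, cfg.seq_error_rate, rng, code)
        name = f"frag{i}:{s}-{e}"
        reads1.append((f"{name}/1", r1))
        reads2.append((f"{name}/2", r2))
    return reads1, reads2


def _with_errors(seq: str, rate: float, rng: np.random.Generator, code: np.ndarray) -> str:
    arr = code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return _decode(_mutate(arr, rate, rng))


def write_fixture_bundle(
    cds_sets: dict[str, dict[str, str]],
    genome: tuple[str, str],
    truth: TruthTable,
    reads: tuple[list[tuple[str, str]], list[tuple[str, str]]],
    cfg: SimConfig,
    outdir: str | Path,
) -> dict:
    """Write the simulation to disk and return (and write) a manifest.

    Files: one FASTA per species CDS set, the query genome FASTA, two FASTQ
    read files, a truth TSV (family_id, status, one gene-id column per
    species), and ``manifest.yaml`` recording the config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise NotADirectoryError(str(outdir))

    files: dict[str, str] = {}
    for sp, cds in cds_sets.items():
        name = f"{sp}_cds.fasta"
        write_fasta(cds, outdir / name)
        files[f"cds_{sp}"] = name
    write_fasta({genome[0]: genome[1]}, outdir / "query_genome.fasta")
    files["genome"] = "query_genome.fasta"
    write_fastq(reads[0], outdir / "reads_1.fastq")
    write_fastq(reads[1], outdir / "reads_2.fastq")
    files["reads_1"] = "reads_1.fastq"
    files["reads_2"] = "reads_2.fastq"

    species = list(cfg.species) + [cfg.query_species]
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("family_id\tstatus\t" + "\t".join(species) + "\n")
        for fam in sorted(truth.status):
            row = [fam, truth.status[fam]]
            row += [truth.genes[fam].get(sp, "-") for sp in species]
            fh.write("\t".join(row) + "\n")
    files["truth"] = "truth.tsv"

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.rng_seed,
        "files": files,
        "n_families": cfg.n_families,
        "n_lost": cfg.n_lost,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
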