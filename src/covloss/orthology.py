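"""Reciprocal-best-hit ortholog clusters and EST utilities.

Clusters are anchored on one pivot-species gene.  A pivot/partner pair is
accepted when each gene is among the other's top hits: the hits tied at the
lowest e-value are considered, and of those, the one with the highest bit
score together with every hit within 10 bit-score points (inclusive) of
that maximum.  Clusters containing at least one member from a species
tagged as monocot form the OGCsM subset used for loss calling.

EST helpers: greedy identity-based deduplication (UCLUST-style, global
end-gap-free identity via edlib) and six-frame longest-ORF extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
from Bio.Seq import Seq

from covloss.alignment import TabularHit
from covloss.seqio import revcomp


@dataclass(frozen=True)
class OrthoCluster:
    """One pivot gene plus its reciprocal-best-hit members per species."""

    pivot_gene_id: str
    members: Mapping[str, tuple[str, ...]]
    has_monocot: bool

    def member_genes(self) -> list[tuple[str, str]]:
        return [(sp, g) for sp, genes in self.members.items() for g in genes]


def _top_hit_sets(hits: Iterable[TabularHit], tie_window: float) -> dict[str, set[str]]:
    """Per query: subjects tied at the lowest e-value, filtered to those with
    bit score >= (max bit among the tied) - tie_window (inclusive boundary)."""
    by_query: dict[str, list[TabularHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, set[str]] = {}
    for q, hs in by_query.items():
        best_e = min(h.evalue for h in hs)
        tied = [h for h in hs if h.evalue == best_e]
        max_bit = max(h.bit_score for h in tied)
        out[q] = {h.subject_id for h in tied if h.bit_score >= max_bit - tie_window}
    return out


def rbb_pairs(
    hits_ab: Iterable[TabularHit],
    hits_ba: Iterable[TabularHit],
    tie_window: float = 10.0,
) -> dict[str, list[str]]:
    """Reciprocal best hits between set A (pivot) and set B.

    ``hits_ab`` are A-queries vs B-subjects, ``hits_ba`` the reverse; both
    already thresholded on e-value.  Returns {A gene -> sorted B partners}.
    The bit-score tie window is applied symmetrically in both directions.
    """
    top_ab = _top_hit_sets(hits_ab, tie_window)
    top_ba = _top_hit_sets(hits_ba, tie_window)
    pairs: dict[str, list[str]] = {}
    for a, bs in top_ab.items():
        partners = sorted(b for b in bs if a in top_ba.get(b, ()))
        if partners:
            pairs[a] = partners
    return pairs


def build_clusters(
    pivot_species: str,
    rbb_maps: Mapping[str, Mapping[str, Sequence[str]]],
    monocot_species: set[str] | frozenset[str],
) -> list[OrthoCluster]:
    """Assemble one cluster per pivot gene with >= 1 RBB partner anywhere.

    ``rbb_maps`` maps each comparison species to its {pivot gene -> partner
    gene ids} RBB map.  Clusters are sorted by pivot gene id.
    """
    if pivot_species in rbb_maps:
        raise ValueError(f"species label collision: pivot {pivot_species!r} also in rbb_maps")
    if len(set(rbb_maps)) != len(list(rbb_maps)):
        raise ValueError("duplicate species labels in rbb_maps")

    pivot_genes: set[str] = set()
    for sp_map in rbb_maps.values():
        pivot_genes.update(g for g, partners in sp_map.items() if partners)

    clusters: list[OrthoCluster] = []
    for g in sorted(pivot_genes):
        members = {
            sp: tuple(sp_map[g])
            for sp, sp_map in rbb_maps.items()
            if sp_map.get(g)
        }
        has_monocot = any(sp in monocot_species for sp in members)
        clusters.append(OrthoCluster(pivot_gene_id=g, members=members, has_monocot=has_monocot))
    return clusters


def clusters_to_tsv(clusters: Iterable[OrthoCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("pivot_gene_id\tspecies_id\tmember_gene_id\thas_monocot\n")
        for cl in clusters:
            for sp, gene in cl.member_genes():
                fh.write(f"{cl.pivot_gene_id}\t{sp}\t{gene}\t{int(cl.has_monocot)}\n")


def _pair_identity(a: str, b: str) -> float:
    """End-gap-free global identity: the shorter sequence aligned into the
    longer (edlib infix mode), mismatches+indels charged against it."""
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0
    res = edlib.align(a, b, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(a))


def dedup_sequences(
    seqs: Mapping[str, str], identity_threshold: float = 0.99
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy identity clustering of (EST) sequences.

    Sequences are visited by decreasing length; each joins the first
    centroid it matches at >= ``identity_threshold`` global identity, or
    founds a new centroid.  Returns (centroids, member -> centroid map).
    """
    if not seqs:
        raise ValueError("empty sequence set")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    centroids: dict[str, str] = {}
    assignment: dict[str, str] = {}
    for name in order:
        seq = seqs[name]
        for cname, cseq in centroids.items():
            if _pair_identity(seq, cseq) >= identity_threshold:
                assignment[name] = cname
                break
        else:
            centroids[name] = seq
            assignment[name] = name
    return centroids, assignment


_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(seq: str) -> list[tuple[int, int]]:
    """ATG-to-stop ORFs (stop excluded) as codon-aligned [start, end) slices."""
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    for pos in range(0, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if start is not None:
                orfs.append((start, pos))
                start = None
        elif codon == "ATG" and start is None:
            start = pos
    return orfs


def longest_orf(seq: str) -> str:
    """Longest ATG-to-stop translation over all six reading frames.

    Frames are scanned in the order +1, +2, +3, -1, -2, -3 and ties go to
    the earlier frame.  Returns the peptide without the stop; an empty
    string (with a warning) when no complete ORF exists in any frame.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    best = ""
    for strand_seq in (seq, revcomp(seq)):
        for off in (0, 1, 2):
            frame = strand_seq[off:]
            for start, end in _orfs_in_frame(frame):
                if end - start > 3 * len(best):
                    best = str(Seq(frame[start:end]).translate())
    if not best:
        warnings.warn("no complete ATG-to-stop ORF found in any frame")
    return best
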