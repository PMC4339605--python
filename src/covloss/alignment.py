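"""Pairwise local nucleotide alignment: an internal seed-and-extend mapper
plus BLAST tabular (outfmt 6) readers/writers and best-hit filtering.

The mapper finds exact k-mer seeds (contiguous by default, an optional
spaced-seed mask emulating discontiguous megaBLAST templates) on both
strands and extends them ungapped with an X-drop rule.  Raw scores are
converted to bit scores and e-values with Karlin-Altschul statistics, with
lambda solved numerically from the match/mismatch scores under uniform base
composition.  External BLAST outfmt-6 files are accepted wherever internal
hits are, so the same downstream code runs on either.

Coordinate conventions follow BLAST: tabular fields are 1-based inclusive,
minus-strand subject hits have s_start > s_end; all internal footprints are
0-based half-open on the subject's forward strand.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence, TextIO

from scipy.optimize import brentq

from covloss.seqio import revcomp

_VALID = set("ACGTN")


@lru_cache(maxsize=None)
def _solve_lambda(reward: int, penalty: int) -> float:
    """Positive root of (1/4)e^(lam*reward) + (3/4)e^(lam*penalty) = 1."""
    f = lambda lam: 0.25 * math.exp(lam * reward) + 0.75 * math.exp(lam * penalty) - 1.0
    return float(brentq(f, 1e-9, 10.0, xtol=1e-12))


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and the derived Karlin-Altschul parameters.

    Gap scores are informational only (the internal engine is ungapped);
    they are kept so external gapped hits can be described consistently.
    """

    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    k_const: float = 0.41

    def __post_init__(self) -> None:
        if not (self.reward > 0 > self.penalty):
            raise ValueError("require reward > 0 > penalty")

    @property
    def lam(self) -> float:
        """Karlin-Altschul lambda (nats per score unit)."""
        return _solve_lambda(self.reward, self.penalty)

    def bit_score(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.k_const)) / math.log(2.0)

    def evalue(self, raw: int, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lam * raw)


@dataclass(frozen=True)
class HitFootprint:
    """Strand-normalized subject interval of a hit (0-based half-open)."""

    subject_id: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError(f"empty or inverted footprint span {self.span}")


@dataclass(frozen=True)
class TabularHit:
    """One hit in BLAST outfmt-6 field order."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")

    @property
    def is_minus(self) -> bool:
        return self.s_start > self.s_end

    def footprint(self) -> HitFootprint:
        lo, hi = sorted((self.s_start, self.s_end))
        return HitFootprint(self.subject_id, (lo - 1, hi))

    def to_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.query_id,
                self.subject_id,
                self.pct_identity,
                self.aln_len,
                self.mismatches,
                self.gap_opens,
                self.q_start,
                self.q_end,
                self.s_start,
                self.s_end,
                self.evalue,
                self.bit_score,
            )
        )


def parse_tabular_hits(source: str | os.PathLike | TextIO | Iterable[str]) -> list[TabularHit]:
    """Parse BLAST outfmt-6 lines into TabularHit records.

    Accepts a path, an open text handle, or an iterable of lines.  ``#``
    comment lines and blank lines are skipped.  Malformed lines raise
    ``ValueError`` naming the 1-based line number.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    hits: list[TabularHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], dest: str | os.PathLike | TextIO) -> None:
    """Write hits as outfmt-6 lines.

    Floats are written with ``str()`` (exact round-trip through the parser);
    external tools' files remain readable since the parser just calls
    ``float()``.
    """
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            for h in hits:
                fh.write(h.to_line() + "\n")
    else:
        for h in hits:
            dest.write(h.to_line() + "\n")


# ---------------------------------------------------------------------------
# internal seed-and-extend engine


def _seed_positions(mask: str | None, seed_len: int) -> tuple[int, ...] | None:
    """Offsets of match positions for a spaced seed mask, or None if contiguous."""
    if mask is None:
        return None
    if set(mask) - {"0", "1"} or mask[0] != "1" or mask[-1] != "1":
        raise ValueError("spaced seed mask must be a 0/1 string starting and ending with 1")
    return tuple(i for i, c in enumerate(mask) if c == "1")


class _SeedIndex:
    """Exact-k-mer index over a CDS database (forward strand only)."""

    def __init__(self, cds: dict[str, str], seed_len: int, mask: str | None = None):
        self.names = list(cds)
        self.seqs = [cds[n] for n in self.names]
        self.total_len = sum(len(s) for s in self.seqs)
        self.seed_len = seed_len
        self.positions = _seed_positions(mask, seed_len)
        self.span = seed_len if self.positions is None else len(mask)  # type: ignore[arg-type]
        index: dict[str, list[tuple[int, int]]] = {}
        for si, seq in enumerate(self.seqs):
            for pos in range(len(seq) - self.span + 1):
                key = self._key(seq, pos)
                if key is None:
                    continue
                index.setdefault(key, []).append((si, pos))
        self.index = index

    def _key(self, seq: str, pos: int) -> str | None:
        if self.positions is None:
            kmer = seq[pos : pos + self.seed_len]
        else:
            kmer = "".join(seq[pos + off] for off in self.positions)
        return None if "N" in kmer else kmer


def _extend_ungapped(
    q: str, s: str, q_pos: int, s_pos: int, span: int, reward: int, penalty: int, xdrop: int
) -> tuple[int, int, int, int, int]:
    """Maximal-scoring ungapped extension of a seed along its diagonal.

    Returns (q_start, q_end, score, matches, aln_len) with q coords 0-based
    half-open; the subject interval follows from the shared diagonal.
    """
    # score across the seed span itself (spaced seeds may hold mismatches)
    score_seed = 0
    for i in range(span):
        score_seed += reward if q[q_pos + i] == s[s_pos + i] != "N" else penalty

    # extend right of the seed
    best_r, run, qe = 0, 0, q_pos + span
    qi, si = q_pos + span, s_pos + span
    lq, ls = len(q), len(s)
    while qi < lq and si < ls:
        run += reward if q[qi] == s[si] != "N" else penalty
        qi += 1
        si += 1
        if run > best_r:
            best_r, qe = run, qi
        elif run <= best_r - xdrop:
            break

    # extend left of the seed
    best_l, run, qs = 0, 0, q_pos
    qi, si = q_pos - 1, s_pos - 1
    while qi >= 0 and si >= 0:
        run += reward if q[qi] == s[si] != "N" else penalty
        if run > best_l:
            best_l, qs = run, qi
        elif run <= best_l - xdrop:
            break
        qi -= 1
        si -= 1

    score = score_seed + best_r + best_l
    matches = sum(1 for i in range(qs, qe) if q[i] == s[i - q_pos + s_pos] != "N")
    return qs, qe, score, matches, qe - qs


def _check_alphabet(name: str, seq: str) -> None:
    extra = set(seq) - _VALID
    if extra:
        raise ValueError(f"sequence {name!r} contains non-ACGTN characters: {sorted(extra)}")


def _search_one(
    qname: str,
    qseq: str,
    index: _SeedIndex,
    scoring: ScoringScheme,
    evalue_max: float,
    xdrop: int,
) -> list[TabularHit]:
    hits: list[TabularHit] = []
    m = len(qseq)
    n = index.total_len
    for strand, q in (("+", qseq), ("-", revcomp(qseq))):
        seen: set[tuple[int, int]] = set()
        for qpos in range(0, m - index.span + 1):
            key = index._key(q, qpos)
            if key is None:
                continue
            for si, spos in index.index.get(key, ()):
                diag = spos - qpos
                if (si, diag) in seen:
                    continue
                seen.add((si, diag))
                s = index.seqs[si]
                qs, qe, score, matches, alen = _extend_ungapped(
                    q, s, qpos, spos, index.span, scoring.reward, scoring.penalty, xdrop
                )
                ev = scoring.evalue(score, m, n)
                if ev > evalue_max:
                    continue
                ss, se = qs + diag, qe + diag
                if strand == "+":
                    qc = (qs + 1, qe)
                    sc = (ss + 1, se)
                else:
                    qc = (m - qe + 1, m - qs)
                    sc = (se, ss + 1)
                hits.append(
                    TabularHit(
                        query_id=qname,
                        subject_id=index.names[si],
                        pct_identity=round(100.0 * matches / alen, 2),
                        aln_len=alen,
                        mismatches=alen - matches,
                        gap_opens=0,
                        q_start=qc[0],
                        q_end=qc[1],
                        s_start=sc[0],
                        s_end=sc[1],
                        evalue=ev,
                        bit_score=round(scoring.bit_score(score), 1),
                    )
                )
    return hits


def map_reads_to_cds(
    reads: Iterable[tuple[str, str]] | dict[str, str],
    cds_set: dict[str, str],
    scoring: ScoringScheme | None = None,
    seed_len: int = 11,
    evalue_max: float = 1e-5,
    xdrop: int = 20,
    spaced_mask: str | None = None,
) -> list[TabularHit]:
    """Map reads against a CDS database; keep hits with e-value <= threshold.

    Seeds are exact k-mers on both strands; extension is ungapped X-drop.
    'N' never seeds and always scores as a mismatch.
    """
    if isinstance(reads, dict):
        reads = list(reads.items())
    else:
        reads = list(reads)
    if not reads or not cds_set:
        raise ValueError("reads and cds_set must be non-empty")
    if seed_len < 8:
        raise ValueError("seed_len must be >= 8")
    scoring = scoring or ScoringScheme()
    for name, seq in cds_set.items():
        _check_alphabet(name, seq)
    index = _SeedIndex(cds_set, seed_len, spaced_mask)
    hits: list[TabularHit] = []
    for name, seq in reads:
        _check_alphabet(name, seq)
        hits.extend(_search_one(name, seq, index, scoring, evalue_max, xdrop))
    return hits


def align_cds_sets(
    query_cds: dict[str, str],
    subject_cds: dict[str, str],
    scoring: ScoringScheme | None = None,
    seed_len: int = 11,
    evalue_max: float = 1e-5,
    xdrop: int = 20,
    spaced_mask: str | None = None,
) -> list[TabularHit]:
    """Align whole CDSs of one set against another (same engine as reads)."""
    return map_reads_to_cds(
        query_cds, subject_cds, scoring, seed_len, evalue_max, xdrop, spaced_mask
    )


def best_hit_filter(hits: Iterable[TabularHit]) -> list[TabularHit]:
    """Keep one hit per query: lowest e-value, then highest bit score, then
    lexicographically smallest subject id."""
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bit_score, h.subject_id) < (
            cur.evalue,
            -cur.bit_score,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return list(best.values())
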