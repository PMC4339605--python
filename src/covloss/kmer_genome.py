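"""K-mer spectrum, peak-based genome-size estimation, and Lander-Waterman
coverage statistics.

The k-mer spectrum of shotgun reads (canonical 21-mers by default) has an
initial error slope, a valley, and a main peak near the effective
sequencing depth.  Genome size is estimated as the number of k-mers beyond
the error valley divided by the peak depth.  The Lander-Waterman model
treats per-base depth as Poisson(C); P(Y=0) = e^(-C) is the expected
unsequenced fraction of the genome at coverage C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from covloss.seqio import revcomp


@dataclass(frozen=True)
class KmerHistogram:
    """Histogram of canonical k-mer multiplicities."""

    k: int
    counts: dict[int, int]   # multiplicity -> number of distinct canonical k-mers

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def to_tsv(self, path) -> None:
        """Jellyfish `histo`-compatible two-column TSV."""
        with open(path, "w") as fh:
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int = 21) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                m, c = line.split()
                counts[int(m)] = int(c)
        return cls(k=k, counts=counts)


@dataclass(frozen=True)
class GenomeSizeEstimate:
    peak_depth: int
    error_valley: int
    size_bp: float

    def __post_init__(self) -> None:
        if self.error_valley >= self.peak_depth:
            raise ValueError("error_valley must lie below peak_depth")
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")


def kmer_histogram(reads: Iterable[tuple[str, str]] | Iterable[str], k: int = 21) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of k-mer and its reverse
    complement) over the reads; k-mers containing N are skipped.

    ``k`` must be odd (a canonical k-mer is otherwise ambiguous for
    palindromes) and >= 15 so random collisions are negligible.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if k < 15:
        raise ValueError("k must be >= 15")
    mults: dict[str, int] = {}
    n_reads = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        n_reads += 1
        L = len(seq)
        if L < k:
            continue
        rc = revcomp(seq)
        for i in range(L - k + 1):
            kf = seq[i : i + k]
            if "N" in kf:
                continue
            kr = rc[L - k - i : L - i]
            key = kf if kf <= kr else kr
            mults[key] = mults.get(key, 0) + 1
    if n_reads == 0:
        raise ValueError("no reads provided")
    counts: dict[int, int] = {}
    for m in mults.values():
        counts[m] = counts.get(m, 0) + 1
    return KmerHistogram(k=k, counts=counts)


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Estimate genome size from the spectrum's valley/peak structure.

    The error valley is the first local minimum of the counts along the
    (sparse, sorted) multiplicity axis; the peak depth is the multiplicity
    with the highest count at or beyond the valley; the size is the total
    number of k-mers at multiplicities >= valley divided by the peak depth
    (the error slope below the valley is excluded from the total).
    """
    ms = sorted(hist.counts)
    if len(ms) < 2:
        raise ValueError("insufficient coverage: k-mer spectrum has no interior structure")
    vals = [hist.counts[m] for m in ms]
    valley_i: int | None = None
    for i in range(len(ms) - 1):
        left_ok = i == 0 or vals[i] <= vals[i - 1]
        if left_ok and vals[i] <= vals[i + 1]:
            valley_i = i
            break
    if valley_i is None:
        raise ValueError("insufficient coverage: k-mer spectrum is monotone, no valley/peak")
    peak_i = max(range(valley_i, len(ms)), key=lambda i: (vals[i], -i))
    if peak_i == valley_i:
        raise ValueError("insufficient coverage: no peak beyond the error valley")
    valley = ms[valley_i]
    peak = ms[peak_i]
    total = sum(m * hist.counts[m] for m in ms if m >= valley)
    return GenomeSizeEstimate(peak_depth=peak, error_valley=valley, size_bp=total / peak)


def lander_waterman(C: float, y: int) -> float:
    """Poisson depth model: P(Y = y) = C^y e^(-C) / y! at coverage C."""
    if C < 0:
        raise ValueError("coverage must be >= 0")
    if y < 0 or int(y) != y:
        raise ValueError("y must be a non-negative integer")
    y = int(y)
    if C == 0:
        return 1.0 if y == 0 else 0.0
    # log space keeps large y finite where C**y would overflow
    return math.exp(y * math.log(C) - C - math.lgamma(y + 1))


def percent_unsequenced(C: float) -> float:
    """Expected percentage of the genome never sequenced at coverage C:
    100 * P(Y=0) = 100 * e^(-C)."""
    return 100.0 * lander_waterman(C, 0)
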