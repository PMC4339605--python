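"""Discrepancy-rate calibration of horizontal-coverage cut-offs.

The feasibility of read-mapping coverage as a stand-in for a full-length
CDS-vs-CDS comparison is evaluated on a species pair where both the reads
and the complete CDS set of the "query" side are available.  At every
candidate cut-off c, genes whose horizontal coverage is < c are called
lost and the rest conserved, and two discrepancy rates are computed against
the CDS-vs-CDS truth:

  DRL(c) = |{called lost with a significant CDS-vs-CDS hit}| / |called lost|
  DRC(c) = |{called conserved without such a hit}| / |called conserved|

Cut-offs where a denominator is empty are reported as undefined (``None``),
never coerced to 0.  Operating cut-offs are read off the curve as the
largest c with DRL within tolerance and the smallest c with DRC within
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from covloss.coverage import CoverageRecord
from covloss.alignment import TabularHit

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))


@dataclass(frozen=True)
class DRCurve:
    """DRL/DRC tabulated over horizontal-coverage cut-offs."""

    cutoffs: tuple[float, ...]
    drl: tuple[float | None, ...]
    drc: tuple[float | None, ...]
    n_lost: tuple[int, ...]
    n_conserved: tuple[int, ...]

    def at(self, cutoff: float) -> tuple[float | None, float | None]:
        i = self.cutoffs.index(cutoff)
        return self.drl[i], self.drc[i]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n_lost": self.n_lost,
                "drl": [v if v is not None else float("nan") for v in self.drl],
                "n_conserved": self.n_conserved,
                "drc": [v if v is not None else float("nan") for v in self.drc],
            }
        )


def truth_hit_set(cds_vs_cds_hits: Iterable[TabularHit]) -> set[str]:
    """Pivot CDS ids with a significant CDS-vs-CDS hit.

    ``cds_vs_cds_hits`` are best-hit-filtered hits of the query species'
    CDSs against the pivot CDS database; the returned set holds every pivot
    CDS that is the best hit of at least one query CDS.
    """
    return {h.subject_id for h in cds_vs_cds_hits}


def compute_dr_curves(
    coverage: Sequence[CoverageRecord],
    truth: set[str],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> DRCurve:
    """Tabulate DRL and DRC over strictly increasing cut-offs in (0, 1)."""
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(not 0.0 < c < 1.0 for c in cutoffs):
        raise ValueError("cutoffs must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")

    cov = {r.gene_id: r.horizontal_coverage for r in coverage}
    drl: list[float | None] = []
    drc: list[float | None] = []
    n_lost: list[int] = []
    n_cons: list[int] = []
    for c in cutoffs:
        lost = {g for g, v in cov.items() if v < c}
        cons = {g for g, v in cov.items() if v >= c}
        n_lost.append(len(lost))
        n_cons.append(len(cons))
        drl.append(len(lost & truth) / len(lost) if lost else None)
        drc.append(len(cons - truth) / len(cons) if cons else None)
    return DRCurve(cutoffs, tuple(drl), tuple(drc), tuple(n_lost), tuple(n_cons))


def select_cutoffs(
    curve: DRCurve, drl_tol: float = 0.05, drc_tol: float = 0.05
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pick operating cut-offs from a DR curve.

    Returns ``((lost_cutoff, drl_at_it), (conserved_cutoff, drc_at_it))``:
    the largest cut-off whose defined DRL is <= ``drl_tol`` and the smallest
    whose defined DRC is <= ``drc_tol``.  Raises ``ValueError`` when no
    cut-off qualifies, suggesting tolerance relaxation.
    """
    if not curve.cutoffs:
        raise ValueError("empty DR curve")
    lost = [
        (c, v) for c, v in zip(curve.cutoffs, curve.drl) if v is not None and v <= drl_tol
    ]
    cons = [
        (c, v) for c, v in zip(curve.cutoffs, curve.drc) if v is not None and v <= drc_tol
    ]
    if not lost:
        raise ValueError(
            f"no cutoff has DRL <= {drl_tol}; relax drl_tol or extend the cutoff grid"
        )
    if not cons:
        raise ValueError(
            f"no cutoff has DRC <= {drc_tol}; relax drc_tol or extend the cutoff grid"
        )
    return lost[-1], cons[0]


def plot_dr_curves(curve: DRCurve, path) -> None:
    """Two-panel DRL/DRC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    xs = curve.cutoffs
    ax1.plot(xs, [v if v is not None else float("nan") for v in curve.drl], "o-", ms=3)
    ax1.set_xlabel("horizontal coverage cutoff")
    ax1.set_ylabel("DRL")
    ax2.plot(xs, [v if v is not None else float("nan") for v in curve.drc], "o-", ms=3)
    ax2.set_xlabel("horizontal coverage cutoff")
    ax2.set_ylabel("DRC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
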