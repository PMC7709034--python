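"""Amplicon balance, coverage breadth, and negative-control contamination metrics.

Amplicon balance compares each amplicon's median read depth to the median of
all amplicons' median depths for the sample (100X against an overall 150X
gives 0.67; 1.0 means balanced). Coverage breadth is the fraction of
reference positions at or above the minimum calling depth. Negative controls
are assessed by *relative read depth*: the negative's depth as a percentage
of a paired positive control's depth at the same position, with positions
where the positive has no coverage reported as undefined rather than 0 or
infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup import Pileup
from .reference import Amplicon, Panel, RCRS_LENGTH
from .calling import Thresholds


@dataclass(frozen=True)
class AmpliconDepth:
    amplicon_id: str
    median_depth: float
    balance: float  # median_depth / median over all amplicons' medians


@dataclass
class QCReport:
    sample_id: str
    per_amplicon: list[AmpliconDepth]
    breadth_at_min_depth: float
    mean_depth: float
    min_depth: int


def amplicon_median_depth(p: Pileup, a: Amplicon, L: int = RCRS_LENGTH) -> float:
    """Median total depth over the amplicon's (possibly wrapping) span.

    Positions missing from the pileup count as depth 0. An even-length span
    uses the mean of the two middle values.
    """
    depths = [p.depth(pos) for pos in a.positions(L)]
    if not depths:
        raise ValueError(f"amplicon {a.id} has an empty span")
    return float(np.median(depths))


def amplicon_balance(p: Pileup, panel: Panel) -> list[AmpliconDepth]:
    """Per-amplicon balance: amplicon median / median of all amplicon medians."""
    if not panel.amplicons:
        raise ValueError("panel contains no amplicons")
    medians = {a.id: amplicon_median_depth(p, a, panel.L) for a in panel.amplicons}
    overall = float(np.median(list(medians.values())))
    if overall == 0:
        raise ValueError("median of amplicon medians is zero; no usable coverage")
    return [
        AmpliconDepth(a.id, medians[a.id], medians[a.id] / overall)
        for a in panel.amplicons
    ]


def coverage_breadth(p: Pileup, min_depth: int = 20, L: int = RCRS_LENGTH) -> float:
    """Fraction of the L reference positions with depth >= min_depth."""
    n_ok = sum(1 for pos, pc in p.positions.items() if pc.total_depth() >= min_depth)
    return n_ok / L


def mean_depth(p: Pileup, L: int = RCRS_LENGTH) -> float:
    return sum(pc.total_depth() for pc in p.positions.values()) / L


def qc_report(
    p: Pileup, panel: Panel, th: Thresholds = Thresholds()
) -> QCReport:
    return QCReport(
        sample_id=p.sample_id,
        per_amplicon=amplicon_balance(p, panel),
        breadth_at_min_depth=coverage_breadth(p, th.min_depth, panel.L),
        mean_depth=mean_depth(p, panel.L),
        min_depth=th.min_depth,
    )


def relative_read_depth(neg: Pileup, pos: Pileup, L: int = RCRS_LENGTH) -> pd.Series:
    """Per-position 100 * neg_depth / pos_depth.

    Returned as a Series indexed by 1..L; positions where the positive
    control has zero depth are NaN (undefined), never 0 or infinity.
    """
    idx = np.arange(1, L + 1)
    neg_d = np.array([neg.depth(i) for i in idx], dtype=float)
    pos_d = np.array([pos.depth(i) for i in idx], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(pos_d > 0, 100.0 * neg_d / pos_d, np.nan)
    return pd.Series(rel, index=idx, name="relative_depth_pct")


@dataclass
class ContaminationSummary:
    profile: pd.DataFrame  # columns: mean, sd (sd NaN with a single negative)
    fraction_below_bound: float  # of defined positions
    bound_pct: float
    flagged_spans: list[tuple[int, int]]
    flagged_amplicons: dict[tuple[int, int], list[str]] = field(default_factory=dict)


def contamination_summary(
    negatives: list[Pileup],
    pos: Pileup,
    th: Thresholds = Thresholds(),
    bound_pct: float = 10.0,
    panel: Panel | None = None,
    L: int = RCRS_LENGTH,
) -> ContaminationSummary:
    """Mean +/- SD relative depth across negatives, with above-bound spans flagged.

    Spans are maximal runs of positions whose mean relative depth exceeds
    *bound_pct*; if a panel is supplied each span is annotated with the
    amplicons overlapping it (primer-artifact hotspots sit in amplicon
    overlaps).
    """
    if not negatives:
        raise ValueError("need at least one negative control")
    profiles = np.vstack([relative_read_depth(n, pos, L).to_numpy() for n in negatives])
    with warnings.catch_warnings():
        # positions undefined in every negative are legitimately all-NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(profiles, axis=0)
        sd = (
            np.nanstd(profiles, axis=0, ddof=1)
            if len(negatives) > 1
            else np.full(L, np.nan)
        )
    idx = np.arange(1, L + 1)
    profile = pd.DataFrame({"mean": mean, "sd": sd}, index=idx)

    defined = ~np.isnan(mean)
    n_defined = int(defined.sum())
    below = int(((mean < bound_pct) & defined).sum())
    fraction_below = below / n_defined if n_defined else float("nan")

    exceed = defined & (mean >= bound_pct)
    spans: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(exceed, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, L))

    flagged_amps = {}
    if panel is not None:
        for s, e in spans:
            flagged_amps[(s, e)] = panel.amplicons_overlapping(s, e)
    return ContaminationSummary(
        profile=profile,
        fraction_below_bound=fraction_below,
        bound_pct=bound_pct,
        flagged_spans=spans,
        flagged_amplicons=flagged_amps,
    )
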