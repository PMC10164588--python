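"""Per-clone and cohort transfer statistics, union coverage and linkage.

Summaries follow the reporting conventions of whole-genome surveys of
natural transformation recombinants: per-clone event counts, maximum /
mean / total transferred DNA in kb (2 decimals), percentages of the donor
genome (2 decimals), cohort union coverage counting overlapping regions
only once, and the co-inheritance of a query marker with a selected
marker as a function of genomic distance.

The co-inheritance curve of two markers decays with distance while both
can sit on one transferred segment, then flattens to a distance-
independent plateau set by double transformation — co-conversion through
two independent uptake events (gene congression). Under the generative
model (Poisson segment counts, exponential lengths, uniform placement)
the curve has the closed form implemented in ``expected_coinheritance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .types import (
    CloneSummary,
    CohortSummary,
    LinkageCurve,
    TransferSegment,
    ValidationError,
    circular_distance,
    interval_contains,
)

Interval = tuple[int, int]


def _seg_intervals(items) -> list[Interval]:
    """Coerce TransferSegment / RecombinationTract / (start, end) inputs."""
    out = []
    for item in items:
        if isinstance(item, TransferSegment):
            out.append((item.start, item.end))
        elif hasattr(item, "span_start"):
            out.append((item.span_start, item.span_end))
        else:
            s, e = item
            out.append((int(s), int(e)))
    return out


def _interval_lengths(items, genome_length: int) -> np.ndarray:
    lengths = []
    for item in items:
        if hasattr(item, "span_length"):
            lengths.append(item.span_length)
        elif hasattr(item, "length"):
            lengths.append(item.length)
        else:
            s, e = item
            lengths.append(e - s + 1 if s <= e else genome_length - s + 1 + e)
    return np.asarray(lengths, dtype=float)


def clone_summary(
    segments_or_tracts, genome_length: int, clone_id: str = ""
) -> CloneSummary:
    """Event count, max/mean/total transferred DNA (kb) and % of genome.

    Accepts called segments, consolidated tracts, or raw (start, end)
    intervals of one clone. kb and percentages reported to 2 decimals;
    total bp retained exactly.
    """
    items = list(segments_or_tracts)
    if not items:
        return CloneSummary(clone_id, 0, 0.0, 0.0, 0.0, 0.0, 0)
    if not clone_id and hasattr(items[0], "clone_id"):
        clone_id = items[0].clone_id
    lengths = _interval_lengths(items, genome_length)
    total = float(lengths.sum())
    return CloneSummary(
        clone_id=clone_id,
        n_events=len(items),
        max_event_kb=round(float(lengths.max()) / 1_000, 2),
        mean_event_kb=round(total / len(items) / 1_000, 2),
        total_transferred_kb=round(total / 1_000, 2),
        pct_genome=round(100.0 * total / genome_length, 2),
        total_transferred_bp=int(total),
    )


def mean_event_kb(total_kb: float, n_events: int) -> float:
    """Mean event size from a printed total and event count (kb, 2 dp)."""
    if n_events <= 0:
        return 0.0
    return round(total_kb / n_events, 2)


def pct_of_genome(total_kb: float, genome_length: int) -> float:
    """Percentage of the donor genome from a printed total (2 dp)."""
    return round(100.0 * total_kb * 1_000 / genome_length, 2)


def union_coverage(
    clones_segments, genome_length: int, circular: bool = True
) -> tuple[int, float]:
    """Union length (bp) and % of genome across clones, overlaps counted once.

    A sort-and-sweep over all intervals of all clones; wrapped intervals
    are split at the origin first.
    """
    pieces: list[Interval] = []
    for clone in clones_segments:
        for s, e in _seg_intervals(clone):
            if s <= e:
                pieces.append((s, e))
            else:
                if not circular:
                    raise ValidationError("wrapped interval on a linear genome")
                pieces.append((s, genome_length))
                pieces.append((1, e))
    if not pieces:
        return 0, 0.0
    pieces.sort()
    union = 0
    cur_s, cur_e = pieces[0]
    for s, e in pieces[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            union += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    union += cur_e - cur_s + 1
    return union, round(100.0 * union / genome_length, 2)


def cohort_summary(
    clone_summaries: list[CloneSummary],
    union_length_bp: int,
    genome_length: int,
) -> CohortSummary:
    """Cross-clone statistics; the overall mean event size pools all clones
    (sum of totals / sum of event counts), not a mean of per-clone means."""
    if not clone_summaries:
        return CohortSummary(0, 0.0, 0, 0.0, 0.0, 0.0)
    events = np.array([c.n_events for c in clone_summaries])
    totals_kb = np.array([c.total_transferred_kb for c in clone_summaries])
    overall = float(totals_kb.sum() / events.sum()) if events.sum() else 0.0
    return CohortSummary(
        n_clones=len(clone_summaries),
        mean_events=round(float(events.mean()), 2),
        max_events=int(events.max()),
        overall_mean_event_kb=round(overall, 2),
        union_length_kb=round(union_length_bp / 1_000, 2),
        union_pct=round(100.0 * union_length_bp / genome_length, 2),
    )


@dataclass
class CoInheritance:
    """Co-inheritance of a query locus among clones selected at another locus."""

    ratio: float
    n_selected: int
    n_double: int
    ci_low: float
    ci_high: float


def _covered(intervals: list[Interval], pos: int) -> bool:
    return any(interval_contains(s, e, pos) for s, e in intervals)


def co_inheritance_ratio(
    clones_segments,
    selected_locus: int,
    query_locus: int,
    strict: bool = False,
) -> CoInheritance:
    """Fraction of selected clones also donor-converted at the query locus.

    ``clones_segments`` is one interval set per clone (called segments or
    planted truth). Clones not converted at the selected locus are
    filtered out first (they would not have grown on the selective
    plate); with ``strict=True`` such a clone raises instead, asserting
    the cohort was pre-selected. The ratio carries an exact
    (Clopper–Pearson) 95% CI.
    """
    selected = []
    for clone in clones_segments:
        intervals = _seg_intervals(clone)
        if _covered(intervals, selected_locus):
            selected.append(intervals)
        elif strict:
            raise ValidationError("clone not converted at the selected locus")
    if not selected:
        return CoInheritance(math.nan, 0, 0, math.nan, math.nan)
    n_double = sum(_covered(intervals, query_locus) for intervals in selected)
    lo, hi = proportion_confint(n_double, len(selected), alpha=0.05, method="beta")
    return CoInheritance(
        ratio=n_double / len(selected),
        n_selected=len(selected),
        n_double=n_double,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def expected_coinheritance(
    d: float, lam: float, mean_length: float, genome_length: int, circular: bool = True
) -> float:
    """Closed-form co-inheritance ratio under the generative model.

    With segments arriving as a Poisson(λ) process, uniform starts on a
    circle of length G and exponential lengths of mean L, the number of
    segments covering a fixed point is Poisson(μA), μA = λL/G, and the
    number covering both of two points at distance d is Poisson(μ1),
    μ1 = λL·exp(−d/L)/G. Splitting coverage into both/only-A/only-B
    independent Poisson components gives

        P(B | A) = [1 − 2·exp(−μA) + exp(−2μA + μ1)] / [1 − exp(−μA)]

    which equals 1 at d = 0 and decays to the double-transformation
    plateau 1 − exp(−μA) as d → ∞. Distances are minor-arc on circular
    genomes.
    """
    if circular:
        d = min(d, genome_length - d)
    if d < 0:
        raise ValidationError("distance must be non-negative")
    mu_a = lam * mean_length / genome_length
    if mu_a == 0:
        return math.nan
    mu_1 = mu_a * math.exp(-d / mean_length)
    p_a = 1.0 - math.exp(-mu_a)
    p_ab = 1.0 - 2.0 * math.exp(-mu_a) + math.exp(-2.0 * mu_a + mu_1)
    return p_ab / p_a


def linkage_curve(
    clones_segments,
    selected_locus: int,
    query_loci,
    genome_length: int,
    circular: bool = True,
    model_params: dict | None = None,
) -> LinkageCurve:
    """Empirical co-inheritance ratio at each query locus vs its distance."""
    distances, ratios, ns = [], [], []
    for q in query_loci:
        ci = co_inheritance_ratio(clones_segments, selected_locus, q)
        distances.append(circular_distance(selected_locus, q, genome_length, circular))
        ratios.append(ci.ratio)
        ns.append(ci.n_selected)
    order = np.argsort(distances)
    return LinkageCurve(
        distances=np.asarray(distances, dtype=float)[order],
        ratios=np.asarray(ratios, dtype=float)[order],
        n_selected=np.asarray(ns, dtype=int)[order],
        model_params=model_params,
    )


def linkage_decomposition(
    curve: LinkageCurve,
    plateau_min_distance: float = 500_000.0,
    mode: str = "mean",
) -> tuple[float, np.ndarray]:
    """Split a co-inheritance curve into a congression plateau and excess.

    The plateau — the double-transformation ratio — is estimated from
    points at distances ≥ ``plateau_min_distance`` (default 500 kb, beyond
    which co-inheritance is distance-independent), either as their mean
    (``mode="mean"``) or from the single farthest point
    (``mode="farthest"``). excess(d) = max(ratio(d) − plateau, 0) is the
    single-segment linkage contribution at each distance.
    """
    far = curve.distances >= plateau_min_distance
    if not far.any():
        raise ValidationError(
            f"no curve point at distance >= {plateau_min_distance:g}"
        )
    if mode == "mean":
        plateau = float(curve.ratios[far].mean())
    elif mode == "farthest":
        plateau = float(curve.ratios[np.argmax(curve.distances)])
    else:
        raise ValidationError(f"unknown plateau mode {mode!r}")
    excess = np.maximum(curve.ratios - plateau, 0.0)
    curve.plateau = plateau
    return plateau, excess


def transformation_efficiency(
    colonies: int, plated_volume_ml: float, dna_conc_ug_per_ml: float
) -> float:
    """Transformants per μg of donor DNA: colonies / (volume × concentration)."""
    if plated_volume_ml <= 0 or dna_conc_ug_per_ml <= 0:
        raise ValidationError("volume and DNA concentration must be positive")
    return colonies / (plated_volume_ml * dna_conc_ug_per_ml)
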