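"""Consolidating called segments into recombination tracts.

Nearby transfer segments in one clone often derive from a single long
donor DNA molecule that was fragmented before or during integration. To
estimate the number of independent uptake events, segments are clustered
into recombination tracts under three criteria:

(i)   the gap between adjacent member segments is < 20 kb;
(ii)  member segments occupy at least 50% of the tract span;
(iii) the tract span is < 500 kb.

Consolidation is greedy left-to-right: a tract grows by appending the
next segment whenever the grown tract still satisfies all three criteria,
and is closed otherwise. Every segment belongs to exactly one tract;
a singleton tract is always valid (occupancy 1).
"""

from __future__ import annotations

import numpy as np

from .types import (
    RecombinationTract,
    TransferSegment,
    ValidationError,
    interval_length,
)

MAX_GAP_DEFAULT = 20_000
MIN_OCCUPANCY_DEFAULT = 0.5
MAX_SPAN_DEFAULT = 500_000


def _unwrap(segments: list[TransferSegment], genome_length: int) -> list[tuple[int, int, TransferSegment]]:
    """Linearise segments as (start', end) with a wrapped segment shifted
    before the origin (start' = start − G ≤ 0).

    Tracts never wrap the origin unless a member segment does; at most one
    segment of a disjoint set can wrap, and shifting it ahead of position 1
    starts the left-to-right scan at that segment while preserving gap and
    span arithmetic.
    """
    out = []
    for seg in segments:
        start = seg.start if seg.start <= seg.end else seg.start - genome_length
        out.append((start, seg.end, seg))
    out.sort(key=lambda t: t[0])
    return out


def _check_disjoint(lin: list[tuple[int, int, TransferSegment]]) -> None:
    for (s1, e1, _), (s2, _, _) in zip(lin, lin[1:]):
        if s2 <= e1:
            raise ValidationError(
                f"segments overlap: [{s1},{e1}] and starting at {s2}"
            )


def consolidate(
    segments: list[TransferSegment],
    genome_length: int,
    max_gap: int = MAX_GAP_DEFAULT,
    min_occupancy: float = MIN_OCCUPANCY_DEFAULT,
    max_span: int = MAX_SPAN_DEFAULT,
) -> list[RecombinationTract]:
    """Greedy left-to-right consolidation under the gap/occupancy/span criteria.

    Criteria are evaluated at every append (a candidate member joining a
    tract must keep gap < max_gap, span < max_span and occupancy ≥
    min_occupancy); there is no look-ahead or backtracking, so the result
    is deterministic and order-canonical.
    """
    if not segments:
        return []
    lin = _unwrap(segments, genome_length)
    _check_disjoint(lin)
    clone_id = segments[0].clone_id

    tracts: list[RecombinationTract] = []
    cur: list[tuple[int, int, TransferSegment]] = [lin[0]]
    cur_occupied = lin[0][2].length

    def close() -> None:
        span_start_lin = cur[0][0]
        span_end = cur[-1][1]
        span_len = span_end - span_start_lin + 1
        span_start = (
            span_start_lin if span_start_lin >= 1 else span_start_lin + genome_length
        )
        tracts.append(
            RecombinationTract(
                clone_id=clone_id,
                members=[m[2] for m in cur],
                span_start=span_start,
                span_end=span_end,
                span_length=span_len,
                occupied_length=cur_occupied,
            )
        )

    for s, e, seg in lin[1:]:
        gap = s - cur[-1][1] - 1
        new_span = e - cur[0][0] + 1
        new_occupied = cur_occupied + seg.length
        if (
            gap < max_gap
            and new_span < max_span
            and new_occupied / new_span >= min_occupancy
        ):
            cur.append((s, e, seg))
            cur_occupied = new_occupied
        else:
            close()
            cur = [(s, e, seg)]
            cur_occupied = seg.length
    close()
    return tracts


def validate_tracts(
    tracts: list[RecombinationTract],
    segments: list[TransferSegment],
    genome_length: int,
    max_gap: int = MAX_GAP_DEFAULT,
    min_occupancy: float = MIN_OCCUPANCY_DEFAULT,
    max_span: int = MAX_SPAN_DEFAULT,
) -> None:
    """Assert every emitted tract satisfies all criteria and that the
    tracts exactly partition the input segments. Raises ValidationError."""
    seen: list[TransferSegment] = []
    for tract in tracts:
        lin = _unwrap(tract.members, genome_length)
        if [m[2] for m in lin] != tract.members:
            raise ValidationError("tract members not sorted")
        for (s1, e1, _), (s2, _, _) in zip(lin, lin[1:]):
            gap = s2 - e1 - 1
            if gap >= max_gap:
                raise ValidationError(f"inter-member gap {gap} >= {max_gap}")
        if tract.span_length >= max_span and len(tract.members) > 1:
            raise ValidationError(f"tract span {tract.span_length} >= {max_span}")
        if tract.occupancy < min_occupancy - 1e-12:
            raise ValidationError(f"tract occupancy {tract.occupancy:.3f} < {min_occupancy}")
        if tract.occupied_length != sum(m.length for m in tract.members):
            raise ValidationError("occupied_length != sum of member lengths")
        expected_span = lin[-1][1] - lin[0][0] + 1
        if tract.span_length != expected_span:
            raise ValidationError("span_length inconsistent with members")
        seen.extend(tract.members)
    if sorted(seen, key=lambda s: s.start) != sorted(segments, key=lambda s: s.start):
        raise ValidationError("tracts do not partition the input segments")


def tracts_as_segments(tracts: list[RecombinationTract]) -> list[TransferSegment]:
    """View tracts as span intervals, e.g. for re-consolidation or summaries."""
    return [
        TransferSegment(
            clone_id=t.clone_id,
            start=t.span_start,
            end=t.span_end,
            length=t.span_length,
            n_support=sum(m.n_support for m in t.members),
        )
        for t in tracts
    ]


def tract_summary(tracts: list[RecombinationTract], genome_length: int) -> dict:
    """Count, mean/max/total span (kb, 2 dp) and % of the donor genome."""
    if not tracts:
        return {
            "n_tracts": 0,
            "mean_span_kb": 0.0,
            "max_span_kb": 0.0,
            "total_span_kb": 0.0,
            "pct_genome": 0.0,
        }
    spans = np.array([t.span_length for t in tracts], dtype=float)
    total = float(spans.sum())
    return {
        "n_tracts": len(tracts),
        "mean_span_kb": round(total / len(tracts) / 1_000, 2),
        "max_span_kb": round(float(spans.max()) / 1_000, 2),
        "total_span_kb": round(total / 1_000, 2),
        "pct_genome": round(100.0 * total / genome_length, 2),
    }
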