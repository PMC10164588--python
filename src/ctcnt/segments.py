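"""Calling transferred DNA segments as runs of donor-state markers.

A transfer event is a maximal run of consecutive informative sites in the
donor state, scanned in increasing coordinate order. A run must be seeded
by at least two donor-state sites (``min_seed``), extends as far as donor
sites continue, and is terminated by a recipient-state site. Missing sites
are transparent: they neither extend support nor interrupt a run, because
poorly supported calls were already filtered out upstream and cannot
witness an interruption. A qualifying run is emitted iff its hull length
(first to last donor-state site, inclusive) strictly exceeds
``min_length`` nucleotides.

On circular chromosomes, a run reaching the last informative site and a
run starting at the first one — with no recipient-state site between them
across the origin — are merged into a single origin-spanning segment
before the seed/length filters, with length computed modulo the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    DONOR,
    MISSING,
    RECIPIENT,
    CloneTruth,
    GenotypeTrack,
    MarkerMap,
    TransferSegment,
    ValidationError,
    interval_length,
)

MIN_SEED_DEFAULT = 2
MIN_LENGTH_DEFAULT = 500  # strict: a run is kept iff hull length > 500 nt


def _runs_with_interrupt_tolerance(
    donor: np.ndarray, max_interrupts: int
) -> list[np.ndarray]:
    """Maximal donor runs over a donor/recipient sequence (missing removed),
    optionally tolerating up to ``max_interrupts`` recipient sites per run."""
    idx = np.flatnonzero(donor)
    if idx.size == 0:
        return []
    if max_interrupts == 0:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return np.split(idx, breaks + 1)
    runs: list[np.ndarray] = []
    current = [int(idx[0])]
    budget = max_interrupts
    for j in idx[1:].tolist():
        gap = j - current[-1] - 1  # recipient sites between consecutive donor sites
        if gap <= budget:
            budget -= gap
            current.append(j)
        else:
            runs.append(np.array(current))
            current = [j]
            budget = max_interrupts
    runs.append(np.array(current))
    return runs


def call_segments(
    track: GenotypeTrack,
    marker_map: MarkerMap,
    min_seed: int = MIN_SEED_DEFAULT,
    min_length: int = MIN_LENGTH_DEFAULT,
    circular: bool | None = None,
    max_interrupts: int = 0,
) -> list[TransferSegment]:
    """Call transfer segments from one clone's genotype track.

    Parameters
    ----------
    min_seed
        Minimum number of donor-state sites for a run to qualify.
    min_length
        Runs are kept iff hull length is strictly greater than this.
    circular
        Override the map's circularity (``circular=False`` forces linear
        scanning, i.e. no merging across the origin).
    max_interrupts
        Number of recipient-state sites a run may absorb before it is
        terminated. The default 0 means a single recipient site ends the
        run.
    """
    if len(track) != len(marker_map):
        raise ValidationError(
            f"track has {len(track)} states for a map of {len(marker_map)} sites"
        )
    if circular is None:
        circular = marker_map.circular
    keep = track.states != MISSING
    states = track.states[keep]
    positions = marker_map.positions[keep]
    donor = states == DONOR
    runs = _runs_with_interrupt_tolerance(donor, max_interrupts)
    if not runs:
        return []

    G = marker_map.genome_length
    hulls: list[tuple[int, int, int]] = [
        (int(positions[r[0]]), int(positions[r[-1]]), int(r.size)) for r in runs
    ]
    first_run, last_run = runs[0], runs[-1]
    spans_all = len(runs) == 1 and first_run.size == donor.size
    if (
        circular
        and len(runs) >= 1
        and not spans_all
        and first_run[0] == 0
        and last_run[-1] == donor.size - 1
        and len(runs) >= 2
    ):
        # no recipient site separates the terminal run from the leading run
        # across the origin: merge them into one wrapped segment
        s_last, e_last, n_last = hulls[-1]
        s_first, e_first, n_first = hulls[0]
        hulls = [(s_last, e_first, n_last + n_first)] + hulls[1:-1]

    segments = [
        TransferSegment.from_hull(track.clone_id, s, e, G, n)
        for s, e, n in hulls
        if n >= min_seed and interval_length(s, e, G) > min_length
    ]
    return sorted(segments, key=lambda seg: seg.start)


def _merge_truth_intervals(
    segments: list[tuple[int, int]], genome_length: int, circular: bool
) -> list[tuple[int, int]]:
    """Union of planted intervals as disjoint components (wrap-aware)."""
    if not segments:
        return []
    pieces: list[tuple[int, int]] = []
    for s, e in segments:
        if s <= e:
            pieces.append((s, e))
        else:
            pieces.append((s, genome_length))
            pieces.append((1, e))
    pieces.sort()
    merged = [list(pieces[0])]
    for s, e in pieces[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if circular and len(merged) > 1 and merged[0][0] == 1 and merged[-1][1] == genome_length:
        first = merged.pop(0)
        merged[-1][1] = first[1]  # wrapped component: start > end
    return [(int(s), int(e)) for s, e in merged]


@dataclass
class TruthMatchReport:
    """Validation of called segments against planted ground truth."""

    matches: pd.DataFrame  # one row per detectable truth component
    undetectable: pd.DataFrame  # components with <min_seed markers or short hull
    false_calls: list[TransferSegment] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return int(self.matches["detected"].sum()) if len(self.matches) else 0


def match_truth(
    segments: list[TransferSegment],
    truth: CloneTruth,
    marker_map: MarkerMap,
    min_seed: int = MIN_SEED_DEFAULT,
    min_length: int = MIN_LENGTH_DEFAULT,
) -> TruthMatchReport:
    """Compare called segments with planted segments of the same clone.

    Planted intervals are first merged into union components (overlapping
    plantings are indistinguishable to any marker-based caller). Each
    component's expected call is its marker hull — the first to last
    informative site it covers. Components whose hull has fewer than
    ``min_seed`` markers, or hull length ≤ ``min_length``, are reported as
    undetectable by design rather than as caller misses.
    """
    G = marker_map.genome_length
    components = _merge_truth_intervals(truth.segments, G, marker_map.circular)
    rows, undet = [], []
    matched_calls: set[int] = set()
    for s, e in components:
        idx = marker_map.site_indices_in(s, e)
        if idx.size:
            hs = int(marker_map.positions[idx[0]])
            he = int(marker_map.positions[idx[-1]])
        hull_len = interval_length(hs, he, G) if idx.size else 0
        if idx.size < min_seed or hull_len <= min_length:
            undet.append(
                {
                    "truth_start": s,
                    "truth_end": e,
                    "n_markers": int(idx.size),
                    "hull_length": hull_len,
                }
            )
            continue
        hit = None
        for k, seg in enumerate(segments):
            if _intervals_overlap(seg.start, seg.end, hs, he, G):
                hit = k
                matched_calls.add(k)
                break
        rows.append(
            {
                "truth_start": s,
                "truth_end": e,
                "hull_start": hs,
                "hull_end": he,
                "detected": hit is not None,
                "exact_hull": hit is not None
                and segments[hit].start == hs
                and segments[hit].end == he,
                "start_offset": abs(segments[hit].start - hs) if hit is not None else None,
                "end_offset": abs(segments[hit].end - he) if hit is not None else None,
            }
        )
    false_calls = [seg for k, seg in enumerate(segments) if k not in matched_calls]
    return TruthMatchReport(
        matches=pd.DataFrame(
            rows,
            columns=[
                "truth_start",
                "truth_end",
                "hull_start",
                "hull_end",
                "detected",
                "exact_hull",
                "start_offset",
                "end_offset",
            ],
        ),
        undetectable=pd.DataFrame(
            undet, columns=["truth_start", "truth_end", "n_markers", "hull_length"]
        ),
        false_calls=false_calls,
    )


def _intervals_overlap(s1: int, e1: int, s2: int, e2: int, G: int) -> bool:
    def pieces(s: int, e: int) -> list[tuple[int, int]]:
        return [(s, e)] if s <= e else [(s, G), (1, e)]

    return any(
        a_s <= b_e and b_s <= a_e
        for a_s, a_e in pieces(s1, e1)
        for b_s, b_e in pieces(s2, e2)
    )
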