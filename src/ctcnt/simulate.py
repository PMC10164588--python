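"""Synthetic donor/recipient genome pairs and recombinant genotype tracks.

The generator emulates the experimental design of cell-to-cell natural
transformation between two diverged strains: a circular donor chromosome
distinguished from the recipient by a dense map of informative SNPs, and
recombinant clones that acquired donor DNA in one or more contiguous
chromosomal segments. Optionally, clones are conditioned on selection at
marker loci (auxotrophic-marker selection modelled as rejection sampling).

The transfer process is modelled as a Poisson number of independent
segments per clone, each starting uniformly on the circle with an
exponentially distributed length. Planted segments are recorded in
continuous coordinates as ground truth; a clone's genotype at a marker
site is donor iff the site is covered by at least one planted segment.

Reproducibility: a single root seed is split into per-clone child streams
(numpy SeedSequence.spawn), so the marker map and each clone are invariant
to the total number of clones requested.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .types import (
    DONOR,
    MISSING,
    RECIPIENT,
    CloneTruth,
    ConfigurationError,
    GenotypeTrack,
    MarkerMap,
    SimulationConfig,
    interval_contains,
)

_BASES = np.array(["A", "C", "G", "T"])


def _map_rng(config: SimulationConfig) -> np.random.Generator:
    root = np.random.SeedSequence(config.rng_seed)
    return np.random.default_rng(root.spawn(1)[0])


def clone_rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    """Per-clone child streams: clone i's stream is independent of n."""
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(n + 1)  # child 0 is reserved for the marker map
    return [np.random.default_rng(c) for c in children[1:]]


def generate_marker_map(config: SimulationConfig) -> MarkerMap:
    """Draw informative SNP sites along the donor reference.

    Under ``poisson_process`` inter-site gaps are i.i.d. geometric with mean
    ``snp_spacing_mean`` (a discretised Poisson process, so the site count
    over a region is Poisson to good approximation). Under ``fixed_grid``
    sites sit at exact multiples of the spacing. Donor and recipient alleles
    are drawn as distinct random bases.
    """
    config.validate()
    rng = _map_rng(config)
    G = config.genome_length
    if config.spacing_model == "fixed_grid":
        step = int(round(config.snp_spacing_mean))
        positions = np.arange(step, G + 1, step, dtype=np.int64)
    else:
        # draw geometric gaps in blocks until we pass the end of the genome
        p = 1.0 / config.snp_spacing_mean
        chunks: list[np.ndarray] = []
        total = 0
        expected = int(G * p)
        while total < G:
            gaps = rng.geometric(p, size=max(1024, expected + 4 * int(math.sqrt(expected + 1))))
            chunks.append(gaps)
            total += int(gaps.sum())
        positions = np.cumsum(np.concatenate(chunks))
        positions = positions[positions <= G].astype(np.int64)
    n = positions.size
    recipient = _BASES[rng.integers(0, 4, size=n)]
    # donor allele differs from recipient: shift by 1..3 in base order
    shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(_BASES, recipient)
    donor = _BASES[(base_idx + shift) % 4]
    return MarkerMap(
        genome_length=G,
        circular=config.circular,
        positions=positions,
        donor_alleles=donor,
        recipient_alleles=recipient,
    )


def _draw_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw planted transfer segments in continuous 1-based coordinates."""
    G = config.genome_length
    if config.segments_per_clone_dist == "poisson":
        n = int(rng.poisson(config.segments_per_clone_mean))
    else:
        n = int(round(config.segments_per_clone_mean))
    if n == 0:
        return []
    starts = rng.integers(1, G + 1, size=n)
    if config.segment_length_dist == "exponential":
        lengths = rng.exponential(config.segment_length_mean, size=n)
    elif config.segment_length_dist == "lognormal":
        sigma = config.segment_length_sigma
        mu = math.log(config.segment_length_mean) - sigma**2 / 2.0
        lengths = rng.lognormal(mu, sigma, size=n)
    else:
        lengths = np.full(n, float(config.segment_length_mean))
    lengths = np.maximum(1, np.rint(lengths).astype(np.int64))
    lengths = np.minimum(lengths, G)  # a segment can at most replace the chromosome
    segments = []
    for s, L in zip(starts.tolist(), lengths.tolist()):
        end = s + L - 1
        if config.circular and end > G:
            end -= G  # wraps the origin: start > end
        else:
            end = min(end, G)
        segments.append((int(s), int(end)))
    return segments


def _genotype_from_segments(
    marker_map: MarkerMap,
    segments: list[tuple[int, int]],
    clone_id: str,
    rng: np.random.Generator,
    missing_rate: float,
) -> GenotypeTrack:
    states = np.full(len(marker_map), RECIPIENT, dtype=np.int8)
    for start, end in segments:
        states[marker_map.site_indices_in(start, end)] = DONOR
    if missing_rate > 0:
        states[rng.random(states.size) < missing_rate] = MISSING
    return GenotypeTrack(clone_id=clone_id, states=states)


def simulate_clone(
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> tuple[GenotypeTrack, CloneTruth]:
    """Simulate one unselected recombinant clone.

    Overlapping planted segments are allowed; their union defines the
    donor-state sites, mirroring the fact that sequencing cannot separate
    overlapping transfer events either.
    """
    segments = _draw_segments(config, rng)
    track = _genotype_from_segments(
        marker_map, segments, clone_id, rng, config.missing_rate
    )
    return track, CloneTruth(clone_id=clone_id, segments=segments)


def _loci_covered(
    segments: list[tuple[int, int]], loci: tuple[int, ...]
) -> bool:
    return all(
        any(interval_contains(s, e, locus) for s, e in segments) for locus in loci
    )


def simulate_selected_clone(
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> tuple[GenotypeTrack, CloneTruth]:
    """Simulate a clone conditioned on selection at ``config.selected_loci``.

    Rejection sampling: clones are redrawn until every selected locus is
    covered by a planted segment and its nearest informative marker is in
    the donor state (so the selection is visible in the genotype track).
    Raises ConfigurationError after ``max_rejections`` failed draws, which
    catches impossible selections such as a zero segment rate.
    """
    if not config.selected_loci:
        raise ConfigurationError("simulate_selected_clone requires selected_loci")
    nearest = [marker_map.nearest_site_index(locus) for locus in config.selected_loci]
    rejections = 0
    while rejections <= config.max_rejections:
        segments = _draw_segments(config, rng)
        if _loci_covered(segments, config.selected_loci):
            track = _genotype_from_segments(
                marker_map, segments, clone_id, rng, config.missing_rate
            )
            if all(track.states[i] == DONOR for i in nearest):
                truth = CloneTruth(
                    clone_id=clone_id,
                    segments=segments,
                    selection_accepted=True,
                    rejection_count=rejections,
                )
                return track, truth
        rejections += 1
    raise ConfigurationError(
        f"selection not satisfied after {config.max_rejections} rejections; "
        "the selected loci may be unreachable under this configuration"
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MarkerMap, list[GenotypeTrack], list[CloneTruth]]:
    """Marker map plus ``n_clones`` recombinants (selected if loci are set)."""
    config.validate()
    marker_map = generate_marker_map(config)
    tracks: list[GenotypeTrack] = []
    truths: list[CloneTruth] = []
    for i, rng in enumerate(clone_rngs(config, config.n_clones)):
        cid = f"clone-{i + 1:03d}"
        if config.selected_loci:
            track, truth = simulate_selected_clone(marker_map, config, rng, cid)
        else:
            track, truth = simulate_clone(marker_map, config, rng, cid)
        tracks.append(track)
        truths.append(truth)
    return marker_map, tracks, truths


def expected_acceptance_rate(config: SimulationConfig) -> float:
    """Closed-form acceptance probability of selection at a single locus.

    For Poisson(λ) segments with exponential mean-L lengths placed uniformly
    on a circle of length G, the number of segments covering a fixed point
    is Poisson with mean λL/G, so P(covered) = 1 − exp(−λL/G). Used as an
    analytic cross-check of the rejection sampler.
    """
    mu = (
        config.segments_per_clone_mean
        * config.segment_length_mean
        / config.genome_length
    )
    return 1.0 - math.exp(-mu)


def write_fixtures(
    marker_map: MarkerMap,
    tracks: list[GenotypeTrack],
    truths: list[CloneTruth],
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit FASTA/VCF/BED/JSON fixtures for the synthetic cohort.

    The donor and recipient FASTA sequences differ exactly at the map
    sites; per-clone VCFs carry GT calls at every map site (1/1 donor,
    0/0 recipient, ./. missing) against the recipient as reference; truth
    BED stores planted segments 0-based half-open (wrapped segments split
    in two lines sharing a name).
    """
    from . import io as ctcnt_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 0xFA57A)))
    background = _BASES[rng.integers(0, 4, size=config.genome_length)]
    recipient_seq = background.copy()
    recipient_seq[marker_map.positions - 1] = marker_map.recipient_alleles
    donor_seq = background.copy()
    donor_seq[marker_map.positions - 1] = marker_map.donor_alleles

    paths: dict[str, Path] = {}
    paths["donor_fasta"] = ctcnt_io.write_fasta(
        outdir / "donor.fasta", "donor", "".join(donor_seq)
    )
    paths["recipient_fasta"] = ctcnt_io.write_fasta(
        outdir / "recipient.fasta", "recipient", "".join(recipient_seq)
    )
    clone_dir = outdir / "clones"
    clone_dir.mkdir(exist_ok=True)
    for track in tracks:
        paths[f"vcf:{track.clone_id}"] = ctcnt_io.write_clone_vcf(
            clone_dir / f"{track.clone_id}.vcf", marker_map, track
        )
    paths["truth_bed"] = ctcnt_io.write_truth_bed(
        outdir / "truth.bed", truths, marker_map.genome_length
    )
    paths["config_json"] = ctcnt_io.write_config_json(
        outdir / "config.json", config
    )
    paths["map_tsv"] = ctcnt_io.write_marker_map_tsv(outdir / "markers.tsv", marker_map)
    return paths
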