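"""Core domain types for the cell-to-cell natural transformation (CTCNT) pipeline.

Coordinates are 1-based inclusive on the donor reference throughout the
package; BED emission converts to 0-based half-open at the boundary. A
transferred interval on a circular chromosome may wrap the replication
origin, in which case ``start > end`` and its length is computed modulo the
genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

# Genotype states of a recombinant clone at an informative marker site.
RECIPIENT = 0
DONOR = 1
MISSING = -1

STATE_NAMES = {RECIPIENT: "recipient", DONOR: "donor", MISSING: "missing"}


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class ConfigurationError(ValidationError):
    """Raised for invalid simulation or pipeline configuration."""


def interval_length(start: int, end: int, genome_length: int) -> int:
    """Length of a 1-based inclusive interval, wrap-aware.

    ``start > end`` denotes an interval wrapping the origin of a circular
    chromosome: [start, G] + [1, end].
    """
    if start <= end:
        return end - start + 1
    return genome_length - start + 1 + end


def interval_contains(start: int, end: int, pos: int) -> bool:
    """Whether a (possibly wrapped) 1-based inclusive interval contains pos."""
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end


def circular_distance(a: int, b: int, genome_length: int, circular: bool = True) -> int:
    """Distance between two positions; minor arc on circular genomes."""
    d = abs(a - b)
    if circular:
        return min(d, genome_length - d)
    return d


@dataclass(frozen=True)
class MarkerSite:
    """One informative position distinguishing donor from recipient."""

    position: int
    donor_allele: str
    recipient_allele: str

    @property
    def informative(self) -> bool:
        return self.donor_allele != self.recipient_allele


@dataclass
class MarkerMap:
    """Ordered informative marker sites along the donor reference.

    Internally stored as parallel arrays (positions sorted strictly
    increasing) for vectorised genotype and run-calling operations.
    """

    genome_length: int
    circular: bool
    positions: np.ndarray  # int64, strictly increasing, 1-based
    donor_alleles: np.ndarray  # unicode length-1
    recipient_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.donor_alleles = np.asarray(self.donor_alleles, dtype="U1")
        self.recipient_alleles = np.asarray(self.recipient_alleles, dtype="U1")
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValidationError("marker positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.genome_length:
                raise ValidationError("marker positions outside [1, genome_length]")

    def __len__(self) -> int:
        return int(self.positions.size)

    def __iter__(self) -> Iterator[MarkerSite]:
        for p, d, r in zip(self.positions, self.donor_alleles, self.recipient_alleles):
            yield MarkerSite(int(p), str(d), str(r))

    def nearest_site_index(self, pos: int) -> int:
        """Index of the informative site nearest to pos (ties -> lower coordinate).

        Distances are minor-arc on circular genomes.
        """
        if not len(self):
            raise ValidationError("empty marker map has no nearest site")
        d = np.abs(self.positions - pos)
        if self.circular:
            d = np.minimum(d, self.genome_length - d)
        return int(np.argmin(d))  # argmin takes the first (lowest-coordinate) tie

    def site_indices_in(self, start: int, end: int) -> np.ndarray:
        """Indices of sites inside a (possibly wrapped) inclusive interval,
        in circular scan order starting from ``start``."""
        if start <= end:
            lo = np.searchsorted(self.positions, start, side="left")
            hi = np.searchsorted(self.positions, end, side="right")
            return np.arange(lo, hi)
        head = self.site_indices_in(start, self.genome_length)
        tail = self.site_indices_in(1, end)
        return np.concatenate([head, tail])


@dataclass
class GenotypeTrack:
    """One recombinant's call (donor/recipient/missing) at each map site."""

    clone_id: str
    states: np.ndarray  # int8, aligned with MarkerMap.positions

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = ~np.isin(self.states, (RECIPIENT, DONOR, MISSING))
        if bad.any():
            raise ValidationError("genotype states must be donor/recipient/missing")

    def __len__(self) -> int:
        return int(self.states.size)

    def state_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.states == code))
            for code, name in STATE_NAMES.items()
        }


@dataclass(frozen=True)
class TransferSegment:
    """A called transfer event: a maximal run of donor-state marker sites.

    start/end are the positions of the first and last donor-state site of
    the run; start > end denotes a run wrapping the origin.
    """

    clone_id: str
    start: int
    end: int
    length: int
    n_support: int

    @classmethod
    def from_hull(
        cls, clone_id: str, start: int, end: int, genome_length: int, n_support: int
    ) -> "TransferSegment":
        return cls(
            clone_id=clone_id,
            start=start,
            end=end,
            length=interval_length(start, end, genome_length),
            n_support=n_support,
        )


@dataclass
class CloneTruth:
    """Planted ground truth for one simulated clone."""

    clone_id: str
    segments: list[tuple[int, int]]  # continuous coords, 1-based inclusive, may wrap
    selection_accepted: bool = True
    rejection_count: int = 0


@dataclass
class RecombinationTract:
    """A cluster of transfer segments consolidated under gap/occupancy/span rules."""

    clone_id: str
    members: list[TransferSegment]
    span_start: int
    span_end: int
    span_length: int
    occupied_length: int

    @property
    def occupancy(self) -> float:
        return self.occupied_length / self.span_length


@dataclass
class CloneSummary:
    """Per-clone transfer statistics (kb and % reported to 2 decimals)."""

    clone_id: str
    n_events: int
    max_event_kb: float
    mean_event_kb: float
    total_transferred_kb: float
    pct_genome: float
    total_transferred_bp: int = 0


@dataclass
class CohortSummary:
    n_clones: int
    mean_events: float
    max_events: int
    overall_mean_event_kb: float  # sum of totals / sum of event counts
    union_length_kb: float
    union_pct: float


@dataclass
class LinkageCurve:
    """Co-inheritance ratio of a query marker with a selected marker vs distance."""

    distances: np.ndarray
    ratios: np.ndarray
    n_selected: np.ndarray
    plateau: float | None = None
    model_params: dict | None = None  # {"lam", "mean_length", "genome_length"}

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.n_selected = np.asarray(self.n_selected, dtype=int)
        if np.any((self.ratios < 0) | (self.ratios > 1)):
            raise ValidationError("co-inheritance ratios must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic donor/recipient pairs and recombinants.

    Defaults model a pair of diverged B. subtilis strains: a 4,011,967 bp
    circular donor chromosome carrying informative SNPs at a mean spacing of
    one per 56 bp, and recombinants acquiring a Poisson number of donor
    segments with exponentially distributed lengths.
    """

    genome_length: int = 4_011_967
    circular: bool = True
    snp_spacing_mean: float = 56.0
    spacing_model: str = "poisson_process"  # or "fixed_grid"
    segments_per_clone_dist: str = "poisson"  # or "fixed"
    segments_per_clone_mean: float = 15.0
    segment_length_dist: str = "exponential"  # or "lognormal", "fixed"
    segment_length_mean: float = 30_000.0
    segment_length_sigma: float = 1.0  # lognormal shape parameter only
    min_output_length: int = 500
    selected_loci: tuple[int, ...] = ()
    n_clones: int = 12
    rng_seed: int = 0
    missing_rate: float = 0.0
    max_rejections: int = 100_000

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be > 0")
        if self.snp_spacing_mean < 1:
            raise ConfigurationError("snp_spacing_mean must be >= 1")
        if self.spacing_model not in ("poisson_process", "fixed_grid"):
            raise ConfigurationError(f"unknown spacing_model {self.spacing_model!r}")
        if self.segments_per_clone_dist not in ("poisson", "fixed"):
            raise ConfigurationError(
                f"unknown segments_per_clone_dist {self.segments_per_clone_dist!r}"
            )
        if self.segments_per_clone_mean < 0:
            raise ConfigurationError("segments_per_clone_mean must be >= 0")
        if self.segment_length_dist not in ("exponential", "lognormal", "fixed"):
            raise ConfigurationError(
                f"unknown segment_length_dist {self.segment_length_dist!r}"
            )
        if self.segment_length_mean < 1:
            raise ConfigurationError("segment_length_mean must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_clones < 0:
            raise ConfigurationError("n_clones must be >= 0")
        for locus in self.selected_loci:
            if not 1 <= locus <= self.genome_length:
                raise ConfigurationError(
                    f"selected locus {locus} outside [1, {self.genome_length}]"
                )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["selected_loci"] = list(self.selected_loci)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "selected_loci" in d:
            d["selected_loci"] = tuple(d["selected_loci"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
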