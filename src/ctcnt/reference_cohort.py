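"""Published reference statistics for CTCNT-C recombinant cohorts.

These are the printed summary statistics of a whole-genome-sequenced
cohort of nine B. subtilis recombinants obtained by cell-to-cell natural
transformation under simultaneous selection for four or five auxotrophic
markers (donor RO-NN-1, recipient a 168-derived multiple auxotroph). They
serve as fixed inputs for the summary arithmetic: event counts, maximum
event sizes and total transferred DNA are primary observations; mean
event sizes and genome percentages are derived and recomputed by the
summarize module.
"""

from __future__ import annotations

from dataclasses import dataclass

DONOR_GENOME_LENGTH = 4_011_967  # bp, circular donor chromosome
RECIPIENT_GENOME_LENGTH = 4_215_071  # bp, circular recipient chromosome
RECIPIENT_PLASMID_LENGTH = 6_299  # bp, circular plasmid
N_INFORMATIVE_SNPS = 70_909  # evenly distributed donor/recipient SNPs
MEAN_SNP_SPACING = 56  # bp, approximate mean marker spacing


@dataclass(frozen=True)
class ReferenceClone:
    clone_id: str
    selected_markers: str
    n_events: int  # primary: number of called transfer segments
    max_event_kb: float  # primary: largest segment
    mean_event_kb: float  # derived: total / n, 2 dp
    total_transferred_kb: float  # primary: sum of segment lengths
    pct_genome: float  # derived: 100 * total / donor genome, 2 dp


MULTI_MARKER_COHORT: tuple[ReferenceClone, ...] = (
    ReferenceClone("PC-1", "metC trpC lysA hisD", 54, 94.85, 15.62, 843.54, 21.03),
    ReferenceClone("PC-2", "metC trpC lysA hisD", 54, 165.10, 24.23, 1_308.24, 32.61),
    ReferenceClone("HC-1", "metC trpC lysA pheA", 36, 212.65, 42.76, 1_539.40, 38.37),
    ReferenceClone("HC-2", "metC trpC lysA pheA", 35, 203.28, 38.60, 1_351.06, 33.68),
    ReferenceClone("H-1", "cysA metC trpC lysA pheA", 26, 161.55, 27.36, 711.45, 17.73),
    ReferenceClone("C-1", "metC trpC lysA pheA hisD", 66, 146.23, 22.67, 1_495.93, 37.29),
    ReferenceClone("C-2", "metC trpC lysA pheA hisD", 31, 170.85, 24.82, 769.37, 19.18),
    ReferenceClone("C-3", "metC trpC lysA pheA hisD", 22, 346.93, 49.29, 1_084.31, 27.03),
    ReferenceClone("C-4", "metC trpC lysA pheA hisD", 32, 82.73, 22.35, 715.13, 17.82),
)

# Cohort-level published values (multi-marker selection).
OVERALL_MEAN_EVENT_KB = 27.58  # sum of totals / sum of event counts
MAX_EVENT_KB = 346.93
MAX_EVENTS = 66

# After consolidating segments into recombination tracts (<20 kb gaps,
# >=50% occupancy, <500 kb span): mean tract size, total transferred DNA
# and its share of the donor genome, and the largest tract.
TRACT_MEAN_KB = 63.65
TRACT_TOTAL_KB = 1_715.4
TRACT_TOTAL_PCT = 42.76
TRACT_MAX_KB = 418.5
MEAN_EVENTS_SINGLE_MARKER = 15  # mean segments per clone, single-marker selection
MEAN_TRACTS_SINGLE_MARKER = 9
MEAN_EVENTS_MULTI_MARKER = 40  # mean segments per clone, multi-marker selection
MEAN_TRACTS_MULTI_MARKER = 20

# Co-inheritance of unselected auxotrophic markers with selected trpC:
# (marker, distance to trpC in bp, observed double/selected ratio).
TRPC_COINHERITANCE: tuple[tuple[str, int, float], ...] = (
    ("lysA", 62_000, 0.3180),
    ("pheA", 475_000, 0.1442),
    ("metC", 988_000, 0.1275),
    ("hisD", 1_209_000, 0.1251),
    ("cysE", 1_950_000, 0.1106),
)
DOUBLE_TRANSFORMATION_RATIO = 0.1106  # trpC-cysE plateau estimate

DONOR_CULTURE_DNA_UG_PER_ML = 0.46  # estimated DNA content of the donor culture
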