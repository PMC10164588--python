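"""Building marker maps and genotype tracks from variant calls.

The informative-marker map is the set of positions at which the donor and
recipient strains carry different alleles; only at those positions is donor
ancestry of a recombinant detectable. Variant input is a table of SNV calls
against a common reference (one per strain, plus one per recombinant
clone), as produced by any standard short-read caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DONOR,
    MISSING,
    RECIPIENT,
    GenotypeTrack,
    MarkerMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = {"pos", "ref", "alt", "gt"}


@dataclass
class GenotypeFilter:
    """Quality thresholds applied before a variant call is trusted.

    Calls failing any threshold — and heterozygous calls — are scored
    missing, mirroring the retain-only-homozygous filtering applied to
    short-read SNP calls before run calling.
    """

    min_qual: float | None = None
    min_depth: int | None = None

    def passes(self, row: pd.Series) -> bool:
        if self.min_qual is not None:
            q = row.get("qual")
            if q is None or (isinstance(q, float) and np.isnan(q)) or q < self.min_qual:
                return False
        if self.min_depth is not None:
            d = row.get("depth")
            if d is None or (isinstance(d, float) and np.isnan(d)) or d < self.min_depth:
                return False
        return True


def _check_table(table: pd.DataFrame, name: str) -> pd.DataFrame:
    missing_cols = _REQUIRED_COLUMNS - set(table.columns)
    if missing_cols:
        raise ValidationError(f"{name} variant table lacks columns {sorted(missing_cols)}")
    return table


def _snv_only(table: pd.DataFrame, name: str) -> pd.DataFrame:
    """Keep biallelic SNV records; log how many were skipped."""
    is_snv = (
        table["ref"].astype(str).str.len().eq(1)
        & table["alt"].astype(str).str.len().eq(1)
        & ~table["alt"].astype(str).str.contains(",")
        & table["ref"].astype(str).str.upper().isin(list("ACGT"))
        & table["alt"].astype(str).str.upper().isin(list("ACGT"))
    )
    skipped = int((~is_snv).sum())
    if skipped:
        logger.info("%s: skipped %d non-SNV/multiallelic records", name, skipped)
    return table[is_snv]


def _hom_allele(row: pd.Series) -> str | None:
    """The allele of a homozygous call, or None for het/missing genotypes."""
    gt = str(row["gt"])
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) == 1:  # haploid call
        alleles = alleles * 2
    if "." in alleles or alleles[0] != alleles[1]:
        return None
    return str(row["ref"]).upper() if alleles[0] == "0" else str(row["alt"]).upper()


def classify_sites(
    donor_variants: pd.DataFrame,
    recipient_variants: pd.DataFrame,
    genome_length: int,
    circular: bool = True,
    exclude: list[tuple[int, int]] | None = None,
) -> MarkerMap:
    """Build the informative-marker map from two strain variant tables.

    A position is informative iff the donor and recipient alleles differ
    there — including positions where one strain simply matches the
    reference (no record) while the other carries a variant. Optional
    ``exclude`` intervals (1-based inclusive) mask regions such as poorly
    conserved prophages.
    """
    donor_variants = _snv_only(_check_table(donor_variants, "donor"), "donor")
    recipient_variants = _snv_only(
        _check_table(recipient_variants, "recipient"), "recipient"
    )

    def to_alleles(table: pd.DataFrame, name: str) -> dict[int, tuple[str, str]]:
        out: dict[int, tuple[str, str]] = {}
        for _, row in table.iterrows():
            pos = int(row["pos"])
            if not 1 <= pos <= genome_length:
                raise ValidationError(
                    f"{name} variant at {pos} outside [1, {genome_length}]"
                )
            allele = _hom_allele(row)
            if allele is None:
                continue  # het/uncalled strain records are not trustworthy markers
            out[pos] = (str(row["ref"]).upper(), allele)
        return out

    donor_by_pos = to_alleles(donor_variants, "donor")
    recipient_by_pos = to_alleles(recipient_variants, "recipient")

    positions, donor_alleles, recipient_alleles = [], [], []
    for pos in sorted(set(donor_by_pos) | set(recipient_by_pos)):
        ref = (donor_by_pos.get(pos) or recipient_by_pos.get(pos))[0]
        d_allele = donor_by_pos.get(pos, (ref, ref))[1]
        r_allele = recipient_by_pos.get(pos, (ref, ref))[1]
        if d_allele == r_allele:
            continue
        if exclude and any(s <= pos <= e for s, e in exclude):
            continue
        positions.append(pos)
        donor_alleles.append(d_allele)
        recipient_alleles.append(r_allele)
    logger.info("classified %d informative sites", len(positions))
    return MarkerMap(
        genome_length=genome_length,
        circular=circular,
        positions=np.array(positions, dtype=np.int64),
        donor_alleles=np.array(donor_alleles, dtype="U1"),
        recipient_alleles=np.array(recipient_alleles, dtype="U1"),
    )


def genotype_clone(
    clone_variants: pd.DataFrame,
    marker_map: MarkerMap,
    quality_filter: GenotypeFilter | None = None,
    clone_id: str = "clone",
    absent_state: int = MISSING,
) -> GenotypeTrack:
    """Score one recombinant at every informative site.

    donor: retained homozygous call equal to the donor allele;
    recipient: equal to the recipient allele; missing: filtered,
    heterozygous, third-allele, or no retained record at the site
    (``absent_state`` may be set to RECIPIENT when the input is known to
    report variants only, i.e. an absent record means reference).
    """
    if absent_state not in (MISSING, RECIPIENT):
        raise ValidationError("absent_state must be MISSING or RECIPIENT")
    quality_filter = quality_filter or GenotypeFilter()
    clone_variants = _snv_only(_check_table(clone_variants, clone_id), clone_id)
    states = np.full(len(marker_map), absent_state, dtype=np.int8)
    pos_index = {int(p): i for i, p in enumerate(marker_map.positions)}
    n_donor = n_recip = n_missing = 0
    for _, row in clone_variants.iterrows():
        i = pos_index.get(int(row["pos"]))
        if i is None:
            continue  # not an informative site
        if not quality_filter.passes(row):
            states[i] = MISSING
            n_missing += 1
            continue
        allele = _hom_allele(row)
        if allele == str(marker_map.donor_alleles[i]):
            states[i] = DONOR
            n_donor += 1
        elif allele == str(marker_map.recipient_alleles[i]):
            states[i] = RECIPIENT
            n_recip += 1
        else:  # het, uncalled, or third allele
            states[i] = MISSING
            n_missing += 1
    logger.info(
        "%s: %d donor, %d recipient, %d missing calls at informative sites",
        clone_id,
        n_donor,
        n_recip,
        n_missing,
    )
    return GenotypeTrack(clone_id=clone_id, states=states)


def windowed_divergence(marker_map: MarkerMap, window: int = 10_000) -> pd.DataFrame:
    """Informative-site counts in tiling windows [1,w], [w+1,2w], ...

    The coordinate-matched analogue of counting per-10-kb differences
    between two aligned genomes; valid when the pair has no structural
    differences, as for synthetic pairs built on a shared coordinate
    system. The final partial window is included; counts sum to the total
    number of informative sites.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    G = marker_map.genome_length
    n_windows = (G + window - 1) // window
    starts = np.arange(n_windows, dtype=np.int64) * window + 1
    ends = np.minimum(starts + window - 1, G)
    idx = (marker_map.positions - 1) // window
    counts = np.bincount(idx, minlength=n_windows)
    return pd.DataFrame(
        {"window_start": starts, "window_end": ends, "count": counts.astype(np.int64)}
    )
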