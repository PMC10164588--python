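"""Readers and writers shared by all pipeline stages.

Conventions: internal coordinates are 1-based inclusive; BED files are
strictly 0-based half-open; VCF is v4.2 with GT-only genotypes; TSV/BED
bodies are deterministic for a fixed input, with provenance recorded in
'#'-prefixed header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .types import (
    DONOR,
    MISSING,
    RECIPIENT,
    CloneTruth,
    GenotypeTrack,
    MarkerMap,
    RecombinationTract,
    SimulationConfig,
    TransferSegment,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message carries the file and line context."""


def provenance_lines(seed: int | None = None, **params) -> list[str]:
    items = {"ctcnt_version": __version__}
    if seed is not None:
        items["seed"] = seed
    items.update(params)
    return [f"# {k}={v}" for k, v in items.items()]


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, name: str, sequence: str) -> Path:
    path = Path(path)
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(Path(path), "fasta")}


# ---------------------------------------------------------------- VCF

_VCF_GT = {DONOR: "1/1", RECIPIENT: "0/0", MISSING: "./."}


def write_clone_vcf(
    path: str | Path,
    marker_map: MarkerMap,
    track: GenotypeTrack,
    chrom: str = "chromosome",
) -> Path:
    """One record per informative site; REF = recipient allele (the
    reference strain), ALT = donor allele; GT 1/1 donor, 0/0 recipient,
    ./. missing."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=ctcnt {__version__}",
        f"##contig=<ID={chrom},length={marker_map.genome_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{track.clone_id}",
    ]
    for pos, ref, alt, state in zip(
        marker_map.positions,
        marker_map.recipient_alleles,
        marker_map.donor_alleles,
        track.states,
    ):
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{_VCF_GT[int(state)]}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf_table(path: str | Path) -> pd.DataFrame:
    """Variant table (pos, ref, alt, gt, qual, depth) from a VCF via pysam.

    Multiallelic ALTs are joined with commas and later skipped by the
    SNV-only filter of the markers module.
    """
    import pysam

    path = Path(path)
    rows = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                if samples:
                    gt_tuple = rec.samples[samples[0]].get("GT")
                    gt = (
                        "/".join("." if a is None else str(a) for a in gt_tuple)
                        if gt_tuple is not None
                        else "./."
                    )
                else:
                    gt = "1/1"  # sites-only VCF: record presence as a hom call
                depth = rec.samples[samples[0]].get("DP") if samples else None
                rows.append(
                    {
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": ",".join(rec.alts) if rec.alts else ".",
                        "gt": gt,
                        "qual": rec.qual if rec.qual is not None else np.nan,
                        "depth": depth if depth is not None else np.nan,
                    }
                )
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: malformed VCF ({exc})") from exc
    return pd.DataFrame(rows, columns=["pos", "ref", "alt", "gt", "qual", "depth"])


# ---------------------------------------------------------------- marker map TSV

def write_marker_map_tsv(path: str | Path, marker_map: MarkerMap) -> Path:
    path = Path(path)
    header = provenance_lines(
        genome_length=marker_map.genome_length, circular=marker_map.circular
    )
    df = pd.DataFrame(
        {
            "position": marker_map.positions,
            "donor_allele": marker_map.donor_alleles,
            "recipient_allele": marker_map.recipient_alleles,
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_marker_map_tsv(path: str | Path) -> MarkerMap:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body_lines.append(line)
    if "genome_length" not in meta:
        raise ParseError(f"{path}: missing '# genome_length=' header")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body_lines)), sep="\t")
    return MarkerMap(
        genome_length=int(meta["genome_length"]),
        circular=meta.get("circular", "True") == "True",
        positions=df["position"].to_numpy(np.int64),
        donor_alleles=df["donor_allele"].to_numpy(dtype="U1"),
        recipient_alleles=df["recipient_allele"].to_numpy(dtype="U1"),
    )


# ---------------------------------------------------------------- BED

def _bed_pieces(start: int, end: int, genome_length: int) -> list[tuple[int, int]]:
    """1-based inclusive (possibly wrapped) -> list of 0-based half-open."""
    if start <= end:
        return [(start - 1, end)]
    return [(start - 1, genome_length), (0, end)]


def write_segments_bed(
    path: str | Path,
    segments: list[TransferSegment],
    genome_length: int,
    chrom: str = "chromosome",
) -> Path:
    """BED6: name = clone_id/segment ordinal, score = n_support; wrapped
    segments are written as two lines sharing a name."""
    path = Path(path)
    lines = provenance_lines(genome_length=genome_length)
    for i, seg in enumerate(segments, 1):
        name = f"{seg.clone_id}.seg{i:03d}"
        for s0, e0 in _bed_pieces(seg.start, seg.end, genome_length):
            lines.append(f"{chrom}\t{s0}\t{e0}\t{name}\t{seg.n_support}\t+")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_segments_tsv(
    path: str | Path, segments: list[TransferSegment], genome_length: int
) -> Path:
    path = Path(path)
    header = provenance_lines(genome_length=genome_length)
    df = pd.DataFrame(
        [
            {
                "clone_id": s.clone_id,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "n_support": s.n_support,
            }
            for s in segments
        ],
        columns=["clone_id", "start", "end", "length", "n_support"],
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_segments_tsv(path: str | Path) -> list[TransferSegment]:
    df = _read_commented_tsv(path)
    return [
        TransferSegment(
            clone_id=str(r.clone_id),
            start=int(r.start),
            end=int(r.end),
            length=int(r.length),
            n_support=int(r.n_support),
        )
        for r in df.itertuples()
    ]


def write_tracts_bed(
    path: str | Path,
    tracts: list[RecombinationTract],
    genome_length: int,
    chrom: str = "chromosome",
) -> Path:
    """BED6 of tract spans; score = occupancy x 1000, rounded."""
    path = Path(path)
    lines = provenance_lines(genome_length=genome_length)
    for i, tract in enumerate(tracts, 1):
        name = f"{tract.clone_id}.tract{i:03d}"
        score = int(round(tract.occupancy * 1000))
        for s0, e0 in _bed_pieces(tract.span_start, tract.span_end, genome_length):
            lines.append(f"{chrom}\t{s0}\t{e0}\t{name}\t{score}\t+")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_truth_bed(
    path: str | Path,
    truths: list[CloneTruth],
    genome_length: int,
    chrom: str = "chromosome",
) -> Path:
    path = Path(path)
    lines = provenance_lines(genome_length=genome_length)
    for truth in truths:
        for i, (s, e) in enumerate(truth.segments, 1):
            name = f"{truth.clone_id}.planted{i:03d}"
            for s0, e0 in _bed_pieces(s, e, genome_length):
                lines.append(f"{chrom}\t{s0}\t{e0}\t{name}\t0\t+")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_truth_bed(path: str | Path, genome_length: int) -> dict[str, list[tuple[int, int]]]:
    """Planted intervals per clone, rejoining origin-wrapped pairs by name."""
    path = Path(path)
    by_name: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{ln}: expected >=4 BED columns")
        try:
            s0, e0 = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-integer BED coordinates") from exc
        name = fields[3]
        if name not in by_name:
            order.append(name)
        by_name.setdefault(name, []).append((s0 + 1, e0))
    out: dict[str, list[tuple[int, int]]] = {}
    for name in order:
        pieces = by_name[name]
        clone_id = name.rsplit(".", 1)[0]
        if len(pieces) == 2:
            # wrapped pair: [start, G] + [1, end]
            tail = next((p for p in pieces if p[1] == genome_length), None)
            head = next((p for p in pieces if p[0] == 1), None)
            if tail is None or head is None:
                raise ParseError(f"{path}: interval {name} split but does not wrap")
            interval = (tail[0], head[1])
        elif len(pieces) == 1:
            interval = pieces[0]
        else:
            raise ParseError(f"{path}: interval {name} appears {len(pieces)} times")
        out.setdefault(clone_id, []).append(interval)
    return out


# ---------------------------------------------------------------- TSV / JSON

def _read_commented_tsv(path: str | Path) -> pd.DataFrame:
    from io import StringIO

    body = [
        line
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return pd.read_csv(StringIO("\n".join(body)), sep="\t")


def write_config_json(path: str | Path, config: SimulationConfig) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def read_config_json(path: str | Path) -> SimulationConfig:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    return SimulationConfig.from_dict(data)
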