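"""Transcript annotation: TSS windows ("pTSS") and BED6 round-trip.

The promoter window of a transcript is the ±1 kb region around its
transcription start site, half-open ``[tss - 1000, tss + 1000)`` — exactly
2000 bp regardless of strand. Strand only matters for orienting
meta-profiles; window coverage sums are symmetric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW_HALFWIDTH = 1000
WINDOW_LENGTH = 2 * WINDOW_HALFWIDTH

#: required columns of an annotation table
ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand", "tss"]


class AnnotationError(ValueError):
    pass


def validate_annotation(ann: pd.DataFrame, halfwidth: int = WINDOW_HALFWIDTH) -> pd.DataFrame:
    """Check an annotation table and return it unchanged.

    Raises :class:`AnnotationError` if required columns are missing,
    transcript IDs collide, strands are malformed, or a window would
    extend past the chromosome start.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise AnnotationError(f"annotation missing columns: {missing}")
    if ann["transcript_id"].duplicated().any():
        dups = ann.loc[ann["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise AnnotationError(f"duplicate transcript_id values: {dups[:5]}")
    bad_strand = set(ann["strand"].unique()) - {"+", "-"}
    if bad_strand:
        raise AnnotationError(f"strand values must be '+' or '-', got {sorted(bad_strand)}")
    if (ann["tss"] < halfwidth).any():
        bad = ann.loc[ann["tss"] < halfwidth, "transcript_id"].tolist()
        raise AnnotationError(
            f"tss - {halfwidth} < 0 for transcripts {bad[:5]}; windows must fit the reference"
        )
    return ann


def windows(ann: pd.DataFrame, halfwidth: int = WINDOW_HALFWIDTH) -> pd.DataFrame:
    """Return per-transcript half-open promoter windows (chrom, start, end)."""
    out = ann[["transcript_id", "gene_id", "chrom", "strand"]].copy()
    out["start"] = ann["tss"] - halfwidth
    out["end"] = ann["tss"] + halfwidth
    return out


def generate_annotation(
    n_genes: int,
    chrom_length: int,
    min_spacing: int = 5000,
    seed: int = 0,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Place ``n_genes`` single-transcript genes on one synthetic chromosome.

    TSS positions are drawn uniformly subject to a minimum pairwise spacing
    so promoter windows never overlap; strands are assigned at random.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise AnnotationError("n_genes must be >= 1")
    if min_spacing < 2 * WINDOW_HALFWIDTH * 2:
        raise AnnotationError(
            f"min_spacing must be >= {4 * WINDOW_HALFWIDTH} so windows cannot overlap"
        )
    # first TSS needs halfwidth of room on each side
    usable = chrom_length - 2 * WINDOW_HALFWIDTH
    if n_genes * min_spacing >= chrom_length or usable < (n_genes - 1) * min_spacing:
        raise AnnotationError(
            f"chromosome too short: need n_genes*min_spacing={n_genes * min_spacing} "
            f"< chrom_length={chrom_length} plus {2 * WINDOW_HALFWIDTH} bp of margin"
        )
    rng = np.random.default_rng(seed)
    # sorted uniform draws in the slack space, then spread by min_spacing
    slack = usable - (n_genes - 1) * min_spacing
    offsets = np.sort(rng.integers(0, slack + 1, size=n_genes))
    tss = WINDOW_HALFWIDTH + offsets + np.arange(n_genes) * min_spacing
    strand = rng.choice(["+", "-"], size=n_genes)
    ann = pd.DataFrame(
        {
            "transcript_id": [f"tx{i:05d}" for i in range(n_genes)],
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "strand": strand,
            "tss": tss.astype(np.int64),
        }
    )
    return validate_annotation(ann)


def write_bed6(ann: pd.DataFrame, path, halfwidth: int = WINDOW_HALFWIDTH) -> None:
    """Write promoter windows as BED6 (name = ``transcript_id|gene_id``)."""
    w = windows(ann, halfwidth)
    bed = pd.DataFrame(
        {
            "chrom": w["chrom"],
            "start": w["start"],
            "end": w["end"],
            "name": w["transcript_id"] + "|" + w["gene_id"],
            "score": 0,
            "strand": w["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path, halfwidth: int = WINDOW_HALFWIDTH) -> pd.DataFrame:
    """Read a BED6 of promoter windows written by :func:`write_bed6`."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        comment="#",
    )
    ids = bed["name"].str.split("|", n=1, expand=True)
    ann = pd.DataFrame(
        {
            "transcript_id": ids[0],
            "gene_id": ids[1],
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "tss": ((bed["start"] + bed["end"]) // 2).astype(np.int64),
        }
    )
    return validate_annotation(ann, halfwidth)
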