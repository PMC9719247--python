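"""Promoter profiling: normalized cfDNA coverage in TSS windows.

The per-transcript statistic is the depth-summed coverage in the ±1 kb
promoter window, scaled RPKM-style::

    normalized = coverage * 1e6 / (total_mapped_reads * length)

with length fixed at 2000 bp (the window size). Active promoters sit in
nucleosome-depleted regions, so low values indicate high gene activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import WINDOW_HALFWIDTH, WINDOW_LENGTH, validate_annotation, windows
from .fragments import FragmentSet


class ProfilingError(ValueError):
    pass


@dataclass
class PromoterProfileMatrix:
    """Samples × features matrix of normalized promoter-profiling values.

    ``values`` is a DataFrame indexed by sample ID with one column per
    transcript or gene; ``level`` records which.
    """

    values: pd.DataFrame
    level: str = "transcript"

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "gene"):
            raise ProfilingError(f"level must be 'transcript' or 'gene', got {self.level!r}")
        if self.values.isna().any().any():
            raise ProfilingError("matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ProfilingError("normalized promoter profiling must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path, header_meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header_meta or {}).items():
                fh.write(f"# {k}={v}\n")
            fh.write(f"# level={self.level}\n")
            self.values.to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "PromoterProfileMatrix":
        level = "transcript"
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# level="):
                    level = line.strip().split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
        return cls(df, level=level)


# ---------------------------------------------------------------- coverage


def compute_window_coverage(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    halfwidth: int = WINDOW_HALFWIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.Series:
    """Weighted base-coverage of each promoter window.

    For each transcript the value is ``sum over fragments of
    (bp overlap with the window) * fragment weight`` — identical to summing
    the per-base weighted depth across the window. Windows that would run
    past a chromosome end (when ``chrom_sizes`` is given) are excluded with
    a warning.
    """
    ann = validate_annotation(annotation, halfwidth)
    win = windows(ann, halfwidth)
    if chrom_sizes is not None:
        over = win["end"] > win["chrom"].map(chrom_sizes).fillna(np.inf)
        if over.any():
            warnings.warn(
                f"{int(over.sum())} windows extend past the reference end and were excluded"
            )
            win = win[~over]
    out = pd.Series(0.0, index=win["transcript_id"].to_numpy(), name=fragments.sample_id)
    rec = fragments.records
    for chrom, wgrp in win.groupby("chrom", sort=False):
        sub = rec[rec["chrom"] == chrom]
        if sub.empty:
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        wts = sub["weight"].to_numpy()[order]
        # fragments are short; a start-sorted scan with a max-length bound
        # finds all overlappers of each window
        max_len = int((ends - starts).max())
        for tid, ws, we in zip(wgrp["transcript_id"], wgrp["start"], wgrp["end"]):
            lo = np.searchsorted(starts, ws - max_len, side="left")
            hi = np.searchsorted(starts, we, side="left")
            if hi <= lo:
                continue
            s = starts[lo:hi]
            e = ends[lo:hi]
            ov = np.minimum(e, we) - np.maximum(s, ws)
            mask = ov > 0
            out[tid] = float(np.sum(ov[mask] * wts[lo:hi][mask]))
    return out


def normalize_profiling(
    raw_coverage, total_mapped_reads: int, length: int = WINDOW_LENGTH
):
    """Scale window coverage to normalized promoter profiling.

    ``raw * 1e6 / (total_mapped_reads * length)``; raises on a zero or
    negative library size rather than emitting NaN.
    """
    if total_mapped_reads <= 0:
        raise ProfilingError("total_mapped_reads must be positive")
    if length <= 0:
        raise ProfilingError("length must be positive")
    return raw_coverage * 1e6 / (total_mapped_reads * length)


def profile_matrix(
    fragment_sets: Iterable[FragmentSet],
    annotation: pd.DataFrame,
    halfwidth: int = WINDOW_HALFWIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> PromoterProfileMatrix:
    """Build the samples × transcripts normalized matrix from fragments."""
    rows = {}
    for fs in fragment_sets:
        raw = compute_window_coverage(fs, annotation, halfwidth, chrom_sizes)
        rows[fs.sample_id] = normalize_profiling(raw, fs.total_mapped_reads, 2 * halfwidth)
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return PromoterProfileMatrix(df, level="transcript")


def collapse_to_gene(matrix: PromoterProfileMatrix, annotation: pd.DataFrame) -> PromoterProfileMatrix:
    """Average transcript columns belonging to the same gene."""
    if matrix.level != "transcript":
        raise ProfilingError("collapse_to_gene requires a transcript-level matrix")
    mapping = annotation.set_index("transcript_id")["gene_id"]
    unmapped = [c for c in matrix.feature_ids if c not in mapping.index]
    if unmapped:
        raise ProfilingError(f"transcripts without gene mapping: {unmapped[:5]}")
    genes = matrix.values.T.groupby(mapping.loc[matrix.feature_ids].to_numpy()).mean().T
    genes = genes[sorted(genes.columns)]
    return PromoterProfileMatrix(genes, level="gene")


# ------------------------------------------------------------ meta-profile


def compute_meta_profile(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    total_mapped_reads: int | None = None,
    halfwidth: int = WINDOW_HALFWIDTH,
) -> pd.DataFrame:
    """Strand-oriented average coverage at each offset from the TSS.

    Returns a DataFrame with ``offset`` (−halfwidth .. halfwidth−1, where
    positive offsets are downstream of the TSS) and ``value`` (per-base
    depth averaged over transcripts, scaled by 1e6 / total mapped reads).
    Minus-strand windows are mirror-flipped before averaging.
    """
    ann = validate_annotation(annotation, halfwidth)
    if len(ann) == 0:
        raise ProfilingError("meta-profile requires a non-empty gene subset")
    if total_mapped_reads is None:
        total_mapped_reads = fragments.total_mapped_reads
    if total_mapped_reads <= 0:
        raise ProfilingError("total_mapped_reads must be positive")
    width = 2 * halfwidth
    depth_sum = np.zeros(width)
    rec = fragments.records
    for chrom, agrp in ann.groupby("chrom", sort=False):
        sub = rec[rec["chrom"] == chrom]
        if sub.empty:
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        wts = sub["weight"].to_numpy()[order]
        max_len = int((ends - starts).max())
        for tss, strand in zip(agrp["tss"], agrp["strand"]):
            ws, we = tss - halfwidth, tss + halfwidth
            lo = np.searchsorted(starts, ws - max_len, side="left")
            hi = np.searchsorted(starts, we, side="left")
            local = np.zeros(width)
            for s, e, w in zip(starts[lo:hi], ends[lo:hi], wts[lo:hi]):
                a, b = max(s, ws) - ws, min(e, we) - ws
                if b > a:
                    local[a:b] += w
            depth_sum += local[::-1] if strand == "-" else local
    mean_depth = depth_sum / len(ann)
    value = mean_depth * 1e6 / total_mapped_reads
    return pd.DataFrame({"offset": np.arange(-halfwidth, halfwidth), "value": value})


# ------------------------------------------------------------ GC weighting


def gc_correct(
    fragments: FragmentSet,
    n_bins: int = 50,
    reference_gc: Sequence[float] | None = None,
    weight_cap: tuple[float, float] = (0.2, 5.0),
) -> FragmentSet:
    """Reweight fragments so the GC-vs-rate trend is flattened.

    Fragments are binned by GC fraction; each bin's weight is the expected
    rate over the observed rate. The expectation comes from ``reference_gc``
    (a sample of genome GC fractions) when given, otherwise a uniform rate
    across occupied bins. Weights are capped to ``weight_cap``; empty bins
    keep weight 1.
    """
    if not fragments.has_gc:
        raise ProfilingError(
            "fragments lack GC fractions; provide them or disable GC correction"
        )
    gc = fragments.records["gc"].to_numpy(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(gc, edges) - 1, 0, n_bins - 1)
    obs = np.bincount(idx, minlength=n_bins).astype(float)
    if reference_gc is not None:
        ref = np.asarray(reference_gc, float)
        ridx = np.clip(np.digitize(ref, edges) - 1, 0, n_bins - 1)
        exp = np.bincount(ridx, minlength=n_bins).astype(float)
        exp = exp / exp.sum() * obs.sum()
    else:
        occupied = obs > 0
        exp = np.where(occupied, obs[occupied].mean(), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bin = np.where(obs > 0, exp / np.where(obs > 0, obs, 1.0), 1.0)
    w_bin = np.clip(w_bin, *weight_cap)
    new_w = fragments.records["weight"].to_numpy(float) * w_bin[idx]
    return fragments.with_weights(new_w)
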