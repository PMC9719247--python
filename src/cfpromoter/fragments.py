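"""Aligned cfDNA fragments for one sample, with BED3/BAM persistence.

Fragments are single-end reads spanning the whole molecule, so "read" and
"fragment" coincide. Coordinates are 0-based half-open. The unweighted
record count is the library size ("totally mapped reads") used by the
promoter-profiling normalization; GC-correction weights rescale coverage
contributions but never the library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


@dataclass
class FragmentSet:
    """One sample's aligned cfDNA fragments.

    Parameters
    ----------
    sample_id
        Sample identifier.
    records
        DataFrame with columns ``chrom``, ``start``, ``end`` plus optional
        ``gc`` (fraction in [0, 1]) and ``weight`` (non-negative, default 1).
    """

    sample_id: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment records missing columns: {missing}")
        if "weight" not in self.records.columns:
            self.records = self.records.assign(weight=1.0)
        r = self.records
        if (r["start"] >= r["end"]).any():
            raise ValueError("fragments require start < end")
        if not np.isfinite(r["weight"]).all() or (r["weight"] < 0).any():
            raise ValueError("weights must be finite and non-negative")

    @property
    def total_mapped_reads(self) -> int:
        """Unweighted number of mapped reads (library size)."""
        return len(self.records)

    @property
    def has_gc(self) -> bool:
        return "gc" in self.records.columns and self.records["gc"].notna().all()

    def with_weights(self, weights: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.records.assign(weight=np.asarray(weights, float)))

    # ------------------------------------------------------------------ I/O

    def to_bed(self, path) -> None:
        """Write fragments as BED3 (or BED4 with GC in column 4 if present)."""
        cols = FRAGMENT_COLUMNS + (["gc"] if "gc" in self.records.columns else [])
        self.records[cols].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, sample_id: str) -> "FragmentSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
        df.columns = FRAGMENT_COLUMNS + (["gc"] if df.shape[1] == 4 else [])
        return cls(sample_id, df)

    def to_bam(self, path, chrom_lengths: dict[str, int]) -> None:
        """Write fragments as a coordinate-sorted BAM with a minimal header."""
        refs = list(chrom_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in refs],
            "RG": [{"ID": self.sample_id, "SM": self.sample_id}],
        }
        rec = self.records.sort_values(["chrom", "start"], kind="stable")
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for i, row in enumerate(rec.itertuples(index=False)):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"{self.sample_id}:{i}"
                length = int(row.end) - int(row.start)
                a.query_sequence = "N" * length
                a.reference_id = refs.index(row.chrom)
                a.reference_start = int(row.start)
                a.cigartuples = [(0, length)]
                a.mapping_quality = 60
                a.flag = 0
                bam.write(a)
        pysam.index(str(path))

    @classmethod
    def from_bam(cls, path, sample_id: str | None = None) -> "FragmentSet":
        """Read single-end fragments from a BAM; warns if duplicates present.

        Duplicate removal is an upstream contract: input is assumed
        deduplicated. Reads flagged as duplicates are dropped with a warning.
        """
        chroms, starts, ends = [], [], []
        n_dup = 0
        with pysam.AlignmentFile(str(path), "rb") as bam:
            if sample_id is None:
                rgs = bam.header.to_dict().get("RG", [])
                sample_id = rgs[0]["SM"] if rgs else "sample"
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped:
                    continue
                if read.is_duplicate:
                    n_dup += 1
                    continue
                chroms.append(read.reference_name)
                starts.append(read.reference_start)
                ends.append(read.reference_end)
        if n_dup:
            warnings.warn(
                f"{n_dup} duplicate-flagged reads skipped; input should be deduplicated upstream"
            )
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        return cls(sample_id, df)
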