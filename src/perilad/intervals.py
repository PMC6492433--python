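"""Genomic interval sets with 0-based half-open coordinates.

The container used throughout the package for pericentromeric regions,
lamina-associated domains, NP-enriched domains and ATAC peaks.  Intervals are
normalized on construction: sorted by (chrom, start) and merged so that every
set is non-overlapping.  All arithmetic (intersection, Jaccard, coverage) is
exact base-pair arithmetic on the half-open convention; a window [a, b) and a
peak [b, c) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomicIntervalSet"]


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or touching intervals; input sorted by start."""
    if len(starts) == 0:
        return starts, ends
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


@dataclass(frozen=True)
class GenomicIntervalSet:
    """Sorted, merged set of (chrom, start, end) intervals.

    Scores (if supplied) are dropped during merging of overlapping intervals;
    sets that carry per-interval scores (island calls) should be normalized
    already, which :meth:`from_records` verifies.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = self.df
        required = ["chrom", "start", "end"]
        if list(df.columns[:3]) != required:
            raise ValueError(f"interval frame must start with columns {required}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df[~(df["start"] < df["end"])].iloc[0]
            raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")

    # ---------------------------------------------------------------- build
    @classmethod
    def from_records(cls, records, scores=None) -> "GenomicIntervalSet":
        """Build a normalized set from (chrom, start, end) triples."""
        df = pd.DataFrame(records, columns=["chrom", "start", "end"])
        if scores is not None:
            df["score"] = scores
        return cls._normalize(df)

    @classmethod
    def _normalize(cls, df: pd.DataFrame) -> "GenomicIntervalSet":
        if len(df) == 0:
            return cls(pd.DataFrame(columns=["chrom", "start", "end"]))
        has_score = "score" in df.columns
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        pieces = []
        for chrom, sub in df.groupby("chrom", sort=True):
            s, e = _merge_sorted(sub["start"].to_numpy(), sub["end"].to_numpy())
            piece = pd.DataFrame({"chrom": chrom, "start": s, "end": e})
            if has_score and len(s) == len(sub):
                piece["score"] = sub["score"].to_numpy()
            pieces.append(piece)
        out = pd.concat(pieces, ignore_index=True)
        return cls(out)

    # ------------------------------------------------------------ properties
    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def total_bp(self) -> int:
        if len(self.df) == 0:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    # ------------------------------------------------------------ arithmetic
    def intersect(self, other: "GenomicIntervalSet") -> "GenomicIntervalSet":
        """Base-pair intersection (classic sorted two-pointer sweep)."""
        records = []
        for chrom in set(self.chroms) & set(other.chroms):
            a_s, a_e = self.arrays(chrom)
            b_s, b_e = other.arrays(chrom)
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                lo = max(a_s[i], b_s[j])
                hi = min(a_e[i], b_e[j])
                if lo < hi:
                    records.append((chrom, int(lo), int(hi)))
                if a_e[i] <= b_e[j]:
                    i += 1
                else:
                    j += 1
        return GenomicIntervalSet.from_records(records)

    def jaccard(self, other: "GenomicIntervalSet") -> tuple[float, float, float]:
        """Base-pair (jaccard, fraction_of_self_covered, fraction_of_other_covered)."""
        inter = self.intersect(other).total_bp()
        a, b = self.total_bp(), other.total_bp()
        union = a + b - inter
        jac = inter / union if union > 0 else 0.0
        return (jac, inter / a if a else 0.0, inter / b if b else 0.0)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        s, e = self.arrays(chrom)
        k = np.searchsorted(s, pos, side="right") - 1
        return k >= 0 and pos < e[k]

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """Any-overlap under half-open semantics."""
        s, e = self.arrays(chrom)
        k = np.searchsorted(s, end, side="left")  # intervals starting before `end`
        return bool(np.any(e[:k] > start))

    # ----------------------------------------------------------------- io
    @classmethod
    def read_bed(cls, path) -> "GenomicIntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str, 1: np.int64, 2: np.int64})
        return cls._normalize(df)

    def write_bed(self, path) -> None:
        cols = ["chrom", "start", "end"] + (["score"] if "score" in self.df.columns else [])
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)
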