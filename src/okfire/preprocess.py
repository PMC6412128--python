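"""Preprocessing of strand-specific coverage into normalized boxed counts.

Raw inputs are per-strand coverage tracks (bedGraph) built from Okazaki
fragments (paired-end fragments length-filtered to 120-200 bp; alignment and
the mapping-quality > 10 filter are upstream of this package) plus a list of
origin positions (BED).  For an origin triplet the region [O1, O3) is boxed
into ``s_box`` windows and locally normalized so the mean of forward +
reverse counts per box is 1, after correcting the reverse strand by the
chromosome-wide strand bias ``b_chr = sum(forward) / sum(reverse)``.

All coordinates are 0-based; bedGraph intervals and BED fragments are
half-open.  Conversion from 1-based inputs is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import OriginTriplet
from .noise_model import BoxedCounts

__all__ = [
    "StrandedCoverage",
    "read_bedgraph",
    "read_bed",
    "filter_fragments",
    "strand_bias",
    "box_and_normalize",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bedgraph(path, chrom: Optional[str] = None) -> pd.DataFrame:
    """Read a 4-column bedGraph into a DataFrame (track lines are skipped)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    df = df.astype({"start": int, "end": int, "value": float})
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return df.reset_index(drop=True)


def read_bed(path, chrom: Optional[str] = None) -> pd.DataFrame:
    """Read a BED3-BED6 file (fragments or origin positions)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype={0: str})
    df = df[~df[0].str.startswith(("track", "browser"))]
    df.columns = _BED_COLS[: df.shape[1]]
    df = df.astype({"start": int, "end": int})
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return df.reset_index(drop=True)


def filter_fragments(
    fragments: pd.DataFrame, min_len: int = 120, max_len: int = 200
) -> pd.DataFrame:
    """Keep fragments whose length (end - start) lies in [min_len, max_len].

    The defaults match the Okazaki-fragment length window used to build the
    coverage tracks; the operation is idempotent and order preserving.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    length = fragments["end"] - fragments["start"]
    return fragments[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


@dataclass
class StrandedCoverage:
    """Per-bp forward/reverse coverage over a contiguous genomic window.

    ``start`` is the 0-based genomic coordinate of ``fwd[0]``/``rev[0]``;
    both strands span the same range.
    """

    chrom: str
    start: int
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 1:
            raise ValueError("fwd and rev must be 1-D arrays of equal length")
        if np.any(self.fwd < 0) or np.any(self.rev < 0):
            raise ValueError("coverage must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.fwd.size

    @classmethod
    def from_bedgraphs(cls, fwd_path, rev_path, chrom: Optional[str] = None) -> "StrandedCoverage":
        """Expand a bedGraph pair to per-bp coverage on their common span."""
        dfs = [read_bedgraph(p, chrom=chrom) for p in (fwd_path, rev_path)]
        for df in dfs:
            if df.empty:
                raise ValueError("empty bedGraph (or no intervals on the requested chromosome)")
        chroms = set(dfs[0]["chrom"]) | set(dfs[1]["chrom"])
        if chrom is None:
            if len(chroms) != 1:
                raise ValueError(f"multiple chromosomes present {chroms}; pass chrom=")
            chrom = chroms.pop()
        lo = int(min(df["start"].min() for df in dfs))
        hi = int(max(df["end"].max() for df in dfs))
        arrays = []
        for df in dfs:
            a = np.zeros(hi - lo)
            for s, e, v in zip(df["start"], df["end"], df["value"]):
                a[s - lo : e - lo] += v
            arrays.append(a)
        return cls(chrom, lo, arrays[0], arrays[1])


def strand_bias(coverage: StrandedCoverage) -> float:
    """Chromosome strand bias: total forward counts over total reverse counts."""
    total_r = float(coverage.rev.sum())
    if total_r == 0:
        raise ValueError("reverse-strand total is zero; strand bias undefined")
    return float(coverage.fwd.sum()) / total_r


def box_and_normalize(
    coverage: StrandedCoverage,
    triplet: OriginTriplet,
    s_box: int = 50,
    b_chr: float = 1.0,
    norm_region: Optional[tuple[float, float]] = None,
) -> BoxedCounts:
    """Box the coverage over [O1, O3) and normalize to mean(c_f + c_r) = 1.

    The normalization constant ``n`` is the mean per-bp bias-corrected count
    over the half-open window [O1, O3) (or ``norm_region``, e.g. [O1, O4)
    when comparing overlapping triplets).  Box k spans
    ``[O1 + k s_box, O1 + (k+1) s_box)``; a trailing partial box is dropped.
    Forward boxes are box sums / (s_box n); reverse boxes additionally carry
    the ``b_chr`` weight.
    """
    if b_chr <= 0:
        raise ValueError("b_chr must be positive")
    x1, _, x3 = triplet.positions
    lo, hi = (x1, x3) if norm_region is None else norm_region
    lo, hi = int(lo), int(hi)
    if lo < coverage.start or hi > coverage.end or int(x3) > coverage.end:
        raise ValueError("coverage does not span the requested region")
    i0 = lo - coverage.start
    i1 = hi - coverage.start
    n = float((coverage.fwd[i0:i1] + b_chr * coverage.rev[i0:i1]).sum()) / (hi - lo)
    if n == 0:
        raise ValueError("no signal in the normalization region")
    nb = triplet.n_boxes(s_box)
    j0 = int(x1) - coverage.start
    f = coverage.fwd[j0 : j0 + nb * s_box].reshape(nb, s_box).sum(axis=1)
    r = coverage.rev[j0 : j0 + nb * s_box].reshape(nb, s_box).sum(axis=1)
    return BoxedCounts(
        f / (s_box * n),
        b_chr * r / (s_box * n),
        triplet.box_starts(s_box),
        s_box,
        n_norm=n,
        b_chr=b_chr,
        chrom=coverage.chrom,
    )
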