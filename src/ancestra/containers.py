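"""Shared in-memory containers for genotype and interval data.

Dosages are stored as ``int8`` with :data:`MISSING` (= -1) marking missing
calls; variant coordinates are 1-based (as in VCF) while all interval
arithmetic is 0-based half-open (as in BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (individuals x variants) with metadata.

    Parameters
    ----------
    dosage
        ``int8`` array of shape ``(n_samples, n_variants)`` with entries in
        {0, 1, 2, MISSING}.
    variants
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based.
    samples
        DataFrame indexed by sample id, with optional ``group`` (ancestry /
        population label) and ``sibship`` columns.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, missing}")
        dup = self.variants.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("variant positions must be unique per chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.samples.index)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing calls as NaN."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=self.samples,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[index, :],
            variants=self.variants,
            samples=self.samples.iloc[index],
        )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals and merge overlapping or book-ended ones per chrom."""
    if len(df) == 0:
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out: list[tuple] = []
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if cur_chrom == chrom and start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class GenomicIntervalSet:
    """Sorted, merged set of 0-based half-open genomic intervals."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )
    label: str | None = None

    def __post_init__(self) -> None:
        df = self.intervals[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy end > start")
        self.intervals = merge_intervals(df)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Membership mask for 0-based positions, vectorized per chromosome."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0)
        mask = np.zeros(len(pos0), dtype=bool)
        for c, sub in self.intervals.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            p = pos0[sel]
            # intervals are sorted and disjoint: position is inside iff the
            # preceding start's interval end exceeds it
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = idx >= 0
            ok[ok] = p[ok] < ends[idx[ok]]
            mask[sel] = ok
        return mask
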