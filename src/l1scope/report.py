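"""Per-sample summaries and consensus-coordinate pile-ups.

Summaries follow long-read L1 reporting conventions: per-category read
counts normalised per 10,000 L1 reads, feature percentages, a 500-bp
read-length histogram, and the fraction of reads at or above 6 kb.
Pile-ups accumulate per-category read coverage over consensus nucleotide
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CodingCategory
from .detect import L1Hit, merge_hits

LENGTH_BIN_BP = 500
LONG_READ_BP = 6000  # inclusive threshold for the ">= 6 kb" fraction


@dataclass
class SampleSummary:
    sample_id: str
    n_reads: int
    n_l1_reads: int
    category_counts: dict[str, int]
    per_10k: dict[str, float] | None  # None when no L1 reads (undefined)
    feature_pcts: dict[str, float]
    length_hist: pd.DataFrame = field(repr=False, default=None)
    pct_reads_ge_6kb: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CodingCategory:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "category": cat.value,
                    "count": self.category_counts.get(cat.value, 0),
                    "per_10k": (self.per_10k or {}).get(cat.value, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def summarize_sample(per_read: pd.DataFrame, sample_id: str = "S1") -> SampleSummary:
    """Summarise a per-read table (columns: is_l1, category, orientation,
    has_utr5, yy1_intact, flank_class, read_length)."""
    n_reads = len(per_read)
    l1 = per_read[per_read["is_l1"]] if "is_l1" in per_read.columns else per_read
    n_l1 = len(l1)
    counts = {cat.value: 0 for cat in CodingCategory}
    if n_l1:
        for cat, c in l1["category"].value_counts().items():
            counts[str(cat)] = int(c)
    per_10k = (
        {k: v / n_l1 * 10_000 for k, v in counts.items()} if n_l1 else None
    )
    feature_pcts = {}
    if n_l1:
        feature_pcts = {
            "sense_pct": 100.0 * (l1["orientation"] == "SENSE").mean(),
            "utr5_pct": 100.0 * l1["has_utr5"].mean(),
            "yy1_pct": 100.0 * l1["yy1_intact"].mean(),
            "flank_intragenic_pct": 100.0 * (l1["flank_class"] == "INTRAGENIC").mean(),
            "flank_intergenic_pct": 100.0 * (l1["flank_class"] == "INTERGENIC").mean(),
            "flank_none_or_unmapped_pct": 100.0
            * l1["flank_class"].isin(["NONE", "UNMAPPED"]).mean(),
        }
    lengths = l1["read_length"].to_numpy() if n_l1 else np.empty(0)
    max_len = int(lengths.max()) if lengths.size else 0
    edges = np.arange(0, max_len + 2 * LENGTH_BIN_BP, LENGTH_BIN_BP)
    hist, _ = np.histogram(lengths, bins=edges)
    length_hist = pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "bin_end": edges[1:].astype(int),
            "n_reads": hist.astype(int),
            "pct_reads": 100.0 * hist / n_l1 if n_l1 else hist * 0.0,
        }
    )
    pct_ge = float(100.0 * (lengths >= LONG_READ_BP).mean()) if lengths.size else 0.0
    return SampleSummary(
        sample_id=sample_id,
        n_reads=n_reads,
        n_l1_reads=n_l1,
        category_counts=counts,
        per_10k=per_10k,
        feature_pcts=feature_pcts,
        length_hist=length_hist,
        pct_reads_ge_6kb=pct_ge,
    )


def pileup(read_hits: list[list[L1Hit]], consensus_len: int) -> np.ndarray:
    """Coverage vector over consensus coordinates: each read increments
    coverage over the union of its merged consensus intervals."""
    delta = np.zeros(consensus_len + 1, dtype=np.int64)
    for hits in read_hits:
        for hit in merge_hits(hits):
            s, e = hit.consensus_interval
            delta[max(0, s)] += 1
            delta[min(consensus_len, e)] -= 1
    return np.cumsum(delta[:-1])


def category_pileups(
    per_read: pd.DataFrame,
    hits_by_read: dict[str, list[L1Hit]],
    consensus_len: int,
) -> dict[str, np.ndarray]:
    """Per-category pile-ups keyed by category name."""
    out = {}
    for cat, df in per_read[per_read.get("is_l1", True) == True].groupby("category"):  # noqa: E712
        hit_lists = [hits_by_read[r] for r in df["read_id"] if r in hits_by_read]
        out[str(cat)] = pileup(hit_lists, consensus_len)
    return out
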