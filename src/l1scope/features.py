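"""Per-read regulatory and context features.

Four features are measured for every L1-containing read: 5'-UTR presence
(consensus-alignment overlap with the UTR interval), YY1-motif intactness
(exact substring of the sense-oriented read), strand orientation, and the
flanking-region class obtained by masking L1 segments and mapping the
remaining flanks to a genome with gene annotations.  A read is INTRAGENIC
when a mapped flank lies fully within an annotated gene span, INTERGENIC
when a flank maps elsewhere, UNMAPPED when no flank maps confidently, and
NONE when the read has no flank of qualifying length.  Features are
reported as observed; no consistency between them is enforced at
measurement time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consensus import ConsensusModel
from .detect import (
    AlignParams,
    L1Hit,
    MaskedRead,
    SequenceIndex,
    find_l1_segments,
)
from .simulate import (
    FLANK_INTERGENIC,
    FLANK_INTRAGENIC,
    FLANK_NONE,
    FLANK_UNMAPPED,
    ToyGenome,
)

DEFAULT_MIN_UTR_OVERLAP = 50
DEFAULT_MIN_FLANK_LEN = 100
DEFAULT_MIN_MAP_IDENTITY = 0.90
DEFAULT_MIN_MAP_COVERAGE = 0.90


@dataclass(frozen=True)
class FeatureRecord:
    read_id: str
    has_utr5: bool
    yy1_intact: bool
    orientation: str  # SENSE / ANTISENSE
    flank_class: str  # INTRAGENIC / INTERGENIC / UNMAPPED / NONE


def has_utr5(hits: list[L1Hit], model: ConsensusModel, min_overlap_bp: int = DEFAULT_MIN_UTR_OVERLAP) -> bool:
    """True iff the union of consensus intervals overlaps the 5'-UTR by at
    least ``min_overlap_bp`` (closed threshold)."""
    us, ue = model.utr5
    intervals = sorted(h.consensus_interval for h in hits)
    total = 0
    prev_end = us
    for s, e in intervals:
        s, e = max(s, us, prev_end), min(e, ue)
        if e > s:
            total += e - s
            prev_end = e
    return total >= min_overlap_bp


def yy1_intact(sense_seq: str, motif: str) -> bool:
    """Exact-substring YY1 motif search on the sense-oriented read."""
    return bool(sense_seq) and motif in sense_seq


class FlankMapper:
    """Maps masked-read flank segments onto a genome with annotations.

    Mapping reuses the exact-seed + chain + extend aligner; a flank maps
    confidently when its best chain covers at least ``min_map_coverage``
    of the flank at identity >= ``min_map_identity``.  Both genome strands
    are searched, so flank classification is invariant to read
    orientation.
    """

    def __init__(
        self,
        genome: ToyGenome,
        min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
        min_map_identity: float = DEFAULT_MIN_MAP_IDENTITY,
        min_map_coverage: float = DEFAULT_MIN_MAP_COVERAGE,
        kmer_size: int = 15,
    ):
        self.genome = genome
        self.min_flank_len = min_flank_len
        self.min_map_identity = min_map_identity
        self.min_map_coverage = min_map_coverage
        self._params = AlignParams(
            kmer_size=kmer_size,
            min_segment_len=min(min_flank_len, 50),
            min_identity=min_map_identity,
            max_gap=50,
        )
        self._indexes = {name: SequenceIndex(seq, kmer_size) for name, seq in genome.chroms.items()}

    def map_flank(self, flank_seq: str) -> tuple[str, tuple[int, int]] | None:
        """Best confident genome placement of a flank, or None."""
        best = None
        for chrom, index in self._indexes.items():
            for hit in find_l1_segments(flank_seq, index, self._params):
                coverage = (hit.read_interval[1] - hit.read_interval[0]) / len(flank_seq)
                if coverage < self.min_map_coverage or hit.identity < self.min_map_identity:
                    continue
                if best is None or hit.score > best[2]:
                    best = (chrom, hit.consensus_interval, hit.score)
        if best is None:
            return None
        return best[0], best[1]

    def classify(self, masked: MaskedRead) -> str:
        if not masked.flank_segments:
            return FLANK_NONE
        mapped_any = False
        for _, flank_seq in masked.flank_segments:
            placement = self.map_flank(flank_seq)
            if placement is None:
                continue
            mapped_any = True
            chrom, (s, e) = placement
            for gene in self.genome.genes:
                if gene.chrom == chrom and gene.start <= s and e <= gene.end:
                    return FLANK_INTRAGENIC
        return FLANK_INTERGENIC if mapped_any else FLANK_UNMAPPED


def classify_flanks(
    masked: MaskedRead,
    genome: ToyGenome,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
    min_map_identity: float = DEFAULT_MIN_MAP_IDENTITY,
) -> str:
    """One-off flank classification (builds a mapper; for corpora build a
    :class:`FlankMapper` once and reuse it)."""
    mapper = FlankMapper(genome, min_flank_len=min_flank_len, min_map_identity=min_map_identity)
    return mapper.classify(masked)


def corpus_feature_summary(records: pd.DataFrame, by_category: bool = True) -> pd.DataFrame:
    """Percentage summaries of the four features, overall and per category.

    ``records`` needs columns orientation, has_utr5, yy1_intact,
    flank_class, and (for stratification) category.  UNMAPPED and NONE are
    additionally merged into a combined bucket for comparison against
    no-flank/unmappable-flank reporting conventions.
    """

    def _summary(df: pd.DataFrame) -> dict:
        n = len(df)
        if n == 0:
            return {"n_reads": 0}
        out = {
            "n_reads": n,
            "sense_pct": 100.0 * (df["orientation"] == "SENSE").mean(),
            "utr5_pct": 100.0 * df["has_utr5"].mean(),
            "yy1_pct": 100.0 * df["yy1_intact"].mean(),
        }
        for fc in (FLANK_INTRAGENIC, FLANK_INTERGENIC, FLANK_UNMAPPED, FLANK_NONE):
            out[f"flank_{fc.lower()}_pct"] = 100.0 * (df["flank_class"] == fc).mean()
        out["flank_none_or_unmapped_pct"] = (
            out[f"flank_{FLANK_UNMAPPED.lower()}_pct"] + out[f"flank_{FLANK_NONE.lower()}_pct"]
        )
        return out

    rows = [{"stratum": "ALL", **_summary(records)}]
    if by_category and "category" in records.columns:
        for cat, df in records.groupby("category", sort=True):
            rows.append({"stratum": str(cat), **_summary(df)})
    return pd.DataFrame(rows)
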