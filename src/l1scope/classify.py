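"""ORF finding, consensus-protein alignment, and six-way coding categories.

Each L1-containing read is sense-oriented from its consensus-alignment
strand, scanned for open reading frames (ATG to stop, or ATG to read end
for truncated transcripts), and each predicted protein is locally aligned
to the consensus ORF1 and ORF2 proteins.  Coverage/identity thresholds
then yield three status flags (ORF1 intact, ORF2 intact, ORF2 partial)
which map onto one of six coding categories:

    NONCODING, ORF1_ONLY, ORF2_ONLY, ORF2P_ONLY, ORF1_ORF2P, ORF1_ORF2

"ORF2 partial" (ORF2P) is a 3'-truncated ORF2 that retains the intact RT
domain; when the read carries no intact ORF1 the EN domain is additionally
required, so that a monocistronic ORF2P call means an EN+RT-bearing
protein.  A flag collapses the two phrasings onto the RT-only definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import START_CODON_ID, STOP_CODON_IDS, codon_ids, encode, revcomp, translate_ids
from .consensus import ConsensusModel, Interval
from .detect import L1Hit


class Orientation(str, enum.Enum):
    SENSE = "SENSE"
    ANTISENSE = "ANTISENSE"


class CodingCategory(str, enum.Enum):
    NONCODING = "NONCODING"
    ORF1_ONLY = "ORF1_ONLY"
    ORF2_ONLY = "ORF2_ONLY"
    ORF2P_ONLY = "ORF2P_ONLY"
    ORF1_ORF2P = "ORF1_ORF2P"
    ORF1_ORF2 = "ORF1_ORF2"


@dataclass(frozen=True)
class OrfCall:
    """A predicted ORF on the sense-oriented read."""

    read_id: str
    nt_interval: Interval  # includes the stop codon when one terminates the ORF
    frame: int
    protein: str
    has_stop: bool


@dataclass(frozen=True)
class ProteinAlignment:
    """Local alignment of a predicted protein to a consensus protein."""

    target: str  # "ORF1" or "ORF2"
    coverage: float  # aligned target span / target length
    identity: float  # matches / aligned columns
    target_interval: Interval  # aligned span on the consensus protein (aa)
    query_interval: Interval
    score: float


@dataclass(frozen=True)
class ClassifyThresholds:
    """Intactness thresholds; the defaults follow BLASTp conventions.

    ``min_protein_len`` of None means automatic: min(100, half the shorter
    consensus protein), so that scaled-down toy models remain classifiable.
    """

    min_protein_len: int | None = None
    intact_cov: float = 0.95
    intact_id: float = 0.80
    domain_cov: float = 0.95
    six_frame: bool = False
    uniform_orf2p: bool = False  # force the RT-only ORF2P definition everywhere

    def __post_init__(self) -> None:
        for name in ("intact_cov", "intact_id", "domain_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def effective_min_protein_len(self, model: ConsensusModel) -> int:
        if self.min_protein_len is not None:
            return self.min_protein_len
        shortest = min(len(model.orf1_protein), len(model.orf2_protein))
        return min(100, shortest // 2)


DEFAULT_THRESHOLDS = ClassifyThresholds()


@dataclass(frozen=True)
class OrfStatus:
    orf1_intact: bool
    orf2_intact: bool
    orf2_partial: bool


@dataclass
class ReadClassification:
    read_id: str
    sample_id: str
    category: CodingCategory
    orientation: Orientation
    orf_calls: list[OrfCall] = field(default_factory=list)
    alignments: list[tuple[OrfCall, ProteinAlignment]] = field(default_factory=list)
    orf1_protein: str | None = None  # called protein supporting the ORF1 flag
    orf2_protein: str | None = None  # called protein supporting the ORF2 flag
    orf1_nt: str | None = None
    orf2_nt: str | None = None


def orient_read(read_seq: str, hits: list[L1Hit]) -> tuple[str, Orientation]:
    """Sense-orient a read from its consensus-alignment strands.

    Majority aligned bp on the minus strand flips the read; ties are SENSE.
    """
    if not hits:
        raise ValueError("orient_read requires at least one L1 hit")
    plus = sum(h.read_interval[1] - h.read_interval[0] for h in hits if h.strand == "+")
    minus = sum(h.read_interval[1] - h.read_interval[0] for h in hits if h.strand == "-")
    if minus > plus:
        return revcomp(read_seq), Orientation.ANTISENSE
    return read_seq, Orientation.SENSE


def find_orfs(seq: str, min_protein_len: int = 100, six_frame: bool = False, read_id: str = "read") -> list[OrfCall]:
    """Maximal ATG-to-stop ORFs in the three forward frames (six with
    ``six_frame``); ORFs running to sequence end without a stop are kept
    to admit truncated transcripts."""
    calls = _scan_strand(seq, min_protein_len, read_id)
    if six_frame:
        calls.extend(_scan_strand(revcomp(seq), min_protein_len, read_id))
    calls.sort(key=lambda c: (c.nt_interval, c.frame))
    return calls


def _scan_strand(seq: str, min_protein_len: int, read_id: str) -> list[OrfCall]:
    codes = encode(seq.upper())
    out: list[OrfCall] = []
    for frame in range(3):
        ids = codon_ids(codes, frame)
        if ids.shape[0] == 0:
            continue
        is_stop = np.isin(ids, list(STOP_CODON_IDS))
        stop_idx = np.flatnonzero(is_stop)
        start_idx = np.flatnonzero(ids == START_CODON_ID)
        region_start = 0
        boundaries = list(stop_idx) + [ids.shape[0]]
        for boundary in boundaries:
            pos = np.searchsorted(start_idx, region_start)
            if pos < start_idx.shape[0] and start_idx[pos] < boundary:
                s = int(start_idx[pos])
                boundary = int(boundary)
                has_stop = boundary < ids.shape[0]
                protein = translate_ids(ids[s:boundary])
                if len(protein) >= min_protein_len:
                    end_codon = boundary + 1 if has_stop else boundary
                    out.append(
                        OrfCall(
                            read_id=read_id,
                            nt_interval=(frame + 3 * s, frame + 3 * end_codon),
                            frame=frame,
                            protein=protein,
                            has_stop=has_stop,
                        )
                    )
            region_start = boundary + 1
    return out


class ProteinAligner:
    """Smith-Waterman protein alignment against the consensus ORFs.

    BLOSUM62 with affine gaps (open 11, extend 1) by default; results are
    memoised per query protein, which makes corpus-scale classification
    cheap because identical predicted proteins recur across reads.
    """

    def __init__(
        self,
        model: ConsensusModel,
        matrix: str = "BLOSUM62",
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
    ):
        self.model = model
        self.targets = {"ORF1": model.orf1_protein, "ORF2": model.orf2_protein}
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(matrix)
        self._aligner.open_gap_score = -abs(gap_open)
        self._aligner.extend_gap_score = -abs(gap_extend)
        self._cache: dict[tuple[str, str], ProteinAlignment | None] = {}

    def align(self, protein: str, target: str) -> ProteinAlignment | None:
        key = (protein, target)
        if key not in self._cache:
            self._cache[key] = self._align(protein, target)
        return self._cache[key]

    def _align(self, protein: str, target: str) -> ProteinAlignment | None:
        target_seq = self.targets[target]
        if not protein:
            return None
        alns = self._aligner.align(target_seq, protein)
        if len(alns) == 0 or alns.score <= 0:
            return None
        best = alns[0]  # deterministic first-optimal tie-break
        t_blocks, q_blocks = best.aligned
        t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
        q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
        counts = best.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / cols if cols else 0.0
        return ProteinAlignment(
            target=target,
            coverage=(t_end - t_start) / len(target_seq),
            identity=identity,
            target_interval=(t_start, t_end),
            query_interval=(q_start, q_end),
            score=float(best.score),
        )


def align_protein(
    orf_protein: str,
    consensus_protein: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ProteinAlignment:
    """One-off local alignment of a predicted protein to a consensus protein."""
    aligner = ProteinAligner.__new__(ProteinAligner)
    aligner.model = None
    aligner.targets = {"TARGET": consensus_protein}
    aligner._aligner = Align.PairwiseAligner()
    aligner._aligner.mode = "local"
    aligner._aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner._aligner.open_gap_score = -abs(gap_open)
    aligner._aligner.extend_gap_score = -abs(gap_extend)
    aligner._cache = {}
    result = aligner.align(orf_protein, "TARGET")
    if result is None:
        return ProteinAlignment("TARGET", 0.0, 0.0, (0, 0), (0, 0), 0.0)
    return result


def _domain_coverage(target_interval: Interval, domain: Interval) -> float:
    s, e = target_interval
    ds, de = domain
    overlap = max(0, min(e, de) - max(s, ds))
    return overlap / (de - ds) if de > ds else 0.0


def call_orf_status(
    alignments: list[tuple[OrfCall, ProteinAlignment]],
    model: ConsensusModel,
    thresholds: ClassifyThresholds = DEFAULT_THRESHOLDS,
) -> OrfStatus:
    """Reduce one read's protein alignments to the three intactness flags."""
    orf1_alns = [a for _, a in alignments if a.target == "ORF1"]
    orf2_alns = [a for _, a in alignments if a.target == "ORF2"]
    orf1_intact = any(
        a.coverage >= thresholds.intact_cov and a.identity >= thresholds.intact_id for a in orf1_alns
    )
    orf2_intact = any(
        a.coverage >= thresholds.intact_cov and a.identity >= thresholds.intact_id for a in orf2_alns
    )
    orf2_partial = False
    if not orf2_intact:
        need_en = (not orf1_intact) and (not thresholds.uniform_orf2p)
        for a in orf2_alns:
            if a.identity < thresholds.intact_id:
                continue
            if _domain_coverage(a.target_interval, model.rt_domain) < thresholds.domain_cov:
                continue
            if need_en and _domain_coverage(a.target_interval, model.en_domain) < thresholds.domain_cov:
                continue
            orf2_partial = True
            break
    return OrfStatus(orf1_intact, orf2_intact, orf2_partial)


def classify_read(status: OrfStatus) -> CodingCategory:
    """Total, single-valued mapping from status flags to coding category."""
    if status.orf1_intact and status.orf2_intact:
        return CodingCategory.ORF1_ORF2
    if status.orf1_intact and status.orf2_partial:
        return CodingCategory.ORF1_ORF2P
    if status.orf2_intact:
        return CodingCategory.ORF2_ONLY
    if status.orf2_partial:
        return CodingCategory.ORF2P_ONLY
    if status.orf1_intact:
        return CodingCategory.ORF1_ONLY
    return CodingCategory.NONCODING


def classify_oriented_read(
    oriented_seq: str,
    read_id: str,
    sample_id: str,
    orientation: Orientation,
    aligner: ProteinAligner,
    thresholds: ClassifyThresholds = DEFAULT_THRESHOLDS,
) -> ReadClassification:
    """Run ORF finding + alignment + category assignment for one read."""
    model = aligner.model
    min_len = thresholds.effective_min_protein_len(model)
    orfs = find_orfs(oriented_seq, min_len, six_frame=thresholds.six_frame, read_id=read_id)
    alignments: list[tuple[OrfCall, ProteinAlignment]] = []
    for orf in orfs:
        for target in ("ORF1", "ORF2"):
            aln = aligner.align(orf.protein, target)
            if aln is not None:
                alignments.append((orf, aln))
    status = call_orf_status(alignments, model, thresholds)
    category = classify_read(status)
    cls = ReadClassification(
        read_id=read_id,
        sample_id=sample_id,
        category=category,
        orientation=orientation,
        orf_calls=orfs,
        alignments=alignments,
    )

    def _best(target: str, predicate) -> tuple[OrfCall, ProteinAlignment] | None:
        cands = [(o, a) for o, a in alignments if a.target == target and predicate(a)]
        if not cands:
            return None
        return max(cands, key=lambda oa: (oa[1].coverage, oa[1].identity, oa[1].score))

    if status.orf1_intact:
        best = _best("ORF1", lambda a: a.coverage >= thresholds.intact_cov and a.identity >= thresholds.intact_id)
        if best:
            orf, _ = best
            cls.orf1_protein = orf.protein
            s, e = orf.nt_interval
            cls.orf1_nt = oriented_seq[s:e]
    if status.orf2_intact or status.orf2_partial:
        if status.orf2_intact:
            best = _best("ORF2", lambda a: a.coverage >= thresholds.intact_cov and a.identity >= thresholds.intact_id)
        else:
            best = _best(
                "ORF2",
                lambda a: a.identity >= thresholds.intact_id
                and _domain_coverage(a.target_interval, model.rt_domain) >= thresholds.domain_cov,
            )
        if best:
            orf, _ = best
            cls.orf2_protein = orf.protein
            s, e = orf.nt_interval
            cls.orf2_nt = oriented_seq[s:e]
    return cls
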