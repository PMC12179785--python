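"""L1 detection: seed-chain-extend local alignment against the consensus.

Reads are screened for L1-derived segments by exact k-mer seeding against
both strands of the consensus, chaining of collinear seeds (tolerating
large consensus-side gaps, the long-read analogue of spliced/internally
deleted alignment), ungapped x-drop extension of chain ends, and
identity/length filtering.  A read is "L1-containing" iff it has at least
one qualifying hit.  The same machinery, with a small gap allowance,
drives repeat-subfamily annotation against a repeat library, and detected
L1 intervals are masked to expose flanking (non-L1) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .consensus import ConsensusModel

Interval = tuple[int, int]


@dataclass(frozen=True)
class AlignParams:
    """Seeding/chaining/scoring parameters for DNA local alignment.

    Scores follow the match/mismatch/gap-open/gap-extend convention with
    the open penalty charged to the first gapped base.
    """

    kmer_size: int = 15
    min_segment_len: int = 100
    min_identity: float = 0.80
    max_gap: int = 5000
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    xdrop: int = 12
    # gaps at least this long are structural (internal deletions/splices):
    # excluded from identity columns and not charged gap penalties
    structural_gap_min: int = 30


DETECT_PARAMS = AlignParams()
# Subfamily attribution wants locally best assignments, not splice-tolerant
# chains that swallow neighbouring segments, hence the small gap allowance
# and stricter identity.
ANNOTATE_PARAMS = AlignParams(max_gap=50, min_identity=0.90)


@dataclass(frozen=True)
class L1Hit:
    read_id: str
    read_interval: Interval
    consensus_interval: Interval
    strand: str  # '+' or '-'
    identity: float
    score: int

    def __post_init__(self) -> None:
        rs, re_ = self.read_interval
        cs, ce = self.consensus_interval
        if rs >= re_ or cs >= ce:
            raise ValueError("hit intervals must be non-empty")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass(frozen=True)
class RepeatLibrary:
    """Named subfamily consensus sequences used for annotation."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("repeat library must contain at least one subfamily")
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"subfamily {name!r} has an empty sequence")


@dataclass(frozen=True)
class MaskedRead:
    read_id: str
    masked_seq: str
    flank_segments: list[tuple[Interval, str]] = field(default_factory=list)


class _StrandIndex:
    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        codes = kmer_codes(encode(seq), k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = order.astype(np.int64)

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, ref_pos) pairs of exact k-mer matches."""
        left = np.searchsorted(self.sorted_codes, query_codes, side="left")
        right = np.searchsorted(self.sorted_codes, query_codes, side="right")
        counts = right - left
        valid = (query_codes >= 0) & (counts > 0)
        counts = np.where(valid, counts, 0)
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(np.arange(query_codes.shape[0]), counts)
        starts = np.repeat(left, counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return qpos, self.sorted_pos[starts + offs]


class SequenceIndex:
    """Two-strand k-mer index of a target sequence (consensus or subfamily)."""

    def __init__(self, seq: str, k: int = 15):
        self.seq = seq.upper()
        self.k = k
        self.fwd = _StrandIndex(self.seq, k)
        self.rev = _StrandIndex(revcomp(self.seq), k)


@dataclass
class _Chain:
    q0: int
    q1: int
    r0: int
    r1: int
    n_seeds: int
    parts: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parts:
            self.parts = [(self.q0, self.q1, self.r0, self.r1)]


def _diagonal_runs(qpos: np.ndarray, rpos: np.ndarray, k: int, run_gap: int = 200) -> list[_Chain]:
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    q, r, d = qpos[order], rpos[order], diag[order]
    breaks = np.flatnonzero((np.diff(d) != 0) | (np.diff(q) > run_gap)) + 1
    runs = []
    for seg in np.split(np.arange(q.shape[0]), breaks):
        runs.append(_Chain(int(q[seg[0]]), int(q[seg[-1]]) + k, int(r[seg[0]]), int(r[seg[-1]]) + k, len(seg)))
    runs.sort(key=lambda c: (c.q0, c.r0))
    return runs


def _chain_runs(runs: list[_Chain], k: int, max_gap: int) -> list[_Chain]:
    chains: list[_Chain] = []
    for run in runs:
        attached = False
        for ch in chains:
            qgap = run.q0 - ch.q1
            rgap = run.r0 - ch.r1
            if -k < qgap <= max_gap and -k < rgap <= max_gap and run.r1 > ch.r1:
                ch.q1 = max(ch.q1, run.q1)
                ch.r1 = run.r1
                ch.n_seeds += run.n_seeds
                ch.parts.append((run.q0, run.q1, run.r0, run.r1))
                attached = True
                break
        if not attached:
            chains.append(replace(run, parts=[(run.q0, run.q1, run.r0, run.r1)]))
    return chains


def _extend(read: str, target: str, chain: _Chain, p: AlignParams) -> _Chain:
    """Greedy ungapped x-drop extension of both chain ends."""
    q0, q1, r0, r1 = chain.q0, chain.q1, chain.r0, chain.r1
    # right
    score, best, bq, br = 0, 0, q1, r1
    qi, ri = q1, r1
    while qi < len(read) and ri < len(target):
        score += p.match if read[qi] == target[ri] else p.mismatch
        qi += 1
        ri += 1
        if score > best:
            best, bq, br = score, qi, ri
        elif score < best - p.xdrop:
            break
    q1, r1 = bq, br
    # left
    score, best, bq, br = 0, 0, q0, r0
    qi, ri = q0, r0
    while qi > 0 and ri > 0:
        qi -= 1
        ri -= 1
        score += p.match if read[qi] == target[ri] else p.mismatch
        if score > best:
            best, bq, br = score, qi, ri
        elif score < best - p.xdrop:
            break
    q0, r0 = bq, br
    parts = list(chain.parts)
    fq0, fq1, fr0, fr1 = parts[0]
    parts[0] = (q0, fq1, r0, fr1)
    lq0, lq1, lr0, lr1 = parts[-1]
    if len(parts) == 1:
        parts[0] = (q0, q1, r0, r1)
    else:
        parts[-1] = (lq0, q1, lr0, r1)
    return _Chain(q0, q1, r0, r1, chain.n_seeds, parts)


def _eq_count(a: str, b: str) -> int:
    return int(
        np.count_nonzero(
            np.frombuffer(a.encode(), np.uint8) == np.frombuffer(b.encode(), np.uint8)
        )
    )


def _score_chain(read: str, target: str, chain: _Chain, p: AlignParams) -> tuple[float, int]:
    """(identity, score) over the chain's collinear parts.

    Each part is a constant-diagonal run, scored by direct base
    comparison.  Inter-part gaps shorter than ``structural_gap_min`` are
    charged affine gap penalties and count as alignment columns; longer
    gaps are structural deletions, excluded from identity (the
    splice-tolerant convention) and unpenalised.
    """
    matches = cols = gap_cols = 0
    gap_score = 0
    prev_q = prev_r = None
    for q0, q1, r0, r1 in chain.parts:
        if prev_q is not None:
            trim = max(0, prev_q - q0, prev_r - r0)
            q0, r0 = q0 + trim, r0 + trim
            qgap, rgap = q0 - prev_q, r0 - prev_r
            mid = min(qgap, rgap)
            if mid > 0:  # unseeded middle: compare directly as columns
                matches += _eq_count(read[prev_q : prev_q + mid], target[prev_r : prev_r + mid])
                cols += mid
            g = abs(qgap - rgap)
            if 0 < g < p.structural_gap_min:
                cols += g
                gap_cols += g
                gap_score += p.gap_open + p.gap_extend * (g - 1)
        if q1 > q0:
            matches += _eq_count(read[q0:q1], target[r0:r1])
            cols += q1 - q0
        prev_q, prev_r = max(q1, q0), max(r1, r0)
    identity = matches / cols if cols else 0.0
    mismatches = cols - matches - gap_cols
    score = p.match * matches + p.mismatch * mismatches + gap_score
    return identity, int(score)


def find_l1_segments(
    read_seq: str,
    consensus: ConsensusModel | SequenceIndex | str,
    params: AlignParams = DETECT_PARAMS,
    read_id: str = "read",
) -> list[L1Hit]:
    """Locate L1-derived segments of a read on both consensus strands.

    Returns hits sorted by read coordinate; an empty list means the read is
    not L1-containing.
    """
    index = _as_index(consensus, params.kmer_size)
    read_seq = read_seq.upper()
    if len(read_seq) < params.kmer_size:
        return []
    qcodes = kmer_codes(encode(read_seq), params.kmer_size)
    hits: list[L1Hit] = []
    n_target = len(index.seq)
    for strand, sidx in (("+", index.fwd), ("-", index.rev)):
        qpos, rpos = sidx.lookup(qcodes)
        if qpos.shape[0] == 0:
            continue
        runs = _diagonal_runs(qpos, rpos, params.kmer_size)
        for chain in _chain_runs(runs, params.kmer_size, params.max_gap):
            chain = _extend(read_seq, sidx.seq, chain, params)
            if chain.q1 - chain.q0 < params.min_segment_len:
                continue
            identity, score = _score_chain(read_seq, sidx.seq, chain, params)
            if identity < params.min_identity:
                continue
            if strand == "+":
                cons_iv = (chain.r0, chain.r1)
            else:
                cons_iv = (n_target - chain.r1, n_target - chain.r0)
            hits.append(
                L1Hit(
                    read_id=read_id,
                    read_interval=(chain.q0, chain.q1),
                    consensus_interval=cons_iv,
                    strand=strand,
                    identity=identity,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.read_interval, h.consensus_interval))
    return hits


def _as_index(consensus: ConsensusModel | SequenceIndex | str, k: int) -> SequenceIndex:
    if isinstance(consensus, SequenceIndex):
        return consensus
    if isinstance(consensus, ConsensusModel):
        return SequenceIndex(consensus.nt_seq, k)
    return SequenceIndex(consensus, k)


def merge_hits(hits: list[L1Hit]) -> list[L1Hit]:
    """Merge read-interval-overlapping hits on the same strand.

    The merged hit keeps the higher score and the identity weighted by
    aligned span; consensus intervals are unioned.
    """
    merged: list[L1Hit] = []
    for hit in sorted(hits, key=lambda h: (h.strand, h.read_interval)):
        if merged and merged[-1].strand == hit.strand and hit.read_interval[0] < merged[-1].read_interval[1]:
            prev = merged[-1]
            w_prev = prev.read_interval[1] - prev.read_interval[0]
            w_new = hit.read_interval[1] - hit.read_interval[0]
            merged[-1] = L1Hit(
                read_id=prev.read_id,
                read_interval=(prev.read_interval[0], max(prev.read_interval[1], hit.read_interval[1])),
                consensus_interval=(
                    min(prev.consensus_interval[0], hit.consensus_interval[0]),
                    max(prev.consensus_interval[1], hit.consensus_interval[1]),
                ),
                strand=prev.strand,
                identity=(prev.identity * w_prev + hit.identity * w_new) / (w_prev + w_new),
                score=max(prev.score, hit.score),
            )
        else:
            merged.append(hit)
    merged.sort(key=lambda h: h.read_interval)
    return merged


def annotate_subfamilies(
    read_seq: str,
    library: RepeatLibrary | dict[str, SequenceIndex],
    params: AlignParams = ANNOTATE_PARAMS,
    read_id: str = "read",
) -> list[tuple[str, Interval, int]]:
    """Per-region best-scoring subfamily assignments for one read.

    Candidate hits from every subfamily compete greedily by score; a
    candidate is kept when it overlaps already-kept annotations over less
    than half of its span, so a read may carry multiple annotations.
    """
    if isinstance(library, RepeatLibrary):
        indexes = {name: SequenceIndex(seq, params.kmer_size) for name, seq in library.entries.items()}
    else:
        indexes = library
    candidates: list[tuple[str, L1Hit]] = []
    for name, idx in indexes.items():
        for hit in find_l1_segments(read_seq, idx, params, read_id=read_id):
            candidates.append((name, hit))
    candidates.sort(key=lambda c: (-c[1].score, c[0]))
    kept: list[tuple[str, Interval, int]] = []
    for name, hit in candidates:
        s, e = hit.read_interval
        overlap = sum(max(0, min(e, ke) - max(s, ks)) for _, (ks, ke), _ in kept)
        if overlap < 0.5 * (e - s):
            kept.append((name, hit.read_interval, hit.score))
    kept.sort(key=lambda a: a[1])
    return kept


def annotate_corpus(
    reads: list[tuple[str, str]],
    library: RepeatLibrary,
    params: AlignParams = ANNOTATE_PARAMS,
) -> dict:
    """Annotate a corpus; returns per-read annotations plus summary stats.

    Per-subfamily percentages are fractions of reads carrying at least one
    annotation of that subfamily and may total more than 100%.
    """
    indexes = {name: SequenceIndex(seq, params.kmer_size) for name, seq in library.entries.items()}
    per_read = {}
    counts: dict[str, int] = {name: 0 for name in library.entries}
    total_annotations = 0
    for read_id, seq in reads:
        anns = annotate_subfamilies(seq, indexes, params, read_id=read_id)
        per_read[read_id] = anns
        total_annotations += len(anns)
        for name in {a[0] for a in anns}:
            counts[name] += 1
    n = len(reads)
    return {
        "per_read": per_read,
        "mean_annotations_per_read": total_annotations / n if n else 0.0,
        "subfamily_pct": {name: 100.0 * c / n if n else 0.0 for name, c in counts.items()},
    }


def toy_repeat_library(model: ConsensusModel, divergence: float = 0.30, seed: int = 1) -> RepeatLibrary:
    """Two-entry toy library: the consensus itself plus a diverged copy."""
    rng = np.random.default_rng(seed)
    seq = model.nt_seq
    bases = "ACGT"
    diverged = list(seq)
    n_mut = int(round(divergence * len(seq)))
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        alts = [b for b in bases if b != seq[pos]]
        diverged[pos] = alts[int(rng.integers(0, 3))]
    return RepeatLibrary({"L1toyHS": seq, "L1toyPA": "".join(diverged)})


def mask_l1(read_seq: str, hits: list[L1Hit], min_flank_len: int = 100, read_id: str = "read") -> MaskedRead:
    """Mask L1 hit intervals with N and collect flank segments.

    Flanks are maximal non-L1 runs of at least ``min_flank_len`` bases;
    masking preserves read length.
    """
    seq = list(read_seq)
    for hit in merge_hits(hits):
        s, e = hit.read_interval
        for i in range(s, min(e, len(seq))):
            seq[i] = "N"
    masked = "".join(seq)
    flanks: list[tuple[Interval, str]] = []
    start = None
    for i, ch in enumerate(masked + "N"):
        if ch != "N" and start is None:
            start = i
        elif ch == "N" and start is not None:
            if i - start >= min_flank_len:
                flanks.append(((start, i), masked[start:i]))
            start = None
    return MaskedRead(read_id=read_id, masked_seq=masked, flank_segments=flanks)
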