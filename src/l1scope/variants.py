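"""Variant collapsing, sample sharing, SAV calling, residue conservation.

Classified coding reads are grouped by exact key sequence (the predicted
protein by default, codon-level nucleotide sequence by flag) within each
coding category; groups supported by at least ``min_support`` reads
(default 3) become variants, with sample membership recorded so that
private-variant fractions (variants seen in exactly one sample) can be
computed.  Each variant's protein is aligned globally (free end gaps, so
truncated variants align without penalty) to the consensus protein;
substitution columns are reported as single-amino-acid variants (SAVs)
and gap columns as truncation/indel spans, never as SAVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .classify import CodingCategory, ReadClassification
from .consensus import ConsensusModel

Interval = tuple[int, int]

DEFAULT_MIN_SUPPORT = 3


@dataclass(frozen=True)
class Sav:
    """A single-amino-acid variant against the consensus protein."""

    position: int  # 0-based index on the consensus protein
    consensus_aa: str
    variant_aa: str


@dataclass
class SavResult:
    savs: list[Sav]
    covered_span: Interval  # aligned span on the consensus protein
    truncation_spans: list[Interval]  # consensus spans opposite gaps


@dataclass
class Variant:
    variant_id: str
    category: CodingCategory
    key: tuple
    proteins: dict[str, str]  # target name -> called protein
    supporting_read_ids: list[str]
    samples: set[str]
    savs: list[Sav] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)


def _read_key(cls: ReadClassification, key_level: str) -> tuple | None:
    if key_level == "protein":
        parts = (cls.orf1_protein, cls.orf2_protein)
    elif key_level == "nucleotide":
        parts = (cls.orf1_nt, cls.orf2_nt)
    else:
        raise ValueError(f"key_level must be 'protein' or 'nucleotide', got {key_level!r}")
    if all(p is None for p in parts):
        return None
    return parts


def call_variants(
    classifications: list[ReadClassification],
    min_support: int = DEFAULT_MIN_SUPPORT,
    key_level: str = "protein",
) -> tuple[list[Variant], list[tuple[tuple, list[str]]]]:
    """Collapse coding reads into supported variants.

    Reads are pooled across samples; sample membership is recorded per
    variant.  Returns (variants, unsupported groups); grouping is
    permutation-invariant with respect to read order.
    """
    groups: dict[tuple, list[ReadClassification]] = {}
    for cls in classifications:
        if cls.category is CodingCategory.NONCODING:
            continue
        key = _read_key(cls, key_level)
        if key is None:
            continue
        groups.setdefault((cls.category, key), []).append(cls)
    variants: list[Variant] = []
    unsupported: list[tuple[tuple, list[str]]] = []
    ordered = sorted(
        groups.items(),
        key=lambda kv: (kv[0][0].value, -len(kv[1]), kv[0][1]),
    )
    for (category, key), members in ordered:
        read_ids = sorted(c.read_id for c in members)
        if len(members) >= min_support:
            proteins = {}
            exemplar = members[0]
            if exemplar.orf1_protein:
                proteins["ORF1"] = exemplar.orf1_protein
            if exemplar.orf2_protein:
                proteins["ORF2"] = exemplar.orf2_protein
            variants.append(
                Variant(
                    variant_id=f"V{len(variants) + 1:04d}",
                    category=category,
                    key=key,
                    proteins=proteins,
                    supporting_read_ids=read_ids,
                    samples={c.sample_id for c in members},
                )
            )
        else:
            unsupported.append(((category, key), read_ids))
    return variants, unsupported


def private_variant_fraction(variants: list[Variant]) -> float:
    """Fraction of variants identified in exactly one sample."""
    if not variants:
        return 0.0
    return sum(1 for v in variants if len(v.samples) == 1) / len(variants)


def _global_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    # free end gaps: truncated variants align to a consensus prefix/suffix
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def find_savs(
    variant_protein: str,
    consensus_protein: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SavResult:
    """Call SAVs from a free-end-gap global alignment to the consensus.

    For gap-free optimal alignments the SAV count equals the Hamming
    distance over the aligned span.
    """
    if not variant_protein or not consensus_protein:
        raise ValueError("find_savs requires non-empty protein sequences")
    aligner = _global_aligner(matrix, gap_open, gap_extend)
    best = aligner.align(consensus_protein, variant_protein)[0]
    t_blocks, q_blocks = best.aligned
    savs: list[Sav] = []
    truncations: list[Interval] = []
    if len(t_blocks) == 0:
        return SavResult([], (0, 0), [(0, len(consensus_protein))])
    for (ts, te), (qs, qe) in zip(t_blocks.tolist(), q_blocks.tolist()):
        for off in range(te - ts):
            ca = consensus_protein[ts + off]
            va = variant_protein[qs + off]
            if ca != va:
                savs.append(Sav(position=ts + off, consensus_aa=ca, variant_aa=va))
    # consensus spans skipped between/outside aligned blocks = truncations/indels
    covered = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    prev_end = None
    for ts, te in t_blocks:
        if prev_end is not None and ts > prev_end:
            truncations.append((int(prev_end), int(ts)))
        prev_end = te
    if covered[0] > 0:
        truncations.insert(0, (0, covered[0]))
    if covered[1] < len(consensus_protein):
        truncations.append((covered[1], len(consensus_protein)))
    return SavResult(savs=savs, covered_span=covered, truncation_spans=truncations)


def annotate_savs(variants: list[Variant], model: ConsensusModel) -> None:
    """Fill each variant's SAV list against the matching consensus protein
    (ORF2 when the variant carries one, ORF1 otherwise)."""
    for v in variants:
        if "ORF2" in v.proteins:
            v.savs = find_savs(v.proteins["ORF2"], model.orf2_protein).savs
        elif "ORF1" in v.proteins:
            v.savs = find_savs(v.proteins["ORF1"], model.orf1_protein).savs


def residue_conservation(
    variants: list[Variant],
    positions: list[int],
    model: ConsensusModel,
    target: str = "ORF2",
) -> pd.DataFrame:
    """Per-position conservation of consensus residues across variants.

    A variant conserves a position when its aligned residue equals the
    consensus residue; variants whose alignment does not cover the
    position count as non-conserving and are tallied as absent.
    """
    consensus_protein = model.orf2_protein if target == "ORF2" else model.orf1_protein
    for pos in positions:
        if not 0 <= pos < len(consensus_protein):
            raise ValueError(f"position {pos} outside consensus {target} protein")
    rows = []
    results = []
    for v in variants:
        protein = v.proteins.get(target)
        results.append(find_savs(protein, consensus_protein) if protein else None)
    for pos in positions:
        conserved = mutated = absent = 0
        for res in results:
            if res is None or not (res.covered_span[0] <= pos < res.covered_span[1]) or any(
                s <= pos < e for s, e in res.truncation_spans
            ):
                absent += 1
                continue
            if any(s.position == pos for s in res.savs):
                mutated += 1
            else:
                conserved += 1
        n = len(variants)
        rows.append(
            {
                "position": pos,
                "consensus_aa": consensus_protein[pos],
                "n_variants": n,
                "conserved_fraction": conserved / n if n else 0.0,
                "mutated_pct": 100.0 * mutated / n if n else 0.0,
                "n_absent": absent,
            }
        )
    return pd.DataFrame(rows)


def variant_table(variants: list[Variant]) -> pd.DataFrame:
    """Tabular view: id, category, support, sample count, SAV count."""
    return pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "category": v.category.value,
                "support": v.support,
                "n_samples": len(v.samples),
                "n_savs": len(v.savs),
            }
            for v in variants
        ]
    )
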