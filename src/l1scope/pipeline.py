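"""End-to-end orchestration: detect -> orient -> classify -> features ->
variants -> summaries.

:func:`analyze_reads` is the in-memory pipeline the CLI, tests, and
acceptance runs all share.  All stages are deterministic; randomness
lives exclusively in the synthetic-data generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import (
    ClassifyThresholds,
    DEFAULT_THRESHOLDS,
    ProteinAligner,
    ReadClassification,
    classify_oriented_read,
    orient_read,
)
from .consensus import ConsensusModel
from .detect import AlignParams, DETECT_PARAMS, L1Hit, SequenceIndex, find_l1_segments, mask_l1
from .features import DEFAULT_MIN_FLANK_LEN, DEFAULT_MIN_UTR_OVERLAP, FlankMapper, has_utr5, yy1_intact
from .report import SampleSummary, summarize_sample
from .simulate import FLANK_NONE, ToyGenome
from .variants import Variant, annotate_savs, call_variants

logger = logging.getLogger("l1scope")


@dataclass
class PipelineResult:
    per_read: pd.DataFrame
    classifications: list[ReadClassification]
    hits_by_read: dict[str, list[L1Hit]]
    variants: list[Variant]
    unsupported: list
    summary: SampleSummary
    model: ConsensusModel = field(repr=False, default=None)


def analyze_reads(
    reads: list[tuple[str, str]],
    model: ConsensusModel,
    genome: ToyGenome | None = None,
    sample_id: str = "S1",
    detect_params: AlignParams = DETECT_PARAMS,
    thresholds: ClassifyThresholds = DEFAULT_THRESHOLDS,
    min_utr_overlap: int = DEFAULT_MIN_UTR_OVERLAP,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
    min_support: int = 3,
) -> PipelineResult:
    """Run the full analysis over an in-memory read set."""
    index = SequenceIndex(model.nt_seq, detect_params.kmer_size)
    aligner = ProteinAligner(model)
    mapper = FlankMapper(genome, min_flank_len=min_flank_len) if genome is not None else None
    rows = []
    classifications: list[ReadClassification] = []
    hits_by_read: dict[str, list[L1Hit]] = {}
    n_l1 = 0
    for read_id, seq in reads:
        hits = find_l1_segments(seq, index, detect_params, read_id=read_id)
        if not hits:
            rows.append(
                {
                    "read_id": read_id,
                    "is_l1": False,
                    "category": None,
                    "orientation": None,
                    "has_utr5": False,
                    "yy1_intact": False,
                    "flank_class": None,
                    "read_length": len(seq),
                }
            )
            continue
        n_l1 += 1
        hits_by_read[read_id] = hits
        oriented, orientation = orient_read(seq, hits)
        cls = classify_oriented_read(oriented, read_id, sample_id, orientation, aligner, thresholds)
        classifications.append(cls)
        utr = has_utr5(hits, model, min_utr_overlap)
        yy1 = yy1_intact(oriented, model.yy1_motif)
        if mapper is not None:
            masked = mask_l1(seq, hits, min_flank_len, read_id=read_id)
            flank_class = mapper.classify(masked)
        else:
            masked = mask_l1(seq, hits, min_flank_len, read_id=read_id)
            flank_class = FLANK_NONE if not masked.flank_segments else "UNMAPPED"
        rows.append(
            {
                "read_id": read_id,
                "is_l1": True,
                "category": cls.category.value,
                "orientation": orientation.value,
                "has_utr5": utr,
                "yy1_intact": yy1,
                "flank_class": flank_class,
                "read_length": len(seq),
            }
        )
    per_read = pd.DataFrame(rows)
    variants, unsupported = call_variants(classifications, min_support=min_support)
    annotate_savs(variants, model)
    summary = summarize_sample(per_read, sample_id=sample_id)
    logger.info(
        "analyzed %d reads: %d L1-containing, %d variants (%d unsupported groups)",
        len(reads),
        n_l1,
        len(variants),
        len(unsupported),
    )
    return PipelineResult(
        per_read=per_read,
        classifications=classifications,
        hits_by_read=hits_by_read,
        variants=variants,
        unsupported=unsupported,
        summary=summary,
        model=model,
    )


def category_percentages(result: PipelineResult) -> dict[str, float]:
    """Percentage of L1 reads per coding category."""
    l1 = result.per_read[result.per_read["is_l1"]]
    n = len(l1)
    out = {}
    for cat, count in result.summary.category_counts.items():
        out[cat] = 100.0 * count / n if n else float("nan")
    return out


def feature_percentages(result: PipelineResult) -> dict[str, float]:
    return dict(result.summary.feature_pcts)


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write deterministic TSV outputs for a pipeline run."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.per_read.to_csv(outdir / "per_read.tsv", sep="\t", index=False)
    # per-read classification detail
    rows = []
    for cls in result.classifications:
        rows.append(
            {
                "read_id": cls.read_id,
                "sample_id": cls.sample_id,
                "category": cls.category.value,
                "orientation": cls.orientation.value,
                "orf1_protein": cls.orf1_protein or "",
                "orf2_protein": cls.orf2_protein or "",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    from .variants import variant_table

    variant_table(result.variants).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    with open(outdir / "variant_proteins.fasta", "w") as fh:
        for v in result.variants:
            for target, protein in sorted(v.proteins.items()):
                fh.write(f">{v.variant_id}_{target} category={v.category.value} support={v.support}\n")
                fh.write(protein + "\n")
    savs_rows = [
        {"variant_id": v.variant_id, "position": s.position, "consensus_aa": s.consensus_aa, "variant_aa": s.variant_aa}
        for v in result.variants
        for s in v.savs
    ]
    pd.DataFrame(savs_rows, columns=["variant_id", "position", "consensus_aa", "variant_aa"]).to_csv(
        outdir / "savs.tsv", sep="\t", index=False
    )
    result.summary.to_frame().to_csv(outdir / "summary_categories.tsv", sep="\t", index=False)
    pd.DataFrame([result.summary.feature_pcts]).to_csv(outdir / "summary_features.tsv", sep="\t", index=False)
    result.summary.length_hist.to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)
    # hits as BED (read id as the "chromosome") plus consensus coordinates
    with open(outdir / "hits.bed", "w") as fh:
        for read_id in sorted(result.hits_by_read):
            for h in result.hits_by_read[read_id]:
                fh.write(
                    f"{read_id}\t{h.read_interval[0]}\t{h.read_interval[1]}\t"
                    f"cons:{h.consensus_interval[0]}-{h.consensus_interval[1]}\t{h.score}\t{h.strand}\n"
                )
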