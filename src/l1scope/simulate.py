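"""Synthetic FLNC read libraries with ground-truth labels.

The generator emulates the structure of a long-read L1 transcriptome
library: a mixture of six coding categories (bicistronic ORF1+ORF2,
ORF1+ORF2P, monocistronic ORF1/ORF2/ORF2P, and noncoding fragments),
5'-truncations and early stop codons, sense-strand bias, 5'-UTR and
YY1-motif content, and read-through flanking sequence copied from a toy
genome (intragenic or intergenic) or absent/unmappable.

Category counts and feature marginals are apportioned deterministically
(largest remainder), so observed fractions equal profile fractions
exactly at corpus sizes where fraction x n is integral; a ``stochastic``
switch enables multinomial draws instead.  Every read carries exactly one
ground-truth record, and noncoding fragments are post-validated with a
brute-force six-frame ORF scan that is independent of the main
classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import CODONS_FOR_AA, random_dna, revcomp, translate
from .classify import ClassifyThresholds, CodingCategory, DEFAULT_THRESHOLDS
from .consensus import ConsensusModel, YY1_MOTIF

CATEGORY_ORDER = [
    CodingCategory.ORF1_ONLY,
    CodingCategory.ORF2_ONLY,
    CodingCategory.ORF2P_ONLY,
    CodingCategory.ORF1_ORF2P,
    CodingCategory.ORF1_ORF2,
    CodingCategory.NONCODING,
]

# Categories whose construction removes the 5' end of the element, so they
# can never carry a 5'-UTR (and hence never an intact YY1 site).
_NO_UTR_CATEGORIES = {CodingCategory.ORF2_ONLY, CodingCategory.ORF2P_ONLY}

FLANK_INTRAGENIC = "INTRAGENIC"
FLANK_INTERGENIC = "INTERGENIC"
FLANK_NONE_OR_UNMAPPED = "NONE_OR_UNMAPPED"
FLANK_NONE = "NONE"
FLANK_UNMAPPED = "UNMAPPED"


class ConfigurationError(ValueError):
    """Raised for unsatisfiable profile/feature combinations."""


@dataclass(frozen=True)
class LengthModel:
    """Read-length distribution; lognormal parameterised by its mean.

    The default mean of 3,541 bp matches full-length L1 transcript
    libraries; sigma 0.23 puts roughly 0.8% of reads at or above 6 kb.
    """

    mean_bp: float = 3541.0
    sigma: float = 0.23
    family: str = "lognormal"

    def draw(self, n: int, seed_or_rng: int | np.random.Generator) -> np.ndarray:
        rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
        if self.family != "lognormal":
            raise ConfigurationError(f"unknown length model family {self.family!r}")
        mu = math.log(self.mean_bp) - self.sigma**2 / 2.0
        return rng.lognormal(mean=mu, sigma=self.sigma, size=n)


@dataclass(frozen=True)
class CompositionProfile:
    """Marginal composition of a library, in percent of L1 reads."""

    category_fractions: dict[CodingCategory, float]
    sense_pct: float
    utr5_pct: float
    yy1_pct: float
    flank_pcts: dict[str, float]
    length_model: LengthModel = field(default_factory=LengthModel)

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 100.0) > 1e-9:
            raise ConfigurationError(f"category fractions must sum to 100, got {total}")
        if self.yy1_pct > self.utr5_pct:
            raise ConfigurationError("yy1_pct cannot exceed utr5_pct (YY1 lies inside the 5'-UTR)")
        ftotal = sum(self.flank_pcts.values())
        if abs(ftotal - 100.0) > 1e-9:
            raise ConfigurationError(f"flank fractions must sum to 100, got {ftotal}")


def paper_means_profile() -> CompositionProfile:
    """The packaged library composition (per-sample means, percent)."""
    fractions = {
        CodingCategory.ORF1_ONLY: 5.77,
        CodingCategory.ORF2_ONLY: 0.017,
        CodingCategory.ORF2P_ONLY: 0.221,
        CodingCategory.ORF1_ORF2P: 0.078,
        CodingCategory.ORF1_ORF2: 0.006,
    }
    fractions[CodingCategory.NONCODING] = 100.0 - sum(fractions.values())
    return CompositionProfile(
        category_fractions=fractions,
        sense_pct=74.55,
        utr5_pct=45.28,
        yy1_pct=19.38,
        flank_pcts={
            FLANK_INTRAGENIC: 43.3,
            FLANK_INTERGENIC: 4.9,
            FLANK_NONE_OR_UNMAPPED: 51.8,
        },
    )


def allocate_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items over percent fractions."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    keys = list(fractions)
    exact = {k: fractions[k] * n / 100.0 for k in keys}
    counts = {k: int(math.floor(exact[k])) for k in keys}
    leftover = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), -fractions[k], keys.index(k)))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def _distribute(quota: int, weights: dict, caps: dict | None = None) -> dict:
    """Largest-remainder split of a quota proportional to weights, with caps."""
    keys = list(weights)
    total_w = sum(weights.values())
    caps = caps or {k: weights[k] for k in keys}
    if quota > sum(caps.values()):
        raise ConfigurationError("feature quota exceeds eligible reads (unsatisfiable profile)")
    if total_w == 0:
        if quota:
            raise ConfigurationError("cannot distribute a quota over zero-weight strata")
        return {k: 0 for k in keys}
    exact = {k: quota * weights[k] / total_w for k in keys}
    out = {k: min(int(math.floor(exact[k])), caps[k]) for k in keys}
    order = sorted(keys, key=lambda k: (-(exact[k] - out[k]), keys.index(k)))
    i = 0
    while sum(out.values()) < quota:
        k = order[i % len(keys)]
        if out[k] < caps[k]:
            out[k] += 1
        i += 1
        if i > 10 * len(keys) + quota:
            raise ConfigurationError("could not satisfy feature quota under caps")
    return out


@dataclass(frozen=True)
class GeneAnnotation:
    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"


@dataclass(frozen=True)
class ToyGenome:
    chroms: dict[str, str]
    genes: list[GeneAnnotation]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate gene IDs in toy genome")
        for g in self.genes:
            if g.chrom not in self.chroms or not (0 <= g.start < g.end <= len(self.chroms[g.chrom])):
                raise ConfigurationError(f"gene {g.gene_id} outside chromosome bounds")

    def intergenic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        spans = sorted((g.start, g.end) for g in self.genes if g.chrom == chrom)
        out, prev = [], 0
        for s, e in spans:
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < len(self.chroms[chrom]):
            out.append((prev, len(self.chroms[chrom])))
        return out

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chroms.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tl1scope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def load_toy_genome(fasta_path: str | Path, annotation_path: str | Path) -> ToyGenome:
    """Reload a toy genome from FASTA plus GFF3 or 6-column BED."""
    from Bio import SeqIO

    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes: list[GeneAnnotation] = []
    path = Path(annotation_path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
        for feat in db.features_of_type("gene"):
            genes.append(
                GeneAnnotation(feat.seqid, feat.start - 1, feat.end, feat.id, feat.strand or "+")
            )
    else:
        table = pd.read_csv(path, sep="\t", header=None, comment="#")
        for row in table.itertuples(index=False):
            genes.append(GeneAnnotation(str(row[0]), int(row[1]), int(row[2]), str(row[3]), str(row[5])))
    if not genes:
        raise ValueError(f"annotation {annotation_path} contains no gene features")
    return ToyGenome(chroms=chroms, genes=genes)


def build_toy_genome(
    n_genes: int = 4,
    gene_len: int = 3000,
    intergenic_len: int = 2000,
    seed: int = 1,
    chrom: str = "chr1",
) -> ToyGenome:
    """Random single-chromosome genome with non-overlapping annotated genes.

    The sequence is scrubbed of chance YY1-motif occurrences so motif
    intactness stays a pure property of the L1-derived part of a read.
    """
    rng = np.random.default_rng(seed)
    parts = [random_dna(intergenic_len, rng)]
    genes = []
    pos = intergenic_len
    for i in range(n_genes):
        parts.append(random_dna(gene_len, rng))
        genes.append(GeneAnnotation(chrom, pos, pos + gene_len, f"gene{i + 1}"))
        pos += gene_len
        parts.append(random_dna(intergenic_len, rng))
        pos += intergenic_len
    seq = "".join(parts)
    seq = _scrub_motif(seq, rng)
    return ToyGenome(chroms={chrom: seq}, genes=genes)


def _scrub_motif(seq: str, rng: np.random.Generator) -> str:
    """Mutate chance occurrences of the YY1 motif (either strand) away."""
    for motif in (YY1_MOTIF, revcomp(YY1_MOTIF)):
        while (idx := seq.find(motif)) != -1:
            mid = idx + len(motif) // 2
            alt = "ACGT"[(("ACGT".index(seq[mid]) + 1 + int(rng.integers(0, 3))) % 4)]
            seq = seq[:mid] + alt + seq[mid + 1 :]
    return seq


@dataclass
class SimulatedLibrary:
    reads: list[tuple[str, str]]
    truth: pd.DataFrame
    manifest: dict

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f">{read_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_fastq(self, path: str | Path, quality: int = 30) -> None:
        qch = chr(quality + 33)
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qch * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _shuffled_flags(n: int, n_true: int, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[:n_true] = True
    rng.shuffle(flags)
    return flags


def _fragment_is_noncoding(
    frag: str,
    model: ConsensusModel,
    min_protein_len: int,
    thresholds: ClassifyThresholds,
    margin: float = 0.02,
) -> bool:
    """Brute-force six-frame ORF scan used to post-validate noncoding reads.

    Independent of the main classifier: enumerates maximal ATG-initiated
    ORFs in all six frames by direct translation and checks exact-substring
    containment in the consensus proteins against the intactness rules.
    """
    p1, p2 = model.orf1_protein, model.orf2_protein
    en, rt = model.en_domain, model.rt_domain
    for strand_seq in (frag, revcomp(frag)):
        for f in range(3):
            prot = translate(strand_seq[f:])
            for seg in prot.split("*"):
                m = seg.find("M")
                if m >= 0:
                    p = seg[m:]
                    if len(p) >= min_protein_len:
                        if p1.find(p) >= 0 and len(p) / len(p1) >= thresholds.intact_cov - margin:
                            return False
                        pos = p2.find(p)
                        if pos >= 0:
                            span = (pos, pos + len(p))
                            if len(p) / len(p2) >= thresholds.intact_cov - margin:
                                return False
                            rt_cov = _overlap(span, rt) / (rt[1] - rt[0])
                            en_cov = _overlap(span, en) / (en[1] - en[0])
                            if rt_cov >= thresholds.domain_cov - margin and en_cov >= thresholds.domain_cov - margin:
                                return False
    return True


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(b[0], a[0]))


class _ReadBuilder:
    """Builds one read per ground-truth record against a consensus model."""

    def __init__(
        self,
        model: ConsensusModel,
        genome: ToyGenome | None,
        rng: np.random.Generator,
        thresholds: ClassifyThresholds,
        flank_len: int,
        polya_len: int,
        min_utr_overlap: int,
    ):
        self.m = model
        self.genome = genome
        self.rng = rng
        self.thresholds = thresholds
        self.flank_len = flank_len
        self.polya_len = polya_len
        self.min_utr_overlap = min_utr_overlap
        self.min_protein_len = thresholds.effective_min_protein_len(model)
        u0, u1 = model.utr5
        ys, ye = model.yy1_position
        if u1 - ye < min_utr_overlap + 5:
            raise ConfigurationError(
                "5'-UTR too short downstream of the YY1 motif to realise "
                "UTR-without-YY1 reads at the configured overlap threshold"
            )

    def _start_for_flags(self, has_utr: bool, yy1: bool) -> int:
        u0, u1 = self.m.utr5
        ys, ye = self.m.yy1_position
        if yy1:
            return int(self.rng.integers(u0, ys + 1))
        if has_utr:
            return int(self.rng.integers(ye, u1 - self.min_utr_overlap + 1))
        return self.m.orf1_nt[0]

    def _truncated_start(self) -> int:
        o1s, o1e = self.m.orf1_nt
        length = o1e - o1s
        lo = o1s + max(3, math.ceil(0.10 * length))
        hi = o1s + int(0.50 * length)
        return int(self.rng.integers(lo, hi + 1))

    def _full_end(self) -> int:
        stop_end = self.m.orf2_nt[1] + 3
        return int(self.rng.integers(stop_end, len(self.m.nt_seq) + 1))

    def _orf2p_end(self) -> tuple[int, int]:
        """(read end, aa cut point) for a 3'-truncated ORF2 retaining RT."""
        o2s, _ = self.m.orf2_nt
        n_aa = len(self.m.orf2_protein)
        lo = self.m.rt_domain[1] + 2
        hi = int(0.92 * n_aa)
        cut = int(self.rng.integers(lo, hi + 1))
        return o2s + 3 * cut, cut

    def build(self, category: CodingCategory, has_utr: bool, yy1: bool) -> tuple[str, int, int, list]:
        """Return (fragment, cons_start, cons_end, mutations)."""
        m = self.m
        nt = m.nt_seq
        mutations: list[tuple[int, str, str]] = []
        if category in (CodingCategory.ORF1_ORF2, CodingCategory.ORF1_ONLY):
            start, end = self._start_for_flags(has_utr, yy1), self._full_end()
            frag = nt[start:end]
            if category is CodingCategory.ORF1_ONLY:
                # early stop codon at the RT-domain midpoint destroys ORF2
                # without truncating the transcript
                rt_mid = (m.rt_domain[0] + m.rt_domain[1]) // 2
                codon_start = m.orf2_nt[0] + 3 * rt_mid
                rel = codon_start - start
                ref = frag[rel : rel + 3]
                frag = frag[:rel] + "TAA" + frag[rel + 3 :]
                for i, (r, a) in enumerate(zip(ref, "TAA")):
                    if r != a:
                        mutations.append((codon_start + i, r, a))
        elif category is CodingCategory.ORF1_ORF2P:
            start = self._start_for_flags(has_utr, yy1)
            end, _ = self._orf2p_end()
            frag = nt[start:end]
        elif category is CodingCategory.ORF2_ONLY:
            start, end = self._truncated_start(), self._full_end()
            frag = nt[start:end]
        elif category is CodingCategory.ORF2P_ONLY:
            start = self._truncated_start()
            end, _ = self._orf2p_end()
            frag = nt[start:end]
        elif category is CodingCategory.NONCODING:
            start, end, frag = self._noncoding_fragment(has_utr, yy1)
        else:  # pragma: no cover - exhaustive over CodingCategory
            raise ConfigurationError(f"unknown category {category}")
        return frag, start, end, mutations

    def _noncoding_fragment(self, has_utr: bool, yy1: bool) -> tuple[int, int, str]:
        m = self.m
        o1s, o1e = m.orf1_nt
        o2s, o2e = m.orf2_nt
        l1 = o1e - o1s
        l2 = o2e - o2s
        for _ in range(200):
            if has_utr:
                start = self._start_for_flags(has_utr, yy1)
                end = int(self.rng.integers(o1s + int(0.30 * l1), o1s + int(0.60 * l1) + 1))
            else:
                start = int(self.rng.integers(o2s + int(0.25 * l2), o2s + int(0.35 * l2) + 1))
                lo = start + 150
                hi = o2s + int(0.70 * l2)
                if lo > hi:
                    raise ConfigurationError("consensus too short for noncoding fragments >= 150 bp")
                end = int(self.rng.integers(lo, hi + 1))
            frag = m.nt_seq[start:end]
            if _fragment_is_noncoding(frag, m, self.min_protein_len, self.thresholds):
                return start, end, frag
        raise ConfigurationError("could not draw a validated noncoding fragment (exhausted redraws)")

    def flank(self, flank_class: str) -> str:
        if flank_class == FLANK_NONE:
            return ""
        if self.genome is None:
            raise ConfigurationError("flank classes other than NONE require a toy genome")
        rng = self.rng
        if flank_class == FLANK_INTRAGENIC:
            gene = self.genome.genes[int(rng.integers(0, len(self.genome.genes)))]
            lo, hi = gene.start + 10, gene.end - 10 - self.flank_len
            if hi < lo:
                raise ConfigurationError("genes too short to host intragenic flanks")
            off = int(rng.integers(lo, hi + 1))
            return self.genome.chroms[gene.chrom][off : off + self.flank_len]
        if flank_class == FLANK_INTERGENIC:
            chrom = next(iter(self.genome.chroms))
            blocks = [
                (s, e)
                for s, e in self.genome.intergenic_intervals(chrom)
                if e - s >= self.flank_len + 20
            ]
            if not blocks:
                raise ConfigurationError("no intergenic block long enough for flanks")
            s, e = blocks[int(rng.integers(0, len(blocks)))]
            off = int(rng.integers(s + 10, e - 10 - self.flank_len + 1))
            return self.genome.chroms[chrom][off : off + self.flank_len]
        if flank_class == FLANK_UNMAPPED:
            genome_seqs = list(self.genome.chroms.values()) if self.genome else []
            for _ in range(100):
                cand = random_dna(self.flank_len, rng)
                if YY1_MOTIF in cand or revcomp(YY1_MOTIF) in cand:
                    continue
                # verified absent from the genome by exact search, both strands
                if any(cand in g or revcomp(cand) in g for g in genome_seqs):
                    continue
                if cand in self.m.nt_seq or revcomp(cand) in self.m.nt_seq:
                    continue
                return cand
            raise ConfigurationError("could not draw an unmappable flank")
        raise ConfigurationError(f"unknown flank class {flank_class!r}")


def simulate_library(
    consensus: ConsensusModel,
    genome: ToyGenome | None,
    profile: CompositionProfile | None = None,
    n: int = 1000,
    seed: int = 1,
    error_rate: float = 0.0,
    stochastic: bool = False,
    flank_len: int = 200,
    polya_len: int = 30,
    min_utr_overlap: int = 50,
    orf2_savs: list[tuple[int, str]] | None = None,
    sample_id: str = "S1",
    thresholds: ClassifyThresholds = DEFAULT_THRESHOLDS,
) -> SimulatedLibrary:
    """Generate a labelled FLNC library against a consensus model.

    ``orf2_savs`` optionally plants single-amino-acid variants (0-based
    position on the consensus ORF2 protein, alternate residue) into every
    read whose fragment covers the mutated codon, for parameter-recovery
    experiments.  ``error_rate`` is a per-base substitution probability
    (HiFi regime; at most 0.01).
    """
    profile = profile or paper_means_profile()
    if not 0.0 <= error_rate <= 0.01:
        raise ConfigurationError("error_rate must lie in [0, 0.01] (HiFi regime)")
    rng = np.random.default_rng(seed)
    if stochastic:
        draws = rng.multinomial(n, [profile.category_fractions[c] / 100.0 for c in CATEGORY_ORDER])
        counts = dict(zip(CATEGORY_ORDER, (int(x) for x in draws)))
    else:
        counts = allocate_counts({c: profile.category_fractions[c] for c in CATEGORY_ORDER}, n)

    utr_quota = allocate_counts({"utr": profile.utr5_pct, "rest": 100 - profile.utr5_pct}, n)["utr"]
    yy1_quota = allocate_counts({"yy1": profile.yy1_pct, "rest": 100 - profile.yy1_pct}, n)["yy1"]
    sense_quota = allocate_counts({"s": profile.sense_pct, "rest": 100 - profile.sense_pct}, n)["s"]
    flank_quotas = allocate_counts(profile.flank_pcts, n)

    utr_weights = {c: (0 if c in _NO_UTR_CATEGORIES else counts[c]) for c in CATEGORY_ORDER}
    utr_per_cat = _distribute(utr_quota, utr_weights)
    yy1_per_cat = _distribute(yy1_quota, utr_weights, caps=utr_per_cat)
    sense_per_cat = _distribute(sense_quota, counts)
    intra_per_cat = _distribute(flank_quotas.get(FLANK_INTRAGENIC, 0), counts)
    inter_per_cat = _distribute(
        flank_quotas.get(FLANK_INTERGENIC, 0),
        counts,
        caps={c: counts[c] - intra_per_cat[c] for c in CATEGORY_ORDER},
    )

    builder = _ReadBuilder(consensus, genome, rng, thresholds, flank_len, polya_len, min_utr_overlap)
    reads: list[tuple[str, str]] = []
    records: list[dict] = []
    idx = 0
    realized = {"utr5": 0, "yy1": 0, "sense": 0, FLANK_INTRAGENIC: 0, FLANK_INTERGENIC: 0}
    for category in CATEGORY_ORDER:
        m_cat = counts[category]
        if m_cat == 0:
            continue
        pair_codes = np.zeros(m_cat, dtype=np.int8)  # 0 none, 1 utr only, 2 utr+yy1
        pair_codes[: yy1_per_cat[category]] = 2
        pair_codes[yy1_per_cat[category] : utr_per_cat[category]] = 1
        rng.shuffle(pair_codes)
        sense_flags = _shuffled_flags(m_cat, sense_per_cat[category], rng)
        flank_labels = np.array(
            [FLANK_INTRAGENIC] * intra_per_cat[category]
            + [FLANK_INTERGENIC] * inter_per_cat[category]
            + [
                FLANK_NONE if j % 2 == 0 else FLANK_UNMAPPED
                for j in range(m_cat - intra_per_cat[category] - inter_per_cat[category])
            ],
            dtype=object,
        )
        rng.shuffle(flank_labels)
        for i in range(m_cat):
            has_utr = pair_codes[i] >= 1
            yy1 = pair_codes[i] == 2
            sense = bool(sense_flags[i])
            flank_class = str(flank_labels[i])
            frag, cons_start, cons_end, mutations = builder.build(category, has_utr, yy1)
            savs_applied: list[tuple[int, str]] = []
            orf2_bearing = category in (
                CodingCategory.ORF2_ONLY,
                CodingCategory.ORF2P_ONLY,
                CodingCategory.ORF1_ORF2P,
                CodingCategory.ORF1_ORF2,
            )
            if orf2_savs and orf2_bearing:
                frag, savs_applied = _apply_orf2_savs(frag, cons_start, cons_end, consensus, orf2_savs)
            flank_seq = builder.flank(flank_class)
            core = flank_seq + frag
            read_seq = core + "A" * polya_len if sense else revcomp(core)
            n_err = 0
            if error_rate > 0:
                read_seq, n_err = _apply_errors(read_seq, error_rate, rng)
            read_id = f"r{idx:06d}"
            idx += 1
            reads.append((read_id, read_seq))
            realized["utr5"] += has_utr
            realized["yy1"] += yy1
            realized["sense"] += sense
            if flank_class in (FLANK_INTRAGENIC, FLANK_INTERGENIC):
                realized[flank_class] += 1
            records.append(
                {
                    "read_id": read_id,
                    "sample_id": sample_id,
                    "true_category": category.value,
                    "sense": sense,
                    "has_utr5": bool(has_utr),
                    "yy1_intact": bool(yy1),
                    "flank_class": flank_class,
                    "cons_start": cons_start,
                    "cons_end": cons_end,
                    "introduced_mutations": ";".join(f"{p}:{r}>{a}" for p, r, a in mutations),
                    "orf2_savs": ";".join(f"{p}{a}" for p, a in savs_applied),
                    "n_seq_errors": n_err,
                    "read_length": len(read_seq),
                }
            )
    truth = pd.DataFrame.from_records(records)
    manifest = {
        "n": n,
        "seed": seed,
        "error_rate": error_rate,
        "stochastic": stochastic,
        "consensus": consensus.name,
        "category_counts": {c.value: counts[c] for c in CATEGORY_ORDER},
        "realized_marginals_pct": {
            "sense": float(100.0 * realized["sense"] / n),
            "utr5": float(100.0 * realized["utr5"] / n),
            "yy1": float(100.0 * realized["yy1"] / n),
            FLANK_INTRAGENIC: float(100.0 * realized[FLANK_INTRAGENIC] / n),
            FLANK_INTERGENIC: float(100.0 * realized[FLANK_INTERGENIC] / n),
        },
        "flank_len": flank_len,
        "polya_len": polya_len,
    }
    return SimulatedLibrary(reads=reads, truth=truth, manifest=manifest)


def _apply_orf2_savs(
    frag: str,
    cons_start: int,
    cons_end: int,
    model: ConsensusModel,
    savs: list[tuple[int, str]],
) -> tuple[str, list[tuple[int, str]]]:
    o2s = model.orf2_nt[0]
    applied = []
    for aa_pos, alt_aa in savs:
        codon_start = o2s + 3 * aa_pos
        if codon_start < cons_start or codon_start + 3 > cons_end:
            continue
        if model.orf2_protein[aa_pos] == alt_aa:
            continue
        rel = codon_start - cons_start
        frag = frag[:rel] + CODONS_FOR_AA[alt_aa][0] + frag[rel + 3 :]
        applied.append((aa_pos, alt_aa))
    return frag, applied


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    n_err = int(rng.binomial(len(seq), rate))
    if n_err == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alts[int(rng.integers(0, 3))]
    return "".join(out), n_err
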