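"""The L1 consensus reference frame.

A :class:`ConsensusModel` fixes the coordinate system every other module
works in: the consensus nucleotide sequence (sense strand) with its
5'-UTR, ORF1 and ORF2 coding intervals, the consensus ORF1/ORF2 proteins,
the endonuclease (EN) / reverse-transcriptase (RT) / C-terminal domain
intervals on the ORF2 protein, and the YY1-binding motif inside the
5'-UTR.  Coordinates are 0-based half-open; ORF intervals cover the
coding sequence *excluding* the terminal stop codon, so that in-frame
translation of an ORF interval reproduces the stored protein exactly.

Real consensus sequences are supplied by the user as FASTA plus a YAML
coordinate config; scaled toy models with the same structural layout are
generated in-package for testing and simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode_protein, random_dna, random_protein, translate

YY1_MOTIF = "CAAGATGGCCG"

Interval = tuple[int, int]


class ConsensusError(ValueError):
    """Raised when a consensus model violates its structural invariants."""


@dataclass(frozen=True)
class ConsensusModel:
    """L1 consensus sequence with structural annotation.

    ``utr5 < orf1_nt < orf2_nt`` on the nucleotide sequence;
    ``en_domain < rt_domain < cterm_domain`` on the ORF2 protein.
    """

    name: str
    nt_seq: str
    utr5: Interval
    orf1_nt: Interval
    orf2_nt: Interval
    orf1_protein: str
    orf2_protein: str
    en_domain: Interval
    rt_domain: Interval
    cterm_domain: Interval
    yy1_motif: str = YY1_MOTIF
    yy1_position: Interval = (0, 0)
    polyA_contact_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.nt_seq)
        for label, (s, e) in (
            ("utr5", self.utr5),
            ("orf1_nt", self.orf1_nt),
            ("orf2_nt", self.orf2_nt),
        ):
            if not (0 <= s < e <= n):
                raise ConsensusError(f"{label} interval {(s, e)} out of range [0, {n})")
        if not (self.utr5[1] <= self.orf1_nt[0] and self.orf1_nt[1] <= self.orf2_nt[0]):
            raise ConsensusError("expected ordering utr5 < orf1_nt < orf2_nt")
        ys, ye = self.yy1_position
        if not (self.utr5[0] <= ys < ye <= self.utr5[1]):
            raise ConsensusError("yy1_position must lie within the 5'-UTR")
        if self.nt_seq[ys:ye] != self.yy1_motif:
            raise ConsensusError("nt_seq does not carry the YY1 motif at yy1_position")
        for orf_iv, protein, label in (
            (self.orf1_nt, self.orf1_protein, "ORF1"),
            (self.orf2_nt, self.orf2_protein, "ORF2"),
        ):
            s, e = orf_iv
            if (e - s) % 3 != 0:
                raise ConsensusError(f"{label} interval length not a multiple of 3")
            got = translate(self.nt_seq[s:e])
            if got != protein:
                raise ConsensusError(
                    f"{label} translation mismatch: interval translates to "
                    f"{got[:10]}... but stored protein starts {protein[:10]}..."
                )
            if "*" in protein:
                raise ConsensusError(f"{label} protein contains an internal stop")
        lp = len(self.orf2_protein)
        doms = (self.en_domain, self.rt_domain, self.cterm_domain)
        for label, (s, e) in zip(("en", "rt", "cterm"), doms):
            if not (0 <= s < e <= lp):
                raise ConsensusError(f"{label}_domain out of range on ORF2 protein")
        if not (doms[0][1] <= doms[1][0] and doms[1][1] <= doms[2][0]):
            raise ConsensusError("expected ordering en < rt < cterm on ORF2 protein")
        for pos in self.polyA_contact_positions:
            if not 0 <= pos < lp:
                raise ConsensusError(f"polyA contact position {pos} outside ORF2 protein")


# Full-scale structural layout (bp / aa) the toy builder scales down.
_FULL_UTR5_BP = 900
_FULL_ORF1_AA = 338
_FULL_SPACER_BP = 63
_FULL_ORF2_AA = 1275
_FULL_TAIL_BP = 150
_YY1_OFFSET = 12

# Default ORF2 domain boundaries as fractions of protein length.  These are
# placeholders for toy models and must be configured for real consensi.
DEFAULT_DOMAIN_FRACTIONS = {"en_end": 0.20, "rt_start": 0.39, "rt_end": 0.61, "cterm_len": 0.25}


def _scaled_layout(scale: float) -> dict[str, int]:
    if not 0 < scale <= 1:
        raise ConsensusError(f"scale must be in (0, 1], got {scale}")
    layout = {
        "utr5_bp": round(_FULL_UTR5_BP * scale),
        "orf1_aa": round(_FULL_ORF1_AA * scale),
        "spacer_bp": max(9, round(_FULL_SPACER_BP * scale)),
        "orf2_aa": round(_FULL_ORF2_AA * scale),
        "tail_bp": max(9, round(_FULL_TAIL_BP * scale)),
    }
    if layout["utr5_bp"] < _YY1_OFFSET + len(YY1_MOTIF) + 60:
        raise ConsensusError(
            f"scale {scale} leaves the 5'-UTR too short to host the YY1 motif "
            "with usable margins"
        )
    if layout["orf1_aa"] < 10 or layout["orf2_aa"] < 30:
        raise ConsensusError(f"scale {scale} leaves an ORF too short to be structured")
    return layout


def _domain_intervals(orf2_aa: int, fractions: dict[str, float]) -> tuple[Interval, Interval, Interval]:
    en = (0, round(fractions["en_end"] * orf2_aa))
    rt = (round(fractions["rt_start"] * orf2_aa), round(fractions["rt_end"] * orf2_aa))
    ct = (orf2_aa - round(fractions["cterm_len"] * orf2_aa), orf2_aa)
    return en, rt, ct


def build_toy_consensus(
    scale: float = 1.0,
    seed: int = 1,
    domain_fractions: dict[str, float] | None = None,
) -> ConsensusModel:
    """Build a random toy L1 consensus with the full structural layout.

    The model carries a 5'-UTR with the YY1 motif verbatim (exactly once in
    the whole sequence), ORF1, an inter-ORF spacer, ORF2 with EN/RT/C-term
    domain intervals, and a 3' tail.  Deterministic for fixed (scale, seed).
    """
    layout = _scaled_layout(scale)
    fractions = dict(DEFAULT_DOMAIN_FRACTIONS, **(domain_fractions or {}))
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        utr = random_dna(layout["utr5_bp"], rng)
        utr = utr[:_YY1_OFFSET] + YY1_MOTIF + utr[_YY1_OFFSET + len(YY1_MOTIF) :]
        orf1_protein = "M" + random_protein(layout["orf1_aa"] - 1, rng)
        orf2_protein = "M" + random_protein(layout["orf2_aa"] - 1, rng)
        orf1_cds = "ATG" + encode_protein(orf1_protein[1:], rng)
        orf2_cds = "ATG" + encode_protein(orf2_protein[1:], rng)
        spacer = random_dna(layout["spacer_bp"], rng)
        tail = random_dna(layout["tail_bp"], rng)
        nt = utr + orf1_cds + "TAA" + spacer + orf2_cds + "TAA" + tail
        if nt.count(YY1_MOTIF) != 1:
            continue  # re-draw: motif must occur exactly once
        u_end = len(utr)
        o1 = (u_end, u_end + len(orf1_cds))
        o2s = o1[1] + 3 + len(spacer)
        o2 = (o2s, o2s + len(orf2_cds))
        en, rt, ct = _domain_intervals(len(orf2_protein), fractions)
        return ConsensusModel(
            name=f"L1toy_s{scale:g}_seed{seed}",
            nt_seq=nt,
            utr5=(0, u_end),
            orf1_nt=o1,
            orf2_nt=o2,
            orf1_protein=orf1_protein,
            orf2_protein=orf2_protein,
            en_domain=en,
            rt_domain=rt,
            cterm_domain=ct,
            yy1_position=(_YY1_OFFSET, _YY1_OFFSET + len(YY1_MOTIF)),
        )
    raise ConsensusError("could not place the YY1 motif uniquely (exhausted redraws)")


def write_consensus(model: ConsensusModel, fasta_path: str | Path, config_path: str | Path) -> None:
    """Write a model as FASTA + YAML coordinate config (round-trips)."""
    rec = SeqRecord(Seq(model.nt_seq), id=model.name, description="L1 consensus")
    SeqIO.write([rec], str(fasta_path), "fasta")
    cfg = {
        "name": model.name,
        "utr5": list(model.utr5),
        "orf1_nt": list(model.orf1_nt),
        "orf2_nt": list(model.orf2_nt),
        "orf1_protein": model.orf1_protein,
        "orf2_protein": model.orf2_protein,
        "en_domain": list(model.en_domain),
        "rt_domain": list(model.rt_domain),
        "cterm_domain": list(model.cterm_domain),
        "yy1_motif": model.yy1_motif,
        "yy1_position": list(model.yy1_position),
        "polyA_contact_positions": sorted(model.polyA_contact_positions),
    }
    Path(config_path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_consensus(fasta_path: str | Path, config_path: str | Path) -> ConsensusModel:
    """Load and validate a consensus model from FASTA + YAML config.

    The config must supply all coordinates.  Proteins are optional: when
    present they are checked against the in-frame translation of the
    corresponding nucleotide interval, when absent they are derived from it.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ConsensusError(f"consensus FASTA must contain exactly one sequence, found {len(records)}")
    nt_seq = str(records[0].seq).upper()
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise ConsensusError("consensus config must be a mapping")

    def iv(key: str) -> Interval:
        try:
            s, e = cfg[key]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConsensusError(f"config key {key!r} missing or not a 2-element interval") from exc
        return int(s), int(e)

    orf1_iv, orf2_iv = iv("orf1_nt"), iv("orf2_nt")
    derived1 = translate(nt_seq[orf1_iv[0] : orf1_iv[1]])
    derived2 = translate(nt_seq[orf2_iv[0] : orf2_iv[1]])
    orf1_protein = cfg.get("orf1_protein", derived1)
    orf2_protein = cfg.get("orf2_protein", derived2)
    if orf1_protein != derived1 or orf2_protein != derived2:
        raise ConsensusError("supplied protein does not match translation of its nucleotide interval")
    return ConsensusModel(
        name=str(cfg.get("name", records[0].id)),
        nt_seq=nt_seq,
        utr5=iv("utr5"),
        orf1_nt=orf1_iv,
        orf2_nt=orf2_iv,
        orf1_protein=orf1_protein,
        orf2_protein=orf2_protein,
        en_domain=iv("en_domain"),
        rt_domain=iv("rt_domain"),
        cterm_domain=iv("cterm_domain"),
        yy1_motif=str(cfg.get("yy1_motif", YY1_MOTIF)),
        yy1_position=iv("yy1_position"),
        polyA_contact_positions=frozenset(int(p) for p in cfg.get("polyA_contact_positions", []) or []),
    )


def with_domains(model: ConsensusModel, en: Interval, rt: Interval, cterm: Interval) -> ConsensusModel:
    """Return a copy of the model with user-specified ORF2 domain intervals."""
    return replace(model, en_domain=en, rt_domain=rt, cterm_domain=cterm)
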