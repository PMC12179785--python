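# Methods

`l1scope` classifies LINE-1 (L1) derived transcripts in long-read
full-length non-concatemeric (FLNC) libraries and quantifies the
companion assay readouts.  This note documents the models, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## The consensus reference frame

All analysis is anchored to a `ConsensusModel`: the L1 sense-strand
nucleotide consensus with 0-based half-open coordinates for the 5′-UTR,
the ORF1 and ORF2 coding intervals (excluding the terminal stop codon,
so in-frame translation of an interval reproduces the stored protein
exactly), the consensus ORF1/ORF2 proteins, the endonuclease (EN) /
reverse-transcriptase (RT) / C-terminal domain intervals in ORF2
protein coordinates, and the 11-mer YY1-binding motif `CAAGATGGCCG`
inside the 5′-UTR.

Real consensus sequences and their coordinates are user-supplied
(FASTA + YAML); the package does not redistribute one.  For testing,
`build_toy_consensus(scale, seed)` generates a random model with the
full structural layout scaled from ~6 kb: 900 bp UTR (motif at offset
12, guaranteed to occur exactly once in the whole sequence), 338-aa
ORF1, 63 bp spacer, 1,275-aa ORF2, 150 bp tail.  ORF2 domain boundaries
default to EN = first 20%, RT = 39–61%, C-terminus = last 25% of the
protein; these are placeholders on toy models and are configurable —
real analyses must supply residue ranges.

## Detection: seed–chain–extend

Reads are matched to both consensus strands by exact 15-mer seeding,
grouped into constant-diagonal runs, and chained when the read-side and
consensus-side gaps are both below `max_gap` (default 5,000 bp),
admitting the large internal deletions characteristic of truncated or
spliced L1 transcripts.  Chain ends are extended by ungapped x-drop
extension (x-drop 12).  Scoring is match/mismatch/gap-open/gap-extend =
2/−4/−4/−2; identity is matches over alignment columns.  Gaps of 30 bp
or more are treated as structural deletions: they are excluded from the
identity denominator and not penalised, the convention splice-aware
long-read aligners use, so that a transcript missing an internal
consensus block is still one high-identity hit.  Hits need
`min_segment_len` ≥ 100 bp and identity ≥ 0.80; a read with at least
one hit is "L1-containing".  These thresholds admit HiFi-quality L1
fragments while rejecting random sequence (a random 500-mer has
essentially zero probability of a qualifying segment; the test suite
proves this per-seed against a full Smith–Waterman oracle).

Subfamily annotation runs the same aligner against a repeat library but
with `max_gap` = 50 and identity ≥ 0.90: attribution should be locally
best, not splice-tolerant, or a chain through one subfamily would
swallow segments better explained by another.  Candidate hits compete
greedily by score with a 50% overlap exclusion, so chimeric reads carry
multiple annotations and corpus summaries report a mean
annotations-per-read plus per-subfamily percentages that may total more
than 100%.

Masking replaces detected L1 intervals (merged per strand) with `N`;
maximal unmasked runs of at least `min_flank_len` = 100 bp are flank
segments.

## ORF classification

Each L1-containing read is sense-oriented by majority aligned bp of its
hit strands (ties → sense).  ORFs are maximal ATG-to-stop runs in the
three forward frames of the oriented read, keeping ORFs that reach the
read end without a stop (truncated transcripts); a `--six-frame` switch
adds the reverse frames.  `min_protein_len` defaults to
min(100, half the shorter consensus protein) so scaled-down toy models
remain classifiable with the same code path.

Predicted proteins are aligned to the consensus ORF1 and ORF2 proteins
by local Smith–Waterman under BLOSUM62 with affine gaps (open 11,
extend 1 — BLASTp conventions).  Coverage is the aligned span on the
target over target length; identity is matches over aligned columns.
Flags:

* `orf1_intact` / `orf2_intact`: some ORF aligns with coverage ≥ 0.95
  and identity ≥ 0.80;
* `orf2_partial`: not intact, but some ORF covers ≥ 0.95 of the RT
  domain at identity ≥ 0.80 — and, when the read has no intact ORF1,
  also ≥ 0.95 of the EN domain.  The conditional EN requirement mirrors
  the two field definitions of a partial ORF2 (RT-retaining for
  bicistronic ORF1+ORF2P; EN+RT-bearing for monocistronic ORF2P); a
  flag forces the uniform RT-only definition.

The flags map totally and single-valuedly onto six categories:
ORF1_ORF2, ORF1_ORF2P, ORF2_ONLY, ORF2P_ONLY, ORF1_ONLY, NONCODING.
The coverage/identity cut-offs are package decisions (no published
values exist for this step); raising `intact_cov` is monotone — it can
only demote reads toward partial/noncoding.

## Read features

* 5′-UTR presence: union of consensus-alignment intervals overlaps the
  UTR by ≥ 50 bp (closed threshold).
* YY1 intactness: exact substring match of the motif on the
  sense-oriented read only.
* Flank class: each flank segment is mapped to the genome with the same
  seed-chain-extend aligner (both strands, `max_gap` 50); a flank maps
  confidently at ≥ 90% coverage and ≥ 0.90 identity ("mapped
  confidently" is not defined anywhere authoritative; 0.90 is a
  decision).  INTRAGENIC requires the mapped interval to lie *fully
  within* a gene span — containment, not overlap; partial overlap is
  INTERGENIC.  UNMAPPED = flanks exist but none maps; NONE = no flank
  ≥ 100 bp.  Summaries also merge UNMAPPED+NONE into one bucket, the
  convention used when reporting "no flanking/unmappable" fractions.

Features are reported as observed; nothing enforces YY1 ⊆ UTR at
measurement time (the generator enforces it in the ground truth).

## Variants and SAVs

Coding reads are grouped per corpus (samples pooled, membership
recorded) by exact key — the predicted protein(s) by default, since
HiFi reads are accurate enough that no clustering tolerance is needed;
codon-level nucleotide keying is a flag.  Groups with ≥ 3 supporting
reads become variants; smaller groups are reported as unsupported, and
supported plus unsupported reads always partition the coding reads.
Whether variants should be called per-sample instead of pooled is an
open convention; pooled is the default here because sample-sharing
statistics (the private-variant fraction) need cross-sample identity of
keys anyway.

SAVs come from a global alignment of the variant protein to the
consensus protein with free end gaps (so truncated variants align to a
prefix without penalty): substitution columns are SAVs (consensus
position, consensus residue, variant residue); gap columns are reported
as truncation/indel spans, never as SAVs.  For gap-free optima the SAV
count equals the Hamming distance.  Residue conservation at configured
positions (e.g. poly(A)-contact residues, which default to the empty
set because no published enumeration exists) counts a variant as
conserving when its aligned residue equals the consensus; variants not
covering the position count as non-conserving and are tallied as
absent.

## Assay arithmetic

* Standard curve: Cq = slope·log10(pU) + intercept by least squares,
  replicate wells averaged on the Cq scale per pU level first (the
  alternative — averaging after back-transformation — is a convention
  choice; Cq-scale averaging matches how replicate wells are normally
  summarised).  pU extrapolation inverts the curve; Cq ≥ 40 cycles is
  below detection.  Delta-Cq is negative-control Cq minus sample Cq.
* H-score: cells binned 0–4 by four ascending intensity thresholds
  (bin 0 anchored at the negative-control ceiling when using the
  default quantile edges); score = Σ bin × percent, range 0–400,
  invariant under monotone rescaling that preserves bin membership.
  Numeric edges are mandatory explicit configuration for real analyses.
* MFI ratios are per-cell numerator/denominator with zero-denominator
  cells excluded and counted; fold change divides each cell's
  signal/area by the control population's median signal/area, so the
  control median is 1 by construction.

## The synthetic-data generator

The generator encodes a library's composition as ground truth and is
the package's validation instrument.  Its defaults are the study
conditions: category fractions ORF1_ONLY 5.77%, ORF2_ONLY 0.017%,
ORF2P_ONLY 0.221%, ORF1_ORF2P 0.078%, ORF1_ORF2 0.006%, NONCODING the
remainder (93.908%); sense 74.55%; 5′-UTR 45.28%; YY1 19.38%; flanks
intragenic 43.3%, intergenic 4.9%, none-or-unmapped 51.8%; read-length
model lognormal with mean 3,541 bp and σ = 0.23 (σ chosen so that
roughly 0.8% of draws are ≥ 6 kb, matching the sparse long tail of such
libraries).  Since printed figures are per-sample means, the generator
models one sample per run and treats the means as that sample's
composition.

Counts are apportioned by largest remainder (deterministic), so at
n = 100,000 every category count is exact; `--stochastic` switches to
multinomial draws.  Feature quotas are distributed across categories
proportionally to category size, except that 5′-truncated categories
(ORF2_ONLY, ORF2P_ONLY) are ineligible for UTR/YY1, whose quota is
reallocated to eligible reads (realized marginals are written to the
manifest; they equal the profile at n = 100,000 because eligible reads
vastly outnumber the quotas).  Within a category, feature flags are
assigned by seeded shuffles so features are uncorrelated with each
other given the category.

Construction rules per category (consensus coordinates, seeded jitter):

* ORF1_ORF2: spans from the UTR/ORF1 start through the ORF2 stop.
* ORF1_ONLY: same span with the codon at the RT-domain midpoint
  replaced by TAA — an early stop inside ORF2 that leaves neither the
  upstream nor the downstream ORF fragment with ≥ 95% RT coverage, so
  the transcript is monocistronic by mutation rather than truncation.
* ORF2_ONLY: 5′-truncated 10–50% into ORF1 (destroying it; any
  internal-Met suffix ORF has ≤ 90% ORF1 coverage), full ORF2.
* ORF2P_ONLY / ORF1_ORF2P: ORF2 3′-truncated at an amino acid drawn
  from (RT end + 2, 92% of ORF2), retaining EN+RT intact while keeping
  total ORF2 coverage below the 95% intactness threshold.
* NONCODING: UTR-carrying fragments end 30–60% into ORF1; others are
  internal ORF2 fragments (25–70% of ORF2, ≥ 150 bp).  Every noncoding
  fragment is post-validated by an independent brute-force six-frame
  ORF scan (direct translation + exact-substring containment against
  the consensus proteins with a 2% safety margin on the thresholds) and
  redrawn if any ORF could pass the intactness rules.  The validator
  deliberately shares no code with the classifier's
  ORF-finder/aligner path.

Flanks (200 bp) are copied verbatim from inside a toy-genome gene
(INTRAGENIC, with margins so containment holds), from outside all genes
(INTERGENIC), or are random sequence verified absent from the genome by
exact search (UNMAPPED); NONE attaches nothing.  The NONE/UNMAPPED
split alternates deterministically inside the merged bucket.  The toy
genome and all random flanks are scrubbed of chance YY1-motif
occurrences so motif intactness stays a pure property of the L1 part of
a read.  Sense reads get a 30 nt poly(A) tail (a fixed length standing
in for oligo-dT-selected cDNA; the exact length is arbitrary);
antisense reads are reverse-complemented in full.

The error model is substitution-only at a configurable per-base rate
capped at 0.01 (HiFi regime; indels are rare enough in HiFi data that
simulating them is out of scope).  Planted ORF2 SAVs
(`orf2_savs=[(position, residue), ...]`) support parameter-recovery
tests.

What the generator does **not** emulate: chimeras/concatemers (FLNC
input is defined to exclude them), indel errors, transcript-level
expression structure beyond the marginal composition, subfamily
mosaicism, methylation, and genome-scale repeat context (the toy genome
is random and L1-free).  Passing round-trip tests therefore
demonstrates that the pipeline's measurement logic inverts the
generative rules exactly — not that it is robust to every artefact of
real libraries.

## Problem sizes and determinism

All analysis stages are deterministic; randomness is confined to the
generator and controlled by integer seeds (numpy `default_rng`).  The
validation corpus used by the acceptance machinery is 100,000 toy-scale
(0.25) reads — large enough that every profile fraction times n is an
integer, so recovery can be asserted exactly — plus 10,000 length-model
draws and a 100-cell synthetic H-score population.  Unit and property
tests use 400–5,000-read libraries.

## Known limitations

* Exact-match variant keying cannot merge reads split by residual
  sequencing errors; at elevated error rates variant counts inflate.
* The brute-force noncoding validator checks exact-substring
  containment, which is sufficient for the generator's pre-error,
  consensus-derived fragments but is not a general ORF-intactness
  decision procedure.
* Flank classification takes the single best-scoring placement;
  multi-mapping flanks in repetitive genomes would need a mapping-
  quality notion the toy genome does not exercise.
* H-score bin edges and ORF2 domain boundaries must be supplied for
  real data; the defaults exist to make toy-scale analyses and tests
  self-contained.
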