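# Methods

## Screen model

The pipeline models a one-round survival screen over a codon-window
saturation library. A motif of L residues (the packaged preset: Rad54
T101–L144, L = 44) is tiled left-to-right into non-overlapping windows of
up to three codons; when L is not divisible by three the final window
carries the remainder (44 → 14 windows of 3 codons + 1 of 2). Each window
library randomizes its 9 (or 6/3) bases to NNN, so all 64 codons —
including the three stops — are sampled per codon position. The designed
single-variant space counts all 20 amino acids at every position
(20 × L = 880 for the Rad54 motif); this includes synonymous wild-type
re-encodings, matching the 20-per-position accounting, with the
19-per-position alternative exposed via `include_wildtype_aa=False`.

Residue coordinates follow the host protein's own numbering, 1-based and
inclusive at both ends (T101..L144 is 44 residues); all internal offsets are
0-based half-open and converted only at the API boundary.

## Read filtering and counting

A read is accepted when it contains, in either orientation, the 20-bp
constant sequence immediately upstream and downstream of a window with
exactly the window length between them (`match_flanks`). Matching is exact
by default — the strictest reading of a "remove all reads lacking the
flanks" filter — with an optional mismatch allowance. The per-window 20-bp
contexts are derived from the wild-type reference: interior windows are
flanked by neighboring wild-type codons, edge windows extend into the
constant amplicon flanks. Windows containing an ambiguous base are rejected
(`ambiguous_base`), not imputed; base qualities are ignored by default
(an optional mean-quality gate exists but is off). Paired mates are searched
independently and contribute one count per pair; disagreeing mates are
dropped as `mate_conflict`. Rejection bookkeeping is exact:
`reads_seen = matched + Σ rejected`, and counting is order-independent.

## Scoring

Counts are aggregated to the amino-acid level per window (synonymous DNA
variants summed) before any frequency is formed. Frequencies are
pseudocounted, `(c + p) / (N + p·K)` with p = 0.5 over the window's K
observed classes, so fold-enrichments are defined for zero counts; p is
configurable and recorded in the matrix metadata. Frequencies are computed
per window by default (each window is its own amplicon library); a
whole-library mode exists because either normalization is defensible — the
wild-type normalization cancels the difference for scores.

The landscape keeps only wild-type and single-substitution observations.
Each variant's fold-enrichment is divided by the window's wild-type
fold-enrichment and log10-transformed; wild-type cells are exactly 0 by
construction, and renormalization is idempotent. Stop- and multi-mutant
classes are scored only in the control summary (stop depletion is the
negative control; per-window wild-type enrichment the positive control).
Variants with input count below `min_input_count` (default 10) are flagged
`omitted_low_input` and left unscored — the operationalization of omitting
alleles underrepresented in the initial pool; a window with no wild-type
observations cannot be normalized and is flagged `missing`. The heat map
uses the three fixed anchors: green at 0 (wild-type-like), white at −0.7
(~5-fold depleted), red at −2 (100-fold depleted).

## Conservation

Column profiles exclude gaps (and non-standard letters) from the 20-way
amino-acid distribution and report the gap fraction separately; information
content is log2 20 − H in bits. The per-residue conservation statistic
plotted by default is the reference-residue frequency — the fraction of
homologs retaining the reference amino acid — with information content as
an alternative; the choice is recorded in the output. The track is smoothed
with a centered 5-residue moving average; edges use the available shorter
window. Note this edge rule re-weights the outermost values, so the
smoothed track's mean is preserved only away from the edges — the interior
behavior is what the tests pin down. Sequence weighting is available but
off by default (redundancy reduction is assumed done upstream of the
alignment).

For the natural-vs-screen logo comparison, screen scores are clipped to
[−2, 0] (the heat map's own floor) and mapped affinely to [0, 1], giving
non-negative letter weights with wild-type at 1; agreement is summarized as
a per-position Spearman correlation between the 20-letter weight vectors.

## Interface geometry

Polar contacts: donor and acceptor typing comes from fixed per-residue
templates (backbone N/O plus side-chain N/O/S; proline's backbone N is not
a donor); residues without a template fall back to element typing with a
warning. Because the models carry no hydrogens, the angular criterion is
evaluated at the donor heavy atom, between its bonded antecedent and the
acceptor, accepted at 110–180° with distance < 4 Å — an approximation of
hydrogen-placement tools that is exact in the anti-periplanar limit.
Hydrophobic contacts are apolar-carbon pairs (template-listed carbons not
bonded to N/O) within 4.5 Å, a conventional cutoff. Atom-level records are
kept and also deduplicated to residue-pair tables.

SASA is Shrake–Rupley with probe 1.4 Å and a deterministic golden-spiral
point set of 960 points per atom over a pinned Bondi-style radius table, so
values are bit-for-bit reproducible. BSA is SASA(A) + SASA(B) − SASA(A∪B);
it is symmetric and exactly translation-invariant. Under rotation the fixed
point set changes the quadrature by O(1/points) — the tests bound this at
2% — and the single-sphere and two-sphere cases are verified against closed
forms. Protomer 5′/3′-facing labels project protomer centroids onto the
axis from the first to the last bound-DNA residue (residue order taken as
strand polarity), which makes the labels rigid-motion-invariant and makes
reversing the stated polarity swap them.

## Synthetic screens

The generator emulates the screen's construction: per read, a window drawn
from the mixing weights (equal by default) and 4^n uniform window bases;
one multinomial selection round with probability ∝ count × fitness (growth
amplification is absorbed into w); amplicon records of
20-bp flank + window + 20-bp flank; substitution-only sequencing errors at
ε = 10⁻³ per base (no indels, matching the gap-free window model); fixed
quality strings. Defaults: 100,000 reads per pool, one selection round.

Fitness scenario ("default"): stops w = 0; every substitution at the
planted critical residues w = 0.01 (for the Rad54 motif: the FxxP
phenylalanine F131 and the key leucine L127; for motifs without an FxxP,
the first residue); all other singles draw w from lognormal(0, 0.8²) —
a near-neutral mode with a realistic minority of partially deleterious
variants, as DMS landscapes of functional elements typically show; multis
combine multiplicatively (no epistasis). Wild-type is exactly 1. These
values are simulation parameters chosen once for realism, not measured
quantities.

What the generator does *not* model: PCR jackpots and amplification bias,
indels, quality-correlated errors, bottleneck drift beyond the single
multinomial stage, and epistasis. Passing recovery tests therefore show the
*estimator* is correct under the stated sampling model, not that real
screens are free of these artifacts.

## Sizing of the recovery benchmark

The end-to-end recovery check (simulate → FASTQ → count → score →
rank-correlate against planted fitness) runs on a single 3-codon window at
100,000 reads per pool. A count-level power analysis fixed this size before
the benchmark was frozen: under uniform NNN sampling only ~1.5% of a
window's reads are single-codon substitutions at the amino-acid level, so
at 10⁵ reads per pool a single window yields ~30–60 input reads per scored
single (comfortably above the QC gate, Spearman ρ ≈ 0.97 against truth),
whereas spreading the same depth over 2+ windows pushes per-variant
coverage toward the QC threshold and recovery below 0.9. Screens over the
full 44-codon motif remain fully supported — they simply need
proportionally deeper sequencing for per-variant scores, exactly as the
real experiment did.

## Numerical and degenerate-input conventions

Translation uses the standard genetic code with `*` for stops; ambiguous
bases raise rather than translate. Classification precedence is stop >
wild-type > single > multi, which partitions all 21^k translated window
outcomes. Zero-read samples are an error at scoring time; empty FASTQ files
count zero reads without error. All randomness flows from a single
`numpy.random.Generator` seeded by the caller; FASTQ output is
byte-identical for a fixed seed.

## Known limitations

- The flank filter is substitution-tolerant only via `max_mismatch`;
  indel-containing reads are unrecoverable by design.
- The polar-contact angle convention underestimates donors whose hydrogen
  points far from the antecedent-opposite direction; with explicit-hydrogen
  models a dedicated H-based criterion would be preferable.
- Logo rendering is left to the caller (matrices are returned/serialized);
  only the landscape heat map is drawn directly.
- The conservation statistic of published motif plots is not uniquely
  defined; both options here are reasonable but neither is guaranteed to
  match any specific figure's y-axis.
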