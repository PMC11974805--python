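"""Motif and library definitions for saturation mutagenesis of short peptides.

A mutagenized motif is a contiguous stretch of residues inside a protein,
addressed in the protein's own residue numbering (1-based, inclusive).  The
library randomizes the motif one *window* at a time: each window covers up to
three consecutive codons whose nine (or six/three) bases are synthesized as
NNN, i.e. every base an equal mixture of A/C/G/T, so every codon — including
stops — is sampled.

Internally all offsets are 0-based half-open; protein numbering is applied
only at the boundary (``Window.first_residue`` arithmetic, ``VariantKey``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_DNA = re.compile(r"^[ACGT]+$")


class AmbiguousBaseError(ValueError):
    """A sequence contains a base outside {A, C, G, T} (e.g. N)."""


def span_length(first_residue: int, last_residue: int) -> int:
    """Number of residues in an inclusive residue-number span.

    Protein coordinates are 1-based and inclusive at both ends, so the span
    T101..L144 contains ``144 - 101 + 1 = 44`` residues.
    """
    if last_residue < first_residue:
        raise ValueError(f"empty span {first_residue}..{last_residue}")
    return last_residue - first_residue + 1


def translate_window(dna: str) -> str:
    """Translate a 3/6/9-nt window under the standard genetic code.

    Stop codons are rendered as ``*``.  Any base outside {A,C,G,T} raises
    :class:`AmbiguousBaseError`: ambiguous reads are rejected upstream, never
    translated.
    """
    dna = dna.upper()
    if len(dna) == 0 or len(dna) % 3:
        raise ValueError(f"window length {len(dna)} is not a positive multiple of 3")
    if not _DNA.match(dna):
        raise AmbiguousBaseError(f"ambiguous base in window {dna!r}")
    return str(Seq(dna).translate())


@dataclass(frozen=True)
class Window:
    """One randomized stretch of the motif (1-3 consecutive codons)."""

    index: int
    codon_start: int  # 0-based codon offset within the motif
    n_codons: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_codons <= 3:
            raise ValueError(f"window spans {self.n_codons} codons, expected 1-3")
        if self.codon_start < 0:
            raise ValueError("negative codon_start")

    @property
    def nt_length(self) -> int:
        return 3 * self.n_codons

    @property
    def codon_end(self) -> int:
        return self.codon_start + self.n_codons


def tile_windows(motif_length_codons: int, window_codons: int = 3) -> list[Window]:
    """Tile a motif with non-overlapping windows, left to right.

    The final window carries the remainder (1 or 2 codons) when the motif
    length is not a multiple of ``window_codons``.
    """
    if window_codons < 1:
        raise ValueError("window_codons must be >= 1")
    if window_codons > 3:
        raise ValueError("windows span at most 3 codons")
    if motif_length_codons < 1:
        raise ValueError("motif must contain at least one codon")
    windows = []
    for i, start in enumerate(range(0, motif_length_codons, window_codons)):
        n = min(window_codons, motif_length_codons - start)
        windows.append(Window(index=i, codon_start=start, n_codons=n))
    return windows


@dataclass(frozen=True)
class VariantKey:
    """Amino-acid-level identity of one library member.

    ``kind`` is one of ``wildtype`` / ``single`` / ``multi`` / ``stop``;
    ``position`` (protein numbering) and ``amino_acid`` are present iff the
    variant is a single substitution.
    """

    kind: str
    position: int | None = None
    amino_acid: str | None = None

    _KINDS = ("wildtype", "single", "multi", "stop")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "single":
            if self.position is None or self.amino_acid not in AMINO_ACIDS:
                raise ValueError("single variants need a position and a standard amino acid")
        elif self.position is not None or self.amino_acid is not None:
            raise ValueError(f"{self.kind} variants carry no position/amino acid")

    def __str__(self) -> str:
        if self.kind == "single":
            return f"{self.position}{self.amino_acid}"
        return self.kind


WILDTYPE = VariantKey("wildtype")
MULTI = VariantKey("multi")
STOP_VARIANT = VariantKey("stop")


@dataclass(frozen=True)
class MotifSpec:
    """The mutagenized region: numbering, sequences, windows, flanks.

    ``dna_reference`` is the wild-type coding sequence of the motif;
    ``upstream_flank``/``downstream_flank`` are the constant sequences
    immediately bordering the motif in the amplicon (>= 20 nt each, so every
    window is bounded by at least 20 nt of constant context on both sides).
    """

    protein_name: str
    first_residue: int
    aa_sequence: str
    dna_reference: str
    upstream_flank: str
    downstream_flank: str
    windows: tuple[Window, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError("empty motif")
        if any(a not in AMINO_ACIDS for a in self.aa_sequence):
            raise ValueError("motif sequence contains a non-standard residue")
        for name in ("dna_reference", "upstream_flank", "downstream_flank"):
            seq = getattr(self, name)
            if not _DNA.match(seq or ""):
                raise ValueError(f"{name} is not plain A/C/G/T DNA")
        if len(self.dna_reference) != 3 * len(self.aa_sequence):
            raise ValueError("dna_reference length must be 3 x motif length")
        if translate_window(self.dna_reference) != self.aa_sequence:
            raise ValueError("dna_reference does not translate to aa_sequence")
        if min(len(self.upstream_flank), len(self.downstream_flank)) < 20:
            raise ValueError("flanks must be at least 20 nt")
        if not self.windows:
            object.__setattr__(self, "windows", tuple(tile_windows(len(self.aa_sequence))))
        self._check_tiling()

    def _check_tiling(self) -> None:
        covered = []
        for w in self.windows:
            covered.extend(range(w.codon_start, w.codon_end))
        if sorted(covered) != list(range(len(self.aa_sequence))) or len(covered) != len(
            set(covered)
        ):
            raise ValueError("windows must tile the motif exactly, without overlap")

    # -- coordinate helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.aa_sequence)

    @property
    def last_residue(self) -> int:
        return self.first_residue + len(self.aa_sequence) - 1

    def window_first_residue(self, window: Window) -> int:
        return self.first_residue + window.codon_start

    def window_aa(self, window: Window) -> str:
        return self.aa_sequence[window.codon_start : window.codon_end]

    def window_dna(self, window: Window) -> str:
        return self.dna_reference[3 * window.codon_start : 3 * window.codon_end]

    def window_flanks(self, window: Window, flank_length: int = 20) -> tuple[str, str]:
        """Constant 20-nt context bordering one window in the amplicon.

        For interior windows the context is wild-type motif sequence; at the
        motif edges it extends into the constant amplicon flanks.
        """
        full = self.upstream_flank + self.dna_reference + self.downstream_flank
        start = len(self.upstream_flank) + 3 * window.codon_start
        end = start + window.nt_length
        up = full[start - flank_length : start]
        down = full[end : end + flank_length]
        if len(up) < flank_length or len(down) < flank_length:
            raise ValueError("amplicon flanks too short for the requested context")
        return up, down

    def positions(self) -> range:
        return range(self.first_residue, self.last_residue + 1)


def enumerate_variant_space(
    spec: MotifSpec, include_wildtype_aa: bool = True
) -> set[tuple[int, str]]:
    """All (residue position, amino acid) pairs reachable by NNN randomization.

    NNN sampling reaches all 20 amino acids at every position (stop codons are
    excluded from the variant space), hence 20 x motif-length pairs.  The
    44-residue Rad54 motif gives the screen's 880-member library.  With
    ``include_wildtype_aa=False`` the wild-type residue is dropped at each
    position (19 x length), the alternative accounting some screens report.
    """
    pairs = set()
    for offset, wt_aa in enumerate(spec.aa_sequence):
        for aa in AMINO_ACIDS:
            if not include_wildtype_aa and aa == wt_aa:
                continue
            pairs.add((spec.first_residue + offset, aa))
    return pairs


def classify_window(observed_aa: str, wildtype_aa: str, window: Window, spec: MotifSpec) -> VariantKey:
    """Assign one translated window observation to its variant class.

    Precedence: any stop -> ``stop``; no differences -> ``wildtype``; exactly
    one difference -> ``single`` at the absolute residue number; two or more
    -> ``multi``.  The four classes are exhaustive and mutually exclusive.
    """
    if len(observed_aa) != len(wildtype_aa):
        raise ValueError(
            f"length mismatch: observed {len(observed_aa)} vs wild-type {len(wildtype_aa)}"
        )
    if STOP in observed_aa:
        return STOP_VARIANT
    diffs = [i for i, (a, b) in enumerate(zip(observed_aa, wildtype_aa)) if a != b]
    if not diffs:
        return WILDTYPE
    if len(diffs) == 1:
        offset = diffs[0]
        return VariantKey(
            "single",
            position=spec.window_first_residue(window) + offset,
            amino_acid=observed_aa[offset],
        )
    return MULTI


def window_amino_acid_space(n_codons: int) -> Iterator[str]:
    """Every translated outcome of an NNN window (21^k strings incl. '*')."""
    letters = AMINO_ACIDS + STOP
    for combo in product(letters, repeat=n_codons):
        yield "".join(combo)


def find_sequence_motif(
    aa_sequence: str, pattern: str = "F..P", first_residue: int = 1
) -> list[tuple[int, str]]:
    """Scan a peptide for a sequence pattern (regex, '.' = any residue).

    Returns ``(residue number of the first matched position, matched text)``
    for every (possibly overlapping) occurrence; used e.g. to locate the FxxP
    recombinase-docking motif, whose phenylalanine sits at Rad54 residue 131.
    """
    hits = []
    rx = re.compile(pattern)
    pos = 0
    while True:
        m = rx.search(aa_sequence, pos)
        if m is None:
            return hits
        hits.append((first_residue + m.start(), m.group()))
        pos = m.start() + 1
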