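"""Natural-sequence conservation of a motif from a homolog alignment.

Works on an aligned FASTA (gaps ``-``); columns are mapped back to the
reference protein's residue numbering, summarized as per-column amino-acid
profiles, smoothed into a conservation track (the 5-residue moving average of
the plotted conservation statistic), and compared against a screen landscape
as a pair of sequence-logo matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.stats import spearmanr

from .motif import AMINO_ACIDS
from .enrichment import EnrichmentMatrix

GAP_CHARS = set("-.")
MAX_IC_BITS = float(np.log2(len(AMINO_ACIDS)))


def read_alignment(path_or_msa):
    """Accept an aligned-FASTA path or an already-parsed alignment."""
    if hasattr(path_or_msa, "__iter__") and not isinstance(path_or_msa, (str, bytes)):
        return path_or_msa
    return AlignIO.read(str(path_or_msa), "fasta")


def _sequences(msa) -> list[str]:
    return [str(rec.seq).upper() for rec in msa]


def map_columns_to_reference(msa, reference_id: str, first_residue: int = 1) -> dict[int, int]:
    """Map alignment columns to reference residue numbers.

    Every column where the reference sequence has a residue maps to a unique
    residue number starting at ``first_residue``; columns gapped in the
    reference are unmapped.
    """
    msa = read_alignment(msa)
    ref = None
    for rec in msa:
        if rec.id == reference_id:
            ref = str(rec.seq).upper()
            break
    if ref is None:
        raise KeyError(f"reference {reference_id!r} not found in alignment")
    mapping = {}
    residue = first_residue
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            mapping[col] = residue
            residue += 1
    return mapping


@dataclass
class AlignmentColumnProfile:
    """Amino-acid composition of one alignment column.

    ``frequencies`` is the 20-way distribution over residues (gaps excluded
    and reported separately as ``gap_fraction``); ``information_content`` is
    ``log2(20)`` minus the Shannon entropy of that distribution, in bits, and
    is undefined (NaN) for an all-gap column.
    """

    column: int
    frequencies: pd.Series
    gap_fraction: float
    information_content: float
    residue_number: int | None = None
    reference_aa: str | None = None

    @property
    def reference_aa_frequency(self) -> float:
        if self.reference_aa is None or self.reference_aa not in AMINO_ACIDS:
            return float("nan")
        return float(self.frequencies[self.reference_aa])


def column_profile(msa, column: int, weights=None) -> AlignmentColumnProfile:
    """Profile one column: weighted frequencies, gap fraction and IC."""
    msa = read_alignment(msa)
    seqs = _sequences(msa)
    if not 0 <= column < len(seqs[0]):
        raise IndexError(f"column {column} out of range")
    if weights is None:
        weights = np.ones(len(seqs))
    weights = np.asarray(weights, dtype=float)
    counts = pd.Series(0.0, index=list(AMINO_ACIDS))
    gap_weight = 0.0
    for seq, w in zip(seqs, weights):
        ch = seq[column]
        if ch in AMINO_ACIDS:
            counts[ch] += w
        else:  # gaps and non-standard letters are excluded from the 20-way profile
            gap_weight += w
    total = counts.sum()
    gap_fraction = gap_weight / (gap_weight + total) if (gap_weight + total) else 1.0
    if total == 0:
        freqs = counts  # all zero
        ic = float("nan")
    else:
        freqs = counts / total
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = MAX_IC_BITS - entropy
    return AlignmentColumnProfile(
        column=column,
        frequencies=freqs,
        gap_fraction=float(gap_fraction),
        information_content=ic,
    )


def motif_profiles(
    msa, reference_id: str, first_residue: int = 1, weights=None
) -> list[AlignmentColumnProfile]:
    """Column profiles for every reference-mapped column, in residue order."""
    msa = read_alignment(msa)
    mapping = map_columns_to_reference(msa, reference_id, first_residue)
    ref = next(str(r.seq).upper() for r in msa if r.id == reference_id)
    profiles = []
    for col, residue in sorted(mapping.items(), key=lambda kv: kv[1]):
        prof = column_profile(msa, col, weights)
        prof.residue_number = residue
        prof.reference_aa = ref[col]
        profiles.append(prof)
    return profiles


def conservation_track(values, window: int = 5) -> np.ndarray:
    """Centered moving average of a per-residue conservation statistic.

    At the track edges the average is taken over the residues available in
    the shortened window, so the track has the same length as the input and
    the same mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    series = pd.Series(np.asarray(values, dtype=float))
    return series.rolling(window, center=True, min_periods=1).mean().to_numpy()


def profiles_track(
    profiles: list[AlignmentColumnProfile], statistic: str = "reference_aa_frequency", window: int = 5
) -> pd.DataFrame:
    """Raw and smoothed conservation per residue.

    ``statistic`` is ``reference_aa_frequency`` (how often homologs retain the
    reference residue — the default) or ``information_content``.
    """
    if statistic == "reference_aa_frequency":
        raw = [p.reference_aa_frequency for p in profiles]
    elif statistic == "information_content":
        raw = [p.information_content for p in profiles]
    else:
        raise ValueError(f"unknown conservation statistic {statistic!r}")
    residues = [p.residue_number for p in profiles]
    return pd.DataFrame(
        {"residue": residues, "raw": raw, "smoothed": conservation_track(raw, window)}
    )


def screen_logo_weights(matrix: EnrichmentMatrix, floor: float = -2.0) -> pd.DataFrame:
    """Convert screen scores to non-negative per-position letter weights.

    Scores are clipped to ``[floor, 0]`` and mapped affinely to ``[0, 1]`` so
    wild-type-like variants get weight 1 and variants at or below the floor
    (the heat map's own lower anchor) get 0.  Unscored cells get weight 0.
    """
    if floor >= 0:
        raise ValueError("floor must be negative")
    clipped = matrix.scores.clip(lower=floor, upper=0.0)
    weights = (clipped - floor) / (-floor)
    return weights.fillna(0.0)


def natural_logo_weights(profiles: list[AlignmentColumnProfile]) -> pd.DataFrame:
    """Per-position amino-acid frequency matrix from alignment profiles."""
    index = [p.residue_number for p in profiles]
    return pd.DataFrame(
        [p.frequencies for p in profiles], index=index, columns=list(AMINO_ACIDS)
    )


def compare_landscapes(
    profiles: list[AlignmentColumnProfile],
    matrix: EnrichmentMatrix,
    floor: float = -2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Natural vs screen logos over the shared residue range.

    Returns the two logo matrices restricted to the shared positions and a
    per-position Spearman rank correlation between the 20-letter weight
    vectors (NaN where either vector is constant).
    """
    natural = natural_logo_weights(profiles)
    screen = screen_logo_weights(matrix, floor)
    shared = sorted(set(natural.index) & set(screen.index))
    if not shared:
        raise ValueError("alignment and screen cover disjoint residue ranges")
    natural = natural.loc[shared]
    screen = screen.loc[shared]
    corr = {}
    for pos in shared:
        a = natural.loc[pos].to_numpy()
        b = screen.loc[pos].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            corr[pos] = float("nan")
        else:
            corr[pos] = float(spearmanr(a, b).statistic)
    return natural, screen, pd.Series(corr, name="spearman")
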