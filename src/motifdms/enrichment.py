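"""Selection scoring: from paired counts to a wild-type-normalized landscape.

For every amino-acid sequence observed at a window, a fold-enrichment score is
the ratio of its normalized frequency in the post-selection (survivor) pool to
its frequency in the pre-selection (input) pool.  Each single-substitution
variant's fold-enrichment is then divided by the wild-type allele's
fold-enrichment at the same position and log10-transformed, so wild-type
scores exactly 0, a variant 5-fold depleted relative to wild-type scores
about -0.7 and a 100-fold-depleted variant scores -2 — the three anchors of
the landscape's green/white/red heat-map scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .motif import AMINO_ACIDS, STOP, MotifSpec, Window, classify_window
from .read_processing import CountTable

FLAG_OK = "ok"
FLAG_OMITTED = "omitted_low_input"
FLAG_MISSING = "missing"

HEATMAP_ANCHORS = (0.0, -0.7, -2.0)  # green / white / red


def normalized_frequency(
    count: int, total: int, pseudocount: float = 0.5, n_keys: int = 1
) -> float:
    """Pseudocounted frequency ``(count + p) / (total + p * n_keys)``.

    With the same pseudocount added to each of the sample's ``n_keys``
    observation classes, frequencies stay strictly positive and sum to one
    over the classes.
    """
    if count < 0:
        raise ValueError("negative count")
    if total < 0:
        raise ValueError("negative total")
    denom = total + pseudocount * n_keys
    if denom <= 0:
        raise ValueError("empty sample with zero pseudocount")
    return (count + pseudocount) / denom


def fold_enrichment(freq_selected: float, freq_input: float) -> float:
    """Ratio of post- to pre-selection normalized frequency."""
    if freq_input <= 0 or freq_selected <= 0:
        raise ValueError("frequencies must be positive (use a pseudocount upstream)")
    return freq_selected / freq_input


def depletion_fold(log10_score: float) -> float:
    """Fold-depletion relative to wild-type: ``10 ** (-score)``.

    A score of -0.7 is ~5-fold depleted; -2 is 100-fold depleted.
    """
    return 10.0 ** (-log10_score)


@dataclass
class EnrichmentMatrix:
    """Positions x 20 amino acids of wild-type-normalized log10 scores.

    All component frames share the same index (residue positions in protein
    numbering) and columns (the 20 amino acids).  ``flags`` is ``ok`` where a
    score exists, ``omitted_low_input`` where the variant was seen but too
    shallowly in the input pool, and ``missing`` where it was never observed
    (or the window lacks a wild-type reference).
    """

    scores: pd.DataFrame
    raw_fold_enrichment: pd.DataFrame
    input_counts: pd.DataFrame
    selected_counts: pd.DataFrame
    flags: pd.DataFrame
    wildtype_fold_enrichment: pd.Series  # per position
    spec: MotifSpec
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> list[int]:
        return list(self.scores.index)

    def scored_values(self) -> np.ndarray:
        """All log10 scores of cells flagged ok (wild-type cells included)."""
        mask = self.flags == FLAG_OK
        return self.scores.values[mask.values]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (position, amino acid) cell."""
        rows = []
        for offset, pos in enumerate(self.scores.index):
            wt_aa = self.spec.aa_sequence[offset]
            for aa in AMINO_ACIDS:
                rows.append(
                    {
                        "position": pos,
                        "wildtype_aa": wt_aa,
                        "amino_acid": aa,
                        "input_count": self.input_counts.at[pos, aa],
                        "selected_count": self.selected_counts.at[pos, aa],
                        "fold_enrichment": self.raw_fold_enrichment.at[pos, aa],
                        "log10_score": self.scores.at[pos, aa],
                        "flag": self.flags.at[pos, aa],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def renormalize_to_wildtype(self) -> "EnrichmentMatrix":
        """Subtract each position's wild-type score (idempotent: already 0)."""
        wt_scores = pd.Series(
            [self.scores.at[pos, self.spec.aa_sequence[i]] for i, pos in enumerate(self.scores.index)],
            index=self.scores.index,
        )
        out = EnrichmentMatrix(
            scores=self.scores.sub(wt_scores, axis=0),
            raw_fold_enrichment=self.raw_fold_enrichment,
            input_counts=self.input_counts,
            selected_counts=self.selected_counts,
            flags=self.flags,
            wildtype_fold_enrichment=self.wildtype_fold_enrichment,
            spec=self.spec,
            metadata=dict(self.metadata),
        )
        return out

    def plot_heatmap(self, path=None, ax=None):
        """Green/white/red heat map anchored at scores 0, -0.7 and -2."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap, Normalize

        lo, mid, hi = -2.0, -0.7, 0.0
        cmap = LinearSegmentedColormap.from_list(
            "depletion",
            [(0.0, "#b2182b"), ((mid - lo) / (hi - lo), "#ffffff"), (1.0, "#1a9850")],
        )
        if ax is None:
            fig, ax = plt.subplots(figsize=(0.35 * len(self.positions) + 2, 6))
        else:
            fig = ax.figure
        data = np.clip(self.scores.values.T.astype(float), lo, hi)
        masked = np.ma.masked_invalid(data)
        im = ax.imshow(masked, aspect="auto", cmap=cmap, norm=Normalize(lo, hi))
        ax.set_xticks(range(len(self.positions)))
        ax.set_xticklabels(
            [f"{a}{p}" for a, p in zip(self.spec.aa_sequence, self.positions)],
            rotation=90,
            fontsize=7,
        )
        ax.set_yticks(range(len(AMINO_ACIDS)))
        ax.set_yticklabels(list(AMINO_ACIDS), fontsize=7)
        omitted = (self.flags == FLAG_OMITTED).values.T
        for (j, i) in zip(*np.nonzero(omitted)):
            ax.text(i, j, "x", ha="center", va="center", fontsize=6)
        fig.colorbar(im, ax=ax, label="log10 score (wild-type normalized)")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax


def _window_fold_enrichments(
    counts: CountTable,
    window: Window,
    pseudocount: float,
    totals: Mapping[str, int] | None = None,
) -> tuple[dict[str, float], dict[str, int], dict[str, int]]:
    """Fold-enrichment per translated window sequence for one window.

    ``totals`` overrides the per-window sample totals (whole-library mode).
    """
    aa_in = counts.aa_counts("input", window.index)
    aa_sel = counts.aa_counts("selected", window.index)
    keys = sorted(set(aa_in) | set(aa_sel))
    n_keys = len(keys)
    tot_in = totals["input"] if totals else sum(aa_in.values())
    tot_sel = totals["selected"] if totals else sum(aa_sel.values())
    fe = {}
    for key in keys:
        fi = normalized_frequency(aa_in.get(key, 0), tot_in, pseudocount, n_keys)
        fs = normalized_frequency(aa_sel.get(key, 0), tot_sel, pseudocount, n_keys)
        fe[key] = fold_enrichment(fs, fi)
    return fe, aa_in, aa_sel


def build_landscape(
    counts: CountTable,
    spec: MotifSpec,
    min_input_count: int = 10,
    pseudocount: float = 0.5,
    per_window_frequencies: bool = True,
) -> EnrichmentMatrix:
    """Build the wild-type-normalized single-variant landscape.

    Only wild-type and single-substitution observations contribute; stop- and
    multi-mutant windows are scored separately by :func:`control_summary`.
    Variants with fewer than ``min_input_count`` input-pool observations are
    flagged ``omitted_low_input`` and carry no score (the screen's treatment
    of alleles underrepresented in the initial pool, such as P117M).  A window
    with no wild-type observations in either pool cannot be normalized and its
    rows are flagged ``missing``.
    """
    for condition in ("input", "selected"):
        if counts.total(condition) == 0:
            raise ValueError(f"counts cover no {condition!r} reads")
    positions = list(spec.positions())
    shape = (len(positions), len(AMINO_ACIDS))
    scores = pd.DataFrame(np.full(shape, np.nan), index=positions, columns=list(AMINO_ACIDS))
    raw_fe = scores.copy()
    inp = pd.DataFrame(np.zeros(shape, dtype=int), index=positions, columns=list(AMINO_ACIDS))
    sel = inp.copy()
    flags = pd.DataFrame(FLAG_MISSING, index=positions, columns=list(AMINO_ACIDS))
    wt_fe_per_position = pd.Series(np.nan, index=positions)

    totals = None
    if not per_window_frequencies:
        totals = {c: counts.total(c) for c in ("input", "selected")}

    for window in spec.windows:
        wt_aa = spec.window_aa(window)
        fe, aa_in, aa_sel = _window_fold_enrichments(counts, window, pseudocount, totals)
        wt_seen = aa_in.get(wt_aa, 0) + aa_sel.get(wt_aa, 0) > 0
        if not wt_seen:
            continue  # rows stay flagged missing
        wt_fe = fe[wt_aa]
        window_positions = [spec.window_first_residue(window) + i for i in range(window.n_codons)]
        for pos in window_positions:
            wt_fe_per_position[pos] = wt_fe
        for observed, ratio in fe.items():
            key = classify_window(observed, wt_aa, window, spec)
            if key.kind == "wildtype":
                for i, pos in enumerate(window_positions):
                    aa = wt_aa[i]
                    inp.at[pos, aa] = aa_in.get(observed, 0)
                    sel.at[pos, aa] = aa_sel.get(observed, 0)
                    raw_fe.at[pos, aa] = ratio
                    scores.at[pos, aa] = 0.0
                    flags.at[pos, aa] = FLAG_OK
            elif key.kind == "single":
                pos, aa = key.position, key.amino_acid
                inp.at[pos, aa] = aa_in.get(observed, 0)
                sel.at[pos, aa] = aa_sel.get(observed, 0)
                raw_fe.at[pos, aa] = ratio
                if aa_in.get(observed, 0) < min_input_count:
                    flags.at[pos, aa] = FLAG_OMITTED
                else:
                    scores.at[pos, aa] = math.log10(ratio / wt_fe)
                    flags.at[pos, aa] = FLAG_OK

    return EnrichmentMatrix(
        scores=scores,
        raw_fold_enrichment=raw_fe,
        input_counts=inp,
        selected_counts=sel,
        flags=flags,
        wildtype_fold_enrichment=wt_fe_per_position,
        spec=spec,
        metadata={
            "pseudocount": pseudocount,
            "min_input_count": min_input_count,
            "per_window_frequencies": per_window_frequencies,
        },
    )


def control_summary(
    matrix: EnrichmentMatrix,
    counts: CountTable,
    pseudocount: float | None = None,
    bins: int = 30,
) -> dict:
    """Internal-control report for a scored screen.

    Wild-type alleles act as positive controls (fold-enrichment > 1 expected
    after selection), stop-containing windows as negative controls (aggregate
    fold-enrichment < 1 expected), and the histogram summarizes all scored
    cells.
    """
    spec = matrix.spec
    if pseudocount is None:
        pseudocount = matrix.metadata.get("pseudocount", 0.5)
    wildtype_fe = {}
    stop_in = stop_sel = 0
    tot_in = tot_sel = 0
    for window in spec.windows:
        wt_aa = spec.window_aa(window)
        fe, aa_in, aa_sel = _window_fold_enrichments(counts, window, pseudocount)
        if wt_aa in fe:
            wildtype_fe[window.index] = fe[wt_aa]
        stop_in += sum(n for k, n in aa_in.items() if STOP in k)
        stop_sel += sum(n for k, n in aa_sel.items() if STOP in k)
        tot_in += sum(aa_in.values())
        tot_sel += sum(aa_sel.values())
    stop_fe = fold_enrichment(
        normalized_frequency(stop_sel, tot_sel, pseudocount, 2),
        normalized_frequency(stop_in, tot_in, pseudocount, 2),
    )
    values = matrix.scored_values()
    hist, edges = np.histogram(values, bins=bins) if len(values) else (np.array([]), np.array([]))
    return {
        "wildtype_fold_enrichment": wildtype_fe,
        "wildtype_enriched": {wi: fe > 1.0 for wi, fe in wildtype_fe.items()},
        "stop_fold_enrichment": stop_fe,
        "stop_depleted": stop_fe < 1.0,
        "score_histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        "n_scored": int(len(values)),
    }
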