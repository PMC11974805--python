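"""Simulation-based self-checks of the full pipeline.

These routines generate a synthetic screen with known truth, push it through
the real FASTQ -> counts -> landscape path, and measure how well the pipeline
recovers what was planted.  The recovery benchmark runs on a single 3-codon
window — the screen's elementary unit — so that at 10^5 reads per pool the
per-variant input coverage clears the low-input QC gate (see docs/methods.md
for the sizing rationale).
"""

from __future__ import annotations

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .enrichment import FLAG_OK, build_landscape, control_summary
from .motif import AMINO_ACIDS, MotifSpec
from .presets import toy_motif_spec
from .read_processing import count_windows
from .simulate import (
    DEFAULT_READS_PER_POOL,
    FitnessModel,
    ScreenConfig,
    pool_to_counts,
    run_screen,
    sample_library,
    select_pool,
)


def scored_singles(matrix, truth: pd.DataFrame) -> pd.DataFrame:
    """Scored single-substitution cells joined with their planted fitness."""
    spec = matrix.spec
    rows = []
    truth_idx = truth.set_index(["position", "amino_acid"]).fitness
    for offset, pos in enumerate(matrix.positions):
        wt_aa = spec.aa_sequence[offset]
        for aa in AMINO_ACIDS:
            if aa == wt_aa or matrix.flags.at[pos, aa] != FLAG_OK:
                continue
            rows.append(
                {
                    "position": pos,
                    "amino_acid": aa,
                    "log10_score": float(matrix.scores.at[pos, aa]),
                    "fitness": float(truth_idx[(pos, aa)]),
                }
            )
    return pd.DataFrame(rows)


def end_to_end_recovery(
    seed: int,
    reads_per_pool: int = DEFAULT_READS_PER_POOL,
    spec: MotifSpec | None = None,
    min_input_count: int = 10,
) -> dict:
    """Full-path parameter recovery on one synthetic screen.

    Simulates the default scenario (stops dead, one or two planted deleterious
    residues, near-neutral bulk), writes real FASTQ, counts windows through the
    flank filter, scores the landscape, and reports the Spearman rank
    correlation between planted fitness and estimated log10 scores over the
    scored singles, plus the internal controls.
    """
    if spec is None:
        spec = toy_motif_spec()
    config = ScreenConfig(spec=spec, reads_per_pool=reads_per_pool, seed=seed)
    fitness = FitnessModel.default_scenario(spec, seed=seed)
    with TemporaryDirectory() as tmp:
        out = run_screen(config, fitness, outdir=tmp)
        counts, reports = count_windows(
            {"input": out.input_fastq, "selected": out.selected_fastq}, spec
        )
    matrix = build_landscape(counts, spec, min_input_count=min_input_count)
    controls = control_summary(matrix, counts)
    joined = scored_singles(matrix, out.truth)
    rho = float(
        spearmanr(joined.log10_score, np.log10(joined.fitness.clip(lower=1e-12))).statistic
    )
    deleterious = joined[joined.fitness <= 0.01]
    null_like = joined[joined.fitness > 0.01]
    return {
        "spearman": rho,
        "n_scored_singles": int(len(joined)),
        "matched_fraction": {
            k: r.matched / max(r.reads_seen, 1) for k, r in reports.items()
        },
        "conservation_holds": all(r.is_conserved() for r in reports.values()),
        "stop_fold_enrichment": controls["stop_fold_enrichment"],
        "stop_depleted": controls["stop_depleted"],
        "wildtype_enriched": all(controls["wildtype_enriched"].values()),
        "deleterious_median_score": float(deleterious.log10_score.median())
        if len(deleterious)
        else float("nan"),
        "null_median_score": float(null_like.log10_score.median())
        if len(null_like)
        else float("nan"),
    }


def neutral_control(
    seed: int,
    reads_per_pool: int = DEFAULT_READS_PER_POOL,
    spec: MotifSpec | None = None,
    stop_fitness: float = 0.0,
) -> dict:
    """Neutral screen (all singles w=1): fold-enrichments sit near 1.

    With ``stop_fitness=0`` the stop class is the only selected-against group
    and must come out depleted; scored single-variant fold-enrichments stay
    near 1 (their log10 scores near 0).  Runs at the count level (no
    sequencing error) so the check isolates the scoring stage.
    """
    if spec is None:
        spec = toy_motif_spec()
    config = ScreenConfig(spec=spec, reads_per_pool=reads_per_pool, seed=seed)
    rng = config.rng()
    fitness = FitnessModel.neutral(spec, stop_fitness=stop_fitness)
    pool = sample_library(config, rng)
    selected = select_pool(pool, fitness, config, rng)
    counts = pool_to_counts(pool, "input")
    counts.update(pool_to_counts(selected, "selected"))
    matrix = build_landscape(counts, spec, min_input_count=30)
    controls = control_summary(matrix, counts)
    scores = matrix.scores.values
    finite = scores[np.isfinite(scores)]
    return {
        "max_abs_log10_score": float(np.abs(finite).max()) if finite.size else float("nan"),
        "mean_abs_log10_score": float(np.abs(finite).mean()) if finite.size else float("nan"),
        "n_scored": int(finite.size),
        "stop_fold_enrichment": controls["stop_fold_enrichment"],
        "stop_depleted": controls["stop_depleted"],
    }
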