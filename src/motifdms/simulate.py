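"""Synthetic selection screens with known ground truth.

Emulates one round of a saturation-mutagenesis survival screen: an input pool
in which each read carries one NNN-randomized window of the motif (every base
of the window an equal mix of A/C/G/T, so all codons including stops are
sampled), multinomial survival selection with per-variant relative fitness,
and FASTQ emission with per-base substitution sequencing error.  With the
seed fixed, output is byte-identical across runs.

Default fitness scenario: stop-containing variants are dead (w = 0), single
substitutions at planted critical residues are strongly deleterious
(w = 0.01), and all other singles draw a near-neutral lognormal fitness;
multi-mutant fitness is the product of its constituent single effects.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motif import (
    AMINO_ACIDS,
    STOP,
    MotifSpec,
    Window,
    classify_window,
    find_sequence_motif,
    translate_window,
)
from .read_processing import CountTable

BASES = "ACGT"

# simulation parameters of the default scenario
DELETERIOUS_FITNESS = 0.01
BULK_SIGMA_LN = 0.8
DEFAULT_ERROR_RATE = 1e-3
DEFAULT_READS_PER_POOL = 100_000


@dataclass
class FitnessModel:
    """Relative fitness per variant class (wild-type is exactly 1).

    ``single`` maps (residue position, amino acid) to w; unlisted singles get
    ``default_single``.  Stop-containing windows get ``stop_fitness``.
    Multi-mutants combine their single effects multiplicatively.
    """

    spec: MotifSpec
    single: dict[tuple[int, str], float] = field(default_factory=dict)
    default_single: float = 1.0
    stop_fitness: float = 0.0

    def __post_init__(self) -> None:
        for (pos, aa), w in self.single.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"fitness for {pos}{aa} must be finite and >= 0")

    def single_fitness(self, position: int, amino_acid: str) -> float:
        offset = position - self.spec.first_residue
        if self.spec.aa_sequence[offset] == amino_acid:
            return 1.0  # synonymous wild-type encoding
        return self.single.get((position, amino_acid), self.default_single)

    def window_fitness(self, observed_aa: str, window: Window) -> float:
        """Fitness of one translated window observation."""
        if STOP in observed_aa:
            return self.stop_fitness
        wt_aa = self.spec.window_aa(window)
        first = self.spec.window_first_residue(window)
        w = 1.0
        for i, (obs, wt) in enumerate(zip(observed_aa, wt_aa)):
            if obs != wt:
                w *= self.single_fitness(first + i, obs)
        return w

    def truth_table(self) -> pd.DataFrame:
        """Planted fitness for every single substitution in the variant space."""
        rows = []
        for offset, wt_aa in enumerate(self.spec.aa_sequence):
            pos = self.spec.first_residue + offset
            for aa in AMINO_ACIDS:
                rows.append(
                    {
                        "position": pos,
                        "wildtype_aa": wt_aa,
                        "amino_acid": aa,
                        "fitness": self.single_fitness(pos, aa),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def neutral(cls, spec: MotifSpec, stop_fitness: float = 1.0) -> "FitnessModel":
        """Every variant (optionally including stops) has fitness 1."""
        return cls(spec=spec, default_single=1.0, stop_fitness=stop_fitness)

    @classmethod
    def default_scenario(
        cls,
        spec: MotifSpec,
        seed: int | np.random.Generator = 0,
        deleterious_positions: list[int] | None = None,
        deleterious_fitness: float = DELETERIOUS_FITNESS,
        bulk_sigma_ln: float = BULK_SIGMA_LN,
    ) -> "FitnessModel":
        """Stops dead, planted critical residues deleterious, bulk near-neutral.

        Critical residues default to the FxxP phenylalanine (if the motif has
        one) plus the leucine three residues upstream of it when present — the
        motif's two functionally critical positions; for motifs without an
        FxxP, the first residue is planted instead.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if deleterious_positions is None:
            hits = find_sequence_motif(spec.aa_sequence, "F..P", spec.first_residue)
            if hits:
                f_pos = hits[0][0]
                deleterious_positions = [f_pos]
                l_pos = f_pos - 4
                if (
                    l_pos >= spec.first_residue
                    and spec.aa_sequence[l_pos - spec.first_residue] == "L"
                ):
                    deleterious_positions.insert(0, l_pos)
            else:
                deleterious_positions = [spec.first_residue]
        single: dict[tuple[int, str], float] = {}
        for offset, wt_aa in enumerate(spec.aa_sequence):
            pos = spec.first_residue + offset
            for aa in AMINO_ACIDS:
                if aa == wt_aa:
                    continue
                if pos in deleterious_positions:
                    single[(pos, aa)] = deleterious_fitness
                else:
                    single[(pos, aa)] = float(np.exp(rng.normal(0.0, bulk_sigma_ln)))
        return cls(spec=spec, single=single, stop_fitness=0.0)


@dataclass
class ScreenConfig:
    """Study conditions of one simulated screen."""

    spec: MotifSpec
    reads_per_pool: int = DEFAULT_READS_PER_POOL
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0
    window_weights: np.ndarray | None = None  # default: equal window mixing
    quality_char: str = "I"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


Pool = dict[tuple[int, str], int]  # (window index, window DNA) -> count


def _random_windows(rng: np.random.Generator, n: int, nt_length: int) -> list[str]:
    """n uniform draws over the 4^nt_length window sequences."""
    idx = rng.integers(0, 4, size=(n, nt_length))
    flat = np.array(list(BASES))[idx]
    return ["".join(row) for row in flat]


def sample_library(config: ScreenConfig, rng: np.random.Generator | None = None) -> Pool:
    """Draw the input pool: windows mixed per composition, bases uniform NNN."""
    if rng is None:
        rng = config.rng()
    windows = config.spec.windows
    weights = config.window_weights
    if weights is None:
        weights = np.full(len(windows), 1.0 / len(windows))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    per_window = rng.multinomial(config.reads_per_pool, weights)
    pool: Pool = {}
    for window, n in zip(windows, per_window):
        if n == 0:
            continue
        for dna in _random_windows(rng, int(n), window.nt_length):
            key = (window.index, dna)
            pool[key] = pool.get(key, 0) + 1
    return pool


def select_pool(
    pool: Pool,
    fitness: FitnessModel,
    config: ScreenConfig,
    rng: np.random.Generator | None = None,
    n_survivors: int | None = None,
) -> Pool:
    """One selection round: multinomial resampling with p proportional to count x w."""
    if rng is None:
        rng = config.rng()
    if n_survivors is None:
        n_survivors = config.reads_per_pool
    windows = {w.index: w for w in config.spec.windows}
    items = sorted(pool.items())
    weights = np.array(
        [
            count * fitness.window_fitness(translate_window(dna), windows[wi])
            for (wi, dna), count in items
        ],
        dtype=float,
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError("selection weights are all zero; nothing survives")
    drawn = rng.multinomial(n_survivors, weights / total)
    return {key: int(n) for (key, _), n in zip(items, drawn) if n > 0}


def pool_to_counts(pool: Pool, condition: str) -> CountTable:
    """Error-free shortcut from a pool straight to a count table."""
    table = CountTable()
    for (wi, dna), n in sorted(pool.items()):
        table.add(condition, wi, dna, n)
    return table


def _apply_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Uniform per-base substitution errors (no indels)."""
    if rate <= 0 or not seqs:
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        base_idx = {b.encode(): i for i, b in enumerate(BASES)}
        bases = np.frombuffer(BASES.encode(), dtype="S1")
        for i in hits:
            current = base_idx[bytes(arr[i])]
            arr[i] = bases[(current + rng.integers(1, 4)) % 4]
    joined = arr.tobytes().decode()
    out, start = [], 0
    for s in seqs:
        out.append(joined[start : start + len(s)])
        start += len(s)
    return out


def emit_fastq(
    pool: Pool,
    config: ScreenConfig,
    path,
    condition: str = "input",
    rng: np.random.Generator | None = None,
) -> Path:
    """Write the pool as flanked amplicon reads with sequencing error.

    Each record is the window's 20-nt upstream context + window + 20-nt
    downstream context, with substitution errors at ``config.error_rate`` and
    a constant quality string.  Deterministic under a fixed generator state.
    """
    if rng is None:
        rng = config.rng()
    path = Path(path)
    spec = config.spec
    flanks = {w.index: spec.window_flanks(w) for w in spec.windows}
    opener = gzip.open if path.suffix == ".gz" else open
    serial = 0
    with opener(path, "wt") as fh:
        for (wi, dna), count in sorted(pool.items()):
            up, down = flanks[wi]
            amplicon = up + dna + down
            reads = _apply_errors([amplicon] * count, config.error_rate, rng)
            qual = config.quality_char * len(amplicon)
            for read in reads:
                serial += 1
                fh.write(f"@sim:{condition}:w{wi}:{serial}\n{read}\n+\n{qual}\n")
    return path


@dataclass
class ScreenOutput:
    input_fastq: Path
    selected_fastq: Path
    truth: pd.DataFrame
    input_pool: Pool
    selected_pool: Pool


def run_screen(
    config: ScreenConfig,
    fitness: FitnessModel | None = None,
    outdir=None,
    write_fastq: bool = True,
) -> ScreenOutput:
    """Generate one full screen: input pool, selection, FASTQ pair, truth table."""
    if fitness is None:
        fitness = FitnessModel.default_scenario(config.spec, seed=config.seed)
    rng = config.rng()
    input_pool = sample_library(config, rng)
    selected_pool = select_pool(input_pool, fitness, config, rng)
    input_path = selected_path = None
    if write_fastq:
        outdir = Path(outdir or ".")
        outdir.mkdir(parents=True, exist_ok=True)
        input_path = emit_fastq(input_pool, config, outdir / "input.fastq", "input", rng)
        selected_path = emit_fastq(
            selected_pool, config, outdir / "selected.fastq", "selected", rng
        )
        fitness.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return ScreenOutput(
        input_fastq=input_path,
        selected_fastq=selected_path,
        truth=fitness.truth_table(),
        input_pool=input_pool,
        selected_pool=selected_pool,
    )
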