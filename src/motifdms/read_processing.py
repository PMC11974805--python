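"""Amplicon read filtering and window counting.

A read is accepted only if it carries the 20-bp constant sequence immediately
upstream and downstream of a randomized window, with exactly the window's
length between the two flanks.  The bounded substring is the window
observation; everything else about the read is ignored.  Reads that fail the
flank filter are rejected with a reason code, and rejection bookkeeping is
exact: ``reads_seen == matched + sum(rejected_by_reason)`` for every sample.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .motif import MotifSpec, Window, classify_window, translate_window

CONDITIONS = ("input", "selected")

# rejection reason codes, ordered from least to most informative: when a read
# fails several ways the most informative reason is reported
REASONS = (
    "no_upstream",
    "no_downstream",
    "bad_gap",
    "mate_conflict",
    "ambiguous_base",
    "low_quality",
)
_PRIORITY = {r: i for i, r in enumerate(REASONS)}

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _occurrences(read: str, pattern: str, max_mismatch: int) -> Iterator[int]:
    if max_mismatch == 0:
        start = read.find(pattern)
        while start != -1:
            yield start
            start = read.find(pattern, start + 1)
    else:
        for start in range(len(read) - len(pattern) + 1):
            if _mismatches(read[start : start + len(pattern)], pattern, max_mismatch) <= max_mismatch:
                yield start


def match_flanks(
    read: str,
    upstream: str,
    downstream: str,
    nt_length: int,
    max_mismatch: int = 0,
) -> tuple[str | None, str | None]:
    """Extract the window bounded by two 20-bp flanks, or reject.

    Returns ``(window, None)`` on success or ``(None, reason)`` with reason in
    ``no_upstream`` / ``no_downstream`` / ``bad_gap`` / ``ambiguous_base``.
    The window is taken at the first co-linear occurrence of the upstream and
    downstream flanks separated by exactly ``nt_length`` bases, each flank
    matching with at most ``max_mismatch`` mismatches.
    """
    if nt_length <= 0:
        raise ValueError("nt_length must be positive")
    if len(upstream) != 20 or len(downstream) != 20:
        raise ValueError("flanks must be exactly 20 nt")
    read = read.upper()
    saw_upstream = False
    for u in _occurrences(read, upstream, max_mismatch):
        saw_upstream = True
        d = u + 20 + nt_length
        if d + 20 > len(read):
            continue
        if _mismatches(read[d : d + 20], downstream, max_mismatch) <= max_mismatch:
            window = read[u + 20 : u + 20 + nt_length]
            if any(b not in "ACGT" for b in window):
                return None, "ambiguous_base"
            return window, None
    if not saw_upstream:
        return None, "no_upstream"
    if next(_occurrences(read, downstream, max_mismatch), None) is None:
        return None, "no_downstream"
    return None, "bad_gap"


def orient_read(
    read: str,
    upstream: str,
    downstream: str,
    nt_length: int,
    max_mismatch: int = 0,
) -> tuple[str | None, str | None]:
    """Return the read in reference orientation, or reject.

    The forward sequence is tried first, then the reverse complement; the
    orientation whose sequence contains the flank structure (co-linear flanks
    with the right gap, regardless of window content) is returned.  A read
    matching in both or neither orientation is rejected.
    """

    def structural(seq: str) -> bool:
        window, reason = match_flanks(seq, upstream, downstream, nt_length, max_mismatch)
        return window is not None or reason == "ambiguous_base"

    fwd = structural(read)
    rc = reverse_complement(read)
    rev = structural(rc)
    if fwd and not rev:
        return read, None
    if rev and not fwd:
        return rc, None
    if fwd and rev:
        return None, "ambiguous_orientation"
    return None, "no_flank"


@dataclass
class ProcessingReport:
    """Per-sample accounting of the read filter."""

    sample_id: str
    reads_seen: int = 0
    matched: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected_by_reason[reason] = self.rejected_by_reason.get(reason, 0) + 1

    @property
    def rejected(self) -> int:
        return sum(self.rejected_by_reason.values())

    def is_conserved(self) -> bool:
        return self.reads_seen == self.matched + self.rejected

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "reads_seen": self.reads_seen,
            "matched": self.matched,
            "rejected_by_reason": dict(self.rejected_by_reason),
        }


class CountTable:
    """Per-sample window observation counts, keyed by window DNA.

    Counts are additive over read batches and independent of read order.
    Amino-acid-level aggregation (summing synonymous DNA observations) is the
    basis of all downstream scoring.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, int, str], int] = {}

    def add(self, condition: str, window_index: int, dna: str, n: int = 1) -> None:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        if n < 0:
            raise ValueError("negative count")
        key = (condition, window_index, dna)
        self._counts[key] = self._counts.get(key, 0) + n

    def update(self, other: "CountTable") -> None:
        for (cond, wi, dna), n in other._counts.items():
            self.add(cond, wi, dna, n)

    def total(self, condition: str, window_index: int | None = None) -> int:
        return sum(
            n
            for (cond, wi, _), n in self._counts.items()
            if cond == condition and (window_index is None or wi == window_index)
        )

    def dna_counts(self, condition: str, window_index: int) -> dict[str, int]:
        return {
            dna: n
            for (cond, wi, dna), n in self._counts.items()
            if cond == condition and wi == window_index
        }

    def aa_counts(self, condition: str, window_index: int) -> dict[str, int]:
        """Counts aggregated over synonymous DNA at the translated level."""
        out: dict[str, int] = {}
        for dna, n in self.dna_counts(condition, window_index).items():
            aa = translate_window(dna)
            out[aa] = out.get(aa, 0) + n
        return out

    def window_indices(self) -> list[int]:
        return sorted({wi for (_, wi, _) in self._counts})

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self._counts == other._counts

    def __len__(self) -> int:
        return len(self._counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": cond,
                "window_index": wi,
                "window_dna": dna,
                "window_aa": translate_window(dna),
                "count": n,
            }
            for (cond, wi, dna), n in sorted(self._counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample", "window_index", "window_dna", "window_aa", "count"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        table = cls()
        for row in frame.itertuples(index=False):
            table.add(row.sample, int(row.window_index), row.window_dna, int(row.count))
        return table

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        record_no = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                yield title, seq.upper(), qual
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {path!r} at record {record_no + 1}: {exc}") from exc


def _mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / max(len(qual), 1)


class _WindowExtractor:
    """Window extraction against every window of a motif, both orientations."""

    def __init__(self, spec: MotifSpec, max_mismatch: int = 0, search_reverse: bool = True):
        self.spec = spec
        self.max_mismatch = max_mismatch
        self.search_reverse = search_reverse
        self.flanks = [(w, *spec.window_flanks(w)) for w in spec.windows]

    def _extract_oriented(self, read: str) -> tuple[tuple[int, str] | None, str | None]:
        best_reason = None
        for window, up, down in self.flanks:
            hit, reason = match_flanks(read, up, down, window.nt_length, self.max_mismatch)
            if hit is not None:
                return (window.index, hit), None
            if best_reason is None or _PRIORITY[reason] > _PRIORITY[best_reason]:
                best_reason = reason
            if reason == "ambiguous_base":
                break
        return None, best_reason

    def extract(self, read: str) -> tuple[tuple[int, str] | None, str | None]:
        hit, reason = self._extract_oriented(read)
        if hit is not None or reason == "ambiguous_base" or not self.search_reverse:
            return hit, reason
        hit_rc, reason_rc = self._extract_oriented(reverse_complement(read))
        if hit_rc is not None:
            return hit_rc, None
        if _PRIORITY[reason_rc] > _PRIORITY[reason]:
            reason = reason_rc
        return None, reason


def count_windows(
    fastq_by_sample: Mapping[str, "str | Sequence[str]"],
    spec: MotifSpec,
    max_mismatch: int = 0,
    search_reverse: bool = True,
    min_mean_quality: float | None = None,
) -> tuple[CountTable, dict[str, ProcessingReport]]:
    """Count window observations per sample from FASTQ files.

    ``fastq_by_sample`` maps a condition label (``input`` / ``selected``) to a
    FASTQ path, or to a pair of paths for paired-end mates.  Mates are
    searched independently and a pair contributes a single count, taken from
    whichever mate matches; mates matching different windows or different
    window sequences are rejected as ``mate_conflict``.  Base qualities are
    ignored unless ``min_mean_quality`` is set.
    """
    extractor = _WindowExtractor(spec, max_mismatch, search_reverse)
    table = CountTable()
    reports: dict[str, ProcessingReport] = {}
    for condition, paths in fastq_by_sample.items():
        if condition not in CONDITIONS:
            raise ValueError(f"sample label {condition!r} must be one of {CONDITIONS}")
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = (paths,)
        report = ProcessingReport(sample_id=condition)
        reports[condition] = report
        streams = [_fastq_records(p) for p in paths]
        if len(streams) == 1:
            for _, seq, qual in streams[0]:
                report.reads_seen += 1
                if min_mean_quality is not None and _mean_quality(qual) < min_mean_quality:
                    report.reject("low_quality")
                    continue
                hit, reason = extractor.extract(seq)
                if hit is None:
                    report.reject(reason)
                else:
                    report.matched += 1
                    table.add(condition, hit[0], hit[1])
        elif len(streams) == 2:
            for (_, seq1, q1), (_, seq2, q2) in zip(streams[0], streams[1]):
                report.reads_seen += 1
                if min_mean_quality is not None and (
                    _mean_quality(q1) < min_mean_quality or _mean_quality(q2) < min_mean_quality
                ):
                    report.reject("low_quality")
                    continue
                hit1, reason1 = extractor.extract(seq1)
                hit2, reason2 = extractor.extract(seq2)
                if hit1 is not None and hit2 is not None and hit1 != hit2:
                    report.reject("mate_conflict")
                    continue
                hit = hit1 if hit1 is not None else hit2
                if hit is None:
                    reason = reason1
                    if _PRIORITY[reason2] > _PRIORITY[reason]:
                        reason = reason2
                    report.reject(reason)
                else:
                    report.matched += 1
                    table.add(condition, hit[0], hit[1])
        else:
            raise ValueError("each sample takes one FASTQ path or a pair of mates")
    return table, reports


def write_report(reports: Mapping[str, ProcessingReport], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: r.to_dict() for k, r in reports.items()}, fh, indent=2)
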