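"""Glutamine/asparagine-rich prion-like motif composition and scanning.

Prion-like motifs (PriLMs) in fungal proteins are low-complexity regions
enriched in glutamine (Q) and asparagine (N).  This module quantifies Q+N
content of stated sequence intervals (count and percentage, as reported in
comparative tables of Kog1 orthologs) and provides a transparent sliding-
window compositional scanner for locating candidate Q/N-rich intervals.  The
scanner is a deliberately simple stand-in for HMM-based prion-domain
predictors: interval boundaries for published motifs should be supplied
explicitly rather than re-derived.

Coordinates are 0-based half-open internally; the report/CLI boundary uses
1-based inclusive coordinates (flagged in headers).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
QN = frozenset("QN")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        up = self.residues.upper()
        bad = set(up) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifInterval:
    """0-based half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QNComposition:
    qn_count: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.qn_count <= self.length:
            raise ValueError("need 0 <= qn_count <= length")

    @property
    def qn_percent(self) -> float:
        return 100.0 * self.qn_count / self.length


def qn_composition(seq: ProteinSequence, interval: MotifInterval) -> QNComposition:
    """Count Q and N residues in an interval.

    X and any non-Q/N character count toward interval length but never toward
    the Q/N tally (conservative percentages).
    """
    if interval.end > len(seq):
        raise IndexError(
            f"interval [{interval.start}, {interval.end}) exceeds sequence "
            f"{seq.id!r} of length {len(seq)}"
        )
    segment = seq.residues[interval.start : interval.end]
    return QNComposition(
        qn_count=sum(r in QN for r in segment), length=len(segment)
    )


def scan_qn_windows(
    seq: ProteinSequence,
    window_length: int = 20,
    qn_threshold: float = 0.4,
    merge_gap: int = 10,
) -> list[MotifInterval]:
    """Locate Q/N-rich intervals by sliding-window composition.

    Windows of ``window_length`` with Q/N fraction >= ``qn_threshold`` are
    flagged; runs of flagged windows separated by <= ``merge_gap`` residues
    are merged, and each merged interval is trimmed to its outermost Q/N
    residues.  Returns disjoint intervals sorted by position.  A window
    longer than the sequence yields an empty list.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if not 0 < qn_threshold <= 1:
        raise ValueError("qn_threshold must be in (0, 1]")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    res = seq.residues
    n = len(res)
    if window_length > n:
        return []

    is_qn = [r in QN for r in res]
    # rolling Q/N count
    count = sum(is_qn[:window_length])
    need = qn_threshold * window_length
    flagged: list[tuple[int, int]] = []  # [start, end) of flagged windows
    for start in range(n - window_length + 1):
        if start > 0:
            count += is_qn[start + window_length - 1] - is_qn[start - 1]
        if count >= need - 1e-12:
            flagged.append((start, start + window_length))
    if not flagged:
        return []

    merged: list[list[int]] = [list(flagged[0])]
    for s, e in flagged[1:]:
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for idx, (s, e) in enumerate(merged):
        while s < e and not is_qn[s]:
            s += 1
        while e > s and not is_qn[e - 1]:
            e -= 1
        if s < e:
            out.append(MotifInterval(seq.id, s, e, label=f"QN{idx + 1}"))
    return out


def mutate_interval_to_alanine(
    seq: ProteinSequence,
    interval: MotifInterval,
    target_residues: frozenset[str] = QN,
) -> ProteinSequence:
    """Replace target residues (default Q and N) within an interval by alanine.

    Mirrors the experimental disruption of prion-like motifs by Q-to-A
    substitution; everything outside the interval, and non-target residues
    inside it, are untouched.
    """
    if interval.end > len(seq):
        raise IndexError("interval exceeds sequence length")
    if not target_residues <= QN:
        raise ValueError("target_residues must be a subset of {Q, N}")
    chars = list(seq.residues)
    for i in range(interval.start, interval.end):
        if chars[i] in target_residues:
            chars[i] = "A"
    return ProteinSequence(id=seq.id, residues="".join(chars))


def composition_table(
    sequences: list[ProteinSequence],
    intervals: list[MotifInterval],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-(sequence, interval) Q/N composition table.

    One row per interval, with qn_count, length and qn_percent (rounded to 2
    decimals in the output column, matching tabular reporting conventions).
    ``annotations`` (indexed by seq_id) columns are passed through.  Dangling
    interval references raise with the offending ids listed.
    """
    by_id = {s.id: s for s in sequences}
    dangling = sorted({iv.seq_id for iv in intervals} - set(by_id))
    if dangling:
        raise KeyError(f"intervals reference absent sequences: {dangling}")
    rows = []
    for iv in intervals:
        comp = qn_composition(by_id[iv.seq_id], iv)
        rows.append(
            {
                "seq_id": iv.seq_id,
                "label": iv.label,
                "start_1based": iv.start + 1,
                "end_1based": iv.end,
                "length": comp.length,
                "qn_count": comp.qn_count,
                "qn_percent": round(comp.qn_percent, 2),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "seq_id", "label", "start_1based", "end_1based",
            "length", "qn_count", "qn_percent",
        ],
    )
    if annotations is not None and not table.empty:
        table = table.join(annotations, on="seq_id")
    return table


def interval_length_from_report(
    qn_count: int, qn_percent: float, max_length: int = 500
) -> list[int]:
    """Interval lengths consistent with a reported (count, rounded percent) pair.

    Brute-force search over 1..max_length for L with
    round(100*count/L, 2) == percent; used to recover interval lengths from
    published count/(percent) tables that omit coordinates.
    """
    return [
        L
        for L in range(max(qn_count, 1), max_length + 1)
        if round(100.0 * qn_count / L, 2) == round(qn_percent, 2)
    ]
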