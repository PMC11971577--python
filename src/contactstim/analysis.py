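"""Single-case (ABACB) analysis layer.

The study design is a within-subject phase sequence A1 B1 A2 C B2 — baseline,
intervention, baseline, control, intervention — and its effect measure is PEM,
the *percentage of data points exceeding the median*: the proportion of
intervention sessions whose response count strictly exceeds the median of the
comparison phase (the preceding baseline, or the control phase).  PEM is a
nonoverlap index: 1.0 means every intervention session outperformed the
comparison median, 0.5 is what exchangeable data produce in expectation.

Tie handling matters because PEM variants differ on it: here a session equal
to the median does NOT exceed it (strict ``>``).  Even-length medians use the
midpoint of the two central order statistics.

The module also computes the inter-rater agreement percentage
(100 x agreements / (agreements + disagreements)), block means for the
blocked graphic convention (2-session blocks in baseline/control, 4-session
blocks in intervention, a final partial block annotated with its size), and
the stimulus preference screening rule (a stimulus is retained only if at
least 50% of >= 10 nonconsecutive presentations drew agreed positive
reactions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ScreeningError, UndefinedAgreementError

PHASE_ORDER = ("A1", "B1", "A2", "C", "B2")

#: Printed per-phase session-count ranges; violations are warnings, not
#: errors, so synthetic mini-studies remain legal.
PHASE_LENGTH_RANGES = {
    "A1": (5, 10),
    "B1": (15, 31),
    "A2": (5, 9),
    "C": (5, 8),
    "B2": (43, 74),
}

#: Blocked-plot convention: sessions per block by phase kind.
BLOCK_SIZES = {"A1": 2, "A2": 2, "C": 2, "B1": 4, "B2": 4}


@dataclass
class PhaseSeries:
    """Per-session response counts of one participant, grouped by phase.

    ``phases`` is an ordered list of ``(label, counts)`` following the ABACB
    design.  Construction validates order and count non-negativity; phase
    lengths outside the printed ranges only warn.
    """

    participant_id: str
    phases: list[tuple[str, list[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.phases]
        if labels != list(PHASE_ORDER[: len(labels)]):
            raise AnalysisError(
                f"phase order {labels} does not follow the ABACB design "
                f"{list(PHASE_ORDER)}"
            )
        for label, counts in self.phases:
            if any((c < 0) or (int(c) != c) for c in counts):
                raise AnalysisError(
                    f"phase {label}: counts must be non-negative integers"
                )
            lo, hi = PHASE_LENGTH_RANGES[label]
            if counts and not (lo <= len(counts) <= hi):
                warnings.warn(
                    f"phase {label} has {len(counts)} sessions, outside the "
                    f"study range {lo}-{hi} (mini-study?)",
                    stacklevel=2,
                )

    def counts(self, label: str) -> list[int]:
        for lab, counts in self.phases:
            if lab == label:
                return list(counts)
        raise AnalysisError(f"phase {label!r} is missing from the series")


@dataclass(frozen=True)
class AgreementRecord:
    """Rater-vs-system tally for one session."""

    session_id: str
    agreements: int
    disagreements: int

    def __post_init__(self) -> None:
        if self.agreements < 0 or self.disagreements < 0:
            raise AnalysisError("agreement tallies must be non-negative")


def pem(
    baseline_counts: Sequence[float], intervention_counts: Sequence[float]
) -> float:
    """Proportion of intervention sessions strictly exceeding the baseline median.

    Ties with the median count as not exceeding.  Raises
    :class:`AnalysisError` on an empty phase.
    """
    if len(baseline_counts) == 0 or len(intervention_counts) == 0:
        raise AnalysisError("pem requires non-empty baseline and intervention phases")
    med = float(np.median(np.asarray(baseline_counts, dtype=float)))
    exceed = sum(1 for c in intervention_counts if c > med)
    return exceed / len(intervention_counts)


def pem_report(series: PhaseSeries) -> dict[str, float]:
    """The study's three PEM comparisons: B1 vs A1, B2 vs A2, B2 vs C."""
    return {
        "B1_vs_A1": pem(series.counts("A1"), series.counts("B1")),
        "B2_vs_A2": pem(series.counts("A2"), series.counts("B2")),
        "B2_vs_C": pem(series.counts("C"), series.counts("B2")),
    }


def agreement_pct(record: AgreementRecord) -> float:
    """100 x agreements / (agreements + disagreements).

    The 0/0 case is undefined and raises :class:`UndefinedAgreementError`
    (deliberately neither 0 nor 100).
    """
    total = record.agreements + record.disagreements
    if total < 1:
        raise UndefinedAgreementError(
            f"session {record.session_id!r}: agreement percentage is undefined "
            "with zero observations"
        )
    return 100.0 * record.agreements / total


def block_means(
    counts: Sequence[float], block_size: int
) -> list[tuple[float, int]]:
    """Consecutive non-overlapping block means, left to right.

    A final partial block is kept and its session count reported (the numeral
    annotating irregular blocks in the blocked graphic convention).
    """
    if block_size < 1:
        raise AnalysisError("block_size must be >= 1")
    out: list[tuple[float, int]] = []
    for start in range(0, len(counts), block_size):
        chunk = counts[start : start + block_size]
        out.append((float(np.mean(chunk)), len(chunk)))
    return out


def screening_retained(presentations: Sequence[bool]) -> bool:
    """Preference-screening retention: >= 50% positive of >= 10 presentations."""
    if len(presentations) < 10:
        raise ScreeningError(
            f"screening needs at least 10 presentations, got {len(presentations)}"
        )
    return sum(bool(p) for p in presentations) / len(presentations) >= 0.5


def study_summary(
    series: PhaseSeries, plot_path: str | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-phase descriptives plus the PEM triple; optionally render the plot.

    Returns ``(table, pems)`` where ``table`` has one row per phase with
    n_sessions / mean / median / min / max.
    """
    rows = []
    for label, counts in series.phases:
        if not counts:
            raise AnalysisError(f"phase {label} is empty")
        arr = np.asarray(counts, dtype=float)
        rows.append(
            {
                "phase": label,
                "n_sessions": len(counts),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "min": float(arr.min()),
                "max": float(arr.max()),
            }
        )
    table = pd.DataFrame(rows)
    pems = pem_report(series)
    if plot_path is not None:
        plot_study(series, plot_path)
    return table, pems


def plot_study(series: PhaseSeries, path: str) -> None:
    """Blocked response-frequency plot in the study's graphic convention.

    Block means (2-session blocks for baseline/control, 4 for intervention)
    are drawn left to right with phase separators; partial blocks are marked
    with a numeral giving their session count.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = 0
    for label, counts in series.phases:
        size = BLOCK_SIZES[label]
        blocks = block_means(counts, size)
        xs = [x + i for i in range(len(blocks))]
        ys = [m for m, _ in blocks]
        ax.plot(xs, ys, marker="o", color="black", linestyle="-")
        for xi, (m, n) in zip(xs, blocks):
            if n != size:  # irregular block: annotate the numeral
                ax.annotate(str(n), (xi, m), textcoords="offset points", xytext=(0, 6))
        mid = x + (len(blocks) - 1) / 2 if blocks else x
        ax.annotate(
            label, (mid, ax.get_ylim()[1]), ha="center",
            xytext=(0, -2), textcoords="offset points",
        )
        x += len(blocks)
        ax.axvline(x - 0.5, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("session blocks")
    ax.set_ylabel("mean responses per session")
    ax.set_title(f"Participant {series.participant_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
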