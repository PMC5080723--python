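"""Per-gene mark states, state transitions across time points, bivalency
retention trajectories, and overlap with reference bivalent gene sets.

A gene's *mark state* at one time point is determined solely by the
co-occurrence of its two mark calls: ``bivalent`` when both H3K4me3 and
H3K27me3 are present, ``K4only`` / ``K27only`` for a single mark,
``none`` otherwise.  Transitions between two time points are summarized
in a full 4x4 count matrix; bivalency gains decompose into gain of
H3K4me3 (from K27only), gain of H3K27me3 (from K4only), and gain of
both (from none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = ("none", "K4only", "K27only", "bivalent")

RETENTION_LABELS = (
    "never",
    "preexisting-retained",
    "gained-retained",
    "gained-lost",
    "other",
)


def _as_bool_series(calls) -> pd.Series:
    """Accept a mark-call DataFrame (with a ``marked`` column), a boolean
    Series indexed by gene, or a mapping gene -> bool."""
    if isinstance(calls, pd.DataFrame):
        return calls["marked"].astype(bool)
    if isinstance(calls, pd.Series):
        return calls.astype(bool)
    return pd.Series(dict(calls), dtype=bool)


def mark_states(k4_calls, k27_calls) -> pd.Series:
    """Four-way state per gene from the two mark calls.

    Both inputs must cover the same gene universe.
    """
    k4 = _as_bool_series(k4_calls)
    k27 = _as_bool_series(k27_calls)
    if set(k4.index) != set(k27.index):
        raise ValueError("H3K4me3 and H3K27me3 calls cover different gene sets")
    k27 = k27.reindex(k4.index)
    out = np.where(
        k4 & k27, "bivalent", np.where(k4, "K4only", np.where(k27, "K27only", "none"))
    )
    return pd.Series(out, index=k4.index, name="state").sort_index()


@dataclass
class TransitionTable:
    """4x4 state-transition counts between two time points."""

    from_timepoint: str
    to_timepoint: str
    counts: pd.DataFrame  # index: origin state, columns: destination state
    gene_lists: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def summaries(self) -> dict[str, int]:
        """Bivalency bookkeeping: how bivalent genes at the destination
        arose, and how many were already bivalent."""
        c = self.counts
        return {
            "bivalency_by_gain_of_K4": int(c.at["K27only", "bivalent"]),
            "bivalency_by_gain_of_K27": int(c.at["K4only", "bivalent"]),
            "bivalency_by_gain_of_both": int(c.at["none", "bivalent"]),
            "preexisting_bivalent": int(c.at["bivalent", "bivalent"]),
        }


def transitions(
    states_a: pd.Series,
    states_b: pd.Series,
    from_timepoint: str = "a",
    to_timepoint: str = "b",
) -> TransitionTable:
    """Full 4x4 transition count matrix between two state vectors over
    the same gene universe; every row sums to the origin-state census."""
    if set(states_a.index) != set(states_b.index):
        raise ValueError("state vectors cover different gene universes")
    states_b = states_b.reindex(states_a.index)
    counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    gene_lists: dict[tuple[str, str], list[str]] = {}
    grouped = pd.DataFrame({"a": states_a, "b": states_b}).groupby(
        ["a", "b"], observed=True
    )
    for (sa, sb), group in grouped:
        counts.at[sa, sb] = len(group)
        gene_lists[(sa, sb)] = sorted(group.index)
    return TransitionTable(from_timepoint, to_timepoint, counts, gene_lists)


def retention(
    states_by_timepoint: pd.DataFrame, target_state: str = "bivalent"
) -> tuple[pd.Series, dict[str, int]]:
    """Trajectory label per gene over ordered time points (first =
    baseline, last = recovery, middle = stress conditions).

    * ``preexisting-retained``: in the target state at baseline and still
      at recovery.
    * ``gained-retained``: acquired the state during stress and kept it
      at recovery; ``gained-lost``: acquired it but reverted.
    * ``never``: never in the target state; ``other``: remaining
      patterns (e.g., lost a preexisting state, or present at recovery
      only).
    """
    if states_by_timepoint.shape[1] < 3:
        raise ValueError("need at least 3 ordered timepoints")
    hit = states_by_timepoint.eq(target_state)
    first = hit.iloc[:, 0]
    last = hit.iloc[:, -1]
    middle = hit.iloc[:, 1:-1].any(axis=1)

    labels = np.full(len(hit), "other", dtype=object)
    labels[(~first & ~middle & ~last).to_numpy()] = "never"
    labels[(first & last).to_numpy()] = "preexisting-retained"
    labels[(~first & middle & last).to_numpy()] = "gained-retained"
    labels[(~first & middle & ~last).to_numpy()] = "gained-lost"
    series = pd.Series(labels, index=hit.index, name="trajectory")
    counts = {lab: int((series == lab).sum()) for lab in RETENTION_LABELS}
    return series, counts


def retained_fraction(counts: dict[str, int]) -> float:
    """Fraction of stress-acquired states kept at recovery."""
    gained = counts["gained-retained"] + counts["gained-lost"]
    if gained == 0:
        raise ValueError("no gained genes; retained fraction undefined")
    return counts["gained-retained"] / gained


def reference_overlap(
    query_gene_ids: set[str],
    reference_gene_ids: set[str],
    mode: str = "query",
) -> float:
    """Percentage of query genes present in the reference set
    (``mode="query"``), or the symmetric Jaccard percentage
    (``mode="jaccard"``)."""
    query = set(query_gene_ids)
    reference = set(reference_gene_ids)
    if not query:
        raise ValueError("query gene set is empty")
    if not reference:
        raise ValueError("reference gene set is empty")
    inter = len(query & reference)
    if mode == "query":
        return 100.0 * inter / len(query)
    if mode == "jaccard":
        return 100.0 * inter / len(query | reference)
    raise ValueError(f"unknown overlap mode {mode!r}")
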