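"""Heterogeneity and population statistics.

Clonal diversity is measured with the Shannon index

    H = -sum_i p_i ln p_i

over the relative abundances p_i of the clone labels present (a clone
label is either a 64-CpG methylation pattern or an integer phenotype).
For S observed labels the maximum attainable index is ln S, reached
when all labels are equally abundant, so the normalized index

    H' = H / ln S  in [0, 1]

compares heterogeneity across populations of different richness: 0 is a
single dominant clone, 1 a fully heterogeneous population. Natural
logarithms throughout; the normalization cancels the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scistats

from .hierarchy import CellType
from .mutation_models import PHENOTYPE_MAX, PHENOTYPE_MIN, pattern_label

__all__ = [
    "CloneAbundanceTable",
    "shannon_index",
    "normalized_shannon",
    "clone_abundance",
    "mean_fitness",
    "phenotype_histogram",
    "compare_groups",
]


@dataclass
class CloneAbundanceTable:
    """Counts of live cells per categorical clone label."""

    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.labels) != self.counts.size:
            raise ValueError("labels and counts differ in length")
        if self.counts.size and self.counts.min() <= 0:
            raise ValueError("clone counts must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("clone labels must be unique")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def relative_abundances(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty abundance table")
        return self.counts / self.total


def shannon_index(table: CloneAbundanceTable) -> float:
    """Shannon index H = -sum p_i ln p_i; 0 iff a single clone."""
    p = table.relative_abundances()
    return float(-np.sum(p * np.log(p)))


def normalized_shannon(table: CloneAbundanceTable) -> float:
    """H / ln S for the S labels observed; defined as 0 when S = 1."""
    s = table.n_species
    if s == 0:
        raise ValueError("empty abundance table")
    if s == 1:
        return 0.0
    return shannon_index(table) / np.log(s)


def clone_abundance(
    state,
    label_kind: str = "methylation",
    compartment: str = "all",
) -> CloneAbundanceTable:
    """Tabulate live cells per clone label.

    ``label_kind`` selects the labeling: ``"methylation"`` keys on the
    hexadecimal 64-bit pattern, ``"phenotype"`` on the integer x.
    ``compartment`` restricts to ``"csc_only"`` or uses ``"all"`` cells.
    """
    if label_kind not in ("methylation", "phenotype"):
        raise ValueError(f"unknown label kind {label_kind!r}")
    if compartment not in ("all", "csc_only"):
        raise ValueError(f"unknown compartment {compartment!r}")
    mask = state.live_mask()
    if compartment == "csc_only":
        mask = mask & (state.cell_type_array() == CellType.CSC)
    if not mask.any():
        raise ValueError(f"compartment {compartment!r} is empty")
    if label_kind == "methylation":
        values = state.methylation_array()[mask]
        uniq, counts = np.unique(values, return_counts=True)
        labels = [pattern_label(u) for u in uniq]
    else:
        values = state.phenotype_array()[mask]
        uniq, counts = np.unique(values, return_counts=True)
        labels = [int(u) for u in uniq]
    return CloneAbundanceTable(labels=labels, counts=counts)


def mean_fitness(state, landscape) -> float:
    """Population mean of f(x) over live cells; requires phenotype tracking."""
    if getattr(state.config, "mode", None) == "neutral":
        raise ValueError("mean fitness is undefined in neutral mode (no phenotypes)")
    mask = state.live_mask()
    if not mask.any():
        raise ValueError("empty tumor has no mean fitness")
    return float(np.mean(landscape.fitness(state.phenotype_array()[mask])))


def phenotype_histogram(state) -> np.ndarray:
    """Counts of live cells per phenotype, aligned to [-24, +25]."""
    mask = state.live_mask()
    xs = state.phenotype_array()[mask]
    n_bins = PHENOTYPE_MAX - PHENOTYPE_MIN + 1
    return np.bincount(xs - PHENOTYPE_MIN, minlength=n_bins).astype(np.int64)


def compare_groups(samples_a: Sequence[float], samples_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value for two replicate groups.

    Exact null distribution for small groups (n <= 12, no ties), normal
    approximation otherwise.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 12 and not ties) else "asymptotic"
    res = _scistats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
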