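"""Quadratic-assignment permutation null for the genome-wide DMR count.

With only three replicates per group, a naive permutation test has
too few distinct relabelings for a fine-grained p-value. The adapted
quadratic-assignment method (QAM) instead:

1. enumerates every balanced relabeling of samples to the two groups
   (complement-collapsed, excluding the true labeling — nine for a
   3-vs-3 design),
2. re-runs the complete DMR analysis under each relabeling and
   records, per 200 bp window, in how many relabelings it comes out a
   DMR, giving each window a null probability ``k / K``,
3. draws many (default 50,000) region-independent realizations of the
   genome-wide DMR count by sampling each window as an independent
   Bernoulli with its probability, and
4. compares the observed DMR count to this null.

The exact law of the null count is Poisson-binomial; an exact
dynamic-programming pmf is provided as an oracle for the Monte-Carlo
sampler and for small-region summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from methperm.dmr import (
    DEFAULT_MIN_DIFF,
    DEFAULT_Q,
    test_windows,
    call_dmrs,
)


@dataclass(frozen=True)
class Relabeling:
    """One balanced sample-to-group assignment."""

    assignment: tuple[tuple[str, str], ...]  # (sample_id, group) pairs

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def canonical_key(self) -> frozenset:
        """Unordered partition: invariant under swapping the two labels."""
        groups: dict[str, set] = {}
        for sid, g in self.assignment:
            groups.setdefault(g, set()).add(sid)
        return frozenset(frozenset(v) for v in groups.values())


@dataclass
class NullDistribution:
    """Null distribution of the genome-wide DMR count."""

    mean: float
    max: float
    draws: Optional[np.ndarray] = None
    quantiles: dict = field(default_factory=dict)
    seed: Optional[int] = None
    n_iter: Optional[int] = None

    @classmethod
    def from_draws(cls, draws: np.ndarray,
                   seed: Optional[int] = None) -> "NullDistribution":
        draws = np.asarray(draws)
        qs = (0.025, 0.25, 0.5, 0.75, 0.975)
        return cls(
            mean=float(draws.mean()),
            max=float(draws.max()),
            draws=draws,
            quantiles={q: float(np.quantile(draws, q)) for q in qs},
            seed=seed,
            n_iter=len(draws),
        )


@dataclass(frozen=True)
class QamSummary:
    observed_dmrs: int
    null_mean: float
    null_max: float
    empirical_p: Optional[float]
    per_dmr_chance_pct: Optional[float]


def enumerate_relabelings(
    sample_ids: Sequence[str],
    groups: dict[str, str],
) -> list[Relabeling]:
    """All non-original balanced relabelings, complement-collapsed.

    Two assignments that merely swap the group labels describe the
    same partition of samples and are counted once, so a balanced
    g-vs-g design yields ``C(2g, g) / 2 - 1`` relabelings (nine for
    3-vs-3). The true labeling is excluded. Order is deterministic.

    Raises
    ------
    ValueError
        For unbalanced designs or anything other than two groups.
    """
    sample_ids = list(sample_ids)
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    sizes = [sum(1 for s in sample_ids if groups[s] == l) for l in labels]
    if sizes[0] != sizes[1] or sizes[0] < 1:
        raise ValueError(
            f"balanced design required, got group sizes {sizes}")
    g = sizes[0]

    original = Relabeling(tuple((s, groups[s]) for s in sample_ids))
    original_key = original.canonical_key

    seen = set()
    out: list[Relabeling] = []
    for side in combinations(sorted(sample_ids), g):
        side_set = set(side)
        assignment = tuple(
            (s, labels[0] if s in side_set else labels[1])
            for s in sample_ids
        )
        rel = Relabeling(assignment)
        key = rel.canonical_key
        if key in seen or key == original_key:
            continue
        seen.add(key)
        out.append(rel)
    return out


def region_dmr_probabilities(
    windows: pd.DataFrame,
    relabelings: Sequence[Relabeling],
    q_threshold: float = DEFAULT_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
    backend: str = "glm",
) -> pd.DataFrame:
    """Per-window probability of being a DMR across relabelings.

    Each relabeling is a complete re-analysis on the same window
    counts, thresholds and (its own) BH family — exactly the observed
    analysis with shuffled labels. ``prob = k / K`` where ``k`` is
    the number of relabelings calling the window a DMR.
    """
    if len(relabelings) == 0:
        raise ValueError("no relabelings given")
    k = np.zeros(len(windows), dtype=int)
    for rel in relabelings:
        tested = test_windows(windows, rel.as_dict(), backend=backend)
        called = call_dmrs(tested, q_threshold=q_threshold,
                           min_diff=min_diff)
        k += called["is_dmr"].to_numpy().astype(int)
    out = windows[["chrom", "start", "end"]].copy()
    out["k"] = k
    out["prob"] = k / len(relabelings)
    return out


def simulate_null(
    table: pd.DataFrame,
    n_iter: int = 50_000,
    seed: int = 0,
    chunk: int = 512,
) -> NullDistribution:
    """Monte-Carlo null of the genome-wide DMR count.

    Each draw sums one independent Bernoulli per region with that
    region's probability; ``n_iter`` draws are tallied.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    probs = np.asarray(table["prob"], dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("region probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_iter, dtype=np.int64)
    nonzero = probs[probs > 0]
    for i in range(0, len(nonzero), chunk):
        p = nonzero[i:i + chunk]
        counts += (rng.random((n_iter, len(p))) < p).sum(axis=1)
    return NullDistribution.from_draws(counts, seed=seed)


def null_distribution_exact(table: pd.DataFrame) -> np.ndarray:
    """Exact Poisson-binomial pmf of the null DMR count.

    Iterative convolution over regions; entry ``j`` is the probability
    of exactly ``j`` DMRs genome-wide. The mean of the pmf equals the
    sum of the region probabilities exactly.
    """
    probs = np.asarray(table["prob"], dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("region probabilities must be in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        if p == 0.0:
            continue
        new = np.empty(len(pmf) + 1)
        new[:-1] = pmf * (1.0 - p)
        new[-1] = 0.0
        new[1:] += pmf * p
        pmf = new
    return pmf


def run_qam_analysis(
    counts_by_sample: dict[str, pd.DataFrame],
    groups: dict[str, str],
    epsilon: float,
    n_iter: int = 50_000,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
    backend: str = "glm",
    lambda_chrom: str = "lambda",
) -> tuple[pd.DataFrame, pd.DataFrame, NullDistribution, "QamSummary"]:
    """Observed DMR analysis plus its full QAM null, end to end.

    Returns ``(dmr_table, region_probabilities, null, summary)``; the
    observed analysis and every relabeling share sites, windows,
    filters and thresholds.
    """
    from methperm.core import call_site_methylation, merge_strands
    from methperm.dmr import bin_windows, filter_sites

    calls = {}
    for sid, df in counts_by_sample.items():
        genome = df[df["chrom"] != lambda_chrom]
        merged = merge_strands(genome[["chrom", "pos", "strand", "m", "n"]])
        calls[sid] = call_site_methylation(merged, epsilon)
    windows = bin_windows(filter_sites(calls))
    observed = call_dmrs(
        test_windows(windows, groups, backend=backend),
        q_threshold=q_threshold, min_diff=min_diff)

    relabelings = enumerate_relabelings(list(counts_by_sample), groups)
    table = region_dmr_probabilities(
        windows, relabelings, q_threshold=q_threshold, min_diff=min_diff,
        backend=backend)
    null = simulate_null(table, n_iter=n_iter, seed=seed)
    summary = summarize_qam(null, int(observed["is_dmr"].sum()))
    return observed, table, null, summary


def per_dmr_chance_pct(null_mean: float, observed_dmrs: int) -> float:
    """Expected null DMRs as a percentage of the observed count.

    The share of the observed genome-wide DMR tally that chance alone
    would produce — i.e. how likely any individual observed DMR is a
    chance call.
    """
    if observed_dmrs <= 0:
        raise ValueError("undefined when no DMRs are observed")
    return 100.0 * null_mean / observed_dmrs


def summarize_qam(
    null: NullDistribution,
    observed_dmrs: int,
) -> QamSummary:
    """Compare the observed DMR count with the QAM null.

    The empirical p-value uses the add-one estimator
    ``(1 + #{draws >= observed}) / (1 + n_iter)`` (ties count as
    exceedances), so it is never exactly zero; it is None when the
    null carries no draws (e.g. built from summary statistics alone).
    """
    if observed_dmrs < 0:
        raise ValueError("observed_dmrs must be non-negative")
    emp_p = None
    if null.draws is not None and len(null.draws):
        n_iter = len(null.draws)
        emp_p = float(
            (1 + int((null.draws >= observed_dmrs).sum())) / (1 + n_iter))
    chance = (per_dmr_chance_pct(null.mean, observed_dmrs)
              if observed_dmrs > 0 else None)
    return QamSummary(
        observed_dmrs=int(observed_dmrs),
        null_mean=float(null.mean),
        null_max=float(null.max),
        empirical_p=emp_p,
        per_dmr_chance_pct=chance,
    )
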