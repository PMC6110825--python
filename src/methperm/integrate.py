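"""Integration of DMRs with expression and splicing results.

Differentially methylated genes are compared with gene lists from
orthogonal analyses (differential expression, alternative splicing,
positive selection) by exclusive set intersection (UpSet-style) and
2x2 chi-square enrichment over an explicit shared gene universe;
gene-body methylation is rank-correlated with expression; and DMR
intervals are checked for direct (>= 1 bp) overlap with splice-event
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    """A named gene list over an explicit universe."""

    name: str
    members: frozenset
    universe: frozenset

    def __post_init__(self):
        if not self.members <= self.universe:
            extra = sorted(set(self.members) - set(self.universe))[:5]
            raise ValueError(
                f"set {self.name!r} has members outside its universe, "
                f"e.g. {extra}")

    @classmethod
    def from_iterables(cls, name, members, universe) -> "GeneSet":
        return cls(name, frozenset(members), frozenset(universe))


@dataclass(frozen=True)
class OverlapTest:
    """2x2 membership table with its chi-square enrichment test."""

    table: tuple  # ((both, a_only), (b_only, neither))
    statistic: float
    p_value: float
    odds_ratio: float


def intersect_sets(sets: list[GeneSet]) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersection counts.

    One row per non-empty membership pattern over the union of the
    sets' members; patterns are mutually exclusive and their counts
    sum to the union size.

    Raises
    ------
    ValueError
        If fewer than two sets are given or universes differ.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    universe = sets[0].universe
    for s in sets[1:]:
        if s.universe != universe:
            raise ValueError(
                f"set {s.name!r} is on a different universe")

    union = set().union(*(s.members for s in sets))
    names = [s.name for s in sets]
    rows = []
    for pattern in product([True, False], repeat=len(sets)):
        if not any(pattern):
            continue
        count = 0
        for g in union:
            if all((g in s.members) == want
                   for s, want in zip(sets, pattern)):
                count += 1
        if count:
            rows.append(dict(zip(names, pattern), count=count))
    out = pd.DataFrame(rows, columns=names + ["count"])
    return out.sort_values("count", ascending=False).reset_index(drop=True)


def overlap_chisq(a: GeneSet, b: GeneSet,
                  correction: bool = False) -> OverlapTest:
    """Pearson chi-square test of association between two gene sets.

    The 2x2 table counts genes of the shared universe by membership
    in A and B; expected counts come from the margins. Yates
    continuity correction is off by default. The odds ratio uses a
    Haldane half-count when any cell is zero. A degenerate margin
    (either set empty or equal to the universe) yields statistic 0
    and p = 1 by convention: no association is estimable.
    """
    if a.universe != b.universe:
        raise ValueError("sets must share a universe")
    universe = a.universe
    if len(universe) == 0:
        raise ValueError("empty universe")

    both = len(a.members & b.members)
    a_only = len(a.members) - both
    b_only = len(b.members) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]], dtype=float)

    degenerate = (len(a.members) in (0, len(universe))
                  or len(b.members) in (0, len(universe)))
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=correction)

    t = table.copy()
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapTest(
        table=tuple(tuple(int(v) for v in row) for row in table),
        statistic=float(stat),
        p_value=float(p),
        odds_ratio=float(odds),
    )


def methylation_expression_correlation(
    gene_meth: pd.DataFrame,
    expression: pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation of gene methylation with expression.

    ``gene_meth`` carries per-sample gene-body levels (columns other
    than ``gene_id`` / ``is_methylated``); levels are averaged across
    samples per gene, genes whose level is undefined in every sample
    are dropped, and the sample-averaged level is rank-correlated
    (mid-rank ties, large-sample p) with ``expression['expression']``
    over the genes present in both tables.

    Raises
    ------
    ValueError
        With fewer than three paired genes, or when either variable
        is constant (the rank correlation is undefined).
    """
    level_cols = [c for c in gene_meth.columns
                  if c not in ("gene_id", "is_methylated")]
    with np.errstate(invalid="ignore"):
        avg = gene_meth[level_cols].mean(axis=1, skipna=True)
    meth = pd.DataFrame({"gene_id": gene_meth["gene_id"], "meth": avg})
    meth = meth.dropna(subset=["meth"])
    paired = meth.merge(expression, on="gene_id", how="inner")
    if len(paired) < 3:
        raise ValueError(f"only {len(paired)} paired genes; need >= 3")
    x = paired["meth"].to_numpy()
    y = paired["expression"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spatial_overlap(
    dmrs: pd.DataFrame,
    events: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Direct interval overlap of DMR windows and splice events.

    A (DMR, event) pair is reported iff the half-open intervals share
    at least one base. The summary counts genes having both a DMR and
    an event (by the events' ``gene_id`` against the DMRs'
    ``gene_ids`` annotation when present) and the subset with a
    direct overlap.

    ``dmrs`` needs ``chrom, start, end`` (+ optional ``gene_ids``);
    ``events`` needs ``chrom, start, end, gene_id`` (+ optional
    ``event_type``).
    """
    only_dmrs = dmrs if "is_dmr" not in dmrs.columns else dmrs[dmrs["is_dmr"]]

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in events.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, e in sub.iterrows():
            if e["end"] > e["start"]:
                tree.addi(int(e["start"]), int(e["end"]), idx)
        trees[chrom] = tree

    rows = []
    for di, d in only_dmrs.iterrows():
        tree = trees.get(d["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(d["start"]), int(d["end"])),
                          key=lambda iv: iv.data):
            e = events.loc[hit.data]
            ov = min(d["end"], e["end"]) - max(d["start"], e["start"])
            rows.append({
                "chrom": d["chrom"],
                "dmr_start": int(d["start"]), "dmr_end": int(d["end"]),
                "event_start": int(e["start"]), "event_end": int(e["end"]),
                "gene_id": e["gene_id"],
                "event_type": e.get("event_type", ""),
                "overlap_bp": int(ov),
            })
    pairs = pd.DataFrame(
        rows, columns=["chrom", "dmr_start", "dmr_end", "event_start",
                       "event_end", "gene_id", "event_type", "overlap_bp"])

    event_genes = set(events["gene_id"])
    if "gene_ids" in only_dmrs.columns:
        dmr_genes = set().union(*only_dmrs["gene_ids"]) \
            if len(only_dmrs) else set()
    else:
        dmr_genes = set()
    both = dmr_genes & event_genes
    summary = {
        "genes_with_both": sorted(both),
        "genes_with_direct_overlap": sorted(set(pairs["gene_id"]) & both)
        if dmr_genes else sorted(set(pairs["gene_id"])),
        "n_overlap_pairs": int(len(pairs)),
    }
    return pairs, summary
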