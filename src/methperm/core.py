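"""Per-CpG methylation calling and gene-level summaries.

The observational unit is a cytosine with a methylated (unconverted)
read count ``m`` out of ``n`` total reads. Because bisulfite
conversion is imperfect, a truly unmethylated cytosine still reads as
methylated at the nonconversion rate ``epsilon``, estimated by pooling
reads over an unmethylated lambda-phage spike-in. A site is called
methylated when its counts are inconsistent with that error process:
an exact one-sided binomial test of ``m`` against ``Binomial(n,
epsilon)`` with Benjamini-Hochberg FDR control across sites within
each sample.

Coordinates are 0-based half-open internally; the cytosine-report
file dialect is 1-based, converted only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REPORT_COLUMNS = ["chrom", "pos", "strand", "count_methylated",
                  "count_unmethylated", "context"]

#: default coverage-bin edges for the hemimethylation diagnostic
HEMI_BINS = (2, 5, 10, 20, 40, 80, 160, 320)


@dataclass(frozen=True)
class ConversionControl:
    """Pooled nonconversion estimate from the lambda spike-in."""

    epsilon: float
    lambda_m: int
    lambda_n: int


def write_cytosine_report(counts: pd.DataFrame, path) -> None:
    """Write a Bismark-style CpG cytosine report (TSV, 1-based)."""
    out = pd.DataFrame({
        "chrom": counts["chrom"],
        "pos": counts["pos"] + 1,
        "strand": counts["strand"],
        "count_methylated": counts["m"],
        "count_unmethylated": counts["n"] - counts["m"],
        "context": "CpG",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a stranded count frame.

    Rows whose context is not ``CpG`` are dropped. Returns columns
    ``chrom, pos, strand, m, n`` with 0-based positions.

    Raises
    ------
    ValueError
        On a malformed row (wrong field count, non-integer counts,
        negative counts), naming the 1-based line number.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except Exception as exc:  # re-raise with a uniform message
        raise ValueError(f"cannot parse cytosine report {path}: {exc}")
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "m", "n"])

    for col in ("pos", "count_methylated", "count_unmethylated"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(
                f"malformed {col} in {path} at line {line}")
        df[col] = vals.astype(int)
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        line = int(((df["count_methylated"] < 0)
                    | (df["count_unmethylated"] < 0)).idxmax()) + 1
        raise ValueError(f"negative count in {path} at line {line}")

    df = df[df["context"] == "CpG"]
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"] - 1,
        "strand": df["strand"],
        "m": df["count_methylated"],
        "n": df["count_methylated"] + df["count_unmethylated"],
    }).reset_index(drop=True)
    return out


def estimate_nonconversion(lambda_sites: pd.DataFrame) -> ConversionControl:
    """Pooled nonconversion rate over all lambda cytosines.

    ``epsilon`` is total methylated reads over total reads, pooled
    across sites (not an average of per-site fractions), so deeply
    covered sites weigh more — the maximum-likelihood estimate for a
    shared error rate.

    Raises
    ------
    ValueError
        If the spike-in has zero total coverage; a conversion-error
        null cannot be formed without it.
    """
    lam_m = int(lambda_sites["m"].sum())
    lam_n = int(lambda_sites["n"].sum())
    if lam_n == 0:
        raise ValueError(
            "lambda spike-in has zero coverage; supply an explicit "
            "nonconversion rate instead"
        )
    return ConversionControl(epsilon=lam_m / lam_n, lambda_m=lam_m,
                             lambda_n=lam_n)


def merge_strands(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse the two strands of each CpG into one record.

    The plus-strand C at position ``p`` and the minus-strand C of the
    same dinucleotide at ``p + 1`` are summed into a merged record at
    ``p``. Records covered on only one strand pass through unchanged
    (as merged singletons at the plus-strand coordinate). Both ``m``
    and ``n`` totals are conserved exactly.

    Raises
    ------
    ValueError
        On duplicate records for the same (chrom, pos, strand).
    """
    if sites.duplicated(subset=["chrom", "pos", "strand"]).any():
        raise ValueError("duplicate (chrom, pos, strand) records")
    if ((sites["m"] < 0) | (sites["m"] > sites["n"])).any():
        raise ValueError("methylated count outside [0, n]")

    key_pos = sites["pos"] - (sites["strand"] == "-").astype(int)
    merged = (
        sites.assign(pos=key_pos)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["m", "n"]]
        .sum()
    )
    merged.insert(2, "strand", "merged")
    return merged


def hemimethylation_by_coverage(
    sites: pd.DataFrame,
    bin_edges: tuple[int, ...] = HEMI_BINS,
) -> pd.DataFrame:
    """Strand discordance of CpGs as a function of total coverage.

    For every CpG covered on both strands, the absolute difference of
    the two strand-wise methylation fractions is computed and averaged
    within coverage bins (bins are ``[e_i, e_{i+1})`` over the summed
    coverage of the pair). Apparent hemimethylation that shrinks with
    coverage is binomial sampling noise, not biology.
    """
    plus = sites[sites["strand"] == "+"]
    minus = sites[sites["strand"] == "-"].copy()
    minus["pos"] = minus["pos"] - 1
    pair = plus.merge(minus, on=["chrom", "pos"], suffixes=("_p", "_m"))
    pair = pair[(pair["n_p"] > 0) & (pair["n_m"] > 0)]

    rows = []
    if not pair.empty:
        cov = (pair["n_p"] + pair["n_m"]).to_numpy()
        disc = np.abs(pair["m_p"] / pair["n_p"]
                      - pair["m_m"] / pair["n_m"]).to_numpy()
        edges = list(bin_edges) + [np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (cov >= lo) & (cov < hi)
            if in_bin.any():
                rows.append((lo, hi, (lo + min(hi, 2 * lo)) / 2,
                             int(in_bin.sum()), float(disc[in_bin].mean())))
    return pd.DataFrame(
        rows, columns=["cov_low", "cov_high", "cov_mid", "n_pairs",
                       "mean_abs_discordance"]
    )


def binomial_pvalues(m: np.ndarray, n: np.ndarray,
                     epsilon: float) -> np.ndarray:
    """Exact upper-tail p-values P[X >= m], X ~ Binomial(n, epsilon).

    Conventions: ``n = 0`` gives p = 1 (no evidence); ``epsilon = 0``
    with ``m > 0`` gives p = 0 (any unconverted read is impossible
    under a perfect-conversion null).
    """
    m = np.asarray(m)
    n = np.asarray(n)
    p = stats.binom.sf(m - 1, np.maximum(n, 1), epsilon)
    return np.where(n == 0, 1.0, p)


def call_site_methylation(
    sites: pd.DataFrame,
    control: ConversionControl | float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call per-site methylation status against the nonconversion null.

    One-sided exact binomial test per site (``p = P[X >= m]`` under
    ``X ~ Binomial(n, epsilon)``) — methylation can only inflate the
    unconverted count above the error rate, never deflate it — with
    Benjamini-Hochberg correction across all sites of the sample.
    A site is methylated iff ``q < alpha``.

    ``control`` may be a :class:`ConversionControl` or a bare epsilon.
    """
    eps = control.epsilon if isinstance(control, ConversionControl) else float(control)
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"epsilon must be in [0, 1), got {eps}")

    out = sites.copy()
    p = binomial_pvalues(out["m"].to_numpy(), out["n"].to_numpy(), eps)
    out["p_value"] = p
    if len(out):
        out["q_value"] = multipletests(p, method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    out["methylated"] = out["q_value"] < alpha
    return out


def gene_methylation_levels(
    counts_by_sample: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Weighted gene-body methylation level per gene and sample.

    The level is total methylated reads over total reads summed across
    every merged CpG falling in the gene span (introns included). A
    gene with zero coverage in a sample has an undefined level (NaN),
    which is distinct from an observed level of 0. ``is_methylated``
    is True iff the level strictly exceeds ``cutoff`` in at least one
    sample; samples with undefined levels do not count either way.

    Parameters
    ----------
    counts_by_sample
        sample_id -> merged count frame (``chrom, pos, m, n``).
    genes
        Frame with ``gene_id, chrom, start, end`` (0-based half-open).
    """
    sample_ids = list(counts_by_sample)
    level_cols: dict[str, np.ndarray] = {}
    gene_ids = genes["gene_id"].to_numpy()

    for sid in sample_ids:
        df = counts_by_sample[sid]
        m_tot = np.zeros(len(genes))
        n_tot = np.zeros(len(genes))
        for ci, (chrom, sub) in enumerate(df.groupby("chrom", sort=False)):
            g = genes[genes["chrom"] == chrom]
            if g.empty:
                continue
            pos = sub["pos"].to_numpy()
            m = sub["m"].to_numpy()
            n = sub["n"].to_numpy()
            for gi, start, end in zip(g.index, g["start"], g["end"]):
                in_span = (pos >= start) & (pos < end)
                row = genes.index.get_loc(gi)
                m_tot[row] += m[in_span].sum()
                n_tot[row] += n[in_span].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(n_tot > 0, m_tot / np.maximum(n_tot, 1), np.nan)
        level_cols[sid] = level

    out = pd.DataFrame({"gene_id": gene_ids})
    for sid in sample_ids:
        out[sid] = level_cols[sid]
    lv = out[sample_ids].to_numpy()
    with np.errstate(invalid="ignore"):
        out["is_methylated"] = np.nanmax(
            np.where(np.isnan(lv), -np.inf, lv), axis=1) > cutoff
    return out


def feature_metaplot(
    counts: pd.DataFrame,
    annotation,
    flank: int = 500,
) -> pd.DataFrame:
    """Pooled methylation and CpG density per gene feature class.

    Features are exon ranks (``exon_1`` .. ``exon_k``), intron ranks
    (``intron_1`` ..), and fixed ``upstream`` / ``downstream`` flanks
    of ``flank`` bp oriented by gene strand. Within each class the
    methylation level is pooled (sum m / sum n over merged CpGs) and
    CpG density is covered CpGs per bp of feature sequence.

    ``counts`` is a merged count frame; ``annotation`` provides
    ``genes`` and ``exons`` frames as produced by the generator or a
    GFF3 reader.
    """
    genes = annotation.genes
    exons = annotation.exons
    if genes.empty:
        return pd.DataFrame(
            columns=["feature", "m", "n", "level", "n_cpgs", "bp",
                     "cpg_density"])

    intervals = []  # (feature, chrom, start, end)
    for _, g in genes.iterrows():
        ex = exons[exons["gene_id"] == g["gene_id"]].sort_values("rank")
        for _, e in ex.iterrows():
            intervals.append((f"exon_{int(e['rank'])}", e["chrom"],
                              int(e["start"]), int(e["end"])))
        ex_sorted = ex.sort_values("start")
        starts = ex_sorted["start"].to_numpy()
        ends = ex_sorted["end"].to_numpy()
        rank_sorted = ex_sorted["rank"].to_numpy()
        for i in range(len(ex_sorted) - 1):
            # intron rank follows the upstream exon in transcription order
            up_rank = int(min(rank_sorted[i], rank_sorted[i + 1]))
            intervals.append((f"intron_{up_rank}", g["chrom"],
                              int(ends[i]), int(starts[i + 1])))
        if g["strand"] == "+":
            up = (max(int(g["start"]) - flank, 0), int(g["start"]))
            down = (int(g["end"]), int(g["end"]) + flank)
        else:
            up = (int(g["end"]), int(g["end"]) + flank)
            down = (max(int(g["start"]) - flank, 0), int(g["start"]))
        intervals.append(("upstream", g["chrom"], up[0], up[1]))
        intervals.append(("downstream", g["chrom"], down[0], down[1]))

    pos_by_chrom = {
        chrom: (sub["pos"].to_numpy(), sub["m"].to_numpy(),
                sub["n"].to_numpy())
        for chrom, sub in counts.groupby("chrom", sort=False)
    }
    agg: dict[str, list[float]] = {}
    for feature, chrom, start, end in intervals:
        rec = agg.setdefault(feature, [0.0, 0.0, 0.0, 0.0])
        rec[3] += max(end - start, 0)
        if chrom not in pos_by_chrom:
            continue
        pos, m, n = pos_by_chrom[chrom]
        sel = (pos >= start) & (pos < end)
        rec[0] += m[sel].sum()
        rec[1] += n[sel].sum()
        rec[2] += int(sel.sum())

    def _order(name: str) -> tuple:
        if name == "upstream":
            return (0, 0)
        if name == "downstream":
            return (3, 0)
        kind, rank = name.split("_")
        return ((1, int(rank)) if kind == "exon" else (2, int(rank)))

    rows = []
    for feature in sorted(agg, key=_order):
        m, n, k, bp = agg[feature]
        rows.append((feature, m, n, m / n if n > 0 else np.nan, int(k), bp,
                     k / bp if bp > 0 else np.nan))
    return pd.DataFrame(
        rows, columns=["feature", "m", "n", "level", "n_cpgs", "bp",
                       "cpg_density"])
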