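"""Fixed-window differential-methylation calling between two groups.

Retained CpGs are pooled into non-overlapping 200 bp tiles and each
tile is tested for a group difference in methylation with a binomial
logistic-regression likelihood-ratio test (equivalently a G-test on
the coverage-pooled group counts, which is the maximum-likelihood fit
of a group-only logistic model to replicated binomial counts — the
behaviour of the widely used methylKit-style caller). A two-sided
Fisher exact test on the pooled 2x2 table is available as an
alternative backend and small-sample oracle.

A window is a DMR when its Benjamini-Hochberg q-value is below 0.01
and the group methylation difference is at least 5 percentage points.
The difference is coverage-weighted (pooled "care" level minus pooled
"no-care" level, times 100); positive means higher in "care".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from methperm.windows import WINDOW_SIZE

DEFAULT_MAX_COVERAGE = 170
DEFAULT_MIN_CPG = 2
DEFAULT_Q = 0.01
DEFAULT_MIN_DIFF = 5.0


def filter_sites(
    calls_by_sample: dict[str, pd.DataFrame],
    max_coverage: int = DEFAULT_MAX_COVERAGE,
) -> pd.DataFrame:
    """Apply the pre-window site filters and align samples.

    Keeps merged CpGs that are

    * significantly methylated (per-site call) in at least one sample
      — background noise from fully unmethylated sites carries no
      differential signal;
    * covered (n >= 1) in every sample — a site missing from a sample
      is treated as coverage 0;
    * covered at most ``max_coverage`` in every sample — extreme
      coverage flags PCR duplicates/artifacts.

    Parameters
    ----------
    calls_by_sample
        sample_id -> per-site call frame from
        :func:`methperm.core.call_site_methylation` (merged sites,
        columns ``chrom, pos, m, n, methylated``).

    Returns
    -------
    Wide frame indexed by (chrom, pos) with columns ``m_<sid>`` and
    ``n_<sid>`` for every sample.

    Raises
    ------
    ValueError
        If the samples share no sites at all (disjoint universes point
        to an upstream coordinate mismatch, not to missing coverage).
    """
    sample_ids = list(calls_by_sample)
    if not sample_ids:
        raise ValueError("no samples given")

    frames = []
    for sid in sample_ids:
        df = calls_by_sample[sid]
        f = df.set_index(["chrom", "pos"])[["m", "n", "methylated"]]
        f.columns = [f"m_{sid}", f"n_{sid}", f"sig_{sid}"]
        frames.append(f)
    wide = pd.concat(frames, axis=1, join="outer")

    covered_any = ~wide[[f"n_{s}" for s in sample_ids]].isna()
    if not covered_any.all(axis=1).any() and len(wide):
        raise ValueError("sample site universes are disjoint")

    for sid in sample_ids:
        wide[f"m_{sid}"] = wide[f"m_{sid}"].fillna(0).astype(int)
        wide[f"n_{sid}"] = wide[f"n_{sid}"].fillna(0).astype(int)
        wide[f"sig_{sid}"] = (
            wide[f"sig_{sid}"].astype("boolean").fillna(False).astype(bool))

    n_mat = wide[[f"n_{s}" for s in sample_ids]].to_numpy()
    sig_mat = wide[[f"sig_{s}" for s in sample_ids]].to_numpy()
    keep = sig_mat.any(axis=1) & (n_mat.min(axis=1) >= 1) \
        & (n_mat.max(axis=1) <= max_coverage)
    out = wide.loc[keep, [c for s in sample_ids
                          for c in (f"m_{s}", f"n_{s}")]]
    return out.sort_index()


def bin_windows(
    filtered: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    min_cpg: int = DEFAULT_MIN_CPG,
) -> pd.DataFrame:
    """Pool retained CpGs into fixed tiles; drop sparse tiles.

    The tile of position ``p`` is ``[floor(p/w)*w, floor(p/w)*w + w)``
    (half-open, so a CpG at exactly a boundary belongs to the tile
    starting there). Tiles with fewer than ``min_cpg`` retained CpGs
    are removed; per-sample ``m`` and ``n`` are summed within tiles.
    """
    if filtered.empty:
        cols = ["chrom", "start", "end", "cpg_count"] + list(filtered.columns)
        return pd.DataFrame(columns=cols)
    df = filtered.reset_index()
    df["start"] = (df["pos"] // window_size) * window_size
    count_cols = [c for c in filtered.columns]
    grouped = df.groupby(["chrom", "start"], as_index=False).agg(
        **{c: (c, "sum") for c in count_cols},
        cpg_count=("pos", "size"),
    )
    grouped = grouped[grouped["cpg_count"] >= min_cpg].reset_index(drop=True)
    grouped.insert(2, "end", grouped["start"] + window_size)
    return grouped[["chrom", "start", "end", "cpg_count"] + count_cols]


def _binom_loglik(m: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood up to the constant binomial coefficient."""
    return xlogy(m, p) + xlogy(n - m, 1.0 - p)


def test_windows(
    windows: pd.DataFrame,
    groups: dict[str, str],
    backend: str = "glm",
) -> pd.DataFrame:
    """Test every window for a group difference in methylation.

    ``groups`` maps each sample_id (matching the ``m_<sid>``/``n_<sid>``
    columns) to one of exactly two labels; the label ``"care"`` (or,
    failing that, the lexicographically first label) is the reference
    whose excess methylation counts as positive ``diff``.

    Backends
    --------
    ``glm``
        Likelihood-ratio test of a binomial logistic regression of
        per-sample (m, n) on group membership. With a group-only
        design the MLE pools coverage within groups, so the statistic
        is the 2x2 G-statistic on pooled counts with a chi-square(1)
        reference.
    ``fisher``
        Two-sided Fisher exact test on the pooled 2x2 table.

    Windows where either group has zero total coverage are untested
    (``p_value`` NaN) and must be excluded from the FDR family.

    Returns the input frame plus ``level_care, level_nocare, diff,
    p_value`` (diff in percentage points, positive = higher in care).
    """
    sample_ids = sorted({c[2:] for c in windows.columns if c.startswith("m_")})
    if set(groups) != set(sample_ids):
        raise ValueError("group labels do not match window sample columns")
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    ref = "care" if "care" in labels else labels[0]
    other = [l for l in labels if l != ref][0]
    care_ids = [s for s in sample_ids if groups[s] == ref]
    nocare_ids = [s for s in sample_ids if groups[s] == other]

    mc = windows[[f"m_{s}" for s in care_ids]].to_numpy().sum(axis=1)
    nc = windows[[f"n_{s}" for s in care_ids]].to_numpy().sum(axis=1)
    mo = windows[[f"m_{s}" for s in nocare_ids]].to_numpy().sum(axis=1)
    no = windows[[f"n_{s}" for s in nocare_ids]].to_numpy().sum(axis=1)

    testable = (nc > 0) & (no > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_care = np.where(nc > 0, mc / np.maximum(nc, 1), np.nan)
        p_no = np.where(no > 0, mo / np.maximum(no, 1), np.nan)
    diff = 100.0 * (p_care - p_no)

    p_value = np.full(len(windows), np.nan)
    if backend == "glm":
        p_all = np.where(nc + no > 0, (mc + mo) / np.maximum(nc + no, 1), 0.0)
        ll_alt = (_binom_loglik(mc, nc, np.where(nc > 0, p_care, 0.5))
                  + _binom_loglik(mo, no, np.where(no > 0, p_no, 0.5)))
        ll_null = _binom_loglik(mc + mo, nc + no, p_all)
        lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
        p_value[testable] = stats.chi2.sf(lrt[testable], df=1)
    elif backend == "fisher":
        for i in np.flatnonzero(testable):
            table = [[int(mc[i]), int(nc[i] - mc[i])],
                     [int(mo[i]), int(no[i] - mo[i])]]
            p_value[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    else:
        raise ValueError(f"unknown backend {backend!r}")

    out = windows.copy()
    out["level_care"] = p_care
    out["level_nocare"] = p_no
    out["diff"] = diff
    out["p_value"] = p_value
    return out


def test_window(
    counts: pd.DataFrame,
    groups: dict[str, str],
    backend: str = "glm",
) -> tuple[float, float]:
    """Test a single window; ``counts`` has columns sample_id, m, n.

    Returns ``(p_value, diff)`` with the same conventions as
    :func:`test_windows`.
    """
    row = {}
    for _, r in counts.iterrows():
        row[f"m_{r['sample_id']}"] = [int(r["m"])]
        row[f"n_{r['sample_id']}"] = [int(r["n"])]
    res = test_windows(pd.DataFrame(row), groups, backend=backend)
    return float(res["p_value"].iloc[0]), float(res["diff"].iloc[0])


def call_dmrs(
    tested: pd.DataFrame,
    q_threshold: float = DEFAULT_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
) -> pd.DataFrame:
    """Flag DMRs after FDR correction over the tested windows.

    BH correction is applied to the family of *tested* windows only
    (untested windows keep NaN q and are never DMRs). A window is a
    DMR iff ``q < q_threshold`` and ``|diff| >= min_diff`` percentage
    points.
    """
    out = tested.copy()
    out["q_value"] = np.nan
    tested_mask = out["p_value"].notna()
    if tested_mask.any():
        out.loc[tested_mask, "q_value"] = multipletests(
            out.loc[tested_mask, "p_value"], method="fdr_bh")[1]
    out["is_dmr"] = (
        (out["q_value"] < q_threshold)
        & (out["diff"].abs() >= min_diff)
    ).fillna(False)
    return out


def dmr_summary(dmrs: pd.DataFrame) -> dict:
    """Headline counts: DMR total and hypermethylation bias."""
    hits = dmrs[dmrs["is_dmr"]]
    n = int(len(hits))
    return {
        "n_windows_tested": int(dmrs["p_value"].notna().sum()),
        "n_dmrs": n,
        "frac_hyper_care": float((hits["diff"] > 0).mean()) if n else np.nan,
    }


def annotate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach the list of genes whose span intersects each window.

    Both sides use 0-based half-open intervals; any non-empty
    intersection counts. A window may hit zero genes (intergenic) or
    several (explaining gene tallies exceeding DMR tallies).
    """
    gene_ids_col = []
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    for _, w in dmrs.iterrows():
        g = by_chrom.get(w["chrom"])
        if g is None:
            gene_ids_col.append([])
            continue
        hit = g[(g["start"] < w["end"]) & (g["end"] > w["start"])]
        gene_ids_col.append(sorted(hit["gene_id"]))
    out = dmrs.copy()
    out["gene_ids"] = gene_ids_col
    return out


def differentially_methylated_genes(annotated: pd.DataFrame) -> set[str]:
    """Union of genes touched by any flagged DMR."""
    out: set[str] = set()
    for _, w in annotated[annotated["is_dmr"]].iterrows():
        out.update(w["gene_ids"])
    return out


def run_dmr_analysis(
    counts_by_sample: dict[str, pd.DataFrame],
    groups: dict[str, str],
    epsilon: float,
    site_alpha: float = 0.05,
    max_coverage: int = DEFAULT_MAX_COVERAGE,
    window_size: int = WINDOW_SIZE,
    min_cpg: int = DEFAULT_MIN_CPG,
    q_threshold: float = DEFAULT_Q,
    min_diff: float = DEFAULT_MIN_DIFF,
    backend: str = "glm",
    lambda_chrom: str = "lambda",
) -> pd.DataFrame:
    """End-to-end DMR calling from stranded count frames.

    Per sample: drop the spike-in chromosome, merge strands, call
    per-site methylation at ``site_alpha`` against ``epsilon``; then
    filter sites, tile into windows, test, correct, and flag DMRs.
    Returns the full window table from :func:`call_dmrs`.
    """
    from methperm.core import call_site_methylation, merge_strands

    calls = {}
    for sid, df in counts_by_sample.items():
        genome = df[df["chrom"] != lambda_chrom]
        merged = merge_strands(genome[["chrom", "pos", "strand", "m", "n"]])
        calls[sid] = call_site_methylation(merged, epsilon, alpha=site_alpha)

    filtered = filter_sites(calls, max_coverage=max_coverage)
    windows = bin_windows(filtered, window_size=window_size, min_cpg=min_cpg)
    tested = test_windows(windows, groups, backend=backend)
    return call_dmrs(tested, q_threshold=q_threshold, min_diff=min_diff)
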