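"""Synthetic bisulfite methylomes with known ground truth.

The generator emulates the statistical structure of a hymenopteran
head methylome assayed by whole-genome bisulfite sequencing:

* sparse, mosaic CpG methylation confined almost entirely to gene
  bodies, with levels decaying from the 5' end of the gene;
* per-strand read coverage drawn from a negative binomial whose mean
  corresponds to ~30X per strand-merged CpG;
* a small bisulfite nonconversion error that makes truly unmethylated
  cytosines read as methylated at rate ``epsilon``;
* an unmethylated lambda-phage spike-in emitted as a pseudo-chromosome
  named ``"lambda"`` for estimating that error;
* a balanced two-group design (default 3 "care" vs 3 "no-care"
  replicates) with an optional set of planted differentially
  methylated 200 bp windows of known effect size.

Every quantity the downstream pipeline estimates (nonconversion rate,
per-CpG methylation probability, DMR locations and effect sizes,
methylated-gene membership, methylation-expression rank correlation)
is available as ground truth, so parameter-recovery tests can score
the pipeline against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from methperm.windows import WINDOW_SIZE

# fixed gene architecture used by the annotation generator (bp)
EXON_LENGTH = 200
INTRON_LENGTH = 100
MIN_INTERGENIC_GAP = 200

CARE = "care"
NOCARE = "nocare"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-methylome generator.

    Probabilities are in [0, 1]; lengths and counts are in bp / units.
    ``coverage_mean`` is the expected total (strand-merged) read depth
    per CpG; each strand receives half of it on average.
    ``coverage_dispersion`` is the negative-binomial overdispersion
    ``alpha`` (variance = mu + alpha * mu^2); 0 gives Poisson coverage.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 500_000
    n_genes: int = 100
    exons_per_gene: int = 5
    cpg_density: float = 0.02
    n_samples_per_group: int = 3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.2
    nonconversion_rate: float = 0.005
    frac_methylated_genes: float = 0.3
    methylated_level: float = 0.7
    five_prime_decay: float = 0.7
    n_true_dmrs: int = 0
    dmr_delta: float = 0.2
    dmr_frac_hyper_care: float = 0.84
    overlap_odds_ratio: float = 1.0
    set_fraction: float = 0.1
    expression_rho: float = 0.24
    n_lambda_sites: int = 5_000
    # optional per-sample beta jitter of pi; None = no biological variance
    pi_jitter_concentration: Optional[float] = None

    def validate(self) -> None:
        probs = {
            "cpg_density": self.cpg_density,
            "nonconversion_rate": self.nonconversion_rate,
            "frac_methylated_genes": self.frac_methylated_genes,
            "methylated_level": self.methylated_level,
            "five_prime_decay": self.five_prime_decay,
            "dmr_delta": self.dmr_delta,
            "dmr_frac_hyper_care": self.dmr_frac_hyper_care,
            "set_fraction": self.set_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_chromosomes", "chrom_length", "exons_per_gene",
                     "n_samples_per_group", "n_lambda_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_true_dmrs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be non-negative")
        if self.overlap_odds_ratio < 0:
            raise ValueError("overlap_odds_ratio must be non-negative")
        if abs(self.expression_rho) > 1:
            raise ValueError("expression_rho must be in [-1, 1]")
        if (self.pi_jitter_concentration is not None
                and self.pi_jitter_concentration <= 0):
            raise ValueError("pi_jitter_concentration must be positive")

    def sample_ids(self) -> list[str]:
        g = self.n_samples_per_group
        return ([f"{CARE}_{i + 1}" for i in range(g)]
                + [f"{NOCARE}_{i + 1}" for i in range(g)])

    def group_labels(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Annotation:
    """Gene and exon models plus the CpG position list.

    Coordinates are 0-based, half-open. ``cpgs['pos']`` is the position
    of the plus-strand cytosine of each CpG dinucleotide; the
    minus-strand cytosine of the same dinucleotide sits at ``pos + 1``.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    exons: pd.DataFrame  # gene_id, chrom, start, end, rank
    cpgs: pd.DataFrame   # chrom, pos

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


@dataclass
class GroundTruth:
    """Per-CpG and per-gene methylation truth of one simulated study."""

    cpg_truth: pd.DataFrame   # chrom, pos, gene_id, exon_rank, pi_care, pi_nocare
    dmr_windows: pd.DataFrame  # chrom, start, end, delta (signed, care - nocare)
    gene_truth: pd.DataFrame   # gene_id, gene_pi, is_methylated

    @property
    def true_methylated_genes(self) -> set[str]:
        g = self.gene_truth
        return set(g.loc[g["is_methylated"], "gene_id"])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams keyed on (seed, stream) so each stage is
    # reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out non-overlapping gene models and place CpG sites.

    Genes are placed at jittered regular intervals along each
    chromosome, alternating strand, each with ``exons_per_gene`` exons
    of ``EXON_LENGTH`` bp separated by ``INTRON_LENGTH`` bp introns.
    CpG plus-strand cytosines are dropped independently per position
    (Bernoulli at ``cpg_density``), matching the roughly uniform CpG
    landscape of an AT-rich insect genome.

    Raises
    ------
    ValueError
        If ``n_genes`` cannot be placed without overlap on the
        configured chromosomes.
    """
    config.validate()
    rng = _rng(config, 0)

    gene_len = (config.exons_per_gene * EXON_LENGTH
                + (config.exons_per_gene - 1) * INTRON_LENGTH)

    # round-robin allocation of genes to chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    for i in range(config.n_genes):
        per_chrom[i % config.n_chromosomes] += 1

    slot = gene_len + MIN_INTERGENIC_GAP
    if per_chrom.max(initial=0) * slot > config.chrom_length:
        raise ValueError(
            f"cannot place {per_chrom.max()} genes of {gene_len} bp with "
            f"{MIN_INTERGENIC_GAP} bp gaps on a {config.chrom_length} bp "
            f"chromosome"
        )

    gene_rows, exon_rows = [], []
    gidx = 0
    for chrom, n_on_chrom in zip(chrom_names, per_chrom):
        if n_on_chrom == 0:
            continue
        pitch = config.chrom_length // n_on_chrom
        jitter_span = max(pitch - slot, 1)
        for j in range(n_on_chrom):
            start = j * pitch + int(rng.integers(0, jitter_span))
            strand = "+" if gidx % 2 == 0 else "-"
            gene_id = f"g{gidx + 1:05d}"
            gene_rows.append((gene_id, chrom, start, start + gene_len, strand))
            for r in range(config.exons_per_gene):
                es = start + r * (EXON_LENGTH + INTRON_LENGTH)
                exon_rows.append((gene_id, chrom, es, es + EXON_LENGTH, r + 1))
            gidx += 1

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "chrom", "start", "end", "rank"]
    )

    cpg_frames = []
    for chrom in chrom_names:
        # the minus-strand G needs pos + 1 < chrom_length
        hits = np.flatnonzero(
            rng.random(config.chrom_length - 1) < config.cpg_density
        )
        cpg_frames.append(pd.DataFrame({"chrom": chrom, "pos": hits}))
    cpgs = pd.concat(cpg_frames, ignore_index=True)

    return Annotation(genes=genes, exons=exons, cpgs=cpgs)


def _assign_cpgs_to_features(annotation: Annotation) -> pd.DataFrame:
    """Per CpG: containing gene (or NA) and exon rank (0 for intronic)."""
    cpgs = annotation.cpgs.copy()
    cpgs["gene_id"] = pd.NA
    cpgs["exon_rank"] = 0

    for chrom, sub in cpgs.groupby("chrom", sort=False):
        genes_c = annotation.genes[annotation.genes["chrom"] == chrom]
        if genes_c.empty:
            continue
        pos = sub["pos"].to_numpy()
        starts = genes_c["start"].to_numpy()
        ends = genes_c["end"].to_numpy()
        # genes are non-overlapping and sorted by construction
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        gene_for = np.where(inside, genes_c["gene_id"].to_numpy()[idx], None)
        cpgs.loc[sub.index[inside], "gene_id"] = gene_for[inside]

        exons_c = annotation.exons[annotation.exons["chrom"] == chrom]
        if not exons_c.empty:
            es = exons_c["start"].to_numpy()
            ee = exons_c["end"].to_numpy()
            er = exons_c["rank"].to_numpy()
            order = np.argsort(es)
            es, ee, er = es[order], ee[order], er[order]
            eidx = np.searchsorted(es, pos, side="right") - 1
            in_exon = (eidx >= 0) & (pos < ee[np.clip(eidx, 0, None)])
            cpgs.loc[sub.index[in_exon], "exon_rank"] = er[eidx[in_exon]]
    return cpgs


# per-gene beta concentrations for the true gene-body level; methylated
# genes sit around `methylated_level`, unmethylated genes near zero but
# strictly positive so gene-level truth is continuous (real gene-body
# levels are never exactly tied at zero either)
_METH_GENE_CONCENTRATION = 30.0
_UNMETH_GENE_MEAN = 0.005
_UNMETH_GENE_CONCENTRATION = 200.0
_INTRON_FACTOR = 0.3


def generate_truth(annotation: Annotation,
                   config: SimulationConfig) -> GroundTruth:
    """Draw the true methylation state of every CpG in both groups.

    A fraction ``frac_methylated_genes`` of genes is methylated; their
    gene-body level is beta-distributed around ``methylated_level``.
    Exonic CpGs in exon rank ``r`` carry ``gene_pi * decay^(r-1)``
    (geometric 5' decay); intronic CpGs carry a reduced level;
    intergenic CpGs are unmethylated apart from the tiny residual of
    their beta draw's gene-free baseline (zero).

    Planted DMR windows are 200 bp tiles wholly inside methylated-gene
    spans with at least two CpGs; within them the two groups differ by
    exactly ``dmr_delta``, hypermethylated in "care" for a
    ``dmr_frac_hyper_care`` share of windows.
    """
    config.validate()
    rng = _rng(config, 1)

    cpgs = _assign_cpgs_to_features(annotation)
    gene_ids = annotation.gene_ids
    n_meth = int(round(config.frac_methylated_genes * len(gene_ids)))
    meth_genes = set(
        rng.choice(gene_ids, size=n_meth, replace=False)) if n_meth else set()

    m = config.methylated_level
    gene_pi = {}
    for gid in gene_ids:
        if gid in meth_genes:
            a = m * _METH_GENE_CONCENTRATION
            b = (1 - m) * _METH_GENE_CONCENTRATION
        else:
            a = _UNMETH_GENE_MEAN * _UNMETH_GENE_CONCENTRATION
            b = (1 - _UNMETH_GENE_MEAN) * _UNMETH_GENE_CONCENTRATION
        gene_pi[gid] = float(rng.beta(a, b))

    gene_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "gene_pi": [gene_pi[g] for g in gene_ids],
        "is_methylated": [g in meth_genes for g in gene_ids],
    })

    pi = np.zeros(len(cpgs))
    in_gene = cpgs["gene_id"].notna()
    gp = cpgs.loc[in_gene, "gene_id"].map(gene_pi).to_numpy(dtype=float)
    rank = cpgs.loc[in_gene, "exon_rank"].to_numpy()
    decay = np.where(rank > 0,
                     config.five_prime_decay ** (np.maximum(rank, 1) - 1),
                     _INTRON_FACTOR)
    pi[in_gene.to_numpy()] = gp * decay

    pi_care = pi.copy()
    pi_nocare = pi.copy()

    # plant DMR windows inside methylated genes
    dmr_rows = []
    if config.n_true_dmrs > 0:
        meth_gene_df = annotation.genes[
            annotation.genes["gene_id"].isin(meth_genes)]
        candidates = []
        for _, g in meth_gene_df.iterrows():
            w0 = -(-g["start"] // WINDOW_SIZE)  # first window fully inside
            w1 = g["end"] // WINDOW_SIZE        # one past the last
            for w in range(int(w0), int(w1)):
                candidates.append((g["chrom"], w * WINDOW_SIZE))
        # keep windows holding >= 2 CpGs so they are callable at all
        cpg_key = cpgs.assign(win=cpgs["pos"] // WINDOW_SIZE)
        win_counts = cpg_key.groupby(["chrom", "win"]).size()
        candidates = [
            (c, s) for (c, s) in candidates
            if win_counts.get((c, s // WINDOW_SIZE), 0) >= 2
        ]
        if len(candidates) < config.n_true_dmrs:
            raise ValueError(
                f"only {len(candidates)} candidate windows inside methylated "
                f"genes; cannot plant {config.n_true_dmrs} DMRs — enlarge the "
                f"genome or raise frac_methylated_genes"
            )
        pick = rng.choice(len(candidates), size=config.n_true_dmrs,
                          replace=False)
        delta = config.dmr_delta
        chrom_arr = cpgs["chrom"].to_numpy()
        pos_arr = cpgs["pos"].to_numpy()
        for i in sorted(pick):
            chrom, start = candidates[i]
            mask = ((chrom_arr == chrom) & (pos_arr >= start)
                    & (pos_arr < start + WINDOW_SIZE))
            hyper_care = rng.random() < config.dmr_frac_hyper_care
            base = np.minimum(pi[mask], 1.0 - delta)
            if hyper_care:
                pi_nocare[mask] = base
                pi_care[mask] = base + delta
                signed = delta
            else:
                pi_care[mask] = base
                pi_nocare[mask] = base + delta
                signed = -delta
            dmr_rows.append((chrom, start, start + WINDOW_SIZE, signed))

    cpg_truth = cpgs[["chrom", "pos", "gene_id", "exon_rank"]].copy()
    cpg_truth["pi_care"] = pi_care
    cpg_truth["pi_nocare"] = pi_nocare
    dmr_windows = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "delta"]
    )
    return GroundTruth(cpg_truth=cpg_truth, dmr_windows=dmr_windows,
                       gene_truth=gene_truth)


def _nb_coverage(rng: np.random.Generator, mean: float, dispersion: float,
                 size: int) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_methylomes(
    annotation: Annotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Draw stranded per-CpG count tables for every sample.

    For each sample and strand, coverage is negative-binomial with mean
    ``coverage_mean / 2`` and dispersion ``coverage_dispersion``; the
    methylated count is ``Binomial(coverage, pi + (1 - pi) * epsilon)``
    where ``epsilon`` is the nonconversion rate. Lambda spike-in sites
    (``pi = 0``) are appended on pseudo-chromosome ``"lambda"``.

    Returns a dict sample_id -> DataFrame with columns
    ``chrom, pos, strand, m, n`` (0-based plus-strand-C coordinates;
    the minus-strand record of a CpG sits at ``pos + 1``).
    """
    config.validate()
    eps = config.nonconversion_rate
    half_mean = config.coverage_mean / 2.0
    labels = config.group_labels()

    ct = truth.cpg_truth
    chrom = ct["chrom"].to_numpy()
    pos = ct["pos"].to_numpy()
    n_cpg = len(ct)

    out: dict[str, pd.DataFrame] = {}
    for k, sid in enumerate(config.sample_ids()):
        rng = _rng(config, 1000 + k)
        pi = (ct["pi_care"] if labels[sid] == CARE
              else ct["pi_nocare"]).to_numpy()
        if config.pi_jitter_concentration is not None:
            c = config.pi_jitter_concentration
            interior = (pi > 0) & (pi < 1)
            jit = pi.copy()
            jit[interior] = rng.beta(c * pi[interior],
                                     c * (1 - pi[interior]))
            pi = jit
        p_obs = pi + (1.0 - pi) * eps

        frames = []
        for strand, offset in (("+", 0), ("-", 1)):
            cov = _nb_coverage(rng, half_mean, config.coverage_dispersion,
                               n_cpg)
            meth = rng.binomial(cov, p_obs)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos + offset, "strand": strand,
                "m": meth, "n": cov,
            }))

        lam_pos = np.arange(config.n_lambda_sites) * 2
        lam_cov = _nb_coverage(rng, half_mean, config.coverage_dispersion,
                               config.n_lambda_sites)
        lam_m = rng.binomial(lam_cov, eps)
        frames.append(pd.DataFrame({
            "chrom": "lambda", "pos": lam_pos, "strand": "+",
            "m": lam_m, "n": lam_cov,
        }))

        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["chrom", "pos", "strand"],
                            kind="stable").reset_index(drop=True)
        df["sample_id"] = sid
        out[sid] = df
    return out


def _conditional_membership_probs(p_marginal: float,
                                  p_given: float,
                                  odds_ratio: float) -> tuple[float, float]:
    """Solve P(B|A) and P(B|not A) for a target odds ratio and marginal."""
    if odds_ratio == 1.0:
        return p_marginal, p_marginal

    def gap(p0: float) -> float:
        o0 = p0 / (1 - p0)
        p1 = odds_ratio * o0 / (1 + odds_ratio * o0)
        return p_given * p1 + (1 - p_given) * p0 - p_marginal

    lo, hi = 1e-12, 1 - 1e-12
    p0 = optimize.brentq(gap, lo, hi)
    o0 = p0 / (1 - p0)
    p1 = odds_ratio * o0 / (1 + odds_ratio * o0)
    return p1, p0


def generate_gene_sets(
    annotation: Annotation,
    config: SimulationConfig,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Draw correlated gene sets and splice-event intervals.

    Three sets over the gene universe — differentially expressed
    ("DE"), alternatively spliced ("AS") and positively selected
    ("selection") — each with marginal membership ``set_fraction``.
    AS and selection membership are drawn conditionally on DE so that
    each pairwise 2x2 table has expected odds ratio
    ``overlap_odds_ratio`` against DE.

    Splice events: one random exon sub-interval per AS gene, with an
    event type drawn from the usual catalogue (differential exon
    usage, skipped exon, retained intron, alt 5'/3', mutually
    exclusive exons), returned as a BED-like frame.
    """
    config.validate()
    if config.overlap_odds_ratio < 0:
        raise ValueError("overlap_odds_ratio must be non-negative")
    rng = _rng(config, 2)
    genes = annotation.gene_ids
    n = len(genes)
    if n == 0:
        raise ValueError("gene universe is empty")
    p = config.set_fraction

    if p == 0:
        de = np.zeros(n, dtype=bool)
        as_ = np.zeros(n, dtype=bool)
        sel = np.zeros(n, dtype=bool)
    else:
        de = rng.random(n) < p
        p1, p0 = _conditional_membership_probs(p, de.mean() if de.any() else p,
                                               config.overlap_odds_ratio)
        as_ = rng.random(n) < np.where(de, p1, p0)
        sel = rng.random(n) < np.where(de, p1, p0)

    sets = {
        "DE": {g for g, keep in zip(genes, de) if keep},
        "AS": {g for g, keep in zip(genes, as_) if keep},
        "selection": {g for g, keep in zip(genes, sel) if keep},
    }

    event_types = ["differential-exon-usage", "skipped-exon",
                   "retained-intron", "alt-5prime", "alt-3prime",
                   "mutually-exclusive"]
    rows = []
    exon_groups = dict(iter(annotation.exons.groupby("gene_id", sort=False)))
    for gid in sorted(sets["AS"]):
        ex = exon_groups.get(gid)
        if ex is None or ex.empty:
            continue
        e = ex.iloc[int(rng.integers(0, len(ex)))]
        lo = int(e["start"]); hi = int(e["end"])
        length = int(rng.integers(20, hi - lo + 1))
        start = lo + int(rng.integers(0, hi - lo - length + 1))
        rows.append((e["chrom"], start, start + length, gid,
                     event_types[int(rng.integers(0, len(event_types)))]))
    events = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "event_type"]
    )
    return sets, events


def generate_expression(
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-gene expression with a target Spearman correlation to truth.

    Uses a Gaussian copula on the ranks of the true gene-body
    methylation level: the Pearson correlation of the latent normals
    is set to ``2 sin(pi * rho / 6)`` so the realized Spearman
    correlation approximates ``expression_rho``. ``rho = +/-1`` yields
    an exact monotone copy.
    """
    config.validate()
    rho = config.expression_rho
    if abs(rho) > 1:
        raise ValueError("expression_rho must be in [-1, 1]")
    rng = _rng(config, 3)
    gt = truth.gene_truth
    x = gt["gene_pi"].to_numpy()
    n = len(x)
    if n == 0:
        return pd.DataFrame(columns=["gene_id", "expression"])

    if rho == 1.0:
        expr = x.copy()
    elif rho == -1.0:
        expr = -x
    else:
        ranks = stats.rankdata(x, method="average")
        z = stats.norm.ppf((ranks - 0.5) / n)
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        expr = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return pd.DataFrame({"gene_id": gt["gene_id"], "expression": expr})
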