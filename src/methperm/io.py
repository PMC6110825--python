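"""File-format boundaries: GFF3 gene models, BED events, gene lists.

Internally everything is 0-based half-open; GFF3 (1-based closed) and
the cytosine report (1-based) are converted at read/write time. BED
is already 0-based half-open.
"""

from __future__ import annotations

import os

import pandas as pd

# BED score field encodes the splice-event type
EVENT_CODES = {
    "differential-exon-usage": 1,
    "skipped-exon": 2,
    "retained-intron": 3,
    "alt-5prime": 4,
    "alt-3prime": 5,
    "mutually-exclusive": 6,
}
EVENT_NAMES = {v: k for k, v in EVENT_CODES.items()}


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene/exon models as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tmethperm\tgene\t{g['start'] + 1}\t"
                f"{g['end']}\t.\t{g['strand']}\t.\tID={g['gene_id']}\n")
            sub = exons[exons["gene_id"] == g["gene_id"]].sort_values("rank")
            for _, e in sub.iterrows():
                fh.write(
                    f"{e['chrom']}\tmethperm\texon\t{e['start'] + 1}\t"
                    f"{e['end']}\t.\t{g['strand']}\t.\t"
                    f"ID={g['gene_id']}.e{int(e['rank'])};"
                    f"Parent={g['gene_id']};rank={int(e['rank'])}\n")


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene/exon models from GFF3 into 0-based half-open frames."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique")
    gene_rows, exon_rows = [], []
    for g in db.features_of_type("gene"):
        gene_rows.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
    for e in db.features_of_type("exon"):
        parent = e.attributes.get("Parent", [""])[0]
        rank = int(e.attributes.get("rank", ["0"])[0])
        exon_rows.append((parent, e.seqid, e.start - 1, e.end, rank))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "chrom", "start", "end", "rank"])
    return genes, exons


def write_gene_set(members, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(members):
            fh.write(f"{gid}\n")


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_events_bed(events: pd.DataFrame, path) -> None:
    """Splice events as BED6: name = gene_id, score = event-type code."""
    with open(path, "w") as fh:
        for _, e in events.iterrows():
            code = EVENT_CODES.get(e.get("event_type", ""), 0)
            fh.write(f"{e['chrom']}\t{e['start']}\t{e['end']}\t"
                     f"{e['gene_id']}\t{code}\t.\n")


def read_events_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"])
    df["event_type"] = df["score"].map(EVENT_NAMES).fillna("unknown")
    return df[["chrom", "start", "end", "gene_id", "event_type"]]


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Flagged DMRs as BED6+; score = -log10 q (capped at 1000)."""
    import numpy as np

    with open(path, "w") as fh:
        hits = dmrs[dmrs["is_dmr"]] if "is_dmr" in dmrs.columns else dmrs
        for i, (_, w) in enumerate(hits.iterrows()):
            q = max(w.get("q_value", 1.0), 1e-300)
            score = min(-np.log10(q), 1000.0)
            fh.write(f"{w['chrom']}\t{w['start']}\t{w['end']}\t"
                     f"dmr_{i + 1}\t{score:.3f}\t.\n")


def write_dmr_table(dmrs: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "cpg_count", "level_care",
                        "level_nocare", "diff", "p_value", "q_value",
                        "is_dmr", "gene_ids") if c in dmrs.columns]
    out = dmrs[cols].copy()
    if "gene_ids" in out.columns:
        out["gene_ids"] = out["gene_ids"].map(
            lambda ids: ",".join(ids) if isinstance(ids, (list, tuple))
            else ids)
    out.to_csv(path, sep="\t", index=False)


def write_truth(truth, outdir) -> None:
    """Ground-truth sidecar TSVs for a simulated dataset."""
    os.makedirs(outdir, exist_ok=True)
    truth.cpg_truth.to_csv(
        os.path.join(outdir, "truth_cpgs.tsv"), sep="\t", index=False)
    truth.dmr_windows.to_csv(
        os.path.join(outdir, "truth_dmrs.tsv"), sep="\t", index=False)
    truth.gene_truth.to_csv(
        os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
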