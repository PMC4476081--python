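"""Turn significant SNPs into flanked genomic intervals and overlap genes.

Significant SNPs from either detector become closed 1-based intervals
[max(1, pos - flank), pos + flank] (default flank 0.25 Mb), overlapping or
book-ended intervals on a chromosome are merged, and every gene record from a
user-supplied GFF3 or BED file whose span intersects an interval by >= 1 bp is
reported.  Strand is ignored.  Cross-method concordance classifies each
chromosome as exact-overlap (a shared significant SNP), regional (nearest
signals within a proximity), or discordant.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dataset import DataError


def make_intervals(
    significant_snps: pd.DataFrame,
    flank_bp: int = 250_000,
    merge: bool = True,
    source: str = "",
) -> pd.DataFrame:
    """Per-SNP +/- flank intervals, optionally merged per chromosome.

    ``significant_snps`` needs ``chromosome``, a position column
    (``position_bp``, ``summit_bp`` or ``central_bp``) and ``snp_id`` (or
    ``summit_snp_id``/``central_snp_id``).  Returns a frame with chromosome,
    start_bp, end_bp (closed, clamped to >= 1), source and seed_snps.
    """
    if len(significant_snps) == 0:
        return pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "source", "seed_snps"]
        )
    pos_col = next(
        c for c in ("position_bp", "summit_bp", "central_bp")
        if c in significant_snps.columns
    )
    id_col = next(
        c for c in ("snp_id", "summit_snp_id", "central_snp_id")
        if c in significant_snps.columns
    )
    df = significant_snps[["chromosome", pos_col, id_col]].copy()
    df.columns = ["chromosome", "pos", "snp_id"]
    df["start_bp"] = (df["pos"] - flank_bp).clip(lower=1)
    df["end_bp"] = df["pos"] + flank_bp
    df = df.sort_values(["chromosome", "start_bp"], kind="stable")

    if not merge:
        out = df[["chromosome", "start_bp", "end_bp"]].copy()
        out["source"] = source
        out["seed_snps"] = df["snp_id"].map(lambda s: [s]).to_list()
        return out.reset_index(drop=True)

    rows = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        cur_start = cur_end = None
        seeds: list = []
        for r in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, seeds = r.start_bp, r.end_bp, [r.snp_id]
            elif r.start_bp <= cur_end + 1:  # overlapping or book-ended
                cur_end = max(cur_end, r.end_bp)
                seeds.append(r.snp_id)
            else:
                rows.append((chrom, cur_start, cur_end, source, seeds))
                cur_start, cur_end, seeds = r.start_bp, r.end_bp, [r.snp_id]
        rows.append((chrom, cur_start, cur_end, source, seeds))
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "source", "seed_snps"]
    )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene spans from GFF3 (feature type ``gene``, 1-based closed) or
    BED (0-based half-open, converted on read).

    Returns a frame with gene_id, gene_name, chromosome (as read, string),
    start_bp, end_bp in 1-based closed coordinates.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6), dtype={"chrom": str},
        )
        return pd.DataFrame(
            {
                "gene_id": bed["name"].fillna("."),
                "gene_name": bed["name"].fillna("."),
                "chromosome": bed["chrom"],
                "start_bp": bed["start"].astype(int) + 1,
                "end_bp": bed["end"].astype(int),
            }
        )
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2].lower() != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("gene_id", "."))
            rows.append(
                (gid, attrs.get("Name", gid), f[0], int(f[3]), int(f[4]))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chromosome", "start_bp", "end_bp"]
    )


def overlap_genes(intervals: pd.DataFrame, genes: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Genes intersecting the (merged) intervals by >= 1 bp.

    ``genes`` may be a frame from :func:`read_genes` or a GFF3/BED path.
    Chromosome names in the annotation are parsed with the same rules as the
    genotype readers; a mismatch (no annotation chromosome matches any
    interval chromosome while both are non-empty) raises a
    :class:`~sweepscan.dataset.DataError`.
    """
    from .io import parse_chromosome

    if not isinstance(genes, pd.DataFrame):
        genes = read_genes(genes)
    if len(intervals) == 0:
        return pd.DataFrame(
            columns=["gene_id", "gene_name", "chromosome", "gene_start_bp",
                     "gene_end_bp", "interval_start_bp", "interval_end_bp",
                     "source", "overlap_bp"]
        )
    genes = genes.assign(chrom_code=genes["chromosome"].map(parse_chromosome))
    if len(genes) and not set(genes["chrom_code"]) & set(intervals["chromosome"]):
        raise DataError(
            "no annotation chromosome matches the SNP map: "
            f"annotation has {sorted(set(genes['chromosome']))[:10]}, "
            f"intervals have {sorted(set(intervals['chromosome']))[:10]}"
        )

    trees: dict[int, IntervalTree] = {}
    for i, r in enumerate(intervals.itertuples(index=False)):
        # half-open tree coordinates: closed [s, e] -> [s, e+1)
        trees.setdefault(r.chromosome, IntervalTree()).addi(
            r.start_bp, r.end_bp + 1, i
        )
    rows = []
    for g in genes.itertuples(index=False):
        tree = trees.get(g.chrom_code)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(g.start_bp, g.end_bp + 1)):
            iv = intervals.iloc[hit.data]
            ov = min(g.end_bp, iv["end_bp"]) - max(g.start_bp, iv["start_bp"]) + 1
            rows.append(
                (g.gene_id, g.gene_name, g.chrom_code, g.start_bp, g.end_bp,
                 iv["start_bp"], iv["end_bp"], iv.get("source", ""), int(ov))
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chromosome", "gene_start_bp",
                 "gene_end_bp", "interval_start_bp", "interval_end_bp",
                 "source", "overlap_bp"],
    )
    return out.drop_duplicates(
        ["gene_id", "chromosome", "interval_start_bp", "interval_end_bp"]
    ).reset_index(drop=True)


def method_concordance(
    chart_snps: pd.DataFrame,
    varld_snps: pd.DataFrame,
    proximity_bp: int = 500_000,
) -> pd.DataFrame:
    """Per-chromosome agreement of the two detectors.

    ``exact`` = a shared significant SNP id (or identical position);
    ``regional`` = nearest significant SNPs within ``proximity_bp``;
    ``discordant`` = signals in at least one set but neither condition met;
    ``no_signal`` = neither detector flagged the chromosome.
    """
    def norm(df):
        if len(df) == 0:
            return pd.DataFrame(columns=["chromosome", "pos", "snp_id"])
        pos_col = next(
            c for c in ("position_bp", "summit_bp", "central_bp") if c in df.columns
        )
        id_col = next(
            c for c in ("snp_id", "summit_snp_id", "central_snp_id") if c in df.columns
        )
        out = df[["chromosome", pos_col, id_col]].copy()
        out.columns = ["chromosome", "pos", "snp_id"]
        return out

    a, b = norm(chart_snps), norm(varld_snps)
    chroms = sorted(set(a["chromosome"]) | set(b["chromosome"]))
    rows = []
    for chrom in chroms:
        ac = a[a["chromosome"] == chrom]
        bc = b[b["chromosome"] == chrom]
        if len(ac) == 0 and len(bc) == 0:
            status, d = "no_signal", np.nan
        elif len(ac) == 0 or len(bc) == 0:
            status, d = "discordant", np.nan
        elif set(ac["snp_id"]) & set(bc["snp_id"]) or (
            set(ac["pos"]) & set(bc["pos"])
        ):
            status, d = "exact", 0.0
        else:
            d = float(
                np.min(np.abs(ac["pos"].to_numpy()[:, None] - bc["pos"].to_numpy()))
            )
            status = "regional" if d <= proximity_bp else "discordant"
        rows.append((chrom, len(ac), len(bc), status, d))
    return pd.DataFrame(
        rows,
        columns=["chromosome", "n_chart_snps", "n_varld_snps", "status",
                 "min_distance_bp"],
    )


def intervals_to_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write merged intervals as BED (0-based half-open on write)."""
    with open(path, "w") as fh:
        for r in intervals.itertuples(index=False):
            name = ",".join(r.seed_snps) if isinstance(r.seed_snps, list) else str(r.seed_snps)
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
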