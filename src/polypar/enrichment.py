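"""TAS windows, region tabulation, gene tagging and over-representation tests.

Trait-associated SNPs (TASs) from a genome scan are expanded into windows of
a configurable size; genes overlapping the merged windows form the
"in-window" set, which is tested for over-representation of annotation terms
and of a DNA-repair gene list with one-sided Fisher's exact tests on the
gene-level 2x2 table. Gene tagging follows per-SNP rules: a gene counts as
tagged when >= 2 TAS windows overlap it (>= 3 for repair genes).

Coordinates are 0-based half-open throughout (BED convention); scan
positions arrive 1-based and are converted here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_windows",
    "tabulate_tas_regions",
    "genes_in_windows",
    "term_enrichment",
    "gene_tagging",
    "repair_gene_enrichment",
]


def _validate_genes(genes: pd.DataFrame) -> None:
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene table has start >= end records")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene table")


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_windows(
    tas: pd.DataFrame,
    size: int,
    chrom_sizes: dict[str, int] | None = None,
    merge: bool = True,
) -> pd.DataFrame:
    """Windows of ``size`` bp centered on each TAS (columns chrom, pos 1-based).

    Intervals are [pos - size/2, pos + size/2) on the 0-based axis, clipped
    at chromosome bounds when sizes are supplied, and merged by default so
    clustered TASs do not multiply-count genes.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if len(tas) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    half = size // 2
    center = tas["pos"].to_numpy(dtype=np.int64)
    out = pd.DataFrame(
        {
            "chrom": tas["chrom"].to_numpy(),
            "start": np.maximum(center - half, 0),
            "end": center + (size - half),
        }
    )
    if chrom_sizes:
        caps = out["chrom"].map(chrom_sizes)
        if caps.notna().any():
            out["end"] = np.minimum(out["end"], caps.fillna(np.inf)).astype(np.int64)
    return _merge_intervals(out) if merge else out.reset_index(drop=True)


def tabulate_tas_regions(
    tas: pd.DataFrame, region_size: int = 1_000_000, min_count: int = 5
) -> pd.DataFrame:
    """Fixed non-overlapping tiles of ``region_size`` per chromosome with
    their TAS counts; only tiles holding >= ``min_count`` TASs are reported.
    Each TAS is assigned to exactly one tile by position. An empty TAS list
    gives an empty table.
    """
    if len(tas) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_tas"])
    tile = (tas["pos"].to_numpy(dtype=np.int64) - 1) // region_size
    counts = (
        pd.DataFrame({"chrom": tas["chrom"].to_numpy(), "tile": tile})
        .value_counts()
        .rename("n_tas")
        .reset_index()
    )
    counts = counts[counts["n_tas"] >= min_count]
    out = pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "start": counts["tile"] * region_size,
            "end": (counts["tile"] + 1) * region_size,
            "n_tas": counts["n_tas"],
        }
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def genes_in_windows(
    genes: pd.DataFrame, windows: pd.DataFrame, mode: str = "any_overlap"
) -> pd.Series:
    """Boolean per gene: does it fall in any window?

    ``any_overlap`` counts a gene whose interval overlaps a window at all;
    ``contained`` requires the gene to lie fully inside one window.
    """
    _validate_genes(genes)
    flags = np.zeros(len(genes), dtype=bool)
    for chrom, win in windows.groupby("chrom"):
        gmask = (genes["chrom"] == chrom).to_numpy()
        if not gmask.any():
            continue
        gs = genes.loc[gmask, "start"].to_numpy()
        ge = genes.loc[gmask, "end"].to_numpy()
        hit = np.zeros(gmask.sum(), dtype=bool)
        for ws, we in zip(win["start"], win["end"]):
            if mode == "any_overlap":
                hit |= (gs < we) & (ge > ws)
            elif mode == "contained":
                hit |= (gs >= ws) & (ge <= we)
            else:
                raise ValueError(f"unknown overlap mode {mode!r}")
        flags[gmask] = hit
    return pd.Series(flags, index=genes["gene_id"].to_numpy(), name="in_window")


def _fisher_record(a: int, b: int, c: int, d: int) -> dict:
    """One-sided (over-representation) Fisher's exact test on the 2x2 table
    [[a, b], [c, d]] = [[in-window with, in-window without],
    [outside with, outside without]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = np.inf if a * d > 0 else 0.0
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": float(p)}


def term_enrichment(
    genes: pd.DataFrame,
    gene_terms: pd.DataFrame,
    in_window: pd.Series,
) -> pd.DataFrame:
    """Per-term over-representation of in-window genes.

    ``gene_terms`` maps gene_id -> term (long format). The gene universe is
    the full gene table; term assignments naming genes outside the universe
    are skipped. Raw one-sided Fisher p-values are reported alongside a
    Benjamini-Hochberg column (no correction is applied to the primary
    p-value).
    """
    _validate_genes(genes)
    universe = set(genes["gene_id"])
    n_universe = len(universe)
    inw = in_window.reindex(genes["gene_id"].to_numpy()).fillna(False)
    n_in = int(inw.sum())
    known = gene_terms[gene_terms["gene_id"].isin(universe)]
    rows = []
    for term, sub in known.groupby("term", sort=True):
        members = set(sub["gene_id"])
        a = int(inw[list(members)].sum())
        b = n_in - a
        c = len(members) - a
        d = n_universe - n_in - c
        rows.append({"term": term, **_fisher_record(a, b, c, d)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value").reset_index(drop=True)
    return out


def gene_tagging(
    genes: pd.DataFrame,
    tas: pd.DataFrame,
    window_size: int,
    general_min: int = 2,
    repair_min: int = 3,
) -> pd.DataFrame:
    """Per-gene TAS counts and tagged flags.

    A TAS tags a gene when the gene's interval overlaps that TAS's
    (unmerged) window. Tagging uses the per-SNP rule: a gene is tagged at
    >= ``general_min`` TASs generally, and a repair gene at >= ``repair_min``.
    """
    _validate_genes(genes)
    wins = build_windows(tas, window_size, merge=False)
    counts = np.zeros(len(genes), dtype=int)
    for chrom, win in wins.groupby("chrom"):
        gmask = (genes["chrom"] == chrom).to_numpy()
        if not gmask.any():
            continue
        gs = genes.loc[gmask, "start"].to_numpy()
        ge = genes.loc[gmask, "end"].to_numpy()
        sub = np.zeros(gmask.sum(), dtype=int)
        for ws, we in zip(win["start"], win["end"]):
            sub += ((gs < we) & (ge > ws)).astype(int)
        counts[gmask] = sub
    out = genes[["gene_id", "chrom", "start", "end"]].copy()
    out["n_tas"] = counts
    out["tagged"] = counts >= general_min
    out["tagged_repair_rule"] = counts >= repair_min
    return out


def repair_gene_enrichment(
    genes: pd.DataFrame,
    repair_genes: list[str] | set[str],
    in_window: pd.Series,
) -> dict:
    """Over-representation of the repair-gene list among in-window genes:
    2x2 over the gene universe (in-window x repair), one-sided Fisher."""
    _validate_genes(genes)
    repair = set(repair_genes)
    if not repair:
        raise ValueError("empty repair gene list")
    missing = repair - set(genes["gene_id"])
    if missing:
        raise ValueError(f"repair genes absent from the gene universe: {sorted(missing)[:5]}")
    inw = in_window.reindex(genes["gene_id"].to_numpy()).fillna(False)
    is_rep = genes["gene_id"].isin(repair).to_numpy()
    a = int((inw.to_numpy() & is_rep).sum())
    b = int((inw.to_numpy() & ~is_rep).sum())
    c = int((~inw.to_numpy() & is_rep).sum())
    d = int((~inw.to_numpy() & ~is_rep).sum())
    return _fisher_record(a, b, c, d)
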