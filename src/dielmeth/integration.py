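"""DMR-gene-expression integration and GO enrichment.

A gene is DMR-associated when a DMR overlaps its body or the 2000 bp
upstream/downstream flanks. The association zone is strand-aware; a DMR
straddling body and flank is zoned "body". GO enrichment is an
upper-tail hypergeometric test reported at raw p < 0.01 (a BH column is
emitted additionally, but the selection matches the uncorrected rule).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FLANK_BP
from .dmr import bh_adjust
from .expression import mannwhitney
from .genome import GenomeModel
from .profiles import _context_arrays, _feature_bin_counts, ZONES

LINK_COLUMNS = [
    "gene_id",
    "chrom",
    "dmr_start",
    "dmr_end",
    "context",
    "direction",
    "zone",
]


def link_dmrs_to_genes(
    dmrs: pd.DataFrame, genome: GenomeModel, flank: int = FLANK_BP
) -> pd.DataFrame:
    """All (gene, DMR) pairs whose intervals intersect within the gene
    body extended by ``flank`` bp on each side."""
    rows = []
    if len(dmrs) == 0 or len(genome.genes) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)
    by_chrom = {c: sub for c, sub in dmrs.groupby("chrom")}
    for g in genome.genes.itertuples():
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        env_s, env_e = g.start - flank, g.end + flank
        hits = sub[(sub["start"] < env_e) & (sub["end"] > env_s)]
        for d in hits.itertuples():
            if d.start < g.end and d.end > g.start:
                zone = "body"
            elif d.end <= g.start:
                zone = "upstream" if g.strand == "+" else "downstream"
            else:
                zone = "downstream" if g.strand == "+" else "upstream"
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "dmr_start": d.start,
                    "dmr_end": d.end,
                    "context": d.context,
                    "direction": d.direction,
                    "zone": zone,
                }
            )
    out = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return out.drop_duplicates(ignore_index=True)


def dmr_associated_degs(links: pd.DataFrame, deg_status: pd.Series) -> dict:
    """Cross-tabulate DMR-gene links against a DEG set.

    ``deg_status`` maps DEG gene ids to a direction label (e.g. 'up' /
    'down'). The headline fraction counts each DEG once regardless of
    how many DMRs it carries; the breakdown counts links per
    (zone x context x DEG direction) stratum.
    """
    degs = set(deg_status.index)
    linked_genes = set(links["gene_id"]) if len(links) else set()
    n_linked = len(degs & linked_genes)
    fraction = n_linked / len(degs) if degs else 0.0
    if len(links):
        deg_links = links[links["gene_id"].isin(degs)].copy()
        deg_links["de_direction"] = deg_links["gene_id"].map(deg_status)
        breakdown = (
            deg_links.groupby(["zone", "context", "de_direction"], observed=True)
            .size()
            .rename("n_links")
            .reset_index()
        )
    else:
        breakdown = pd.DataFrame(columns=["zone", "context", "de_direction", "n_links"])
    return {
        "n_degs": len(degs),
        "n_linked_degs": n_linked,
        "fraction": fraction,
        "breakdown": breakdown,
    }


def go_enrichment(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    go_map: pd.DataFrame,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric GO over-representation of a study set.

    p = P(X >= k) with X ~ Hypergeom(N population, K term genes,
    n study genes). Terms with raw p < ``p_cut`` are returned sorted by
    p; no multiple-testing correction is applied to the selection (a
    'q_value' BH column over all tested terms is provided alongside).
    """
    population = set(population_genes)
    study = set(study_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    gm = go_map[go_map["gene_id"].isin(population)]
    N, n = len(population), len(study)
    rows = []
    for go_id, genes in gm.groupby("go_id")["gene_id"]:
        term = set(genes)
        K = len(term)
        if K == 0:
            continue
        k = len(term & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append(
            {"go_id": go_id, "k": k, "n": n, "K": K, "N": N, "p_value": p, "ratio": ratio}
        )
    if not rows:
        return pd.DataFrame(
            columns=["go_id", "k", "n", "K", "N", "p_value", "ratio", "q_value"]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"])
    out = out[out["p_value"] < p_cut].sort_values("p_value", ignore_index=True)
    return out


def methylation_by_expression(
    region_levels: pd.DataFrame,
    strata: pd.Series,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    strata_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (stratum x region x context) summaries plus pairwise
    Mann-Whitney tests between strata.

    ``region_levels`` is the long table from
    :func:`dielmeth.profiles.region_level_table` (optionally several
    contexts concatenated); ``strata`` maps gene_id to a stratum label.
    Strata with fewer than two genes are flagged and skipped in tests.
    """
    lv = region_levels.copy()
    lv["stratum"] = lv["gene_id"].map(strata)
    lv = lv[lv["stratum"].notna()]
    order = (
        list(strata_order)
        if strata_order is not None
        else sorted(lv["stratum"].unique())
    )
    summary = (
        lv.groupby(["stratum", "region", "context"], observed=True)["level"]
        .agg(n="count", median="median")
        .reset_index()
    )
    test_rows = []
    for (region, ctx), sub in lv.groupby(["region", "context"], observed=True):
        groups = {
            s: sub.loc[sub["stratum"] == s, "level"].dropna().to_numpy()
            for s in order
        }
        for i, s1 in enumerate(order):
            for s2 in order[i + 1 :]:
                a, b = groups.get(s1, []), groups.get(s2, [])
                if len(a) < 2 or len(b) < 2:
                    p, skipped = np.nan, True
                else:
                    p, skipped = mannwhitney(a, b, "two-sided"), False
                test_rows.append(
                    {
                        "region": region,
                        "context": ctx,
                        "stratum_1": s1,
                        "stratum_2": s2,
                        "n_1": len(a),
                        "n_2": len(b),
                        "p_value": p,
                        "skipped": skipped,
                    }
                )
    return summary, pd.DataFrame(test_rows)


def gene_bin_dynamics(
    calls_by_sample: Mapping[str, pd.DataFrame],
    genome: GenomeModel,
    gene_ids: Sequence[str],
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    n_bins: int = 20,
    flank: int = FLANK_BP,
    dmrs: pd.DataFrame | None = None,
) -> dict:
    """Per-gene, per-sample 60-bin (upstream/body/downstream) methylation
    matrix for candidate genes, plus each gene's overlapping DMRs.

    Returns ``{'bins': long DataFrame, 'dmr_overlaps': DataFrame}``.
    Unknown gene ids raise a KeyError naming the id.
    """
    genes = genome.genes.set_index("gene_id")
    for gid in gene_ids:
        if gid not in genes.index:
            raise KeyError(f"unknown gene id {gid!r}")
    rows = []
    for sample, calls in calls_by_sample.items():
        for ctx in contexts:
            arrays = _context_arrays(calls, ctx)
            for gid in gene_ids:
                g = genes.loc[gid]
                feature = pd.Series(
                    {"chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand}
                )
                meth, tot = _feature_bin_counts(arrays, feature, flank, n_bins)
                with np.errstate(invalid="ignore"):
                    level = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": gid,
                            "sample": sample,
                            "context": ctx,
                            "zone": np.repeat(ZONES, n_bins),
                            "bin": np.tile(np.arange(n_bins), 3),
                            "level": level,
                        }
                    )
                )
    bins = pd.concat(rows, ignore_index=True)
    if dmrs is not None and len(dmrs):
        overlaps = link_dmrs_to_genes(dmrs, genome, flank)
        overlaps = overlaps[overlaps["gene_id"].isin(gene_ids)].reset_index(drop=True)
    else:
        overlaps = pd.DataFrame(columns=LINK_COLUMNS)
    return {"bins": bins, "dmr_overlaps": overlaps}
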