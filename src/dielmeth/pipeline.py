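"""End-to-end analysis of a (synthetic or on-disk) study.

``run_study`` executes the whole chain — QC, window tables, diel and
tissue DMR calling, DMR classification and dynamics, expression
quantification and DE testing, DMR-DEG association and GO enrichment —
and returns a result dict whose entries the acceptance script and the
report command consume. Planted-truth evaluation (sensitivity /
empirical FDR against the generator's ground truth) is included when
the study carries a GroundTruth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import core, dmr as dmrmod, expression as exprmod, integration, profiles
from .config import (
    CONTEXTS,
    DIEL_CHAIN,
    DMR_THRESHOLDS,
    TIMES,
    SimConfig,
    group_samples,
)
from .genome import GenomeModel, interval_overlap_bp, merge_intervals
from .simulate import GroundTruth, RECOVERY_COMPARISON, simulate_study


def group_windows(
    calls: dict[str, pd.DataFrame],
    group: str,
    chrom_sizes: dict[str, int],
    width: int = 100,
) -> pd.DataFrame:
    """Pooled-replicate window table for a tissue_time group."""
    pooled = core.pool_calls([calls[s] for s in group_samples(group)])
    return core.make_windows(pooled, chrom_sizes, width=width)


def call_group_dmrs(
    windows: dict[str, pd.DataFrame],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_cytosines: int = 4,
) -> pd.DataFrame:
    return dmrmod.call_dmrs(
        windows[group_a],
        windows[group_b],
        thresholds=DMR_THRESHOLDS,
        alpha=alpha,
        min_cytosines=min_cytosines,
        group_a=group_a,
        group_b=group_b,
    )


def evaluate_recovery(
    called: pd.DataFrame, truth: GroundTruth, kind: str = "recovery"
) -> pd.DataFrame:
    """Planted-region sensitivity and window-level empirical FDR per context.

    A planted region is recovered when at least one called window of the
    same context and direction overlaps it; a called window is a false
    positive when it overlaps no planted region of its context.
    """
    planted = truth.planted_dmrs
    planted = planted[planted["kind"] == kind]
    rows = []
    for ctx in CONTEXTS:
        pl = planted[planted["context"] == ctx]
        ca = called[called["context"] == ctx]
        recovered = 0
        for r in pl.itertuples():
            hits = ca[
                (ca["chrom"] == r.chrom)
                & (ca["start"] < r.end)
                & (ca["end"] > r.start)
                & (ca["direction"] == r.direction)
            ]
            recovered += int(len(hits) > 0)
        false = 0
        for w in ca.itertuples():
            over = pl[
                (pl["chrom"] == w.chrom)
                & (pl["start"] < w.end)
                & (pl["end"] > w.start)
            ]
            false += int(len(over) == 0)
        n_called = len(ca)
        rows.append(
            {
                "context": ctx,
                "n_planted": len(pl),
                "n_recovered": recovered,
                "sensitivity": recovered / len(pl) if len(pl) else np.nan,
                "n_called": n_called,
                "n_false": false,
                "fdr": false / n_called if n_called else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    cfg: SimConfig | None = None,
    study: dict | None = None,
    alpha: float = 0.05,
    ranking_group: str = "green_10am",
) -> dict:
    """Run the full integrated analysis; see module docstring."""
    if study is None:
        if cfg is None:
            cfg = SimConfig()
        study = simulate_study(cfg)
    genome: GenomeModel = study["genome"]
    truth: GroundTruth | None = study.get("truth")
    calls: dict[str, pd.DataFrame] = study["calls"]
    chrom_sizes = {c: len(genome.seqs[c]) for c in genome.chromosomes}

    # ---- QC
    qc = {
        "conversion_rate": {
            s: core.conversion_rate(c, genome.control_contig) for s, c in calls.items()
        }
    }
    rep_windows = {
        s: core.make_windows(calls[s], chrom_sizes) for s in group_samples(ranking_group)
    }
    r1, r2 = list(rep_windows)
    qc["replicate_correlation"] = {
        ctx: core.replicate_correlation(rep_windows[r1], rep_windows[r2], ctx)
        for ctx in CONTEXTS
    }

    # ---- pooled group windows
    groups = [f"{t}_{tm}" for t in ("green", "white") for tm in TIMES]
    windows = {g: group_windows(calls, g, chrom_sizes) for g in groups}

    # ---- DMR calling
    comparisons: dict[str, tuple[str, str]] = {}
    for a, b in DIEL_CHAIN:
        comparisons[f"{a}_vs_{b}"] = (a, b)
    comparisons["recovery"] = RECOVERY_COMPARISON
    for tm in TIMES:
        comparisons[f"tissue_{tm}"] = (f"green_{tm}", f"white_{tm}")
    dmrs = {
        name: call_group_dmrs(windows, a, b, alpha=alpha)
        for name, (a, b) in comparisons.items()
    }

    diel_names = [f"{a}_vs_{b}" for a, b in DIEL_CHAIN]
    diel_counts = {
        ctx: int(sum((dmrs[n]["context"] == ctx).sum() for n in diel_names))
        for ctx in CONTEXTS
    }
    first = dmrs[diel_names[0]]
    chh_first = first[first["context"] == "CHH"]
    frac_hyper_4pm = (
        float((chh_first["direction"] == "hyper").mean()) if len(chh_first) else np.nan
    )
    transitions = {
        ctx: dmrmod.dmr_transitions([(n, dmrs[n]) for n in diel_names], ctx)
        for ctx in CONTEXTS
    }
    density = dmrmod.dmr_density_summary({n: dmrs[n] for n in diel_names})
    classified = dmrmod.classify_dmr_features(dmrs[diel_names[0]], genome)

    recovery_eval = (
        evaluate_recovery(dmrs["recovery"], truth) if truth is not None else None
    )

    # ---- expression
    counts, lengths = study["counts"], study["lengths"]
    fpkm_tab = exprmod.fpkm(counts, lengths)
    ranking_key = fpkm_tab[group_samples(ranking_group)].mean(axis=1)
    strata_q = exprmod.expression_strata(ranking_key, "quintiles")
    strata_3 = exprmod.expression_strata(ranking_key, "three_class")

    de_results = {}
    for tm in TIMES:
        a = counts[group_samples(f"green_{tm}")]
        b = counts[group_samples(f"white_{tm}")]
        de_results[tm] = exprmod.de_test(a, b, alpha=alpha)
    # union of DEGs across time points; direction from the strongest call
    status_rows = []
    for tm, res in de_results.items():
        hit = res[res["status"] != "ns"]
        for gid, r in hit.iterrows():
            status_rows.append((gid, r["status"], r["q_value"]))
    if status_rows:
        st = pd.DataFrame(status_rows, columns=["gene_id", "status", "q"])
        st = st.sort_values(["gene_id", "q"], kind="stable").drop_duplicates("gene_id")
        deg_status = st.set_index("gene_id")["status"].map(
            {"up_in_A": "up_in_green", "up_in_B": "up_in_white"}
        )
    else:
        deg_status = pd.Series(dtype=object)

    # ---- integration
    tissue_dmrs = pd.concat(
        [dmrs[f"tissue_{tm}"] for tm in TIMES], ignore_index=True
    )
    links = integration.link_dmrs_to_genes(tissue_dmrs, genome)
    assoc = integration.dmr_associated_degs(links, deg_status)

    go_pop = sorted(set(study["go_map"]["gene_id"]))
    assoc_degs = sorted(
        set(deg_status.index) & set(links["gene_id"]) if len(links) else set()
    )
    go = integration.go_enrichment(assoc_degs, go_pop, study["go_map"])

    region_levels = pd.concat(
        [
            profiles.region_level_table(
                core.pool_calls([calls[s] for s in group_samples(ranking_group)]),
                genome.genes,
                ctx,
                chrom_sizes=chrom_sizes,
            )
            for ctx in CONTEXTS
        ],
        ignore_index=True,
    )
    meth_by_expr = integration.methylation_by_expression(
        region_levels, strata_3, strata_order=["unexpressed", "low", "mid", "high"]
    )

    # tissue contrast of per-gene body CHH (green vs white, all times pooled)
    body = {}
    for tissue in ("green", "white"):
        pooled = core.pool_calls(
            [calls[s] for tm in TIMES for s in group_samples(f"{tissue}_{tm}")]
        )
        lv = profiles.region_level_table(pooled, genome.genes, "CHH", chrom_sizes=chrom_sizes)
        body[tissue] = lv[lv["region"] == "body"].set_index("gene_id")["level"]
    paired = pd.concat(body, axis=1).dropna()
    tissue_chh = {
        "green_median": float(paired["green"].median()),
        "white_median": float(paired["white"].median()),
        "p_value": exprmod.mannwhitney(
            paired["green"].to_numpy(), paired["white"].to_numpy(), "greater"
        ),
    }

    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "qc": qc,
        "windows": windows,
        "dmrs": dmrs,
        "diel_counts": diel_counts,
        "frac_hyper_4pm_chh": frac_hyper_4pm,
        "transitions": transitions,
        "density": density,
        "classified_dmrs": classified,
        "recovery": recovery_eval,
        "fpkm": fpkm_tab,
        "strata_quintiles": strata_q,
        "strata_three_class": strata_3,
        "de_results": de_results,
        "deg_status": deg_status,
        "links": links,
        "deg_association": assoc,
        "go_enrichment": go,
        "meth_by_expression": meth_by_expr,
        "tissue_chh_body": tissue_chh,
    }
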