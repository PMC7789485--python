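"""Window-based differential methylation calling and DMR bookkeeping.

A 100-bp window is a DMR between two sample groups when, with replicate
counts pooled within each group,

1. both groups have coverage and at least ``min_cytosines`` covered
   cytosines of the context in the window,
2. a two-sided Fisher exact test on the pooled 2x2 count table passes
   Benjamini-Hochberg control at ``alpha``, and
3. the absolute difference of weighted levels reaches the per-context
   threshold (defaults 0.4 / 0.2 / 0.1 for CG / CHG / CHH).

Direction is relative to the first-named group: "hyper" means the first
group is more methylated. Adjacent significant windows are *not* merged
by default (counting stays window-level); ``merge_dmrs`` merges runs
within a gap and recomputes pooled statistics.
"""

from __future__ import annotations

from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import DMR_THRESHOLDS, FLANK_BP
from .genome import GenomeModel, interval_overlap_bp, merge_intervals

_REL_TOL = 1.0 + 1e-7  # two-sided inclusion tolerance for probability ties

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "group_a",
    "group_b",
    "n_cytosines",
    "meth_a",
    "total_a",
    "meth_b",
    "total_b",
    "m_a",
    "m_b",
    "delta",
    "direction",
    "p_value",
    "q_value",
]

FEATURE_PRECEDENCE = ["promoter", "exon", "intron", "downstream", "intergenic"]


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table.

    Sums hypergeometric probabilities no larger than that of the
    observed table at fixed margins, computed in exact integer
    arithmetic. An empty margin gives p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(r1, k)
    obs = comb(r1, a) * comb(r2, c)
    # integer-exact tie rule mirroring the float tolerance: include x when
    # num(x) <= num(obs) * (1 + 1e-7)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, k - x)
        if w * 10_000_000 <= obs * 10_000_001:
            num += w
    return float(min(num / comb(n, k), 1.0))


def fisher_exact_many(
    meth_a: np.ndarray,
    total_a: np.ndarray,
    meth_b: np.ndarray,
    total_b: np.ndarray,
    chunk_terms: int = 20_000_000,
) -> np.ndarray:
    """Vectorized two-sided Fisher exact test over many 2x2 tables.

    Tables are [[meth_a, total_a - meth_a], [meth_b, total_b - meth_b]].
    Uses a cached log-factorial table; probability ties are included with
    a 1e-7 relative tolerance (the convention of ``fisher_exact``).
    """
    a = np.asarray(meth_a, dtype=np.int64)
    ra = np.asarray(total_a, dtype=np.int64)
    c = np.asarray(meth_b, dtype=np.int64)
    rb = np.asarray(total_b, dtype=np.int64)
    if (a > ra).any() or (c > rb).any() or min(a.min(initial=0), c.min(initial=0)) < 0:
        raise ValueError("invalid tables")
    n = ra + rb
    k = a + c
    out = np.ones(len(a), dtype=float)
    active = (ra > 0) & (rb > 0) & (k > 0) & (k < n)
    if not active.any():
        return out
    idx = np.flatnonzero(active)
    lf = gammaln(np.arange(int(n.max()) + 2))  # lf[m] = log((m-1)!)

    def logc(nn, kk):
        return lf[nn + 1] - lf[kk + 1] - lf[nn - kk + 1]

    lo = np.maximum(0, k - rb)
    hi = np.minimum(ra, k)
    width = hi - lo + 1
    # process in chunks bounded by total support terms
    start = 0
    while start < len(idx):
        stop = start
        terms = 0
        while stop < len(idx) and (terms == 0 or terms + width[idx[stop]] <= chunk_terms):
            terms += int(width[idx[stop]])
            stop += 1
        sel = idx[start:stop]
        w = width[sel]
        offs = np.repeat(np.arange(len(sel)), w)
        x = np.concatenate([np.arange(lo[i], hi[i] + 1) for i in sel])
        ra_e, rb_e, k_e = ra[sel][offs], rb[sel][offs], k[sel][offs]
        logpmf = logc(ra_e, x) + logc(rb_e, k_e - x) - logc(ra_e + rb_e, k_e)
        log_obs = (
            logc(ra[sel], a[sel]) + logc(rb[sel], c[sel]) - logc(ra[sel] + rb[sel], k[sel])
        )
        include = logpmf <= log_obs[offs] + np.log(_REL_TOL)
        p = np.zeros(len(sel))
        np.add.at(p, offs, np.where(include, np.exp(logpmf), 0.0))
        out[sel] = np.minimum(p, 1.0)
        start = stop
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    context: str | None = None,
    thresholds: Mapping[str, float] = DMR_THRESHOLDS,
    alpha: float = 0.05,
    min_cytosines: int = 4,
    group_a: str = "A",
    group_b: str = "B",
) -> pd.DataFrame:
    """Call per-window DMRs between two pooled window tables.

    ``windows_a``/``windows_b`` come from :func:`dielmeth.core.make_windows`
    on pooled group calls and must share the window grid. ``context=None``
    calls all three contexts (BH adjustment runs within each context).
    """
    contexts = [context] if context else ["CG", "CHG", "CHH"]
    records = []
    for ctx in contexts:
        wa = windows_a[windows_a["context"] == ctx]
        wb = windows_b[windows_b["context"] == ctx]
        m = wa.merge(
            wb, on=["chrom", "start", "end", "context"], suffixes=("_a", "_b"),
            how="outer", indicator=True,
        )
        if (m["_merge"] != "both").any():
            raise ValueError("window grids of the two groups do not match")
        assess = (
            (m["sum_total_a"] > 0)
            & (m["sum_total_b"] > 0)
            & (m["n_cytosines_a"] >= min_cytosines)
            & (m["n_cytosines_b"] >= min_cytosines)
        )
        t = m[assess].reset_index(drop=True)
        if len(t) == 0:
            continue
        p = fisher_exact_many(
            t["sum_meth_a"].to_numpy(),
            t["sum_total_a"].to_numpy(),
            t["sum_meth_b"].to_numpy(),
            t["sum_total_b"].to_numpy(),
        )
        q = bh_adjust(p)
        m_a = t["sum_meth_a"] / t["sum_total_a"]
        m_b = t["sum_meth_b"] / t["sum_total_b"]
        delta = m_a - m_b
        keep = (q <= alpha) & (delta.abs() >= thresholds[ctx])
        sub = t[keep]
        if len(sub) == 0:
            continue
        records.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"],
                    "start": sub["start"],
                    "end": sub["end"],
                    "context": ctx,
                    "group_a": group_a,
                    "group_b": group_b,
                    "n_cytosines": np.minimum(
                        sub["n_cytosines_a"], sub["n_cytosines_b"]
                    ),
                    "meth_a": sub["sum_meth_a"],
                    "total_a": sub["sum_total_a"],
                    "meth_b": sub["sum_meth_b"],
                    "total_b": sub["sum_total_b"],
                    "m_a": m_a[keep],
                    "m_b": m_b[keep],
                    "delta": delta[keep],
                    "direction": np.where(delta[keep] > 0, "hyper", "hypo"),
                    "p_value": p[keep.to_numpy()],
                    "q_value": q[keep.to_numpy()],
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["context", "chrom", "start"], ignore_index=True)[
        DMR_COLUMNS
    ]


def merge_dmrs(dmrs: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge same-context, same-direction DMR windows within ``gap`` bp,
    recomputing pooled counts and levels (p/q of merged runs are dropped)."""
    if len(dmrs) == 0:
        return dmrs.copy()
    rows = []
    for (ctx, chrom, direction), sub in dmrs.groupby(
        ["context", "chrom", "direction"], sort=True
    ):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples():
            if cur is not None and r.start <= cur["end"] + gap:
                cur["end"] = max(cur["end"], r.end)
                for f in ("n_cytosines", "meth_a", "total_a", "meth_b", "total_b"):
                    cur[f] += getattr(r, f)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": r.start,
                    "end": r.end,
                    "context": ctx,
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "direction": direction,
                    "n_cytosines": r.n_cytosines,
                    "meth_a": r.meth_a,
                    "total_a": r.total_a,
                    "meth_b": r.meth_b,
                    "total_b": r.total_b,
                }
        rows.append(cur)
    out = pd.DataFrame(rows)
    out["m_a"] = out["meth_a"] / out["total_a"]
    out["m_b"] = out["meth_b"] / out["total_b"]
    out["delta"] = out["m_a"] - out["m_b"]
    return out.sort_values(["context", "chrom", "start"], ignore_index=True)


def classify_dmr_features(dmrs: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Assign each DMR one genomic feature class by maximal overlap.

    Classes: promoter (2 kb upstream of the TSS, strand-aware), exon,
    intron, downstream (2 kb past the 3' end) and intergenic; ties break
    by precedence promoter > exon > intron > downstream.
    """
    out = dmrs.copy()
    if len(out) == 0:
        out["feature"] = pd.Series(dtype=object)
        return out
    genes = genome.genes
    plus = genes["strand"] == "+"
    feat_ivs = {
        "promoter": pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": np.where(plus, genes["start"] - FLANK_BP, genes["end"]),
                "end": np.where(plus, genes["start"], genes["end"] + FLANK_BP),
            }
        ),
        "exon": genome.exons[["chrom", "start", "end"]],
        "intron": genome.introns()[["chrom", "start", "end"]],
        "downstream": pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": np.where(plus, genes["end"], genes["start"] - FLANK_BP),
                "end": np.where(plus, genes["end"] + FLANK_BP, genes["start"]),
            }
        ),
    }
    overlaps = np.zeros((len(out), len(FEATURE_PRECEDENCE) - 1), dtype=np.int64)
    for j, name in enumerate(FEATURE_PRECEDENCE[:-1]):
        ivs = feat_ivs[name]
        for chrom, sub in ivs.groupby("chrom"):
            sel = np.flatnonzero(out["chrom"].to_numpy() == chrom)
            if len(sel) == 0:
                continue
            ms, me = merge_intervals(
                np.maximum(sub["start"].to_numpy(), 0), sub["end"].to_numpy()
            )
            overlaps[sel, j] = interval_overlap_bp(
                out["start"].to_numpy()[sel], out["end"].to_numpy()[sel], ms, me
            )
    best = np.argmax(overlaps, axis=1)  # ties -> lowest index = precedence
    feature = np.array(FEATURE_PRECEDENCE, dtype=object)[best]
    feature[overlaps.max(axis=1) == 0] = "intergenic"
    out["feature"] = feature
    return out


def feature_distribution(classified: pd.DataFrame) -> pd.DataFrame:
    """DMR counts per context x feature class."""
    if len(classified) == 0:
        return pd.DataFrame(
            0, index=pd.Index([], name="context"), columns=FEATURE_PRECEDENCE
        )
    tab = (
        classified.groupby(["context", "feature"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return tab.reindex(columns=FEATURE_PRECEDENCE, fill_value=0)


def dmr_transitions(
    dmr_sets: Sequence[tuple[str, pd.DataFrame]], context: str
) -> dict[str, pd.DataFrame]:
    """DMR state dynamics across an ordered chain of comparisons.

    For every window that is a DMR in at least one comparison, its state
    per comparison is hyper/hypo/unchanged; returns a 3x3 transition
    count matrix for each successive pair of comparisons.
    """
    states = ["hyper", "hypo", "unchanged"]
    keys: dict[tuple, dict[str, str]] = {}
    for name, dmrs in dmr_sets:
        sub = dmrs[dmrs["context"] == context]
        for r in sub.itertuples():
            keys.setdefault((r.chrom, r.start, r.end), {})[name] = r.direction
    out = {}
    names = [name for name, _ in dmr_sets]
    for a, b in zip(names[:-1], names[1:]):
        mat = pd.DataFrame(0, index=states, columns=states)
        for st in keys.values():
            mat.loc[st.get(a, "unchanged"), st.get(b, "unchanged")] += 1
        out[f"{a}->{b}"] = mat
    return out


def dmr_density_summary(
    dmr_sets: Mapping[str, pd.DataFrame], hist_bins: int = 20
) -> pd.DataFrame:
    """Per comparison x context: DMR count, hyper/hypo split and a |delta|
    histogram (as a list column of bin counts over [0, 1])."""
    rows = []
    edges = np.linspace(0, 1, hist_bins + 1)
    for name, dmrs in dmr_sets.items():
        for ctx in ("CG", "CHG", "CHH"):
            sub = dmrs[dmrs["context"] == ctx]
            hist = np.histogram(sub["delta"].abs(), bins=edges)[0]
            rows.append(
                {
                    "comparison": name,
                    "context": ctx,
                    "n_dmrs": len(sub),
                    "n_hyper": int((sub["direction"] == "hyper").sum()),
                    "n_hypo": int((sub["direction"] == "hypo").sum()),
                    "delta_hist": hist.tolist(),
                }
            )
    return pd.DataFrame(rows)
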