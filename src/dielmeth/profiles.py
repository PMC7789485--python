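"""Aggregate methylation summaries: metaplots, chromosome tracks and
per-feature region levels.

Metaplots follow the upstream / body / downstream layout: fixed-width
flank bins (100 bp for a 2-kb flank split into 20 bins) and 20
proportional bins over the feature body, all oriented 5'->3' in feature
orientation (minus-strand features are reversed). Bin levels pool raw
counts across features (weighted methylation), not means of per-feature
levels; a mean-of-features mode exists for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ZONES = ("upstream", "body", "downstream")


def _context_arrays(calls: pd.DataFrame, context: str | None):
    """Per-chrom sorted (pos0, meth, total) arrays for one context."""
    sub = calls if context is None else calls[calls["context"] == context]
    out = {}
    for chrom, s in sub.groupby("chrom", sort=False, observed=True):
        pos0 = s["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos0, kind="stable")
        out[chrom] = (
            pos0[order],
            s["n_meth"].to_numpy(dtype=np.int64)[order],
            s["n_total"].to_numpy(dtype=np.int64)[order],
        )
    return out


def _feature_bin_counts(
    arrays: dict, feature, flank: int, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """(meth, total) sums over 3*n_bins bins for one stranded feature."""
    meth = np.zeros(3 * n_bins, dtype=np.int64)
    tot = np.zeros(3 * n_bins, dtype=np.int64)
    if feature.chrom not in arrays:
        return meth, tot
    pos0, m, t = arrays[feature.chrom]
    bin_bp = flank // n_bins
    start, end = int(feature.start), int(feature.end)
    lo = np.searchsorted(pos0, start - flank, side="left")
    hi = np.searchsorted(pos0, end + flank, side="left")
    p = pos0[lo:hi]
    if len(p) == 0:
        return meth, tot
    length = max(end - start, 1)
    bins = np.empty(len(p), dtype=np.int64)
    up = p < start
    body = (p >= start) & (p < end)
    down = p >= end
    bins[up] = (p[up] - (start - flank)) // bin_bp
    bins[body] = n_bins + np.minimum(
        (n_bins * (p[body] - start)) // length, n_bins - 1
    )
    bins[down] = 2 * n_bins + np.minimum((p[down] - end) // bin_bp, n_bins - 1)
    if feature.strand == "-":
        bins = 3 * n_bins - 1 - bins
    np.add.at(meth, bins, m[lo:hi])
    np.add.at(tot, bins, t[lo:hi])
    return meth, tot


def feature_metaprofile(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_bins: int = 20,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Aggregate 5'->3' methylation profile over stranded features.

    Returns one row per bin (3*n_bins rows: upstream, body, downstream)
    with pooled counts and the bin's weighted level. ``mode='mean'``
    averages per-feature bin levels instead of pooling counts.
    """
    if flank % n_bins != 0:
        raise ValueError("flank must be divisible by n_bins")
    if mode not in ("pooled", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    arrays = _context_arrays(calls, context)
    meth = np.zeros(3 * n_bins, dtype=np.int64)
    tot = np.zeros(3 * n_bins, dtype=np.int64)
    level_sum = np.zeros(3 * n_bins)
    level_n = np.zeros(3 * n_bins, dtype=np.int64)
    for feature in features.itertuples():
        fm, ft = _feature_bin_counts(arrays, feature, flank, n_bins)
        meth += fm
        tot += ft
        ok = ft > 0
        level_sum[ok] += fm[ok] / ft[ok]
        level_n += ok
    if mode == "pooled":
        with np.errstate(invalid="ignore"):
            level = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            level = np.where(level_n > 0, level_sum / np.maximum(level_n, 1), np.nan)
    zone = np.repeat(ZONES, n_bins)
    return pd.DataFrame(
        {
            "zone": zone,
            "bin": np.tile(np.arange(n_bins), 3),
            "context": context,
            "sum_meth": meth,
            "sum_total": tot,
            "level": level,
        }
    )


def region_level_table(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    context: str,
    flank: int = 2000,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """One weighted level per feature per region (body / upstream2k /
    downstream2k, strand-aware). Regions truncated by a contig end are
    flagged; uncovered regions get NaN."""
    arrays = _context_arrays(calls, context)
    rows = []
    for f in features.itertuples():
        start, end = int(f.start), int(f.end)
        if f.strand == "+":
            regions = {
                "upstream2k": (start - flank, start),
                "body": (start, end),
                "downstream2k": (end, end + flank),
            }
        else:
            regions = {
                "upstream2k": (end, end + flank),
                "body": (start, end),
                "downstream2k": (start - flank, start),
            }
        size = None if chrom_sizes is None else chrom_sizes.get(f.chrom)
        for name, (a, b) in regions.items():
            a_c = max(a, 0)
            b_c = b if size is None else min(b, size)
            truncated = (a_c != a) or (b_c != b)
            level = np.nan
            if f.chrom in arrays and b_c > a_c:
                pos0, m, t = arrays[f.chrom]
                lo = np.searchsorted(pos0, a_c, side="left")
                hi = np.searchsorted(pos0, b_c, side="left")
                tt = int(t[lo:hi].sum())
                if tt > 0:
                    level = float(m[lo:hi].sum()) / tt
            rows.append(
                {
                    "gene_id": getattr(f, "gene_id", getattr(f, "te_id", "")),
                    "region": name,
                    "context": context,
                    "level": level,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(rows)


def chromosome_track(
    windows: pd.DataFrame, genes: pd.DataFrame, tes: pd.DataFrame
) -> pd.DataFrame:
    """Attach gene/TE densities (overlapping-feature counts) to a window
    table, e.g. 500-kb windows sliding by 100 kb for chromosome views."""
    out = windows.copy()
    out["gene_count"] = 0
    out["te_count"] = 0
    for name, feats in (("gene_count", genes), ("te_count", tes)):
        for chrom, sub in feats.groupby("chrom"):
            sel = out["chrom"] == chrom
            if not sel.any():
                continue
            starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
            ends = np.sort(sub["end"].to_numpy(dtype=np.int64))
            ws = out.loc[sel, "start"].to_numpy(dtype=np.int64)
            we = out.loc[sel, "end"].to_numpy(dtype=np.int64)
            n = np.searchsorted(starts, we, side="left") - np.searchsorted(
                ends, ws, side="right"
            )
            out.loc[sel, name] = n
    return out


def plot_metaprofile(profiles: dict, path=None, title: str | None = None):
    """Plot one or more metaprofiles ({label: DataFrame}) as a metaplot.

    Requires matplotlib (optional dependency). Returns the figure;
    saves to ``path`` (PNG/SVG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    for label, prof in profiles.items():
        ax.plot(np.arange(len(prof)), prof["level"], label=label)
    n = next(iter(profiles.values()))
    n_bins = len(n) // 3
    for x in (n_bins - 0.5, 2 * n_bins - 0.5):
        ax.axvline(x, color="grey", lw=0.6, ls=":")
    ax.set_xticks([n_bins / 2, 1.5 * n_bins, 2.5 * n_bins])
    ax.set_xticklabels(["upstream", "body", "downstream"])
    ax.set_ylabel("weighted methylation")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
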