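"""Expression quantification, stratification and differential testing.

FPKM = count * 1e9 / (gene length * library size). Genes with
FPKM > 0.5 count as expressed. The differential-expression stage is a
deliberately minimal negative-binomial Wald test: median-of-ratios size
factors, a pooled method-of-moments dispersion with a small-sample
floor, and a normal Wald statistic on the log2 fold change with BH
control. It is *not* DESeq2 (no shrinkage, no Cox-Reid dispersion, no
independent filtering); result tables carry ``method='nb-wald-mor'``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import FPKM_EXPRESSED
from .dmr import bh_adjust

DE_METHOD = "nb-wald-mor"


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments.

    ``library_sizes`` defaults to per-sample count totals.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:3]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


def _ranked_groups(values: pd.Series, n_groups: int) -> pd.Series:
    """Split genes into near-equal rank groups (1 = lowest), ties broken
    by stable gene-id order."""
    order = values.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="stable")
    n = len(order)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    labels = np.repeat(np.arange(1, n_groups + 1), sizes)
    return pd.Series(labels, index=order["gene_id"])


def expression_strata(
    fpkm_values: pd.Series,
    mode: str = "quintiles",
    expressed_cutoff: float = FPKM_EXPRESSED,
) -> pd.Series:
    """Stratum labels from a ranking sample's (or group mean) FPKM.

    ``quintiles``: expressed genes ranked into groups 'Q1' (lowest) ..
    'Q5'; unexpressed genes labelled 'unexpressed'. ``three_class``:
    'unexpressed' (FPKM <= cutoff), then terciles of the expressed genes
    as 'low' / 'mid' / 'high' (analyses typically drop 'mid').
    """
    expressed = fpkm_values > expressed_cutoff
    labels = pd.Series("unexpressed", index=fpkm_values.index, dtype=object)
    n_exp = int(expressed.sum())
    if mode == "quintiles":
        if n_exp < 5:
            raise ValueError(f"only {n_exp} expressed genes; need >= 5 for quintiles")
        g = _ranked_groups(fpkm_values[expressed], 5)
        labels.loc[g.index] = "Q" + g.astype(str)
    elif mode == "three_class":
        if n_exp >= 3:
            g = _ranked_groups(fpkm_values[expressed], 3)
            labels.loc[g.index] = g.map({1: "low", 2: "mid", 3: "high"})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return labels


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    finite = np.isfinite(log).all(axis=1)
    if finite.sum() == 0:
        tot = counts.sum(axis=0).astype(float)
        sf = tot / np.exp(np.mean(np.log(tot)))
        return sf
    ref = log[finite].mean(axis=1)
    sf = np.exp(np.median(log[finite] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    alpha: float = 0.05,
    min_dispersion: float = 0.01,
) -> pd.DataFrame:
    """Minimal two-condition NB Wald test (see module docstring).

    ``counts_a``/``counts_b`` are genes x replicates with matching gene
    index and >= 2 replicates per group. Returns per gene: normalized
    means, log2fc (A vs B), p, BH q and status in
    {'up_in_A', 'up_in_B', 'ns'}; all-zero genes are flagged and not
    tested.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene indexes of the two groups differ")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    joint = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(joint)
    sf_a = sf.iloc[: counts_a.shape[1]].to_numpy()
    sf_b = sf.iloc[counts_a.shape[1] :].to_numpy()
    norm_a = counts_a.to_numpy(dtype=float) / sf_a
    norm_b = counts_b.to_numpy(dtype=float) / sf_b
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    all_zero = (joint.to_numpy() == 0).all(axis=1)

    # pooled method-of-moments dispersion from within-group variability
    var_within = (
        norm_a.var(axis=1, ddof=1) * (n_a - 1) + norm_b.var(axis=1, ddof=1) * (n_b - 1)
    ) / (n_a + n_b - 2)
    mu_pool = (mu_a * n_a + mu_b * n_b) / (n_a + n_b)
    inv_sf = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_g = (var_within - mu_pool * inv_sf) / mu_pool**2
    ok = np.isfinite(disp_g) & (mu_pool > 5)
    if ok.sum() >= 10:
        pooled = float(np.mean(np.clip(disp_g[ok], 0, np.quantile(disp_g[ok], 0.9))))
    else:
        pooled = min_dispersion
    disp = max(pooled, min_dispersion)

    pc = 0.5
    lfc = np.log2((mu_a + pc) / (mu_b + pc))
    inv_a = float(np.mean(1.0 / sf_a))
    inv_b = float(np.mean(1.0 / sf_b))
    va = (np.maximum(mu_a, pc) * inv_a + disp * np.maximum(mu_a, pc) ** 2) / n_a
    vb = (np.maximum(mu_b, pc) * inv_b + disp * np.maximum(mu_b, pc) ** 2) / n_b
    se = np.sqrt(
        va / np.maximum(mu_a, pc) ** 2 + vb / np.maximum(mu_b, pc) ** 2
    ) / np.log(2)
    z = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(all_zero, np.nan, p)
    q = np.full(len(p), np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    status = np.where(
        tested & (q <= alpha), np.where(lfc > 0, "up_in_A", "up_in_B"), "ns"
    )
    out = pd.DataFrame(
        {
            "base_mean": mu_pool,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2fc": lfc,
            "se": se,
            "p_value": p,
            "q_value": q,
            "status": status,
            "all_zero": all_zero,
        },
        index=counts_a.index,
    )
    out.attrs["method"] = DE_METHOD
    out.attrs["dispersion"] = disp
    return out


def mannwhitney(
    x, y, alternative: str = "two-sided"
) -> float:
    """Mann-Whitney rank-sum p-value.

    Exact enumeration for small tie-free samples (both n <= 20),
    tie-corrected normal approximation otherwise; all-tied degenerate
    input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue
    )


def simulate_nb_counts(
    mu: np.ndarray, dispersion: float, n_reps: int, rng: np.random.Generator
) -> pd.DataFrame:
    """NB count matrix (genes x replicates) at the given mean vector;
    utility for DE-test calibration studies."""
    mu = np.asarray(mu, dtype=float)
    cols = {}
    for j in range(n_reps):
        if dispersion > 0:
            r = 1.0 / dispersion
            cols[f"r{j + 1}"] = rng.negative_binomial(r, r / (r + mu))
        else:
            cols[f"r{j + 1}"] = rng.poisson(mu)
    return pd.DataFrame(cols, index=pd.RangeIndex(len(mu)).map(lambda i: f"g{i}"))
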