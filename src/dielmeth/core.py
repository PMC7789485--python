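"""Methylome core: cytosine contexts, call-set QC and weighted methylation.

A *call set* is a pandas DataFrame with one row per cytosine per strand:

    chrom   contig id
    pos     1-based position of the cytosine (CX-report convention)
    strand  '+' or '-'
    context 'CG', 'CHG' or 'CHH' (H = A, T or C)
    n_meth  reads supporting methylation
    n_total total reads covering the cytosine

The weighted methylation level of any region is the ratio of count sums
(sum methylated reads / sum total reads), never a mean of per-site
ratios; a region whose denominator is zero has an *undefined* (NaN)
level, which propagates as missing rather than as zero.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "n_cytosines",
    "sum_meth",
    "sum_total",
    "level",
]

_CTX_CODES = {0: "CG", 1: "CHG", 2: "CHH"}


def contexts_in_sequence(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosines of a contig on both strands.

    Returns ``(pos0, strand_is_minus, context_code)`` with 0-based
    positions, sorted by position then strand ('+' before '-'), and
    context codes 0=CG, 1=CHG, 2=CHH. Cytosines whose downstream context
    is truncated by the contig end are classified CHH by convention
    unless the CG dinucleotide is still decidable.
    """
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L = len(b)
    C, G = ord("C"), ord("G")
    is_c = b == C
    is_g = b == G

    # plus strand: context read 5'->3' to the right
    n1 = np.zeros(L, dtype=bool)  # next base is G
    n2 = np.zeros(L, dtype=bool)  # next-next base is G
    n1[:-1] = is_g[1:]
    n2[:-2] = is_g[2:]
    ctx_plus = np.full(L, 2, dtype=np.int8)  # CHH default (covers truncation)
    ctx_plus[n1] = 0  # CG
    valid_chg = np.zeros(L, dtype=bool)
    valid_chg[: max(L - 2, 0)] = True
    ctx_plus[~n1 & n2 & valid_chg] = 1  # CHG

    # minus strand: a cytosine sits where the plus strand shows G; its
    # downstream context runs leftwards on the complement
    p1 = np.zeros(L, dtype=bool)  # previous base is C
    p2 = np.zeros(L, dtype=bool)
    p1[1:] = is_c[:-1]
    p2[2:] = is_c[:-2]
    ctx_minus = np.full(L, 2, dtype=np.int8)
    ctx_minus[p1] = 0
    valid_chg_m = np.zeros(L, dtype=bool)
    valid_chg_m[2:] = True
    ctx_minus[~p1 & p2 & valid_chg_m] = 1

    pos_p = np.flatnonzero(is_c)
    pos_m = np.flatnonzero(is_g)
    pos0 = np.concatenate([pos_p, pos_m])
    minus = np.concatenate(
        [np.zeros(len(pos_p), dtype=bool), np.ones(len(pos_m), dtype=bool)]
    )
    ctx = np.concatenate([ctx_plus[pos_p], ctx_minus[pos_m]])
    order = np.lexsort((minus, pos0))
    return pos0[order], minus[order], ctx[order]


def classify_context(genome: GenomeModel, chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at a 1-based position, or ``not-a-cytosine``."""
    if chrom not in genome.seqs:
        raise KeyError(f"unknown contig {chrom!r}")
    seq = genome.seqs[chrom]
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            return "not-a-cytosine"
        if i + 1 < len(seq) and seq[i + 1] == "G":
            return "CG"
        if i + 2 < len(seq) and seq[i + 1] != "G" and seq[i + 2] == "G":
            return "CHG"
        return "CHH"
    if strand == "-":
        if seq[i] != "G":
            return "not-a-cytosine"
        if i - 1 >= 0 and seq[i - 1] == "C":
            return "CG"
        if i - 2 >= 0 and seq[i - 1] != "C" and seq[i - 2] == "C":
            return "CHG"
        return "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def validate_calls(calls: pd.DataFrame) -> None:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call set missing columns {missing}")
    if (calls["n_meth"] > calls["n_total"]).any():
        raise ValueError("n_meth exceeds n_total in call set")
    if (calls["n_meth"] < 0).any() or (calls["n_total"] < 0).any():
        raise ValueError("negative counts in call set")


def conversion_rate(calls: pd.DataFrame, control_contig: str) -> float:
    """Bisulfite conversion rate: one minus the weighted methylation level
    of the unmethylated control contig (all contexts pooled).

    Returns NaN (QC failure) when the control has no covered cytosine.
    """
    sub = calls[calls["chrom"] == control_contig]
    total = int(sub["n_total"].sum())
    if total == 0:
        return float("nan")
    return 1.0 - float(sub["n_meth"].sum()) / total


def coverage_filter(
    calls: pd.DataFrame, min_reads: int = 4
) -> tuple[pd.DataFrame, float]:
    """Keep cytosines covered by at least ``min_reads`` reads.

    Returns the filtered call set and the fraction of cytosines retained.
    """
    if len(calls) == 0:
        return calls, float("nan")
    keep = calls["n_total"] >= min_reads
    return calls[keep].reset_index(drop=True), float(keep.mean())


def weighted_methylation(
    calls: pd.DataFrame,
    region: tuple[str, int, int],
    context: str | None = None,
) -> float:
    """Weighted methylation level of a 0-based half-open region.

    ``context=None`` pools all contexts. Returns NaN when no covered
    cytosine of the requested context lies in the region.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"invalid interval [{start}, {end})")
    mask = (calls["chrom"] == chrom) & (calls["pos"] >= start + 1) & (calls["pos"] <= end)
    if context is not None:
        mask &= calls["context"] == context
    sub = calls[mask]
    total = int(sub["n_total"].sum())
    if total == 0:
        return float("nan")
    return float(sub["n_meth"].sum()) / total


def pool_calls(call_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate call sets by summing counts per cytosine."""
    if len(call_sets) == 1:
        return call_sets[0]
    first = call_sets[0]
    same = all(
        len(cs) == len(first)
        and (cs["pos"].to_numpy() == first["pos"].to_numpy()).all()
        and (cs["chrom"].to_numpy() == first["chrom"].to_numpy()).all()
        and (cs["strand"].to_numpy() == first["strand"].to_numpy()).all()
        for cs in call_sets[1:]
    )
    if same:  # fast path: identical cytosine catalogue (common case)
        out = first.copy()
        out["n_meth"] = sum(cs["n_meth"].to_numpy() for cs in call_sets)
        out["n_total"] = sum(cs["n_total"].to_numpy() for cs in call_sets)
        return out
    cat = pd.concat(call_sets, ignore_index=True)
    out = (
        cat.groupby(["chrom", "pos", "strand", "context"], sort=True, observed=True)[
            ["n_meth", "n_total"]
        ]
        .sum()
        .reset_index()
    )
    return out[CALL_COLUMNS]


def make_windows(
    calls: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    width: int = 100,
    step: int | None = None,
) -> pd.DataFrame:
    """Per-window, per-context weighted methylation.

    Windows tile (``step == width``, default) or slide (``step < width``)
    each contig; the trailing partial window is retained. Levels are
    count-sum ratios; windows without covered cytosines get NaN.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    step = width if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    pieces = []
    for chrom in chrom_sizes:
        L = int(chrom_sizes[chrom])
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + width, L)
        sub = calls[calls["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        meth = sub["n_meth"].to_numpy(dtype=np.int64)[order]
        tot = sub["n_total"].to_numpy(dtype=np.int64)[order]
        ctx = np.asarray(sub["context"], dtype=object)[order]
        for context in ("CG", "CHG", "CHH"):
            sel = ctx == context
            p = pos0[sel]
            cm = np.concatenate([[0], np.cumsum(meth[sel])])
            ct = np.concatenate([[0], np.cumsum(tot[sel])])
            cc = np.concatenate([[0], np.cumsum((tot[sel] > 0).astype(np.int64))])
            lo = np.searchsorted(p, starts, side="left")
            hi = np.searchsorted(p, ends, side="left")
            sm = cm[hi] - cm[lo]
            st = ct[hi] - ct[lo]
            nc = cc[hi] - cc[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                level = np.where(st > 0, sm / np.maximum(st, 1), np.nan)
            pieces.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "context": context,
                        "n_cytosines": nc,
                        "sum_meth": sm,
                        "sum_total": st,
                        "level": level,
                    }
                )
            )
    if not pieces:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    out = pd.concat(pieces, ignore_index=True)
    return out[WINDOW_COLUMNS]


def replicate_correlation(
    rep1: pd.DataFrame, rep2: pd.DataFrame, context: str
) -> float:
    """Pearson correlation of per-window levels between two replicates.

    Windows with an undefined level in either replicate are dropped
    pairwise; fewer than two complete pairs gives NaN.
    """
    a = rep1[rep1["context"] == context]
    b = rep2[rep2["context"] == context]
    merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_1", "_2"))
    x = merged["level_1"].to_numpy(dtype=float)
    y = merged["level_2"].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
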