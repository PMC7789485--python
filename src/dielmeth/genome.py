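"""Genome model (sequences, gene/TE annotation) and interval utilities.

Coordinates are 0-based half-open everywhere inside the package; file
writers/readers translate to the 1-based closed conventions of GFF3 and
CX reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
TE_COLUMNS = ["te_id", "chrom", "start", "end"]


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene models and TE intervals.

    ``seqs`` maps contig id to an upper-case DNA string; ``genes`` and
    ``exons`` are DataFrames (one row per gene / exon), ``tes`` one row
    per transposable element. ``control_contig`` names the unmethylated
    control (chloroplast stand-in) used for conversion-rate QC.
    """

    seqs: dict[str, str]
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS)
    )
    exons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EXON_COLUMNS)
    )
    tes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TE_COLUMNS))
    control_contig: str | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    @property
    def chromosomes(self) -> list[str]:
        """Contig ids excluding the control contig."""
        return [c for c in self.seqs if c != self.control_contig]

    def introns(self) -> pd.DataFrame:
        """Intron intervals derived as gene span minus exons."""
        rows = []
        for gid, sub in self.exons.groupby("gene_id", sort=False):
            sub = sub.sort_values("start")
            chrom = sub["chrom"].iloc[0]
            strand = sub["strand"].iloc[0]
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            for a, b in zip(ends[:-1], starts[1:]):
                if b > a:
                    rows.append((gid, chrom, int(a), int(b), strand))
        return pd.DataFrame(rows, columns=EXON_COLUMNS)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into a disjoint sorted set."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts)[order]
    e = np.asarray(ends)[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(b))
        else:
            out_s.append(int(a))
            out_e.append(int(b))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def interval_overlap_bp(
    q_start: np.ndarray,
    q_end: np.ndarray,
    ref_start: np.ndarray,
    ref_end: np.ndarray,
) -> np.ndarray:
    """Total overlap (bp) of each query interval with a *merged, sorted*
    disjoint reference interval set. Vectorized via prefix sums."""
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    if len(ref_start) == 0:
        return np.zeros(len(q_start), dtype=np.int64)
    ref_start = np.asarray(ref_start, dtype=np.int64)
    ref_end = np.asarray(ref_end, dtype=np.int64)
    lens = ref_end - ref_start
    cum = np.concatenate([[0], np.cumsum(lens)])
    # intervals intersecting the query: [lo, hi)
    lo = np.searchsorted(ref_end, q_start, side="right")
    hi = np.searchsorted(ref_start, q_end, side="left")
    out = np.zeros(len(q_start), dtype=np.int64)
    inside = hi > lo
    if not inside.any():
        return out
    li, hi_i = lo[inside], hi[inside]
    total = cum[hi_i] - cum[li]
    clip_left = np.maximum(0, q_start[inside] - ref_start[li])
    clip_right = np.maximum(0, ref_end[hi_i - 1] - q_end[inside])
    out[inside] = total - clip_left - clip_right
    return out


def point_in_intervals(pos: np.ndarray, ref_start: np.ndarray, ref_end: np.ndarray) -> np.ndarray:
    """Boolean mask of positions falling inside a merged sorted interval set."""
    pos = np.asarray(pos, dtype=np.int64)
    if len(ref_start) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(np.asarray(ref_start, dtype=np.int64), pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < np.asarray(ref_end, dtype=np.int64)[idx[ok]]
    return out
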