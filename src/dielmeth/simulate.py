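"""Synthetic diel methylome/transcriptome study with planted ground truth.

Generates a complete miniature study: a random genome with TE-dense
pericentromeres and non-overlapping genes on the chromosome arms, an
unmethylated control contig, per-cytosine bisulfite counts for 16
samples (2 tissues x 4 diel time points x 2 replicates), RNA-seq counts,
a GO map, and a :class:`GroundTruth` record of every planted effect.

Planted structure
-----------------
* context baselines CG > CHG > CHH, additive TE boost;
* tissue contrast: CHH reduced genome-wide in "white";
* diel oscillation in "green": CHH (and, weakly, CHG) up at 4 pm/10 pm
  and down at 4 am/10 am;
* recovery DMRs: per context, grid-aligned multi-window regions with
  effect size equal to the calling threshold, planted on one side of the
  white 4 am vs white 10 am comparison (a background-free pair);
* silenced genes: low expression plus methylation boost over the gene
  and its 2-kb flanks in every sample;
* DE genes green vs white, a fixed fraction of which carry a planted
  promoter/body DMR of the tissue comparison within the 2-kb envelope;
* a planted GO term concentrated in the DE genes.

Methylation counts are binomial at Poisson coverage; incomplete
bisulfite conversion adds false methylation to unmethylated cytosines
(observed success probability p + (1-p)*conversion_error), so the
control contig reads out the conversion error directly. RNA counts are
negative binomial with a gene-length- and library-size-scaled mean.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CONTEXTS,
    DIEL_SIGN,
    FLANK_BP,
    TIMES,
    TISSUES,
    REPLICATES,
    SimConfig,
    sample_name,
)
from .core import contexts_in_sequence, CALL_COLUMNS
from .genome import GenomeModel, merge_intervals, point_in_intervals

RECOVERY_COMPARISON = ("white_4am", "white_10am")
PLANTED_DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "group_a",
    "group_b",
    "kind",
    "gene_id",
]

#: clearance kept around genes when placing TEs and planted regions, so
#: that planted intergenic effects never fall inside a gene's 2-kb
#: association envelope.
_GENE_CLEARANCE = FLANK_BP + 100


@dataclass
class GroundTruth:
    """Planted effects of a synthetic study (0-based half-open intervals)."""

    planted_dmrs: pd.DataFrame
    de_genes: pd.DataFrame  # gene_id, sign (+1 up in green), dmr_linked
    silenced_genes: list[str]
    control_contig: str
    recovery_comparison: tuple[str, str] = RECOVERY_COMPARISON

    def to_dict(self) -> dict:
        return {
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "de_genes": self.de_genes.to_dict(orient="records"),
            "silenced_genes": list(self.silenced_genes),
            "control_contig": self.control_contig,
            "recovery_comparison": list(self.recovery_comparison),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_dmrs=pd.DataFrame(
                d["planted_dmrs"], columns=PLANTED_DMR_COLUMNS
            ),
            de_genes=pd.DataFrame(
                d["de_genes"], columns=["gene_id", "sign", "dmr_linked"]
            ),
            silenced_genes=list(d["silenced_genes"]),
            control_contig=d["control_contig"],
            recovery_comparison=tuple(d["recovery_comparison"]),
        )


class _Occupancy:
    """Sorted disjoint interval set supporting try-insert."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)

    def is_free(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, end)
        if i > 0 and self.ends[i - 1] > start:
            return False
        if i < len(self.starts) and self.starts[i] < end:
            return False
        return True

    def try_add(self, start: int, end: int) -> bool:
        if not self.is_free(start, end):
            return False
        self.add(start, end)
        return True


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def pericentromere(cfg: SimConfig, chrom_len: int) -> tuple[int, int]:
    half = int(chrom_len * cfg.pericentromere_fraction / 2)
    mid = chrom_len // 2
    return mid - half, mid + half


def simulate_genome(cfg: SimConfig) -> GenomeModel:
    """Random genome with arm genes, pericentromere-enriched TEs and an
    unmethylated control contig."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    seqs = {c: _random_seq(rng, cfg.chrom_len) for c in chroms}
    control = "chrC"
    seqs[control] = _random_seq(rng, cfg.control_len)

    occupancy = {c: _Occupancy() for c in chroms}

    # --- genes on chromosome arms, spaced so 2-kb envelopes stay disjoint
    gene_rows, exon_rows = [], []
    if cfg.n_genes > 0:
        arms = []
        for c in chroms:
            ps, pe = pericentromere(cfg, cfg.chrom_len)
            edge = _GENE_CLEARANCE + 100
            arms.append((c, edge, max(ps - edge, edge)))
            arms.append((c, pe + edge, cfg.chrom_len - edge))
        arm_lens = np.array([max(e - s, 0) for _, s, e in arms], dtype=float)
        if arm_lens.sum() <= 0:
            raise ValueError("no arm space available for genes")
        counts = np.floor(cfg.n_genes * arm_lens / arm_lens.sum()).astype(int)
        for i in np.argsort(-arm_lens)[: cfg.n_genes - counts.sum()]:
            counts[i] += 1
        gid = 0
        min_gap = 2 * _GENE_CLEARANCE  # neighbouring envelopes disjoint
        for (c, a_start, a_end), k in zip(arms, counts):
            if k == 0:
                continue
            lengths = rng.integers(
                cfg.gene_len_range[0], cfg.gene_len_range[1] + 1, size=k
            )
            need = int(lengths.sum()) + (k - 1) * min_gap
            free = (a_end - a_start) - need
            if free < 0:
                raise ValueError(
                    f"chrom_len too small to place {k} genes in arm "
                    f"{c}:{a_start}-{a_end}"
                )
            u = rng.random(k + 1)
            extra = np.floor(free * u / u.sum()).astype(int)
            pos = a_start + extra[0]
            for j in range(k):
                gid += 1
                gene_id = f"gene{gid:04d}"
                start, end = int(pos), int(pos + lengths[j])
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((gene_id, c, start, end, strand))
                exon_rows.extend(
                    _make_exons(rng, gene_id, c, start, end, strand, cfg.max_exons)
                )
                occupancy[c].add(start - _GENE_CLEARANCE, end + _GENE_CLEARANCE)
                pos = end + min_gap + extra[j + 1]

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )

    # --- TEs: enriched in the pericentromere, avoiding gene envelopes
    te_rows = []
    chrom_weights = np.full(len(chroms), 1.0 / len(chroms))
    for i in range(cfg.n_tes):
        length = int(rng.integers(cfg.te_len_range[0], cfg.te_len_range[1] + 1))
        placed = False
        for _ in range(2000):
            c = chroms[rng.choice(len(chroms), p=chrom_weights)]
            ps, pe = pericentromere(cfg, cfg.chrom_len)
            if rng.random() < cfg.te_pericentromere_frac:
                lo, hi = ps, pe - length
            else:
                lo, hi = 100, cfg.chrom_len - length - 100
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if occupancy[c].try_add(start, start + length):
                te_rows.append((f"te{i + 1:04d}", c, start, start + length))
                placed = True
                break
        if not placed:
            raise ValueError("chrom_len too small to place requested TEs")
    tes = pd.DataFrame(te_rows, columns=["te_id", "chrom", "start", "end"])

    return GenomeModel(
        seqs=seqs, genes=genes, exons=exons, tes=tes, control_contig=control
    )


def _make_exons(rng, gene_id, chrom, start, end, strand, max_exons):
    n_ex = int(rng.integers(1, max_exons + 1))
    length = end - start
    if n_ex == 1 or length < 60 * (2 * n_ex - 1):
        return [(gene_id, chrom, start, end, strand)]
    n_blocks = 2 * n_ex - 1  # exon/intron alternation, exons at both ends
    u = rng.random(n_blocks)
    sizes = 60 + np.floor((length - 60 * n_blocks) * u / u.sum()).astype(int)
    sizes[-1] += length - int(sizes.sum())
    edges = start + np.concatenate([[0], np.cumsum(sizes)])
    return [
        (gene_id, chrom, int(edges[i]), int(edges[i + 1]), strand)
        for i in range(0, n_blocks, 2)
    ]


# ---------------------------------------------------------------------------
# methylome


def _choose_gene_roles(genome: GenomeModel, cfg: SimConfig, rng) -> tuple:
    gene_ids = list(genome.genes["gene_id"])
    n_sil = int(round(cfg.frac_silenced * len(gene_ids)))
    perm = list(rng.permutation(gene_ids))
    silenced = sorted(perm[:n_sil])
    candidates = perm[n_sil:]
    if cfg.n_de_genes > len(candidates):
        raise ValueError("not enough non-silenced genes for requested DE genes")
    de_ids = candidates[: cfg.n_de_genes]
    signs = np.where(np.arange(len(de_ids)) % 2 == 0, 1, -1)
    n_linked = int(round(cfg.frac_dmr_linked_degs * len(de_ids)))
    linked = np.zeros(len(de_ids), dtype=bool)
    linked[list(rng.choice(len(de_ids), size=n_linked, replace=False))] = True
    de = pd.DataFrame({"gene_id": de_ids, "sign": signs, "dmr_linked": linked})
    de = de.sort_values("gene_id", ignore_index=True)
    return silenced, de


def _plant_regions(genome: GenomeModel, cfg: SimConfig, rng, de: pd.DataFrame):
    """Choose grid-aligned planted DMR intervals (recovery + DEG-linked)."""
    chroms = genome.chromosomes
    occ = {c: _Occupancy() for c in chroms}
    for _, g in genome.genes.iterrows():
        occ[g.chrom].add(g.start - _GENE_CLEARANCE, g.end + _GENE_CLEARANCE)
    for _, t in genome.tes.iterrows():
        occ[t.chrom].add(t.start - 100, t.end + 100)

    rows = []
    # recovery regions: intergenic, background-free comparison
    for context in CONTEXTS:
        for i in range(cfg.n_planted_dmrs):
            placed = False
            for _ in range(5000):
                c = chroms[int(rng.integers(0, len(chroms)))]
                L = len(genome.seqs[c])
                n_slots = (L - cfg.planted_dmr_len) // 100
                start = int(rng.integers(1, n_slots)) * 100
                end = start + cfg.planted_dmr_len
                if occ[c].try_add(start - 100, end + 100):
                    direction = "hyper" if i % 2 == 0 else "hypo"
                    rows.append(
                        (c, start, end, context, direction)
                        + RECOVERY_COMPARISON
                        + ("recovery", "")
                    )
                    placed = True
                    break
            if not placed:
                raise ValueError("no room left for planted DMR regions")

    # DEG-linked regions: in the promoter or body of linked DE genes,
    # planted on the tissue (green vs white) contrast at all times
    genes = genome.genes.set_index("gene_id")
    linked_ids = list(de.loc[de["dmr_linked"], "gene_id"])
    for j, gid in enumerate(linked_ids):
        g = genes.loc[gid]
        zone = "promoter" if j % 2 == 0 else "body"
        if zone == "promoter":
            if g.strand == "+":
                lo, hi = g.start - FLANK_BP, g.start - cfg.deg_dmr_len
            else:
                lo, hi = g.end, g.end + FLANK_BP - cfg.deg_dmr_len
        else:
            lo, hi = g.start, g.end - cfg.deg_dmr_len
        starts = [s for s in range(-(-lo // 100) * 100, hi + 1, 100)]
        if not starts:  # very short gene: fall back to promoter
            continue
        start = int(starts[int(rng.integers(0, len(starts)))])
        context = CONTEXTS[j % 3]
        direction = "hypo" if de.set_index("gene_id").loc[gid, "sign"] > 0 else "hyper"
        rows.append(
            (g.chrom, start, start + cfg.deg_dmr_len, context, direction)
            + ("green", "white")
            + ("deg", gid)
        )
    return pd.DataFrame(rows, columns=PLANTED_DMR_COLUMNS)


def simulate_methylome(
    genome: GenomeModel, cfg: SimConfig
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-sample cytosine call sets plus the ground truth of planted effects."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    design_rng = np.random.default_rng([cfg.seed, 3])
    silenced, de = _choose_gene_roles(genome, cfg, design_rng)
    planted = _plant_regions(genome, cfg, design_rng, de)
    truth = GroundTruth(
        planted_dmrs=planted,
        de_genes=de,
        silenced_genes=silenced,
        control_contig=genome.control_contig,
    )

    base = np.array([cfg.base_levels[c] for c in CONTEXTS])
    diel_amp = {
        "CG": cfg.diel_cg_amplitude,
        "CHG": cfg.diel_chg_amplitude,
        "CHH": cfg.diel_chh_amplitude,
    }

    calls: dict[str, pd.DataFrame] = {
        s: [] for s in (sample_name(t, tm, r) for t in TISSUES for tm in TIMES for r in REPLICATES)
    }
    contigs = list(genome.chromosomes) + [genome.control_contig]
    for chrom in contigs:
        pos0, minus, ctx = contexts_in_sequence(genome.seqs[chrom])
        n = len(pos0)
        te_mask = np.zeros(n, dtype=bool)
        if chrom == genome.control_contig:
            p_shared = np.zeros(n)
        else:
            p_shared = base[ctx].copy()
            te = genome.tes[genome.tes["chrom"] == chrom]
            if len(te):
                ms, me = merge_intervals(te["start"].to_numpy(), te["end"].to_numpy())
                te_mask = point_in_intervals(pos0, ms, me)
                p_shared[te_mask] += cfg.te_boost
            sil = genome.genes[genome.genes["gene_id"].isin(silenced)]
            sil = sil[sil["chrom"] == chrom]
            if len(sil):
                ms, me = merge_intervals(
                    sil["start"].to_numpy() - FLANK_BP, sil["end"].to_numpy() + FLANK_BP
                )
                p_shared[point_in_intervals(pos0, ms, me)] += cfg.silenced_promoter_boost
            # shared regional variation of the true level (identical in all
            # samples, so it never creates differential signal)
            tile = pos0 // cfg.regional_tile
            n_tiles = int(tile.max()) + 1 if n else 0
            for ci, cname in enumerate(CONTEXTS):
                sd = cfg.regional_sd.get(cname, 0.0)
                jit = rng.normal(0.0, sd, n_tiles) if sd > 0 else np.zeros(n_tiles)
                sel = ctx == ci
                p_shared[sel] += jit[tile[sel]]
            # planted regions keep a clean baseline so effect sizes are exact
            for d in planted[planted["chrom"] == chrom].itertuples():
                ci = CONTEXTS.index(d.context)
                lo = np.searchsorted(pos0, d.start, side="left")
                hi = np.searchsorted(pos0, d.end, side="left")
                sel = np.flatnonzero(ctx[lo:hi] == ci) + lo
                p_shared[sel] = base[ci]

        # pre-resolve planted-region site selections; planted sites keep a
        # clean context baseline (no tissue/diel/regional terms) so the
        # realized |delta| of each planted comparison equals its effect
        pl_rows = []
        for d in planted[planted["chrom"] == chrom].itertuples():
            ci = CONTEXTS.index(d.context)
            lo = np.searchsorted(pos0, d.start, side="left")
            hi = np.searchsorted(pos0, d.end, side="left")
            sel = np.flatnonzero(ctx[lo:hi] == ci) + lo
            boosted = d.group_a if d.direction == "hyper" else d.group_b
            pl_rows.append((sel, ci, boosted, cfg.planted_effect[d.context]))
        for tissue in TISSUES:
            for time in TIMES:
                p = p_shared.copy()
                if chrom != genome.control_contig:
                    if tissue == "white":
                        p[ctx == 2] -= cfg.tissue_chh_delta
                    else:
                        scope = te_mask if cfg.diel_scope == "te" else np.ones(n, bool)
                        for ci, cname in enumerate(CONTEXTS):
                            amp = diel_amp[cname]
                            if amp:
                                p[scope & (ctx == ci)] += DIEL_SIGN[time] * amp
                    group = f"{tissue}_{time}"
                    for sel, ci, boosted, effect in pl_rows:
                        p[sel] = base[ci]
                        if boosted == group or boosted == tissue:
                            p[sel] += effect
                np.clip(p, 0.0, 1.0, out=p)
                p_obs = p + (1.0 - p) * cfg.conversion_error
                for rep in REPLICATES:
                    s = sample_name(tissue, time, rep)
                    tot = rng.poisson(cfg.mean_coverage, size=n)
                    meth = rng.binomial(tot, p_obs)
                    calls[s].append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": (pos0 + 1).astype(np.int64),
                                "strand": np.where(minus, "-", "+"),
                                "context": np.array(CONTEXTS, dtype=object)[ctx],
                                "n_meth": meth.astype(np.int64),
                                "n_total": tot.astype(np.int64),
                            }
                        )
                    )

    out = {
        s: pd.concat(parts, ignore_index=True)[CALL_COLUMNS]
        for s, parts in calls.items()
    }
    return out, truth


# ---------------------------------------------------------------------------
# expression


def exonic_lengths(genome: GenomeModel) -> pd.Series:
    """Summed exon length per gene (bp)."""
    if len(genome.exons) == 0:
        return pd.Series(dtype=np.int64, name="length")
    lens = (
        (genome.exons["end"] - genome.exons["start"])
        .groupby(genome.exons["gene_id"])
        .sum()
    )
    lens.name = "length"
    return lens.reindex(genome.genes["gene_id"]).astype(np.int64)


def simulate_expression(
    genome: GenomeModel, truth: GroundTruth, cfg: SimConfig
) -> dict:
    """Negative-binomial RNA counts, gene lengths and a GO map.

    Returns a dict with ``counts`` (genes x 16 samples), ``lengths``
    (exonic bp per gene) and ``go_map`` (gene_id, go_id rows).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    gene_ids = list(genome.genes["gene_id"])
    lengths = exonic_lengths(genome)

    base = rng.lognormal(np.log(cfg.base_mean_count), cfg.expression_sdlog, len(gene_ids))
    base = pd.Series(base, index=gene_ids)
    base[truth.silenced_genes] *= cfg.silenced_expression_factor
    de = truth.de_genes.set_index("gene_id")
    # keep planted DE genes comfortably detectable
    base[de.index] = np.maximum(base[de.index], 50.0)

    samples = [
        sample_name(t, tm, r) for t in TISSUES for tm in TIMES for r in REPLICATES
    ]
    lib_factor = {s: rng.uniform(0.7, 1.3) for s in samples}
    counts = {}
    r_disp = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else None
    for s in samples:
        tissue = s.split("_")[0]
        mu = base.to_numpy() * (lengths.to_numpy() / 1000.0) * lib_factor[s]
        fc = np.ones(len(gene_ids))
        sign = de["sign"].reindex(gene_ids).fillna(0).to_numpy()
        shift = 2.0 ** (cfg.de_log2fc / 2.0)
        if tissue == "green":
            fc = np.where(sign > 0, shift, np.where(sign < 0, 1 / shift, 1.0))
        else:
            fc = np.where(sign > 0, 1 / shift, np.where(sign < 0, shift, 1.0))
        mu = mu * fc
        if r_disp is None:
            counts[s] = rng.poisson(mu)
        else:
            p = r_disp / (r_disp + mu)
            counts[s] = rng.negative_binomial(r_disp, p)
    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))

    go_rows = []
    de_set = set(de.index)
    for g in gene_ids:
        go_rows.append((g, "GO:0008150"))  # root term: every gene annotated
        pr = cfg.planted_go_de_frac if g in de_set else cfg.planted_go_bg_frac
        if rng.random() < pr:
            go_rows.append((g, cfg.planted_go_term))
        for t in range(cfg.n_go_terms):
            if rng.random() < 0.12:
                go_rows.append((g, f"GO:{7000000 + t}"))
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_id"])
    return {"counts": counts, "lengths": lengths, "go_map": go_map}


def simulate_study(cfg: SimConfig) -> dict:
    """Full synthetic study: genome, methylome calls, truth, expression."""
    genome = simulate_genome(cfg)
    calls, truth = simulate_methylome(genome, cfg)
    expr = simulate_expression(genome, truth, cfg)
    return {"genome": genome, "truth": truth, "calls": calls, **expr}
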