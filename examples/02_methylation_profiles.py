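"""Gene metaplots and chromosome-scale methylation tracks.

Computes the classic upstream / gene-body / downstream metaplot (100-bp
flank bins, 20 proportional body bins) for the CHH context in both
tissues, and a sliding-window chromosome track with gene/TE densities.
"""

import numpy as np

import dielmeth as dm
from dielmeth.core import pool_calls
from dielmeth.profiles import chromosome_track

cfg = dm.SimConfig(
    seed=7, n_chrom=1, chrom_len=200_000, control_len=5_000,
    n_genes=20, n_tes=15, n_planted_dmrs=5, n_de_genes=8,
)
study = dm.simulate_study(cfg)
genome = study["genome"]
sizes = {c: len(genome.seqs[c]) for c in genome.chromosomes}

for tissue in ("green", "white"):
    pooled = pool_calls(
        [study["calls"][s] for tm in dm.TIMES for s in dm.group_samples(f"{tissue}_{tm}")]
    )
    prof = dm.feature_metaprofile(pooled, genome.genes, "CHH", flank=2000, n_bins=20)
    body = prof[prof["zone"] == "body"]["level"].mean()
    up = prof[prof["zone"] == "upstream"]["level"].mean()
    print(f"{tissue}: mean CHH level  upstream 2kb = {up:.3f}  gene body = {body:.3f}")
# green exceeds white in CHH: the tissue contrast the study design plants.

pooled = pool_calls([study["calls"][s] for s in dm.group_samples("green_4pm")])
wt = dm.make_windows(pooled, sizes, width=50_000, step=10_000)
track = chromosome_track(wt, genome.genes, genome.tes)
chh = track[track["context"] == "CHH"]
print("\nchromosome track (window start, CHH level, TE count):")
for r in chh.iloc[::4].itertuples():
    bar = "#" * int(40 * (0 if np.isnan(r.level) else r.level))
    print(f"  {r.start:>7} {r.level:5.3f} te={r.te_count:<2} {bar}")
# the TE-dense centre of the chromosome (pericentromere) is hypermethylated.
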