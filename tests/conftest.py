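import pandas as pd
import pytest

from dielmeth import SimConfig, simulate_study


def tiny_config(seed: int = 11, **overrides) -> SimConfig:
    """Scaled-down study used by unit tests (one 200-kb chromosome)."""
    base = dict(
        seed=seed,
        n_chrom=1,
        chrom_len=200_000,
        control_len=5_000,
        n_genes=20,
        n_tes=15,
        n_planted_dmrs=5,
        n_de_genes=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg) -> dict:
    return simulate_study(tiny_cfg)


def toy_calls(rows) -> pd.DataFrame:
    """Call-set DataFrame from (chrom, pos, strand, context, n_meth, n_total) rows."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
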