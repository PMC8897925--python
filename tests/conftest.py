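import numpy as np
import pandas as pd
import pytest

from lensepi.config import SimConfig
from lensepi.synthetic import simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=42, genome_length=1_500_000, cpg_rate=0.04,
                    n_genes=120, n_planted_dmrs=80, dmr_span_range=(200, 300),
                    effect_size=0.4, dispersion_phi=0.1, coverage_mean=30,
                    dmr_min_cpgs=8)
    return simulate_bundle(cfg)


def make_records(rows):
    """Cytosine-record table from (chrom, pos, group, rep, n_meth, n_total)."""
    return pd.DataFrame(
        [(c, p, "CG", g, r, m, t) for c, p, g, r, m, t in rows],
        columns=["chrom", "pos", "context", "group", "replicate",
                 "n_meth", "n_total"],
    )


def pearson(x, y):
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])
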