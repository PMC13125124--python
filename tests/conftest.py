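import numpy as np
import pandas as pd
import pytest

from bsaqtl.genofilter import GenotypeMatrix
from bsaqtl.simdata import PlantedQtl, default_config, simulate_genotypes, simulate_phenotypes


def make_matrix(calls, samples=None, chrom="Chr01", start=1000, spacing=1000):
    """GenotypeMatrix from a (n_loci, n_samples) array of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samples = calls.shape
    samples = samples or [f"S{i}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(n_loci),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(loci=loci, samples=list(samples), calls=calls)


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated population shared across tests: 4 chromosomes,
    one large-effect QTL on Chr02, 80 RILs, clean calls."""
    cfg = default_config(
        seed=11,
        n_chromosomes=4,
        snps_per_chr=300,
        chr_length_bp=20_000_000,
        n_rils=80,
        traits=["protein", "lysine"],
        trait_means={"protein": 43.5, "lysine": 2.72},
        var_G={"protein": 1.2, "lysine": 0.008},
        var_E={"protein": 1.0, "lysine": 0.007},
        var_GEI={"protein": 0.6, "lysine": 0.004},
        var_block={"protein": 0.1, "lysine": 0.001},
        var_error={"protein": 0.8, "lysine": 0.006},
        trait_cor=np.array([[1.0, 0.6], [0.6, 1.0]]),
        qtl=[PlantedQtl("Chr02", 10_000_000, {"protein": 1.0, "lysine": 0.08})],
        missing_rate=0.0,
        error_rate=0.0,
    )
    G, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(G, truth, cfg)
    return cfg, G, truth, pheno
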