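import numpy as np
import pandas as pd
import pytest

from legacygwas import (GenotypePanel, SimConfig, compute_kinship, impute_missing,
                        qc_filter, simulate_genotypes)

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


def panel_from_dosages(dosages, chrom="chr1", spacing=1000, varieties=None):
    """Build a GenotypePanel directly from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame({
        "id": [f"{chrom}_{(j + 1) * spacing}" for j in range(m)],
        "chrom": chrom,
        "pos": [(j + 1) * spacing for j in range(m)],
        "ref": "A", "alt": "T",
    })
    varieties = varieties or [f"v{i:03d}" for i in range(n)]
    return GenotypePanel(markers, varieties, dosages)


@pytest.fixture(scope="session")
def small_panel():
    """LD panel with missing calls, 120 varieties x 2 chromosomes."""
    cfg = SimConfig(n_individuals=120, markers_per_chromosome=120,
                    n_chromosomes=2, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def imputed_panel(small_panel):
    return impute_missing(qc_filter(small_panel))


@pytest.fixture(scope="session")
def kinship(imputed_panel):
    return compute_kinship(imputed_panel)
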