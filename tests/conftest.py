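import pandas as pd
import pytest

from nascentreg.counts_differential import SampleSheet
from nascentreg.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete synthetic dataset shared across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(
        seed=11,
        n_chrom=2,
        chrom_len=250_000,
        n_genes=60,
        n_promoter_peaks=60,
        n_enhancer_peaks=35,
        n_intronic_peaks=20,
        n_contaminant_peaks=5,
    )
    truth = simulate_dataset(config, out)
    return out, truth, config


@pytest.fixture
def sheet_6v6():
    """csRNA-style design: 6 sulfidic vs 6 non-sulfidic over 3 drainages."""
    drainages = ["Pichucalco", "Puyacatengo", "Tacotalpa"]
    rows = []
    for eco in ("sulfidic", "nonsulfidic"):
        for drain in drainages:
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"cs_{eco}_{drain}_{rep}",
                        "assay": "csrna",
                        "ecotype": eco,
                        "drainage": drain,
                        "species": "mexicana",
                    }
                )
    return SampleSheet(pd.DataFrame(rows))
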