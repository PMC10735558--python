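import numpy as np
import pandas as pd
import pytest

from durumwp import assoc, simdata


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete synthetic trial bundle shared across tests."""
    cfg = simdata.SimConfig(n_genotypes=80, n_environments=14, n_markers=300,
                            n_chromosomes=4, n_qtl=3, seed=42)
    dosage, marker_map, plots, climate, truth = simdata.simulate_dataset(cfg)
    return {"cfg": cfg, "dosage": dosage, "marker_map": marker_map,
            "plots": plots, "climate": climate, "truth": truth}


@pytest.fixture()
def random_panel():
    """Unstructured random inbred panel: 200 genotypes × 500 markers."""
    rng = np.random.default_rng(7)
    n, m = 200, 500
    G = rng.choice([0.0, 2.0], size=(n, m))
    genos = [f"g{i:03d}" for i in range(n)]
    markers = [f"m{j:04d}" for j in range(m)]
    dosage = pd.DataFrame(G, index=genos, columns=markers)
    marker_map = pd.DataFrame({"marker_id": markers, "chromosome": "chr1",
                               "position": np.arange(m) * 1_000_000 + 1,
                               "alleles": "A/B"})
    return assoc.MarkerPanel(dosage, marker_map)
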