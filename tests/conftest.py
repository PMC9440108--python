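import warnings

import numpy as np
import pytest

import paleoseason as ps

# taxa excluded after bootstrap resampling etc. are routine in small fixtures
warnings.filterwarnings("ignore", message="taxa absent from all training sites")


@pytest.fixture(scope="session")
def small_training():
    """Compact synthetic survey for cheap unit tests (80 sites, 20 taxa)."""
    cfg = ps.SimConfig(n_sites=80, n_species=20, count_depth=400)
    responses = ps.make_species_responses(cfg, seed=11)
    taxa, env = ps.simulate_training_set(cfg, responses, seed=11)
    return cfg, responses, taxa, env


@pytest.fixture(scope="session")
def default_run():
    """Full default study conditions plus the fossil sequence and truth."""
    cfg = ps.SimConfig()
    responses = ps.make_species_responses(cfg, seed=1)
    taxa, env = ps.simulate_training_set(cfg, responses, seed=1)
    history = ps.simulate_temperature_history(seed=1)
    fossil, truth = ps.simulate_fossil_sequence(
        history, responses, resolution=cfg.fossil_resolution,
        count_depth=cfg.count_depth, seed=1)
    return {"cfg": cfg, "responses": responses, "taxa": taxa, "env": env,
            "history": history, "fossil": fossil, "truth": truth}


@pytest.fixture()
def linear_system():
    """Noise-free two-taxon mixing system: WA with deshrinking recovers the
    gradient exactly, so cross-validation errors are numerically zero."""
    x = np.linspace(5.0, 95.0, 30)
    vals = np.column_stack([x, 100.0 - x])
    taxa = ps.TaxonTable([f"s{i}" for i in range(30)], ["taxA", "taxB"],
                         vals, kind="percent")
    return taxa, x
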