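import numpy as np
import pandas as pd
import pytest

from offtarget import fbarescue, synthio

SUPPLEMENTS = ["thymidine", "uridine", "imp", "amp",
               "serine", "glycine", "aspartate", "citrate"]


@pytest.fixture(scope="session")
def toy_model():
    return synthio.make_toy_model()


@pytest.fixture(scope="session")
def shutoff_model(toy_model):
    """Toy model with wild-type expression applied (adeD/citT off, no
    spontaneous reactions)."""
    spec = synthio.ToyModelSpec()
    m = fbarescue.apply_expression_shutoff(
        toy_model, set(spec.unexpressed_genes), scope="global")
    return fbarescue.close_spontaneous_reactions(m)


@pytest.fixture(scope="session")
def baseline_solution(toy_model):
    return fbarescue.pfba(toy_model)


@pytest.fixture(scope="session")
def strong_panel():
    """Metabolomics panel with class effects far above noise (clearly
    separable; separability is asserted by oracle where needed)."""
    cfg = synthio.SynthConfig(seed=11, n_replicates=3, noise_sd=0.2,
                              effect_size=3.0)
    return synthio.simulate_metabolomics(cfg)


@pytest.fixture(scope="session")
def experimental_rescue():
    """Constructed rescue growth-rate pattern: thymidine/IMP/serine grow near
    0.6 1/hr, the rest stay near the inhibited rate."""
    rng = np.random.default_rng(5)
    vals = {}
    for s in SUPPLEMENTS:
        base = 0.6 if s in ("thymidine", "imp", "serine") else 0.12
        vals[s] = base + 0.01 * rng.standard_normal()
    return pd.Series(vals)
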