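import numpy as np
import pandas as pd
import pytest

from ridgescape.simdata import (SimulationConfig, env_at_sites, place_demes,
                                simulate_genotypes, simulate_landscape)


def standard_sim(seed: int, **overrides):
    """One synthetic study system: landscape, deme env table, genotypes, truth."""
    cfg = SimulationConfig(seed=seed, **overrides)
    land = simulate_landscape(cfg)
    cells = place_demes(cfg)
    site_env = env_at_sites(land["current"], cells)
    gm, truth = simulate_genotypes(cfg, site_env)
    env_per_sample = site_env.loc[gm.demes].reset_index(drop=True)
    return {"config": cfg, "land": land, "cells": cells, "site_env": site_env,
            "gm": gm, "truth": truth, "env": env_per_sample}


@pytest.fixture(scope="session")
def planted_sim():
    """Standard conditions with planted clines (slope 2, FST 0.05)."""
    return standard_sim(3)


@pytest.fixture(scope="session")
def null_sim():
    """No planted effect: every locus neutral."""
    return standard_sim(11, n_adaptive_loci=0)


@pytest.fixture(scope="session")
def small_sim():
    """Cheap instance for structural checks."""
    return standard_sim(7, n_demes=8, n_per_deme=6, n_neutral_loci=120,
                        n_adaptive_loci=10, grid_shape=(15, 15))
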