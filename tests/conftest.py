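import numpy as np
import pytest

import adipoloc as al


@pytest.fixture()
def single_signal_region():
    """A well-powered single-causal-variant region with its ground truth."""
    config = al.RegionSimConfig(
        n_variants=30,
        n_individuals=2000,
        ld_rho=0.9,
        causal_indices=(12,),
        effect_sizes=(0.25,),
        noise_sd=1.0,
        seed=42,
    )
    panel = al.simulate_genotypes(config)
    trait = al.simulate_trait(panel, config)
    stats = al.marginal_summary_stats(panel, trait)
    return config, panel, trait, stats


@pytest.fixture()
def ideal_standard_curve():
    """Noise-free identity standard curve at the five default mix levels."""
    levels = np.repeat([30.0, 40.0, 50.0, 60.0, 70.0], 3)
    return al.StandardCurveData(true_pct=levels, observed_pct=levels.copy())
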