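import numpy as np
import pytest
from hypothesis import settings

import ilrkit as ik

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return ik.load_registry()


@pytest.fixture(scope="session")
def tricaprylin_formulation(registry):
    return ik.Formulation(
        components=((registry["tricaprylin"], 125.0),),
        volume_ml=20.0, surfactant_mass_fraction=0.25, name="tricaprylin")


@pytest.fixture(scope="session")
def clean_config(tricaprylin_formulation):
    """Zero-noise, zero-lag, fully ionized, blank-free synthetic setup:
    the pipeline should recover its ground truth up to discretization."""
    return ik.SyntheticConfig(
        formulation=tricaprylin_formulation, diameter_nm=250.0,
        ground_truth_ilr=5.0e-3, lag_min=0.0, ionized_fraction=1.0,
        blank_rate_umol_min=0.0, noise_sd_umol=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_experiment(clean_config):
    return ik.generate_experiment(clean_config)


def recover_ilr(experiment, **segment_kwargs):
    """Run the full correction + segmentation + normalisation pipeline."""
    curve = ik.process_record(experiment.sample, experiment.blank)
    rate = ik.segment_curve(
        curve, theoretical_fa_umol=experiment.ground_truth[
            "theoretical_fa_umol"], **segment_kwargs)
    area = ik.total_surface_area(experiment.droplets)
    return ik.compute_ilr(rate, area), rate, curve
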