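import numpy as np
import pytest

from spindrift import eem as eemod
from spindrift import synthetic as syn
from spindrift.pipeline import analyze_campaign, process_eem


@pytest.fixture(scope="session")
def truth():
    return syn.EEMTruth()


@pytest.fixture(scope="session")
def water_reference(truth):
    return syn.make_water_reference(truth)


@pytest.fixture(scope="session")
def calibration(truth, water_reference):
    """Calibration fitted from synthetic standards at the default noise."""
    standards = [
        (c, syn.make_eem(c, truth, noise_sigma=1.0, seed=100 + i, include_ambient=False))
        for i, c in enumerate((0.5, 1.0, 2.0, 4.0, 8.0))
    ]
    band = truth.raman_band
    processed = [(c, process_eem(e, water_reference, band)) for c, e in standards]
    return eemod.fit_calibration(processed, raman_band=band)


@pytest.fixture(scope="session")
def noise_free_calibration(truth, water_reference):
    standards = [
        (c, syn.make_eem(c, truth, noise_sigma=0.0, include_ambient=False))
        for c in (1.0, 2.0, 5.0)
    ]
    band = truth.raman_band
    processed = [(c, process_eem(e, water_reference, band)) for c, e in standards]
    return eemod.fit_calibration(processed, raman_band=band)


def quantify_raw(raw, water_reference, cal):
    proc = process_eem(raw, water_reference, cal)
    return eemod.quantify(proc, cal)


@pytest.fixture(scope="session")
def campaign():
    return syn.make_campaign(syn.CampaignConfig(seed=1))


@pytest.fixture(scope="session")
def campaign_result(campaign):
    return analyze_campaign(campaign)


@pytest.fixture(scope="session")
def recovery_result():
    camp = syn.make_campaign(syn.recovery_config(seed=2))
    return camp, analyze_campaign(camp)


def small_config(**overrides) -> syn.CampaignConfig:
    """A reduced-domain single-day campaign for fast tests."""
    base = dict(
        seed=0,
        n_days=1,
        alongshore_length_m=1200.0,
        offshore_width_m=240.0,
        inland_width_m=800.0,
        release_alongshore_m=600.0,
        sampler_sites=(("T1", 100.0, 600.0),),
    )
    base.update(overrides)
    return syn.CampaignConfig(**base).validate()
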