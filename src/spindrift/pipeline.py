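"""End-to-end analysis driver: raw campaign bundle -> results table.

Processing order per sample: background-correct -> Raman-normalise ->
quantify liquid concentration -> air concentration -> pattern flag; then
blank statistics -> LoD -> dual-criteria classification; in parallel,
wind/tide source attribution; finally the joined results table and
campaign summary.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import attribution as attr
from . import eem as eemod
from . import exposure, reporting
from .eem import CalibrationModel
from .exposure import BlankSet
from .synthetic import Campaign


@dataclass
class CampaignResult:
    calibration: CalibrationModel
    blank_set: BlankSet
    table: pd.DataFrame
    attributions: pd.DataFrame
    summary: dict


def process_eem(raw, water_reference, cal_or_band, background_rect=None):
    """Background-correct and Raman-normalise one raw EEM."""
    if isinstance(cal_or_band, CalibrationModel):
        rect = cal_or_band.background_rect
        band = cal_or_band.raman_band
    else:
        rect = background_rect if background_rect is not None else eemod.DEFAULT_BACKGROUND_RECT
        band = cal_or_band
    ref = eemod.background_correct(water_reference, rect)
    corrected = eemod.background_correct(raw, rect)
    return eemod.raman_normalize(corrected, ref, band)


def fit_campaign_calibration(campaign: Campaign, **kwargs) -> CalibrationModel:
    """Fit the calibration model from the campaign's standards, processed
    through the same correction/normalisation chain as the samples."""
    band = campaign.truth.raman_band
    kwargs.setdefault("raman_band", band)
    processed = [
        (c, process_eem(e, campaign.water_reference, band, kwargs.get("background_rect")))
        for c, e in campaign.standards
    ]
    return eemod.fit_calibration(processed, **kwargs)


def analyze_campaign(
    campaign: Campaign, pattern_threshold: float = 0.9
) -> CampaignResult:
    """Run the complete pipeline on a campaign bundle."""
    cal = fit_campaign_calibration(campaign)

    def _measure(sample):
        proc = process_eem(sample.eem, campaign.water_reference, cal)
        sample.liquid_conc_ppb = eemod.quantify(proc, cal)
        sample.compute_air_concentration()
        sample.pattern_flag = eemod.detect_pattern(proc, cal, pattern_threshold)
        return sample

    for s in campaign.samples:
        _measure(s)
    for b in campaign.blanks:
        _measure(b)

    blank_set = BlankSet([b.air_conc_pg_m3 for b in campaign.blanks])

    atts = attr.attribute_samples(
        campaign.samples,
        campaign.wind,
        campaign.dye_maps,
        campaign.terrain,
        campaign.water_level,
    )
    samples_df = pd.DataFrame(
        {
            "id": [s.id for s in campaign.samples],
            "site": [s.site_id for s in campaign.samples],
            "period": [
                "night" if (s.end - s.start) > pd.Timedelta(hours=10) else "day"
                for s in campaign.samples
            ],
            "air_volume_m3": [s.air_volume_m3 for s in campaign.samples],
            "pattern": [s.pattern_flag for s in campaign.samples],
            "air_conc_pg_m3": [s.air_conc_pg_m3 for s in campaign.samples],
        }
    )
    table = reporting.build_results_table(samples_df, atts, blank_set.lod)
    for s in campaign.samples:
        exposure.classify(s, blank_set.lod)
    summary = reporting.summarize(table)
    summary["lod_pg_m3"] = blank_set.lod
    return CampaignResult(
        calibration=cal,
        blank_set=blank_set,
        table=table,
        attributions=atts,
        summary=summary,
    )
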