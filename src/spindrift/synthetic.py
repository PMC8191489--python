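"""Synthetic coastal dye-release campaign generator.

Emulates every input stream the exposure analysis consumes, so the full
pipeline is testable without field data:

* a planar beach (constant slope) whose shoreline excursion under a
  water level ``eta`` is exactly ``eta / slope`` — analytically checkable;
* a sinusoidal semidiurnal tide;
* a diurnally modulated onshore wind with Gaussian direction jitter;
* a surfzone-confined dye plume: Gaussian alongshore (advected by a
  steady alongshore current, spreading diffusively), with a fixed
  cross-shore profile hugging the tidally moving shoreline, rasterised
  to 2 m x 2 m hourly daytime maps;
* EEM spectra whose tracer signal is linear in concentration, riding on
  a constant background, a water-Raman ridge, a weak broad ambient
  fluorophore hump, and additive Gaussian noise;
* aerosol samples whose *true* air concentration couples to the sea as

      [dye]_air = k * [dye]_sea * exp(-downwind / decay_length)

  where [dye]_sea is the upwind-window average computed with the same
  attribution geometry the pipeline uses, so with decay disabled the
  transfer coefficient k is recoverable end to end.

Fixing the seed makes every output bit-identical across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .attribution import attribute_sample
from .core import DyeMap, Terrain, WaterLevelSeries, WindSeries
from .eem import EEM, RamanBand, acquisition_grids, raman_shifted_emission
from .exposure import AerosolSample

HOUR = np.timedelta64(3600, "s")


class ConfigurationError(ValueError):
    pass


@dataclass
class CampaignConfig:
    """All knobs of the synthetic campaign; defaults are the study
    conditions the analysis assumes (see docs/methods.md)."""

    seed: int = 0
    start_time: str = "2015-09-23T06:00:00"
    n_days: int = 2

    # domain and beach (local metres; shoreline alongshore = y/north,
    # ocean at x < 0, land at x > 0, datum shoreline at x = shore_x)
    alongshore_length_m: float = 3000.0
    offshore_width_m: float = 400.0
    inland_width_m: float = 1500.0
    beach_slope: float = 0.02
    shore_x_m: float = 0.0
    terrain_cell_m: float = 10.0

    # tide
    tide_amplitude_m: float = 0.8
    tide_period_h: float = 12.42

    # wind regime (onshore = from the west for this layout)
    wind_mean_speed_ms: float = 5.0
    wind_mean_dir_deg: float = 270.0
    wind_diurnal_amplitude_ms: float = 2.0
    wind_speed_sigma_ms: float = 0.5
    wind_dir_sigma_deg: float = 12.0
    wind_dt_min: float = 10.0

    # dye release and surfzone plume
    release_mass_ppb_m2: float = 2.0e5
    release_alongshore_m: float = 800.0
    release_delay_h: float = 2.0
    current_ms: float = 0.03
    diffusivity_m2s: float = 1.0
    surfzone_width_m: float = 100.0
    initial_sigma_m: float = 50.0
    dye_cell_m: float = 2.0
    map_interval_h: float = 1.0
    map_day_start_h: float = 8.0
    map_day_end_h: float = 17.0

    # air-sea coupling truth
    k_pg_m3_per_ppb: float = 200.0
    decay_length_m: Optional[float] = 500.0

    # sampling
    sampler_sites: tuple = (
        ("S1", 120.0, 1200.0),
        ("S2", 350.0, 1500.0),
        ("S3", 700.0, 900.0),
    )  # (site_id, x inland of datum shoreline, y alongshore)
    air_flow_m3_per_h: float = 27.0  # 450 l/min sampler
    liquid_volume_ml: float = 10.0
    n_blanks: int = 4

    # EEM instrument truth
    eem_noise_sigma: float = 1.0
    standard_concs_ppb: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)

    def validate(self) -> "CampaignConfig":
        if self.beach_slope <= 0:
            raise ConfigurationError("beach slope must be positive")
        for name in (
            "alongshore_length_m", "offshore_width_m", "inland_width_m",
            "terrain_cell_m", "dye_cell_m", "tide_amplitude_m",
            "wind_mean_speed_ms", "release_mass_ppb_m2", "diffusivity_m2s",
            "surfzone_width_m", "k_pg_m3_per_ppb", "eem_noise_sigma",
            "air_flow_m3_per_h", "liquid_volume_ml",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 <= self.release_alongshore_m <= self.alongshore_length_m):
            raise ConfigurationError("dye release lies outside the domain")
        if self.decay_length_m is not None and self.decay_length_m <= 0:
            raise ConfigurationError("decay length must be positive (or None to disable)")
        max_tide_excursion = self.tide_amplitude_m / self.beach_slope
        for site_id, x, _y in self.sampler_sites:
            if x <= self.shore_x_m + max_tide_excursion:
                raise ConfigurationError(
                    f"sampler {site_id} is seaward of the shoreline at high tide"
                )
        return self

    @property
    def start(self) -> np.datetime64:
        return np.datetime64(self.start_time, "s")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["sampler_sites"] = [list(s) for s in self.sampler_sites]
        doc["standard_concs_ppb"] = list(self.standard_concs_ppb)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "sampler_sites" in doc:
            doc["sampler_sites"] = tuple(tuple(s) for s in doc["sampler_sites"])
        if "standard_concs_ppb" in doc:
            doc["standard_concs_ppb"] = tuple(doc["standard_concs_ppb"])
        return cls(**doc).validate()


# ---------------------------------------------------------------------------
# terrain and tide


def make_terrain(config: CampaignConfig) -> Terrain:
    """Planar beach: elevation = slope * (x - shore_x), so the shoreline
    at water level eta sits at x = shore_x + eta / slope."""
    config.validate()
    x = np.arange(-config.offshore_width_m, config.inland_width_m + 1e-9, config.terrain_cell_m)
    ny = int(round(config.alongshore_length_m / config.terrain_cell_m)) + 1
    elev_row = config.beach_slope * (x - config.shore_x_m)
    elevation = np.tile(elev_row, (ny, 1))
    return Terrain(elevation, (-config.offshore_width_m, 0.0), config.terrain_cell_m)


def make_water_level(config: CampaignConfig) -> WaterLevelSeries:
    """Sinusoidal semidiurnal tide sampled on the wind time base."""
    times = _campaign_times(config)
    t_h = (times - config.start) / HOUR
    eta = config.tide_amplitude_m * np.sin(2.0 * np.pi * t_h / config.tide_period_h)
    return WaterLevelSeries(times, eta)


def _campaign_times(config: CampaignConfig) -> np.ndarray:
    dt = np.timedelta64(int(round(config.wind_dt_min * 60)), "s")
    t0 = config.start - HOUR
    t1 = config.start + np.timedelta64(24 * config.n_days + 1, "h")
    n = int((t1 - t0) / dt) + 1
    return t0 + dt * np.arange(n)


# ---------------------------------------------------------------------------
# wind


def make_wind(config: CampaignConfig, seed: Optional[int] = None) -> WindSeries:
    """Diurnally modulated onshore wind regime with Gaussian jitter.

    Speed peaks mid-afternoon (sea-breeze-like); direction is the
    configured onshore mean plus wrapped Gaussian noise.  Identical seed
    reproduces the series exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = _campaign_times(config)
    hour_of_day = ((times - times.astype("datetime64[D]")) / HOUR) % 24.0
    diurnal = np.sin(2.0 * np.pi * (hour_of_day - 9.0) / 24.0)
    speed = (
        config.wind_mean_speed_ms
        + config.wind_diurnal_amplitude_ms * diurnal
        + rng.normal(0.0, config.wind_speed_sigma_ms, len(times))
    )
    speed = np.clip(speed, 0.0, None)
    direction = config.wind_mean_dir_deg + rng.normal(
        0.0, config.wind_dir_sigma_deg, len(times)
    )
    return WindSeries(times, speed, np.mod(direction, 360.0))


# ---------------------------------------------------------------------------
# dye plume maps


def _map_times(config: CampaignConfig) -> list:
    release_time = config.start + np.timedelta64(int(config.release_delay_h * 3600), "s")
    out = []
    step = np.timedelta64(int(config.map_interval_h * 3600), "s")
    for day in range(config.n_days):
        t = config.start.astype("datetime64[D]") + np.timedelta64(day, "D") + np.timedelta64(
            int(config.map_day_start_h * 3600), "s"
        )
        t_end = config.start.astype("datetime64[D]") + np.timedelta64(day, "D") + np.timedelta64(
            int(config.map_day_end_h * 3600), "s"
        )
        while t <= t_end:
            if t >= release_time:
                out.append(t)
            t = t + step
    return out


def make_dye_maps(config: CampaignConfig, seed: Optional[int] = None) -> list:
    """Hourly daytime 2 m x 2 m dye rasters.

    Alongshore: a Gaussian of variance sigma0^2 + 2*K*t advected at the
    configured current, analytically normalised so grid-integrated mass
    equals the released mass while the plume is interior.  Cross-shore:
    a half-Gaussian surfzone profile seaward of the instantaneous
    shoreline, numerically normalised to unit integral, so cross-shore
    truncation never loses mass.
    """
    config.validate()
    release_time = config.start + np.timedelta64(int(config.release_delay_h * 3600), "s")
    water = make_water_level(config)
    cell = config.dye_cell_m
    x_edge0 = -config.offshore_width_m
    # extend slightly landward so high-tide shorelines stay on the grid
    x_edge1 = config.shore_x_m + config.tide_amplitude_m / config.beach_slope + 20.0
    nx = int(np.ceil((x_edge1 - x_edge0) / cell))
    ny = int(np.ceil(config.alongshore_length_m / cell))
    xc = x_edge0 + cell * (np.arange(nx) + 0.5)
    yc = cell * (np.arange(ny) + 0.5)

    maps = []
    for t in _map_times(config):
        dt_s = float((t - release_time) / np.timedelta64(1, "s"))
        eta = float(water.at(t)[0])
        x_shore = config.shore_x_m + eta / config.beach_slope
        # cross-shore surfzone profile, zero landward of the shoreline
        w = config.surfzone_width_m
        gx = np.exp(-((xc - (x_shore - w / 2.0)) ** 2) / (2.0 * (w / 3.0) ** 2))
        gx[xc > x_shore] = 0.0
        area_x = gx.sum() * cell
        if area_x > 0:
            gx = gx / area_x
        # alongshore advected/diffusing Gaussian
        sigma2 = config.initial_sigma_m**2 + 2.0 * config.diffusivity_m2s * max(dt_s, 0.0)
        y_c = config.release_alongshore_m + config.current_ms * max(dt_s, 0.0)
        gy = np.exp(-((yc - y_c) ** 2) / (2.0 * sigma2)) / np.sqrt(2.0 * np.pi * sigma2)
        conc = config.release_mass_ppb_m2 * np.outer(gy, gx)  # (ny, nx)
        maps.append(DyeMap(t, conc, (x_edge0, 0.0), cell))
    return maps


# ---------------------------------------------------------------------------
# EEM synthesis


@dataclass(frozen=True)
class EEMTruth:
    """Ground-truth spectral model of the synthetic fluorometer."""

    signal_per_ppb: float = 120.0  # raw units per ppb at the RWT peak
    peak_ex_nm: float = 558.0
    peak_em_nm: float = 582.0
    sigma_ex_nm: float = 10.0
    sigma_em_nm: float = 12.0
    raman_amplitude: float = 400.0
    raman_sigma_nm: float = 6.0
    raman_shift_cm1: float = 3400.0
    background_offset: float = 50.0
    ambient_amplitude: float = 15.0  # broad CDOM-like hump
    ambient_ex_nm: float = 450.0
    ambient_em_nm: float = 530.0
    ambient_sigma_ex_nm: float = 40.0
    ambient_sigma_em_nm: float = 60.0

    @property
    def raman_band(self) -> RamanBand:
        """An on-grid Raman normalisation band: the ridge of the lowest
        acquisition excitation line (425 nm -> ~497 nm emission)."""
        em_peak = float(raman_shifted_emission(425.0, self.raman_shift_cm1))
        return RamanBand(425.0, em_peak - 17.0, em_peak + 17.0)


def _spectral_components(truth: EEMTruth):
    ex, em = acquisition_grids()
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    signal_shape = np.exp(
        -((exg - truth.peak_ex_nm) ** 2) / (2.0 * truth.sigma_ex_nm**2)
        - ((emg - truth.peak_em_nm) ** 2) / (2.0 * truth.sigma_em_nm**2)
    )
    raman_em = raman_shifted_emission(exg, truth.raman_shift_cm1)
    raman = truth.raman_amplitude * np.exp(
        -((emg - raman_em) ** 2) / (2.0 * truth.raman_sigma_nm**2)
    )
    ambient = truth.ambient_amplitude * np.exp(
        -((exg - truth.ambient_ex_nm) ** 2) / (2.0 * truth.ambient_sigma_ex_nm**2)
        - ((emg - truth.ambient_em_nm) ** 2) / (2.0 * truth.ambient_sigma_em_nm**2)
    )
    return ex, em, signal_shape, raman, ambient


def make_eem(
    conc_ppb: float,
    truth: EEMTruth = EEMTruth(),
    noise_sigma: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    include_ambient: bool = True,
) -> EEM:
    """Raw EEM of a liquid with the given tracer concentration.

    Signal amplitude is exactly linear in ``conc_ppb``; the spectrum also
    carries the constant background offset, the water-Raman ridge, an
    optional ambient fluorophore hump, and additive Gaussian noise.
    """
    if conc_ppb < 0:
        raise ValueError("concentration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    ex, em, signal_shape, raman, ambient = _spectral_components(truth)
    intensity = truth.background_offset + raman + conc_ppb * truth.signal_per_ppb * signal_shape
    if include_ambient:
        intensity = intensity + ambient
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, intensity.shape)
    return EEM(ex, em, intensity, "raw")


def make_water_reference(truth: EEMTruth = EEMTruth()) -> EEM:
    """Noise-free pure-water blank scan: background + Raman ridge only."""
    ex, em, _signal, raman, _ambient = _spectral_components(truth)
    return EEM(ex, em, truth.background_offset + raman, "raw")


# ---------------------------------------------------------------------------
# full campaign


@dataclass
class Campaign:
    """A complete synthetic campaign bundle."""

    config: CampaignConfig
    truth: EEMTruth
    terrain: Terrain
    water_level: WaterLevelSeries
    wind: WindSeries
    dye_maps: list
    samples: list  # AerosolSample, EEMs attached, truth concentrations set
    blanks: list  # AerosolSample with zero tracer
    standards: list  # (ppb, raw EEM)
    water_reference: EEM
    true_air_conc: dict  # sample id -> truth pg/m^3


def _sample_schedule(config: CampaignConfig) -> list:
    """(site_id, x, y, start, end, period_label) for every sample."""
    day0 = config.start.astype("datetime64[D]")
    rows = []
    for day in range(config.n_days):
        d = day0 + np.timedelta64(day, "D")
        for site_id, x, y in config.sampler_sites:
            rows.append(
                (site_id, x, y, d + np.timedelta64(9, "h"), d + np.timedelta64(15, "h"), "day")
            )
        if day < config.n_days - 1:
            # overnight sampling starts after the last daytime dye map,
            # so night samples carry no concurrent sea-surface data
            night_start = d + np.timedelta64(
                int((config.map_day_end_h + 0.5) * 3600), "s"
            )
            for site_id, x, y in config.sampler_sites[:2]:
                rows.append(
                    (site_id, x, y, night_start, d + np.timedelta64(31, "h"), "night")
                )
    return rows


def make_campaign(config: CampaignConfig = CampaignConfig(), seed: Optional[int] = None) -> Campaign:
    """Generate the full bundle: terrain, tide, wind, dye maps, aerosol
    samples with EEMs, field blanks, calibration standards."""
    config.validate()
    root_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    truth = EEMTruth()

    terrain = make_terrain(config)
    water = make_water_level(config)
    wind = make_wind(config, seed=int(rng.integers(2**31)))
    maps = make_dye_maps(config)

    samples = []
    true_air = {}
    noise = config.eem_noise_sigma
    for i, (site_id, x, y, start, end, period) in enumerate(_sample_schedule(config), start=1):
        duration_h = float((end - start) / HOUR)
        air_volume = config.air_flow_m3_per_h * duration_h
        att = attribute_sample(i, (x, y), start, end, wind, maps, terrain, water)
        if att.dye_sea_ppb is None:
            air_true = 0.0
        else:
            decay = (
                1.0
                if config.decay_length_m is None or att.downwind_m is None
                else float(np.exp(-att.downwind_m / config.decay_length_m))
            )
            air_true = config.k_pg_m3_per_ppb * att.dye_sea_ppb * decay
        liquid_true = air_true * air_volume / (1000.0 * config.liquid_volume_ml)
        eem = make_eem(liquid_true, truth, noise, rng=rng)
        samples.append(
            AerosolSample(
                id=i,
                site_id=site_id,
                location=(x, y),
                start=start,
                end=end,
                air_volume_m3=air_volume,
                liquid_volume_ml=config.liquid_volume_ml,
                eem=eem,
            )
        )
        true_air[i] = air_true

    blanks = []
    blank_day = config.start.astype("datetime64[D]") + np.timedelta64(config.n_days + 7, "D")
    for b in range(config.n_blanks):
        site_id, x, y = config.sampler_sites[b % len(config.sampler_sites)]
        start = blank_day + np.timedelta64(9 + 3 * b, "h")
        end = start + np.timedelta64(6, "h")
        blanks.append(
            AerosolSample(
                id=1000 + b,
                site_id=site_id,
                location=(x, y),
                start=start,
                end=end,
                air_volume_m3=config.air_flow_m3_per_h * 6.0,
                liquid_volume_ml=config.liquid_volume_ml,
                eem=make_eem(0.0, truth, noise, rng=rng),
            )
        )

    standards = [
        (c, make_eem(c, truth, noise, rng=rng, include_ambient=False))
        for c in config.standard_concs_ppb
    ]
    return Campaign(
        config=config,
        truth=truth,
        terrain=terrain,
        water_level=water,
        wind=wind,
        dye_maps=maps,
        samples=samples,
        blanks=blanks,
        standards=standards,
        water_reference=make_water_reference(truth),
        true_air_conc=true_air,
    )


def recovery_config(seed: int = 0, decay: bool = False) -> CampaignConfig:
    """A single-day campaign with eight near-shore samplers spread along
    the plume path, used for end-to-end transfer-coefficient recovery."""
    sites = tuple(
        (f"R{i+1}", 100.0 + 15.0 * i, 600.0 + 260.0 * i) for i in range(8)
    )
    return CampaignConfig(
        seed=seed,
        n_days=1,
        sampler_sites=sites,
        decay_length_m=500.0 if decay else None,
        wind_dir_sigma_deg=6.0,
    ).validate()
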