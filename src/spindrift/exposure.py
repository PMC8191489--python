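"""Air-concentration computation, blank statistics, and detection criteria.

The air sampler concentrates airborne constituents from a known sampled
air volume (m^3) into a small liquid volume (default 10 ml).  The tracer
amount in that liquid, divided by the air volume, gives the mean air
concentration over the sampling interval in pg/m^3.

Detection follows two joint criteria: the sample's EEM must show the
tracer fluorescence pattern, and its air concentration must exceed the
blank-derived limit of detection

    LoD = alpha + 3.29 * beta

where alpha and beta are the mean and sample standard deviation of the
field-blank air concentrations.  (3.29 = 2 * z_0.95 is the standard
IUPAC-style multiplier for a false-positive/false-negative rate of 5%.)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .eem import EEM

#: 1 ppb aqueous = 1 ng/ml = 1000 pg/ml
PG_PER_ML_PER_PPB = 1000.0

#: LoD multiplier on the blank standard deviation
LOD_MULTIPLIER = 3.29


def liquid_to_air_mass(liquid_conc_ppb: float, liquid_volume_ml: float = 10.0) -> float:
    """Tracer mass (pg) in the collection liquid."""
    if liquid_conc_ppb < 0 or liquid_volume_ml < 0:
        raise ValueError("concentration and volume must be non-negative")
    return liquid_conc_ppb * PG_PER_ML_PER_PPB * liquid_volume_ml


def air_concentration(mass_pg: float, air_volume_m3: float) -> float:
    """Mean air concentration (pg/m^3) over the sampling interval."""
    if air_volume_m3 <= 0:
        raise ValueError("air volume must be positive")
    return mass_pg / air_volume_m3


def blank_stats(blank_air_concs) -> tuple:
    """(alpha, beta): mean and sample SD (n-1 denominator) of the blanks."""
    concs = np.asarray(blank_air_concs, dtype=float)
    if concs.size < 2:
        raise ValueError("at least two field blanks are required")
    return float(concs.mean()), float(concs.std(ddof=1))


def limit_of_detection(alpha: float, beta: float) -> float:
    """LoD (pg/m^3) = alpha + 3.29 * beta."""
    if beta < 0:
        raise ValueError("blank standard deviation must be non-negative")
    return alpha + LOD_MULTIPLIER * beta


@dataclass
class BlankSet:
    """Field-blank air concentrations with derived statistics."""

    blank_air_concs: list
    alpha: float = field(init=False)
    beta: float = field(init=False)
    lod: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha, self.beta = blank_stats(self.blank_air_concs)
        self.lod = limit_of_detection(self.alpha, self.beta)


@dataclass
class AerosolSample:
    """One air-collection interval and its derived quantities."""

    id: int
    site_id: str
    location: Optional[tuple] = None  # (x, y) metres, local coordinates
    start: Optional[np.datetime64] = None
    end: Optional[np.datetime64] = None
    air_volume_m3: float = 0.0
    liquid_volume_ml: float = 10.0
    eem: Optional[EEM] = None
    liquid_conc_ppb: Optional[float] = None
    air_conc_pg_m3: Optional[float] = None
    pattern_flag: Optional[bool] = None
    above_lod_flag: Optional[bool] = None
    detected: Optional[bool] = None

    def compute_air_concentration(self) -> float:
        """Fill ``air_conc_pg_m3`` from the quantified liquid concentration."""
        if self.liquid_conc_ppb is None:
            raise ValueError("liquid concentration has not been quantified")
        mass = liquid_to_air_mass(self.liquid_conc_ppb, self.liquid_volume_ml)
        self.air_conc_pg_m3 = air_concentration(mass, self.air_volume_m3)
        return self.air_conc_pg_m3


def classify(sample: AerosolSample, lod: float) -> AerosolSample:
    """Set the above-LoD and detected flags on ``sample`` (in place).

    Detection is the conjunction of the spectral-pattern criterion and a
    strictly-above-LoD air concentration.
    """
    if sample.air_conc_pg_m3 is None or sample.pattern_flag is None:
        raise ValueError("air concentration and pattern flag must be computed first")
    sample.above_lod_flag = bool(sample.air_conc_pg_m3 > lod)
    sample.detected = bool(sample.pattern_flag and sample.above_lod_flag)
    return sample


def classify_table(
    df: pd.DataFrame,
    lod: float,
    air_col: str = "air_conc_pg_m3",
    pattern_col: str = "pattern",
) -> pd.DataFrame:
    """Vectorised dual-criteria classification of a samples table.

    Adds/overwrites ``above_lod`` and ``detected`` boolean columns; rows
    with missing air concentration get missing flags.
    """
    out = df.copy()
    air = pd.to_numeric(out[air_col], errors="coerce")
    above = (air > lod).astype("boolean")
    above[air.isna()] = pd.NA
    pattern = out[pattern_col].astype("boolean")
    out["above_lod"] = above
    out["detected"] = (pattern & out["above_lod"]).astype("boolean")
    return out
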