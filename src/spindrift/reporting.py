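"""Results assembly: campaign table, wind roses, summaries, ocean-air pairs."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WindSeries

#: canonical results-table columns
TABLE_COLUMNS = [
    "id", "release", "date", "period", "site", "inland_m", "downwind_m",
    "air_volume_m3", "pattern", "above_lod", "air_conc_pg_m3", "dye_sea_ppb",
    "detected",
]


@dataclass
class WindRose:
    """Percent-frequency wind rose over (FROM-direction sector, speed class).

    Records calmer than the calm threshold are tallied separately in
    ``calm_percent``; sector/class frequencies plus the calm fraction sum
    to 100%.
    """

    direction_centers_deg: np.ndarray
    speed_edges_ms: np.ndarray  # class k covers [edge_k, edge_{k+1}); last is open
    frequency_percent: np.ndarray  # (n_sectors, n_classes)
    calm_percent: float
    calm_threshold_ms: float

    def total_percent(self) -> float:
        return float(self.frequency_percent.sum() + self.calm_percent)

    def to_frame(self) -> pd.DataFrame:
        edges = list(self.speed_edges_ms)
        labels = [
            f"{edges[k]:g}-{edges[k+1]:g} m/s" for k in range(len(edges) - 1)
        ] + [f">{edges[-1]:g} m/s"]
        df = pd.DataFrame(
            self.frequency_percent, index=self.direction_centers_deg, columns=labels
        )
        df.index.name = "direction_deg_from"
        return df


def wind_rose(
    winds: WindSeries,
    sector_width_deg: float = 22.5,
    speed_edges_ms=(0.0, 2.0, 4.0, 6.0),
    calm_threshold_ms: float = 0.5,
) -> WindRose:
    """Bin a wind record into percent of records per (sector, speed class).

    Sectors are centred on north and its multiples (the first sector
    spans +-width/2 around 0 deg), so FROM-directions either side of
    north fall in the same sector.
    """
    if len(winds) == 0:
        raise ValueError("empty wind series")
    n = len(winds)
    calm = winds.speed_ms < calm_threshold_ms
    n_sectors = int(round(360.0 / sector_width_deg))
    sector = np.round(winds.dir_deg_from / sector_width_deg).astype(int) % n_sectors
    edges = np.asarray(speed_edges_ms, dtype=float)
    # class index: last class is open-ended above the final edge
    cls = np.clip(np.searchsorted(edges[1:], winds.speed_ms, side="right"), 0, len(edges) - 1)
    freq = np.zeros((n_sectors, len(edges)))
    np.add.at(freq, (sector[~calm], cls[~calm]), 1.0)
    freq = freq / n * 100.0
    return WindRose(
        direction_centers_deg=sector_width_deg * np.arange(n_sectors),
        speed_edges_ms=edges,
        frequency_percent=freq,
        calm_percent=float(calm.sum()) / n * 100.0,
        calm_threshold_ms=calm_threshold_ms,
    )


# ---------------------------------------------------------------------------
# results table


def build_results_table(
    samples: pd.DataFrame, attributions: pd.DataFrame, lod: float
) -> pd.DataFrame:
    """Join exposure and attribution outputs and apply the dual detection
    criteria; one row per sample, ordered by id.

    ``samples`` needs columns id, pattern, air_conc_pg_m3 (plus any
    passthrough metadata); ``attributions`` needs id plus dye_sea_ppb /
    inland_m / downwind_m.  Every sample id must appear in exactly one
    attribution row.
    """
    from .exposure import classify_table

    if samples["id"].duplicated().any() or attributions["id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    missing = set(samples["id"]) - set(attributions["id"])
    if missing:
        raise ValueError(f"samples without attribution records: {sorted(missing)}")
    merged = samples.merge(attributions, on="id", how="left", validate="one_to_one")
    merged = classify_table(merged, lod)
    merged = merged.sort_values("id").reset_index(drop=True)
    cols = [c for c in TABLE_COLUMNS if c in merged.columns]
    extra = [c for c in merged.columns if c not in cols]
    return merged[cols + extra]


def summarize(table: pd.DataFrame) -> dict:
    """Campaign summary: detection count, distance maxima among detected
    samples, per-release detection counts, and the number of distinct
    sampling locations."""
    t = table
    if "kind" in t.columns:
        samples = t[t["kind"] == "sample"]
        sites = t.loc[t["kind"] != "rinse", "site"].dropna().unique()
    else:
        samples = t
        sites = t["site"].dropna().unique()
    det = samples[samples["detected"].fillna(False).astype(bool)]
    per_release = (
        det.groupby("release")["id"].count().to_dict()
        if len(det) and "release" in det.columns
        else {}
    )

    def _max(col):
        vals = pd.to_numeric(det[col], errors="coerce").dropna()
        return float(vals.max()) if len(vals) else None

    return {
        "n_samples": int(len(samples)),
        "n_detected": int(len(det)),
        "detected_ids": [int(i) for i in det["id"]],
        "max_inland_m_detected": _max("inland_m"),
        "max_downwind_m_detected": _max("downwind_m"),
        "n_sites": int(len(sites)),
        "detected_per_release": {str(k): int(v) for k, v in per_release.items()},
    }


def ocean_air_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """(dye_sea, air_conc, detected) for rows with a source-water value —
    the underlying point set of the ocean-vs-air comparison."""
    t = table
    if "kind" in t.columns:
        t = t[t["kind"] == "sample"]
    t = t[pd.to_numeric(t["dye_sea_ppb"], errors="coerce").notna()]
    out = t[["id", "dye_sea_ppb", "air_conc_pg_m3", "detected"]].reset_index(drop=True)
    return out


def render_table(table: pd.DataFrame) -> str:
    """Human-readable table: air concentrations of samples that did not
    meet both detection criteria are wrapped in parentheses; detected
    rows are marked with '*'."""
    lines = []
    header = ["id", "site", "period", "inland_m", "downwind_m", "pattern",
              "above_lod", "air_pg_m3", "sea_ppb"]
    lines.append("\t".join(header))
    for _, row in table.iterrows():
        detected = bool(row.get("detected")) if pd.notna(row.get("detected")) else False
        air = row.get("air_conc_pg_m3")
        if pd.isna(air):
            air_s = "NA"
        else:
            air_s = f"{air:.1f}" if detected else f"({air:.1f})"
        sea = row.get("dye_sea_ppb")
        sea_s = "NA" if pd.isna(sea) else f"{sea:.1f}"
        dw = row.get("downwind_m")
        dw_s = "NA" if pd.isna(dw) else f"{dw:.0f}"
        inland = row.get("inland_m")
        inland_s = "NA" if pd.isna(inland) else f"{inland:.0f}"

        def yn(v):
            return "NA" if pd.isna(v) else ("Yes" if v else "No")

        mark = "*" if detected else ""
        lines.append(
            "\t".join(
                [
                    f"{row['id']}{mark}", str(row.get("site", "")), str(row.get("period", "")),
                    inland_s, dw_s, yn(row.get("pattern")), yn(row.get("above_lod")),
                    air_s, sea_s,
                ]
            )
        )
    return "\n".join(lines)
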