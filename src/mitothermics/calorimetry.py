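"""Indirect calorimetry: RER, energy expenditure and substrate oxidation.

Metabolic-cage traces arrive as 30-min bins of oxygen consumption (VO2,
ml/min), carbon dioxide production (VCO2, ml/min), beam-break activity
counts, cumulative food intake and body weight, under a fixed light/dark
schedule.  From these the module derives per bin:

    RER = VCO2 / VO2
    EE  = VO2 / bw**0.75          (ml/min/g^0.75, metabolic body size)
    CHO (g/min) = 4.585 * VCO2 - 3.2255 * VO2     [VO2, VCO2 in L/min]
    FAO (g/min) = 1.6946 * VO2 - 1.7012 * VCO2

The CHO/FAO coefficients are the protein-free whole-body substrate
oxidation equations of Peronnet & Massicotte (Can J Sport Sci 16:23-29,
1991).  They place the pure-fat threshold (CHO = 0) at RER = 3.2255/4.585
= 0.7035 and the pure-carbohydrate threshold (FAO = 0) at RER =
1.6946/1.7012 = 0.9961; negative rates under measurement noise are clamped
to zero with a per-bin flag, raw values kept in debug columns.

Circadian summaries use exactly the first two complete light+dark cycles
(48 h) starting at the first light-phase onset, averaging per animal per
phase; EE is normalized by each animal's mean recorded body weight over
that window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHO_VCO2_COEF",
    "CHO_VO2_COEF",
    "FAO_VO2_COEF",
    "FAO_VCO2_COEF",
    "CageTrace",
    "PhaseSummary",
    "read_cage_csv",
    "derive_metabolic_series",
    "circadian_phase_summary",
    "intake_metrics",
]

# Peronnet & Massicotte (1991), protein-free, inputs in L/min, outputs g/min
CHO_VCO2_COEF = 4.585
CHO_VO2_COEF = 3.2255
FAO_VO2_COEF = 1.6946
FAO_VCO2_COEF = 1.7012

CAGE_COLUMNS = [
    "animal_id", "group", "timestamp",
    "vo2_ml_min", "vco2_ml_min", "activity_counts", "food_g", "bw_g",
]

RER_SANITY = (0.6, 1.3)


@dataclass
class CageTrace:
    """Binned gas-exchange trace for a cohort of animals.

    data: one row per animal per bin with the CAGE_COLUMNS schema,
    timestamps strictly increasing within each animal, bins equally spaced.
    """

    data: pd.DataFrame
    light_onset_hour: float = 6.0
    phase_hours: float = 12.0
    bin_minutes: float = 30.0

    def __post_init__(self):
        missing = [c for c in CAGE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cage trace missing column(s): {', '.join(missing)}")
        df = self.data
        if not pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
            df = df.assign(timestamp=pd.to_datetime(df["timestamp"]))
            self.data = df
        period_min = 2 * self.phase_hours * 60
        if period_min % self.bin_minutes:
            raise ValueError(
                f"bin width {self.bin_minutes} min does not divide the "
                f"{2 * self.phase_hours} h light/dark period"
            )
        for animal, sub in df.groupby("animal_id", sort=False):
            ts = sub["timestamp"].to_numpy()
            if len(ts) > 1:
                deltas = np.diff(ts).astype("timedelta64[s]").astype(float)
                if np.any(deltas <= 0):
                    raise ValueError(f"timestamps not strictly increasing for {animal}")
                if np.ptp(deltas) > 1e-6:
                    raise ValueError(f"bins not equally spaced for {animal}")
        if np.any(df["vo2_ml_min"].to_numpy() < 0):
            raise ValueError("negative VO2")

    def is_light(self, timestamps: pd.Series) -> np.ndarray:
        """Light-phase flag; a bin exactly at onset belongs to light."""
        hours = (
            timestamps.dt.hour + timestamps.dt.minute / 60 + timestamps.dt.second / 3600
        ).to_numpy()
        rel = (hours - self.light_onset_hour) % 24.0
        return rel < self.phase_hours


def read_cage_csv(
    path,
    light_onset_hour: float = 6.0,
    phase_hours: float = 12.0,
    bin_minutes: float = 30.0,
) -> CageTrace:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return CageTrace(df, light_onset_hour, phase_hours, bin_minutes)


def derive_metabolic_series(trace: CageTrace, bw: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-bin RER, EE, CHO and FAO for every animal.

    ``bw`` optionally overrides the per-animal body weight (g) used for the
    EE normalization; by default each animal's mean recorded weight is
    used.  Bins with VO2 = 0 are masked (NaN derived values, ``masked``
    flag) rather than dropped.  Negative oxidation rates are clamped to 0
    with ``cho_clamped``/``fao_clamped`` flags; raw values stay in
    ``cho_raw_mg_min``/``fao_raw_mg_min``.
    """
    df = trace.data.copy()
    if bw is None:
        bw_map = df.groupby("animal_id")["bw_g"].mean()
    else:
        bw_map = pd.Series(dict(bw))
    if np.any(bw_map.to_numpy() <= 0):
        raise ValueError("body weight must be positive")

    vo2 = df["vo2_ml_min"].to_numpy(dtype=float)
    vco2 = df["vco2_ml_min"].to_numpy(dtype=float)
    masked = vo2 == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(masked, np.nan, vco2 / vo2)
    bw_arr = df["animal_id"].map(bw_map).to_numpy(dtype=float)
    ee = np.where(masked, np.nan, vo2 / bw_arr ** 0.75)

    # equations take L/min and yield g/min; ml/min in, mg/min out keeps
    # the coefficients unchanged (both scale by 1000)
    cho_raw = CHO_VCO2_COEF * vco2 - CHO_VO2_COEF * vo2
    fao_raw = FAO_VO2_COEF * vo2 - FAO_VCO2_COEF * vco2
    cho_raw = np.where(masked, np.nan, cho_raw)
    fao_raw = np.where(masked, np.nan, fao_raw)

    out = df[["animal_id", "group", "timestamp", "activity_counts", "food_g", "bw_g"]].copy()
    out["rer"] = rer
    out["ee_ml_min_g075"] = ee
    out["cho_raw_mg_min"] = cho_raw
    out["fao_raw_mg_min"] = fao_raw
    out["cho_mg_min"] = np.clip(cho_raw, 0, None)
    out["fao_mg_min"] = np.clip(fao_raw, 0, None)
    out["cho_clamped"] = cho_raw < 0
    out["fao_clamped"] = fao_raw < 0
    out["masked"] = masked
    out["light"] = trace.is_light(out["timestamp"])
    return out


@dataclass
class PhaseSummary:
    """Per animal per phase (light/dark/total) means over the 48-h window."""

    table: pd.DataFrame    # animal_id, group, phase, ee, rer, cho, fao, activity
    window_start: pd.Timestamp
    n_bins: int


def circadian_phase_summary(trace: CageTrace, derived: pd.DataFrame | None = None) -> PhaseSummary:
    """Summarize exactly the first two complete circadian cycles (48 h).

    The window opens at the first bin at/after the configured light onset
    and spans 48 h; a shorter trace is an error.  Means are per animal per
    phase; activity is summed.  ``total`` is computed over all window bins,
    i.e. the duration-weighted combination of light and dark.
    """
    if derived is None:
        derived = derive_metabolic_series(trace)
    df = derived
    light = trace.is_light(df["timestamp"])
    onset_candidates = df.loc[light, "timestamp"]
    if onset_candidates.empty:
        raise ValueError("no light-phase bins in trace")
    start = onset_candidates.min()
    end = start + pd.Timedelta(hours=48)
    span = df["timestamp"].max() + pd.Timedelta(minutes=trace.bin_minutes) - start
    if span < pd.Timedelta(hours=48):
        short = pd.Timedelta(hours=48) - span
        raise ValueError(f"trace covers only {span} after first light onset; {short} short of 48 h")
    win = df[(df["timestamp"] >= start) & (df["timestamp"] < end)].copy()
    win["phase"] = np.where(win["light"], "light", "dark")

    frames = []
    for phase_name, sub in [("light", win[win["phase"] == "light"]),
                            ("dark", win[win["phase"] == "dark"]),
                            ("total", win)]:
        g = sub.groupby(["animal_id", "group"], sort=True)
        agg = g.agg(
            ee=("ee_ml_min_g075", "mean"),
            rer=("rer", "mean"),
            cho_mg_min=("cho_mg_min", "mean"),
            fao_mg_min=("fao_mg_min", "mean"),
            activity=("activity_counts", "sum"),
        ).reset_index()
        agg.insert(2, "phase", phase_name)
        frames.append(agg)
    table = pd.concat(frames, ignore_index=True)

    bad = table[(table["rer"] < RER_SANITY[0]) | (table["rer"] > RER_SANITY[1])]
    if not bad.empty:
        import warnings

        warnings.warn(
            f"{len(bad)} phase summary row(s) with mean RER outside {RER_SANITY}",
            stacklevel=2,
        )
    return PhaseSummary(table=table, window_start=start, n_bins=len(win) // win["animal_id"].nunique())


def intake_metrics(
    food_g: float | np.ndarray,
    bw_before_g: float,
    bw_after_g: float,
    diet_kj_per_g: float,
) -> tuple[float, float]:
    """Energy intake per gram body weight and weight change per energy.

    Returns (intake kJ per g mean BW, weight change mg per kJ intake).
    Zero intake makes the second quantity undefined (NaN) and is flagged.
    """
    if diet_kj_per_g <= 0:
        raise ValueError("diet energy density must be positive")
    total_food = float(np.sum(food_g))
    intake_kj = total_food * diet_kj_per_g
    mean_bw = (bw_before_g + bw_after_g) / 2.0
    if mean_bw <= 0:
        raise ValueError("body weight must be positive")
    intake_per_g = intake_kj / mean_bw
    delta_mg = (bw_after_g - bw_before_g) * 1000.0
    if intake_kj == 0:
        import warnings

        warnings.warn("zero energy intake: weight change per energy undefined", stacklevel=2)
        return intake_per_g, float("nan")
    return intake_per_g, delta_mg / intake_kj
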