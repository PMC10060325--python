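"""Synthetic cohorts for every input kind the analysis consumes.

The generators emulate a two-group (control vs chronically stressed, here
"Ctrl" / "Cvs") mouse study with n = 6 animals per group: extracellular-flux
plates run in technical triplicate, 72-h metabolic-cage traces binned every
30 min starting at the 06:00 light onset, a ~1000-protein label-free
abundance table with a designated truly-regulated set, and Nd1/Lpl qPCR
triplicates.  Default effect sizes follow the magnitudes the study design
anticipates: a 55%/56% drop in ADP-stimulated respiration (state 3) with a
complex-II coupling shift past the uppermost thermodynamic set point, a
lower whole-animal energy expenditure driven by the dark phase (total 7.2
vs 6.3 ml/min/g^0.75), an RER shift 0.95 -> 0.89, 73 up- and 13
down-regulated proteins at two-fold, and a modestly raised mtDNA/nDNA
ratio.

Every generator draws from its own RNG stream keyed by (master seed,
generator id), so adding one generator never perturbs another's draws, and
every generator returns a ground-truth sidecar (plain dict, JSON-ready)
that downstream recovery tests can score against without re-deriving the
truth.  Analysis code never reads sidecars.

Mechanisms that push state-4o readings negative — as raw plate exports can
be — are exposed as options: a negative per-tick drift, or subtraction of
the non-mitochondrial (post-antimycin) signal from every tick
(``nonmito_subtract``).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .calorimetry import CageTrace
from .flux_assay import (
    EQUILIBRATION_PHASE,
    PLATE_COLUMNS,
    PlateAssay,
    _validate_plate,
    resolve_protocol,
)
from .omics_enrichment import AbundanceTable, QpcrRecords

__all__ = [
    "FluxBlock",
    "CageBlock",
    "OmicsBlock",
    "QpcrBlock",
    "GeneratorConfig",
    "gen_flux_plate",
    "gen_cage_trace",
    "gen_abundance_table",
    "gen_qpcr",
]

# fixed stream ids: (master_seed, _STREAM[name]) seeds each generator
_STREAM = {"flux": 1, "cage": 2, "omics": 3, "qpcr": 4}

GROUPS = ("Ctrl", "Cvs")

# Per-group mean OCR (pmol O2/min) at each protocol phase.  Coupling-assay
# contrasts encode: state 2 down 40%/36%, state 3 down 55%/56%, state 3u
# down 42%/47% (complex I / complex II), respiratory control ratio
# preserved on complex I, and the complex-II leak collapsed so the stressed
# group's coupling degree crosses the economic-power set point (q = 0.975
# vs 0.856 in controls).
DEFAULT_FLUX_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "coupling-CI": {
        "Ctrl": {"basal": 150.0, "state3": 500.0, "state4o": 70.0,
                 "state3u": 600.0, "residual": 20.0},
        "Cvs": {"basal": 90.0, "state3": 225.0, "state4o": 31.5,
                "state3u": 348.0, "residual": 20.0},
    },
    "coupling-CII": {
        "Ctrl": {"basal": 180.0, "state3": 450.0, "state4o": 120.0,
                 "state3u": 500.0, "residual": 25.0},
        "Cvs": {"basal": 115.0, "state3": 198.0, "state4o": 10.0,
                "state3u": 265.0, "residual": 25.0},
    },
    "electron-flow": {
        "Ctrl": {"basal_uncoupled": 800.0, "post_inhibition": 400.0,
                 "post_stimulation": 700.0, "post_antimycin": 30.0,
                 "post_tmpd": 900.0},
        "Cvs": {"basal_uncoupled": 464.0, "post_inhibition": 200.0,
                "post_stimulation": 175.0, "post_antimycin": 30.0,
                "post_tmpd": 720.0},
    },
}


class FluxBlock(BaseModel):
    """Flux-plate generator parameters."""

    state_means: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=lambda: {k: {g: dict(v) for g, v in d.items()}
                                 for k, d in DEFAULT_FLUX_MEANS.items()}
    )
    noise_cv: float = Field(0.05, ge=0)        # per-tick, relative to phase mean
    animal_cv: float = Field(0.05, ge=0)       # between-animal scale factor SD
    drift_per_tick: float = 0.0                # linear within-phase drift (pmol/min per tick)
    replicates: int = Field(3, ge=1)           # technical replicate wells per animal
    protein_ug: float = Field(2.5, gt=0)
    cs_activity_mean: float = Field(1.0, gt=0)
    cs_activity_cv: float = Field(0.0, ge=0)
    nonmito_subtract: bool = False             # subtract residual mean from all ticks
    tick_minutes: float = Field(3.5, gt=0)


class CageBlock(BaseModel):
    """Metabolic-cage generator parameters (30-min bins, 72 h)."""

    duration_h: float = Field(72.0, ge=48.0)
    bin_minutes: float = Field(30.0, gt=0)
    light_onset_hour: float = 6.0
    phase_hours: float = 12.0
    start_clock_hour: float = 6.0
    bw_g: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 25.0, "Cvs": 24.0})
    bw_sd_g: float = Field(0.8, ge=0)
    # phase-mean energy expenditure targets, ml/min/g^0.75
    ee_light: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 6.3, "Cvs": 5.9})
    ee_dark: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 8.1, "Cvs": 6.7})
    ee_ripple: float = Field(0.3, ge=0)        # 12-h sinusoid, zero phase-mean
    ee_noise_cv: float = Field(0.05, ge=0)
    rer_light: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 0.92, "Cvs": 0.86})
    rer_dark: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 0.98, "Cvs": 0.92})
    rer_noise_sd: float = Field(0.02, ge=0)
    # beam-break counts per 30-min bin (Poisson rates)
    activity_light: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 12.0, "Cvs": 16.2})
    activity_dark: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 33.0, "Cvs": 51.9})
    # daily food intake, g/day (stressed animals eat ~20% more per g BW)
    food_g_per_day: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 4.0, "Cvs": 4.6})
    food_dark_fraction: float = Field(0.7, ge=0, le=1)

    @model_validator(mode="after")
    def _bin_divides_period(self):
        if (2 * self.phase_hours * 60) % self.bin_minutes:
            raise ValueError("bin width must divide the light/dark period")
        return self


class OmicsBlock(BaseModel):
    """Label-free abundance-table generator parameters."""

    n_proteins: int = Field(1090, ge=1)
    n_samples_per_group: int = Field(5, ge=2)
    log2_mean: float = 20.0                    # location of per-protein base intensity
    log2_between_protein_sd: float = Field(2.0, ge=0)
    log2_noise_sd: float = Field(0.25, ge=0)   # per-sample measurement noise
    n_de_up: int = Field(73, ge=0)
    n_de_down: int = Field(13, ge=0)
    fold_change: float = Field(2.0, gt=0)

    @model_validator(mode="after")
    def _de_fits_universe(self):
        if self.n_de_up + self.n_de_down > self.n_proteins:
            raise ValueError("designated DE set exceeds protein universe")
        return self


class QpcrBlock(BaseModel):
    """Nd1/Lpl qPCR generator parameters."""

    n_animals_per_group: int = Field(5, ge=1)
    replicates: int = Field(3, ge=1)
    ct_nuclear_mean: float = Field(25.0, gt=0)
    replicate_sd: float = Field(0.1, ge=0)
    animal_ct_sd: float = Field(0.3, ge=0)     # shared shift, cancels in the ratio
    true_ratio: dict[str, float] = Field(default_factory=lambda: {"Ctrl": 1.0, "Cvs": 1.2})

    @model_validator(mode="after")
    def _ratios_positive(self):
        if any(r <= 0 for r in self.true_ratio.values()):
            raise ValueError("true mtDNA ratios must be positive")
        return self


class GeneratorConfig(BaseModel):
    """Master configuration: one seed, one cohort size, four blocks."""

    seed: int = 0
    n_animals_per_group: int = Field(6, ge=2)
    groups: tuple[str, str] = GROUPS
    flux: FluxBlock = Field(default_factory=FluxBlock)
    cage: CageBlock = Field(default_factory=CageBlock)
    omics: OmicsBlock = Field(default_factory=OmicsBlock)
    qpcr: QpcrBlock = Field(default_factory=QpcrBlock)


def _rng(config: GeneratorConfig, name: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[name], extra])


# ---------------------------------------------------------------------------
# Flux plates
# ---------------------------------------------------------------------------

_ASSAY_IDS = {"coupling-CI": 0, "coupling-CII": 1, "electron-flow": 2}


def gen_flux_plate(
    config: GeneratorConfig,
    assay_kind: Literal["coupling-CI", "coupling-CII", "electron-flow"],
) -> tuple[PlateAssay, dict]:
    """One plate per cohort: animals x technical replicates, tick series per
    phase as phase mean + within-phase linear drift + Gaussian noise.

    Returns the validated PlateAssay and a ground-truth sidecar with the
    configured per-group state means and per-animal scale factors.
    """
    protocol = resolve_protocol(assay_kind)
    fx = config.flux
    if assay_kind not in fx.state_means:
        raise ValueError(
            f"no state means configured for {assay_kind!r}; known: {sorted(fx.state_means)}"
        )
    means = fx.state_means[assay_kind]
    rng = _rng(config, "flux", _ASSAY_IDS[assay_kind])

    rows = []
    animal_factors: dict[str, float] = {}
    for group in config.groups:
        if group not in means:
            raise ValueError(f"no state means for group {group!r} in {assay_kind}")
        gmeans = means[group]
        missing = set(protocol.state_labels) - set(gmeans)
        if missing:
            raise ValueError(f"{assay_kind}/{group} missing state mean(s) {sorted(missing)}")
        for i in range(config.n_animals_per_group):
            animal = f"{group}-{i + 1:02d}"
            factor = 1.0 + fx.animal_cv * rng.standard_normal() if fx.animal_cv else 1.0
            animal_factors[animal] = factor
            nonmito = gmeans.get("residual", gmeans.get("post_antimycin", 0.0))
            for rep in range(1, fx.replicates + 1):
                well = f"{animal}-r{rep}"
                cs = fx.cs_activity_mean * (
                    1.0 + fx.cs_activity_cv * rng.standard_normal()
                    if fx.cs_activity_cv else 1.0
                )
                cs = max(cs, 1e-6)
                t = 0.0
                tick_global = 0
                phase_plan = [(EQUILIBRATION_PHASE, protocol.equilibration_cycles,
                               gmeans[protocol.state_labels[0]])]
                phase_plan += [(lab, n_ticks, gmeans[lab])
                               for lab, _, n_ticks in protocol.phases]
                for phase, n_ticks, mu in phase_plan:
                    mu = mu * factor
                    if fx.nonmito_subtract:
                        mu = mu - nonmito * factor
                    for j in range(n_ticks):
                        val = mu + fx.drift_per_tick * j
                        if fx.noise_cv:
                            val += fx.noise_cv * abs(mu) * rng.standard_normal()
                        rows.append(
                            (well, animal, group, rep, assay_kind, phase, tick_global,
                             round(t, 3), val, fx.protein_ug, cs)
                        )
                        t += fx.tick_minutes
                        tick_global += 1
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    plate = PlateAssay(_validate_plate(df, protocol), protocol)
    truth = {
        "assay_kind": assay_kind,
        "state_means": {g: dict(means[g]) for g in config.groups},
        "animal_factors": animal_factors,
        "noise_cv": fx.noise_cv,
        "animal_cv": fx.animal_cv,
        "drift_per_tick": fx.drift_per_tick,
        "nonmito_subtract": fx.nonmito_subtract,
    }
    return plate, truth


# ---------------------------------------------------------------------------
# Cage traces
# ---------------------------------------------------------------------------

def gen_cage_trace(config: GeneratorConfig) -> tuple[CageTrace, dict]:
    """72-h binned gas-exchange trace for the whole cohort.

    Per-bin energy expenditure is a light/dark square wave plus a 12-h
    zero-phase-mean sinusoidal ripple and multiplicative noise; VO2 is
    back-computed from the EE target and the animal's body weight, and
    VCO2 = RER(t) * VO2(t) with RER a phase-dependent square wave plus
    Gaussian noise.  Activity is Poisson per bin; food intake accumulates
    per bin with a dark-phase bias.
    """
    cg = config.cage
    rng = _rng(config, "cage")
    n_bins = int(round(cg.duration_h * 60 / cg.bin_minutes))
    start = pd.Timestamp("2023-01-09") + pd.Timedelta(hours=cg.start_clock_hour)
    ts = start + pd.to_timedelta(np.arange(n_bins) * cg.bin_minutes, unit="min")
    hours = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy()
    rel = (hours - cg.light_onset_hour) % 24.0
    light = rel < cg.phase_hours
    ripple = np.sin(2.0 * np.pi * (rel % cg.phase_hours) / cg.phase_hours)

    bins_per_day = int(24 * 60 / cg.bin_minutes)
    frames = []
    truth_animals = {}
    for group in config.groups:
        ee_phase = np.where(light, cg.ee_light[group], cg.ee_dark[group])
        rer_phase = np.where(light, cg.rer_light[group], cg.rer_dark[group])
        act_rate = np.where(light, cg.activity_light[group], cg.activity_dark[group])
        food_day = cg.food_g_per_day[group]
        light_bins_per_day = bins_per_day // 2
        food_rate = np.where(
            light,
            food_day * (1 - cg.food_dark_fraction) / light_bins_per_day,
            food_day * cg.food_dark_fraction / (bins_per_day - light_bins_per_day),
        )
        for i in range(config.n_animals_per_group):
            animal = f"{group}-{i + 1:02d}"
            bw = cg.bw_g[group] + (cg.bw_sd_g * rng.standard_normal() if cg.bw_sd_g else 0.0)
            bw = max(bw, 1.0)
            ee = ee_phase + cg.ee_ripple * ripple
            if cg.ee_noise_cv:
                ee = ee * (1.0 + cg.ee_noise_cv * rng.standard_normal(n_bins))
            ee = np.clip(ee, 1e-9, None)
            vo2 = ee * bw ** 0.75
            rer = rer_phase + (cg.rer_noise_sd * rng.standard_normal(n_bins)
                               if cg.rer_noise_sd else 0.0)
            vco2 = rer * vo2
            activity = rng.poisson(act_rate)
            food = food_rate.copy()
            frames.append(pd.DataFrame({
                "animal_id": animal, "group": group, "timestamp": ts,
                "vo2_ml_min": vo2, "vco2_ml_min": vco2,
                "activity_counts": activity, "food_g": food, "bw_g": bw,
            }))
            truth_animals[animal] = {"bw_g": bw}
    data = pd.concat(frames, ignore_index=True)
    trace = CageTrace(data, cg.light_onset_hour, cg.phase_hours, cg.bin_minutes)
    truth = {
        "ee_light": dict(cg.ee_light), "ee_dark": dict(cg.ee_dark),
        "rer_light": dict(cg.rer_light), "rer_dark": dict(cg.rer_dark),
        "rer_total": {g: (cg.rer_light[g] + cg.rer_dark[g]) / 2 for g in config.groups},
        "ee_total": {g: (cg.ee_light[g] + cg.ee_dark[g]) / 2 for g in config.groups},
        "food_g_per_day": dict(cg.food_g_per_day),
        "animals": truth_animals,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def gen_abundance_table(config: GeneratorConfig) -> tuple[AbundanceTable, dict]:
    """Log-normal abundance table with a designated truly-regulated set.

    The first ``n_de_up`` proteins are shifted +log2(fold) and the next
    ``n_de_down`` by -log2(fold) in the second (stressed) group.  The
    sidecar names the regulated proteins and their directions.
    """
    om = config.omics
    rng = _rng(config, "omics")
    proteins = [f"P{i + 1:05d}" for i in range(om.n_proteins)]
    ctrl_group, cvs_group = config.groups
    samples = {
        ctrl_group: [f"{ctrl_group}_s{i + 1}" for i in range(om.n_samples_per_group)],
        cvs_group: [f"{cvs_group}_s{i + 1}" for i in range(om.n_samples_per_group)],
    }
    base = om.log2_mean + om.log2_between_protein_sd * rng.standard_normal(om.n_proteins)
    shift = np.zeros(om.n_proteins)
    lf = np.log2(om.fold_change)
    shift[: om.n_de_up] = lf
    shift[om.n_de_up: om.n_de_up + om.n_de_down] = -lf

    cols = {}
    for s in samples[ctrl_group]:
        cols[s] = base + om.log2_noise_sd * rng.standard_normal(om.n_proteins)
    for s in samples[cvs_group]:
        cols[s] = base + shift + om.log2_noise_sd * rng.standard_normal(om.n_proteins)
    log2_values = pd.DataFrame(cols, index=proteins)
    values = 2.0 ** log2_values
    groups = pd.Series(
        {s: g for g, ss in samples.items() for s in ss}, name="group"
    )
    table = AbundanceTable(values, groups)
    truth = {
        "de_up": proteins[: om.n_de_up],
        "de_down": proteins[om.n_de_up: om.n_de_up + om.n_de_down],
        "fold_change": om.fold_change,
        "log2_noise_sd": om.log2_noise_sd,
    }
    return table, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def gen_qpcr(config: GeneratorConfig) -> tuple[QpcrRecords, dict]:
    """Nd1/Lpl Ct triplicates per animal.

    The true mtDNA/nDNA ratio r sets Ct(Nd1) = Ct(Lpl) - log2(r); an
    animal-level Ct shift applies to both genes (and so cancels in the
    ratio), replicate noise is Gaussian per reading.
    """
    qp = config.qpcr
    rng = _rng(config, "qpcr")
    rows = []
    truth_animals = {}
    for group in config.groups:
        r = qp.true_ratio[group]
        for i in range(qp.n_animals_per_group):
            animal = f"{group}-q{i + 1:02d}"
            shift = qp.animal_ct_sd * rng.standard_normal() if qp.animal_ct_sd else 0.0
            ct_lpl = qp.ct_nuclear_mean + shift
            ct_nd1 = ct_lpl - np.log2(r)
            truth_animals[animal] = {"true_ratio": r}
            for gene, ct0 in (("Nd1", ct_nd1), ("Lpl", ct_lpl)):
                for rep in range(1, qp.replicates + 1):
                    ct = ct0 + (qp.replicate_sd * rng.standard_normal()
                                if qp.replicate_sd else 0.0)
                    rows.append((animal, group, gene, rep, ct))
    data = pd.DataFrame(rows, columns=["animal_id", "group", "gene", "replicate", "ct"])
    records = QpcrRecords(data)
    truth = {"true_ratio": dict(qp.true_ratio), "animals": truth_animals}
    return records, truth
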