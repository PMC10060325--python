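"""End-to-end orchestration: simulate or load, analyze, report.

A run is driven by one YAML config (``RunConfig``): either a simulation
block (a :class:`~mitothermics.synthetic_data.GeneratorConfig`) or explicit
input paths per data kind, plus the per-module options.  Stages run in the
order flux -> bioenergetics -> calorimetry -> omics, each writing a
self-describing CSV into the output directory, and the run ends with a
machine-readable ``summary.json`` (group means, percent changes, coupling
bands, test results) and a ``manifest.json`` (config hash, seed, package
and library versions).  Identical config and seed give byte-identical
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .bioenergetics import classify_coupling, stucki_setpoints, thermodynamic_coupling
from .calorimetry import (
    circadian_phase_summary,
    derive_metabolic_series,
    intake_metrics,
    read_cage_csv,
)
from .flux_assay import (
    electron_flow_summary,
    extract_states,
    normalize_states,
    read_plate,
)
from .omics_enrichment import (
    PathwayDef,
    de_filter,
    enrich_pathways,
    mtdna_ratio,
    pathway_zscores,
    read_abundance_tsv,
    read_gmt,
    read_qpcr_csv,
    read_sample_map,
)
from .stats_core import compare_groups
from .synthetic_data import (
    GeneratorConfig,
    gen_abundance_table,
    gen_cage_trace,
    gen_flux_plate,
    gen_qpcr,
)

__all__ = ["RunConfig", "ModuleOptions", "InputPaths", "run_pipeline", "load_config"]

log = logging.getLogger("mitothermics")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

SCHEMA_VERSION = 1
DATA_KINDS = ("flux", "cage", "omics", "qpcr")
COUPLING_ASSAYS = ("coupling-CI", "coupling-CII")


class ModuleOptions(BaseModel):
    """Per-module analysis options (documented defaults)."""

    phase_stat: Literal["mean", "last"] = "mean"
    epsilon: float | Literal["auto"] = "auto"
    q_policy: Literal["clamp", "strict"] = "clamp"
    fold_threshold: float = Field(1.5, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    ease_variant: Literal["ease", "classic"] = "ease"
    diet_kj_per_g: float = Field(12.8, gt=0)   # metabolizable energy, standard chow
    antimycin_correct: bool = False


class InputPaths(BaseModel):
    """Explicit input files; any omitted kind must come from simulation."""

    flux_coupling_ci: str | None = None
    flux_coupling_cii: str | None = None
    flux_electron_flow: str | None = None
    cage: str | None = None
    abundance: str | None = None
    sample_map: str | None = None
    pathways_gmt: str | None = None
    qpcr: str | None = None

    def covers(self, kind: str) -> bool:
        if kind == "flux":
            return bool(self.flux_coupling_ci and self.flux_coupling_cii)
        if kind == "cage":
            return bool(self.cage)
        if kind == "omics":
            return bool(self.abundance and self.sample_map and self.pathways_gmt)
        if kind == "qpcr":
            return bool(self.qpcr)
        raise ValueError(kind)


class RunConfig(BaseModel):
    """One pipeline run: data sources, options, output directory, seed."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    out_dir: str = "results"
    simulation: GeneratorConfig | None = None
    inputs: InputPaths | None = None
    options: ModuleOptions = Field(default_factory=ModuleOptions)

    @model_validator(mode="after")
    def _one_source_per_kind(self):
        inputs = self.inputs or InputPaths()
        for kind in DATA_KINDS:
            has_path = inputs.covers(kind)
            has_sim = self.simulation is not None
            if has_path and has_sim:
                raise ValueError(
                    f"data kind {kind!r} configured from both input paths and simulation"
                )
            if not has_path and not has_sim:
                raise ValueError(f"no data source for kind {kind!r}")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _jsonable(obj: Any) -> Any:
    """Round floats and coerce numpy scalars so summaries are reproducible."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, 10) if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.options
    summary: dict[str, Any] = {"schema_version": config.schema_version, "seed": config.seed}
    sim = config.simulation
    if sim is not None and sim.seed != config.seed:
        sim = sim.model_copy(update={"seed": config.seed})

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    timings: dict[str, float] = {}

    # ----- flux + bioenergetics ------------------------------------------
    t0 = stage("flux")
    try:
        flux_summary: dict[str, Any] = {}
        for assay in COUPLING_ASSAYS + ("electron-flow",):
            if sim is not None:
                plate, truth = gen_flux_plate(sim, assay)
                (out / f"truth_{assay}.json").write_text(
                    json.dumps(_jsonable(truth), sort_keys=True, indent=2)
                )
            else:
                attr = {"coupling-CI": "flux_coupling_ci",
                        "coupling-CII": "flux_coupling_cii",
                        "electron-flow": "flux_electron_flow"}[assay]
                path = getattr(config.inputs, attr)
                if path is None:
                    continue
                plate = read_plate(path, assay)
            states = extract_states(plate, phase_stat=opts.phase_stat)
            states = normalize_states(states, plate)
            _write_csv(states.table.reset_index(), out / f"states_{assay}.csv")
            flow = electron_flow_summary(states)
            _write_csv(flow, out / f"group_summary_{assay}.csv")
            assay_summary: dict[str, Any] = {
                "percent_change": dict(zip(flow["state"], flow["percent_change"])),
                "p": dict(zip(flow["state"], flow["p"])),
            }
            if assay in COUPLING_ASSAYS:
                tbl = states.table
                coup = thermodynamic_coupling(
                    tbl["state3"], tbl["state4o"], samples=tbl.index,
                    epsilon=opts.epsilon, policy=opts.q_policy,
                )
                ct = coup.table.merge(
                    tbl[["group"]], left_on="sample", right_index=True
                )
                _write_csv(ct, out / f"coupling_{assay}.csv")
                by_group = {}
                for g, sub in ct.groupby("group", sort=True):
                    mean_q = float(sub["q"].mean())
                    by_group[g] = {
                        "mean_q": mean_q,
                        "mean_eta_opt": float(sub["eta_opt"].mean()),
                        "mean_rcr": float(sub["rcr"].mean()),
                        "band_of_mean_q": classify_coupling(mean_q),
                        "bands": sorted(sub["band"].unique()),
                    }
                groups = sorted(ct["group"].unique())
                tests = {}
                for metric in ("q", "eta_opt", "rcr"):
                    cmpres = compare_groups(
                        {g: ct.loc[ct["group"] == g, metric].to_numpy() for g in groups}
                    )
                    tests[metric] = {"test": cmpres.test_name, "p": cmpres.p,
                                     "mean_diff": cmpres.mean_diff}
                assay_summary["coupling"] = {
                    "offset": coup.offset, "by_group": by_group, "tests": tests,
                }
            flux_summary[assay] = assay_summary
        sp = stucki_setpoints()
        flux_summary["stucki_setpoints"] = {
            "q_f": sp.q_f, "q_p": sp.q_p, "q_f_ec": sp.q_f_ec, "q_p_ec": sp.q_p_ec,
        }
        summary["flux"] = flux_summary
    except Exception as e:
        raise RuntimeError(f"stage 'flux' failed: {e}") from e
    timings["flux"] = time.perf_counter() - t0

    # ----- calorimetry ----------------------------------------------------
    t0 = stage("calorimetry")
    try:
        if sim is not None:
            trace, truth = gen_cage_trace(sim)
            (out / "truth_cage.json").write_text(
                json.dumps(_jsonable(truth), sort_keys=True, indent=2)
            )
        else:
            trace = read_cage_csv(config.inputs.cage)
        derived = derive_metabolic_series(trace)
        phases = circadian_phase_summary(trace, derived)
        _write_csv(phases.table, out / "phase_summary.csv")
        cage_summary: dict[str, Any] = {"window_bins": phases.n_bins, "phases": {}}
        for phase_name, sub in phases.table.groupby("phase", sort=True):
            groups = sorted(sub["group"].unique())
            entry: dict[str, Any] = {}
            for metric in ("ee", "rer", "cho_mg_min", "fao_mg_min", "activity"):
                means = {g: float(sub.loc[sub["group"] == g, metric].mean()) for g in groups}
                cmpres = compare_groups(
                    {g: sub.loc[sub["group"] == g, metric].to_numpy() for g in groups}
                )
                entry[metric] = {"group_means": means, "test": cmpres.test_name, "p": cmpres.p}
            cage_summary["phases"][phase_name] = entry
        # intake over the 48-h window, per animal
        win = derived[(derived["timestamp"] >= phases.window_start)
                      & (derived["timestamp"] < phases.window_start + pd.Timedelta(hours=48))]
        rows = []
        for animal, sub in win.groupby("animal_id", sort=True):
            sub = sub.sort_values("timestamp")
            intake_per_g, wc_per_kj = intake_metrics(
                sub["food_g"].to_numpy(),
                float(sub["bw_g"].iloc[0]), float(sub["bw_g"].iloc[-1]),
                opts.diet_kj_per_g,
            )
            rows.append({"animal_id": animal, "group": sub["group"].iloc[0],
                         "intake_kj_per_g_bw": intake_per_g,
                         "weight_change_mg_per_kj": wc_per_kj})
        intake = pd.DataFrame(rows)
        _write_csv(intake, out / "intake_metrics.csv")
        cage_summary["intake_kj_per_g_bw"] = {
            g: float(sub["intake_kj_per_g_bw"].mean())
            for g, sub in intake.groupby("group", sort=True)
        }
        summary["calorimetry"] = cage_summary
    except Exception as e:
        raise RuntimeError(f"stage 'calorimetry' failed: {e}") from e
    timings["calorimetry"] = time.perf_counter() - t0

    # ----- omics ----------------------------------------------------------
    t0 = stage("omics")
    try:
        if sim is not None:
            table, truth = gen_abundance_table(sim)
            (out / "truth_omics.json").write_text(
                json.dumps(_jsonable(truth), sort_keys=True, indent=2)
            )
            non_de = [p for p in table.values.index
                      if p not in set(truth["de_up"]) | set(truth["de_down"])]
            pathways = [
                PathwayDef("regulated_up", frozenset(truth["de_up"])),
                PathwayDef("regulated_down", frozenset(truth["de_down"])),
                PathwayDef("background_sample", frozenset(non_de[:50])),
            ]
        else:
            table = read_abundance_tsv(
                config.inputs.abundance, read_sample_map(config.inputs.sample_map)
            )
            pathways = read_gmt(config.inputs.pathways_gmt)
        ctrl, cvs = sorted(table.groups.unique())[:2]
        if "Ctrl" in set(table.groups):
            ctrl = "Ctrl"
            cvs = next(g for g in table.groups.unique() if g != "Ctrl")
        de = de_filter(table, ctrl, cvs, opts.fold_threshold, opts.alpha)
        _write_csv(de.table.reset_index(names="protein"), out / "de_table.csv")
        enr = enrich_pathways(
            list(de.significant.index), pathways, list(table.values.index),
            variant=opts.ease_variant,
        )
        _write_csv(enr, out / "enrichment.csv")
        zrows = []
        for pw in pathways:
            try:
                z = pathway_zscores(table, pw, ctrl, cvs)
            except ValueError:
                continue
            zrows.append({"pathway": pw.name, "mean_difference": z.mean_difference,
                          "ci_low": z.ci_low, "ci_high": z.ci_high,
                          **{f"mean_z_{g}": m for g, m in z.group_means.items()}})
        _write_csv(pd.DataFrame(zrows), out / "pathway_zscores.csv")
        summary["omics"] = {
            "n_tested": de.n_tested, "n_up": de.n_up, "n_down": de.n_down,
            "enrichment": {r["pathway"]: {"p": r["p"], "q": r["q"], "overlap": r["overlap"]}
                           for r in enr.to_dict("records")},
            "pathway_zscores": {r["pathway"]: {k: v for k, v in r.items() if k != "pathway"}
                                for r in zrows},
        }
    except Exception as e:
        raise RuntimeError(f"stage 'omics' failed: {e}") from e
    timings["omics"] = time.perf_counter() - t0

    # ----- qPCR -----------------------------------------------------------
    t0 = stage("qpcr")
    try:
        if sim is not None:
            records, truth = gen_qpcr(sim)
            (out / "truth_qpcr.json").write_text(
                json.dumps(_jsonable(truth), sort_keys=True, indent=2)
            )
        else:
            records = read_qpcr_csv(config.inputs.qpcr)
        ratios = mtdna_ratio(records)
        _write_csv(ratios, out / "mtdna_ratio.csv")
        groups = sorted(ratios["group"].unique())
        cmpres = compare_groups(
            {g: ratios.loc[ratios["group"] == g, "ratio"].to_numpy() for g in groups}
        )
        summary["qpcr"] = {
            "group_means": {g: float(ratios.loc[ratios["group"] == g, "ratio"].mean())
                            for g in groups},
            "test": cmpres.test_name, "p": cmpres.p,
        }
    except Exception as e:
        raise RuntimeError(f"stage 'qpcr' failed: {e}") from e
    timings["qpcr"] = time.perf_counter() - t0

    # ----- report ---------------------------------------------------------
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n")
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "schema_version": config.schema_version,
        "versions": {
            "mitothermics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    for name, dt in timings.items():
        log.info("stage %s took %.2fs", name, dt)
    return summary
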