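"""Extracellular-flux plate parsing and respiration-state extraction.

A plate run measures the oxygen consumption rate (OCR, pmol O2/min) of
isolated mitochondria in each well over a sequence of injection phases.
Three protocols are supported:

* ``coupling-CI`` / ``coupling-CII`` — basal respiration on complex I- or
  complex II-specific substrate (state 2), then ADP (state 3), oligomycin
  (state 4o), FCCP (state 3u) and antimycin A (non-mitochondrial residual);
* ``electron-flow`` — FCCP-uncoupled basal on full substrate, then
  complex-specific inhibitor, complex-specific substrate re-stimulation,
  antimycin A, and TMPD/ascorbate to drive complex IV.

Each protocol opens with two equilibration cycles whose ticks are excluded
from every state.  State 2 (and the uncoupled basal of electron-flow runs)
is the *second* basal tick — the first only verifies equilibration.  Every
other state is the mean of its phase's ticks by default (``phase_stat=
"last"`` keeps only the final tick for plateau-seeking use).  Technical
replicate wells of one animal are averaged after state extraction, because
cohort statistics run on animals, not wells.

Normalization divides each state by (protein loaded / 2.5 ug reference) and
then by citrate-synthase activity, the mitochondrial-content marker; the
chain applied is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats_core

__all__ = [
    "InjectionProtocol",
    "PROTOCOLS",
    "PlateAssay",
    "RespirationStates",
    "read_plate",
    "extract_states",
    "normalize_states",
    "electron_flow_summary",
    "PROTEIN_REFERENCE_UG",
]

PROTEIN_REFERENCE_UG = 2.5   # mitochondrial protein loaded per well
EQUILIBRATION_PHASE = "equilibration"


@dataclass(frozen=True)
class InjectionProtocol:
    """Ordered injection phases of one assay protocol.

    phases: (state label, injected compound, number of measurement ticks).
    Equilibration cycles precede the first phase and carry no state.
    """

    name: str
    phases: tuple[tuple[str, str, int], ...]
    equilibration_cycles: int = 2

    def __post_init__(self):
        labels = [p[0] for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate phase labels in protocol {self.name}")

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.phases)


PROTOCOLS: dict[str, InjectionProtocol] = {
    "coupling-CI": InjectionProtocol(
        "coupling-CI",
        (
            ("basal", "pyruvate/malate (+malonate)", 2),
            ("state3", "ADP 2 mmol/l", 3),
            ("state4o", "oligomycin 2 umol/l", 3),
            ("state3u", "FCCP 6 umol/l", 3),
            ("residual", "antimycin A 2 umol/l", 3),
        ),
    ),
    "coupling-CII": InjectionProtocol(
        "coupling-CII",
        (
            ("basal", "succinate (+rotenone)", 2),
            ("state3", "ADP 2 mmol/l", 3),
            ("state4o", "oligomycin 2 umol/l", 3),
            ("state3u", "FCCP 6 umol/l", 3),
            ("residual", "antimycin A 2 umol/l", 3),
        ),
    ),
    "electron-flow": InjectionProtocol(
        "electron-flow",
        (
            ("basal_uncoupled", "pyr/mal/succ + FCCP", 2),
            ("post_inhibition", "rotenone or malonate", 3),
            ("post_stimulation", "complex-specific substrate", 3),
            ("post_antimycin", "antimycin A 2 umol/l", 3),
            ("post_tmpd", "TMPD/ascorbate", 3),
        ),
    ),
}

# second-basal rule applies to the first (basal) phase of every protocol,
# including the uncoupled basal of electron-flow runs (same instrument logic)
_BASAL_LABELS = {"basal", "basal_uncoupled"}

PLATE_COLUMNS = [
    "well_id", "animal_id", "group", "replicate", "assay_kind", "phase",
    "tick_index", "time_min", "ocr_pmol_min", "protein_ug", "cs_activity",
]


@dataclass
class PlateAssay:
    """Validated plate table: one row per well per measurement tick."""

    data: pd.DataFrame
    protocol: InjectionProtocol

    @property
    def wells(self) -> pd.DataFrame:
        return (
            self.data[["well_id", "animal_id", "group", "replicate",
                       "protein_ug", "cs_activity"]]
            .drop_duplicates("well_id")
            .reset_index(drop=True)
        )


def _validate_plate(df: pd.DataFrame, protocol: InjectionProtocol) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing column(s): {', '.join(missing)}")
    known = set(protocol.state_labels) | {EQUILIBRATION_PHASE}
    unknown = df.loc[~df["phase"].isin(known)]
    if not unknown.empty:
        rows = unknown.index.tolist()[:10]
        raise ValueError(
            f"unknown phase label(s) {sorted(unknown['phase'].unique())} at row(s) {rows}; "
            f"protocol {protocol.name} knows {sorted(known)}"
        )
    dup = df.duplicated(subset=["well_id", "phase", "tick_index"])
    if dup.any():
        raise ValueError(f"duplicate (well, phase, tick) at row(s) {df.index[dup].tolist()[:10]}")
    if np.any(df["protein_ug"].to_numpy() <= 0):
        raise ValueError("protein_ug must be positive")
    if np.any(df["cs_activity"].to_numpy() <= 0):
        raise ValueError("cs_activity must be positive")

    df = df.sort_values(["well_id", "time_min"], kind="stable").reset_index(drop=True)
    order = {lab: i for i, lab in enumerate((EQUILIBRATION_PHASE,) + protocol.state_labels)}
    for well, sub in df.groupby("well_id", sort=False):
        t = sub["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"tick times not strictly increasing in well {well}")
        codes = sub["phase"].map(order).to_numpy()
        if np.any(np.diff(codes) < 0):
            raise ValueError(f"rows out of protocol phase order in well {well}")
        present = set(sub["phase"]) - {EQUILIBRATION_PHASE}
        absent = set(protocol.state_labels) - present
        if absent:
            raise ValueError(f"well {well} missing phase(s) {sorted(absent)}")
        norms = sub[["protein_ug", "cs_activity"]].drop_duplicates()
        if len(norms) != 1:
            raise ValueError(f"well {well} has inconsistent normalizer values")
    return df


def read_plate(path, protocol: InjectionProtocol | str) -> PlateAssay:
    """Read and validate a plate CSV against its injection protocol.

    The CSV schema is the PLATE_COLUMNS header.  Row order is free: rows
    are keyed by (well, phase, tick) and re-sorted by time.
    """
    if isinstance(protocol, str):
        protocol = resolve_protocol(protocol)
    df = pd.read_csv(path)
    return PlateAssay(_validate_plate(df, protocol), protocol)


def resolve_protocol(name: str) -> InjectionProtocol:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise ValueError(
            f"unknown assay kind {name!r}; known protocols: {sorted(PROTOCOLS)}"
        ) from None


@dataclass
class RespirationStates:
    """Per-animal respiration states for one assay kind.

    ``table`` is indexed by animal with one column per state label plus
    ``group``.  ``normalized`` flips exactly once, in normalize_states;
    ``metadata`` records the normalization chain.
    """

    table: pd.DataFrame
    assay_kind: str
    phase_stat: str
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def state_labels(self) -> list[str]:
        return [c for c in self.table.columns if c != "group"]


def extract_states(
    plate: PlateAssay,
    phase_stat: Literal["mean", "last"] = "mean",
) -> RespirationStates:
    """Respiration states per animal from a validated plate.

    Basal phases take the *second* tick; all other phases take the mean of
    their ticks (or the last tick under ``phase_stat="last"``).
    Equilibration ticks never contribute.  Technical replicate wells are
    averaged per animal after extraction.
    """
    if phase_stat not in ("mean", "last"):
        raise ValueError("phase_stat must be 'mean' or 'last'")
    df = plate.data[plate.data["phase"] != EQUILIBRATION_PHASE]

    rows = []
    for (well, phase), sub in df.groupby(["well_id", "phase"], sort=False):
        sub = sub.sort_values("time_min")
        ocr = sub["ocr_pmol_min"].to_numpy(dtype=float)
        if len(ocr) == 0:
            raise ValueError(f"empty phase {phase} in well {well}")
        if phase in _BASAL_LABELS:
            if len(ocr) < 2:
                raise ValueError(
                    f"well {well}: phase {phase} needs >= 2 ticks for the second-basal rule"
                )
            value = ocr[1]
        elif phase_stat == "mean":
            value = float(np.mean(ocr))
        else:
            value = ocr[-1]
        meta = sub.iloc[0]
        rows.append(
            {"well_id": well, "animal_id": meta["animal_id"], "group": meta["group"],
             "phase": phase, "value": value}
        )
    per_well = pd.DataFrame(rows)
    wide = per_well.pivot_table(
        index=["animal_id", "group"], columns="phase", values="value", aggfunc="mean"
    )
    wide = wide[[lab for lab in plate.protocol.state_labels]]  # protocol order
    wide.columns.name = None
    table = wide.reset_index().set_index("animal_id")
    table = table[["group"] + list(plate.protocol.state_labels)]
    return RespirationStates(
        table=table,
        assay_kind=plate.protocol.name,
        phase_stat=phase_stat,
        metadata={"replicate_aggregation": "mean over technical replicates"},
    )


def normalize_states(states: RespirationStates, plate: PlateAssay) -> RespirationStates:
    """Divide every state by (protein/2.5 ug) then by CS activity.

    Normalizers are per well; replicate wells of one animal share them by
    plate validation, so the per-animal mean is exact.  Double
    normalization is rejected.
    """
    if states.normalized:
        raise ValueError("states already normalized")
    wells = plate.wells
    norm = wells.groupby("animal_id")[["protein_ug", "cs_activity"]].mean()
    if np.any(norm.to_numpy() <= 0):
        raise ValueError("nonpositive normalizer")
    table = states.table.copy()
    factors = (norm["protein_ug"] / PROTEIN_REFERENCE_UG) * norm["cs_activity"]
    missing = set(table.index) - set(factors.index)
    if missing:
        raise ValueError(f"plate lacks normalizers for animal(s) {sorted(missing)}")
    for col in states.state_labels:
        table[col] = table[col] / factors.reindex(table.index)
    meta = dict(states.metadata)
    meta["normalization"] = [
        f"protein: /(protein_ug/{PROTEIN_REFERENCE_UG})",
        "citrate synthase: /cs_activity",
    ]
    return RespirationStates(
        table=table,
        assay_kind=states.assay_kind,
        phase_stat=states.phase_stat,
        normalized=True,
        metadata=meta,
    )


def electron_flow_summary(
    states: RespirationStates,
    control: str = "Ctrl",
    treated: str = "Cvs",
) -> pd.DataFrame:
    """Group means and percent change (treated vs control) per state.

    percent change = 100 * (mean_treated - mean_control) / mean_control.
    Group comparison (normality-gated test) is delegated to stats_core and
    reported per state.
    """
    table = states.table
    for g in (control, treated):
        if (table["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} absent or has fewer than 2 animals")
    rows = []
    for state in states.state_labels:
        a = table.loc[table["group"] == control, state].to_numpy(dtype=float)
        b = table.loc[table["group"] == treated, state].to_numpy(dtype=float)
        cmp = stats_core.compare_groups({control: a, treated: b})
        rows.append(
            {
                "state": state,
                f"mean_{control}": float(np.mean(a)),
                f"mean_{treated}": float(np.mean(b)),
                "percent_change": 100.0 * (np.mean(b) - np.mean(a)) / np.mean(a),
                "test": cmp.test_name,
                "p": cmp.p,
            }
        )
    return pd.DataFrame(rows)
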