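import numpy as np
import pandas as pd
import pytest

from mitothermics.flux_assay import PLATE_COLUMNS, PROTOCOLS, PlateAssay, _validate_plate
from mitothermics.synthetic_data import GeneratorConfig


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture
def quiet_config():
    """Fully deterministic generator: every noise source zeroed."""
    cfg = GeneratorConfig(seed=1)
    cfg.flux.noise_cv = 0.0
    cfg.flux.animal_cv = 0.0
    cfg.flux.drift_per_tick = 0.0
    cfg.flux.cs_activity_cv = 0.0
    cfg.cage.ee_noise_cv = 0.0
    cfg.cage.rer_noise_sd = 0.0
    cfg.cage.bw_sd_g = 0.0
    cfg.cage.ee_ripple = 0.0
    cfg.qpcr.replicate_sd = 0.0
    cfg.qpcr.animal_ct_sd = 0.0
    cfg.omics.log2_noise_sd = 0.0
    return cfg


def build_plate(well_states, protocol_name="coupling-CI", protein_ug=2.5, cs_activity=1.0):
    """Hand-build a validated coupling plate.

    well_states: list of dicts with keys animal_id, group, replicate and a
    per-phase OCR mapping under 'states' (scalar -> constant ticks, or a
    list of tick values).
    """
    protocol = PROTOCOLS[protocol_name]
    rows = []
    for w, spec in enumerate(well_states):
        well = f"w{w}"
        t = 0.0
        tick = 0
        basal_label = protocol.state_labels[0]
        plan = [("equilibration", protocol.equilibration_cycles,
                 spec["states"][basal_label])]
        plan += [(lab, n, spec["states"][lab]) for lab, _, n in protocol.phases]
        for phase, n_ticks, val in plan:
            vals = val if isinstance(val, (list, tuple)) else [val] * n_ticks
            for v in vals[:n_ticks] if phase == "equilibration" else vals:
                rows.append((well, spec["animal_id"], spec["group"], spec["replicate"],
                             protocol_name, phase, tick, t, float(v),
                             spec.get("protein_ug", protein_ug),
                             spec.get("cs_activity", cs_activity)))
                t += 3.5
                tick += 1
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    return PlateAssay(_validate_plate(df, protocol), protocol)


def coupling_states(basal=100.0, state3=300.0, state4o=60.0, state3u=350.0, residual=10.0):
    return {"basal": basal, "state3": state3, "state4o": state4o,
            "state3u": state3u, "residual": residual}
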