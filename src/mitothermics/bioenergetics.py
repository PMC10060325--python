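"""Thermodynamic coupling analysis of oxidative phosphorylation.

Isolated mitochondria respiring in an extracellular-flux plate are modelled
as a linear two-flow energy converter: an input flow (substrate oxidation)
drives an output flow (ADP phosphorylation) through a coupling of degree
``q`` in [0, 1].  Oligomycin-inhibited respiration (state 4o) is the pure
leak flow, ADP-stimulated respiration (state 3) the fully loaded flow, which
gives

    q       = sqrt(1 - state4o / state3)
    eta_opt = q**2 / (1 + sqrt(1 - q**2))**2

where ``eta_opt`` is the efficiency of the converter when operated at the
optimal-efficiency force ratio x_opt = -q / (1 + sqrt(1 - q**2)).

The converter theory singles out four degrees of coupling at which the state
of optimal efficiency coincides with the maximum of a physiologically
meaningful output function: net output flow (ATP flow), output power,
economic flow (flow x efficiency) and economic power (power x efficiency).
These "set points" are found here by numerical maximization of

    F_n(q) = q**n * s / (1 + s)**n,   s = sqrt(1 - q**2),   n = 1..4

over q in (0, 1), and samples are classified into the half-open bands the
set points delimit.

The respiratory control ratio RCR = state3/state4o is computed with the
batch offset rule used for plate data whose state-4o readings can go
negative: a single constant c = -min(state4o) + epsilon is added to every
state-3 and state-4o reading in the batch before taking ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "StuckiSetpoints",
    "CouplingResult",
    "respiratory_control_ratio",
    "coupling_degree",
    "optimal_efficiency",
    "thermodynamic_coupling",
    "stucki_setpoints",
    "classify_coupling",
    "BAND_LABELS",
]

BAND_LABELS = (
    "below q_f",
    "q_f-q_p",
    "q_p-q_f_ec",
    "q_f_ec-q_p_ec",
    "above q_p_ec",
)


# ---------------------------------------------------------------------------
# q and eta-opt: the two-flow converter mapping, isolated so a corrected
# state->flow identification would be a one-line change.
# ---------------------------------------------------------------------------

def coupling_degree(state3, state4o, policy: Literal["clamp", "strict"] = "clamp"):
    """Degree of thermodynamic coupling q from state 3 and state 4o.

    q = sqrt(1 - state4o/state3).  state4o > state3 makes the ratio
    undefined; under ``policy="clamp"`` such samples get q = 0 with a
    warning, under ``"strict"`` they raise.  Negative state 4o (possible
    on raw plate readings) is clamped to the perfect-coupling limit q = 1
    under "clamp".
    """
    s3 = np.asarray(state3, dtype=float)
    s4 = np.asarray(state4o, dtype=float)
    if np.any(s3 <= 0):
        raise ValueError("state3 must be positive (apply the batch offset first)")
    ratio = s4 / s3
    bad_high = ratio > 1.0
    bad_low = ratio < 0.0
    if policy == "strict":
        if np.any(bad_high):
            raise ValueError("state4o > state3: q undefined under strict policy")
        if np.any(bad_low):
            raise ValueError("negative state4o: q undefined under strict policy")
    else:
        if np.any(bad_high):
            warnings.warn(
                f"{int(np.sum(bad_high))} sample(s) with state4o > state3; q clamped to 0",
                stacklevel=2,
            )
        if np.any(bad_low):
            warnings.warn(
                f"{int(np.sum(bad_low))} sample(s) with negative state4o; q clamped to 1",
                stacklevel=2,
            )
    q = np.sqrt(1.0 - np.clip(ratio, 0.0, 1.0))
    return q if q.ndim else float(q)


def optimal_efficiency(q):
    """Optimal thermodynamic efficiency eta_opt(q) = q^2 / (1 + sqrt(1-q^2))^2.

    Continuous and strictly increasing on [0, 1] with eta_opt(0) = 0 and
    eta_opt(1) = 1.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    s = np.sqrt(1.0 - q * q)
    eta = (q / (1.0 + s)) ** 2
    return eta if eta.ndim else float(eta)


# ---------------------------------------------------------------------------
# RCR with the batch offset rule
# ---------------------------------------------------------------------------

def respiratory_control_ratio(
    state3: Sequence[float],
    state4o: Sequence[float],
    epsilon: float | Literal["auto"] = "auto",
) -> tuple[np.ndarray, float]:
    """RCR = (state3 + c) / (state4o + c) with a uniform batch offset c.

    c = 0 when every state 4o is positive; otherwise c = -min(state4o) +
    epsilon, added to ALL state-3 and state-4o readings of the batch so
    negative resting respiration becomes usable.  ``epsilon="auto"`` uses
    1% of the median state 3.

    Returns (rcr per sample, c).  RCR < 1 (state3 < state4o) is allowed but
    flagged with a warning.
    """
    s3 = np.asarray(state3, dtype=float)
    s4 = np.asarray(state4o, dtype=float)
    if s3.shape != s4.shape:
        raise ValueError("state3 and state4o must be aligned by sample")
    if s3.size == 0:
        raise ValueError("empty batch")
    if epsilon == "auto":
        eps = 0.01 * float(np.median(s3))
        if eps <= 0:
            raise ValueError("auto epsilon requires positive median state3")
    else:
        eps = float(epsilon)
        if eps <= 0:
            raise ValueError("epsilon must be > 0")
    c = 0.0 if float(np.min(s4)) > 0 else -float(np.min(s4)) + eps
    s3c, s4c = s3 + c, s4 + c
    if np.any(s4c <= 0):  # contract: the offset must make every reading positive
        raise AssertionError("offset failed to raise all state4o above zero")
    rcr = s3c / s4c
    if np.any(rcr < 1):
        warnings.warn(
            f"{int(np.sum(rcr < 1))} sample(s) with RCR < 1 (state3 < state4o)",
            stacklevel=2,
        )
    return rcr, c


# ---------------------------------------------------------------------------
# Set points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StuckiSetpoints:
    """The four degrees of coupling at which optimal efficiency coincides
    with a maximal output function, and the force ratio at each."""

    q_f: float      # maximal net output flow
    q_p: float      # maximal output power
    q_f_ec: float   # maximal economic flow (flow x efficiency)
    q_p_ec: float   # maximal economic power (power x efficiency)
    x_opt: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.q_f < self.q_p < self.q_f_ec < self.q_p_ec < 1):
            raise ValueError("set points must satisfy 0 < q_f < q_p < q_f_ec < q_p_ec < 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.q_f, self.q_p, self.q_f_ec, self.q_p_ec)


def output_function(q, n: int):
    """F_n(q) = q^n * s / (1+s)^n with s = sqrt(1-q^2): the n-th output
    function (net flow, power, economic flow, economic power for n = 1..4)
    evaluated at the optimal-efficiency force ratio."""
    q = np.asarray(q, dtype=float)
    s = np.sqrt(1.0 - q * q)
    f = q ** n * s / (1.0 + s) ** n
    return f if f.ndim else float(f)


def _argmax_fn(n: int, tol: float) -> float:
    res = minimize_scalar(
        lambda q: -output_function(q, n),
        bounds=(1e-9, 1.0 - 1e-12),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(f"set-point optimization failed for output function n={n}")
    # guard: the maximum must be interior, not at a bracket end
    if not (1e-6 < res.x < 1 - 1e-9):
        raise RuntimeError(f"set-point optimum at bracket boundary for n={n}")
    return float(res.x)


@lru_cache(maxsize=None)
def stucki_setpoints(tolerance: float = 1e-8) -> StuckiSetpoints:
    """Derive the four set points by bracketed scalar maximization.

    tolerance is the optimizer's absolute x-tolerance, in (0, 1e-3].
    Results are cached after first derivation.
    """
    if not (0 < tolerance <= 1e-3):
        raise ValueError("tolerance must be in (0, 1e-3]")
    qs = [_argmax_fn(n, tolerance) for n in (1, 2, 3, 4)]
    names = ("q_f", "q_p", "q_f_ec", "q_p_ec")
    x_opt = {
        name: -q / (1.0 + float(np.sqrt(1 - q * q))) for name, q in zip(names, qs)
    }
    return StuckiSetpoints(*qs, x_opt=x_opt)


def classify_coupling(q, setpoints: StuckiSetpoints | None = None):
    """Assign q to a set-point band; boundaries are half-open [lower, upper)."""
    if setpoints is None:
        setpoints = stucki_setpoints()
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("q must lie in [0, 1]")
    edges = np.asarray(setpoints.as_tuple())
    idx = np.searchsorted(edges, q_arr, side="right")
    labels = np.asarray(BAND_LABELS, dtype=object)[idx]
    return labels if np.ndim(q) else str(labels[0])


# ---------------------------------------------------------------------------
# Per-sample coupling table
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    """Per-sample RCR, coupling degree, optimal efficiency and band."""

    table: pd.DataFrame            # columns: sample, rcr, offset, q, eta_opt, band
    offset: float                  # batch offset c applied to state 3 / state 4o
    setpoints: StuckiSetpoints
    warnings: list[str] = field(default_factory=list)


def thermodynamic_coupling(
    state3: Sequence[float],
    state4o: Sequence[float],
    samples: Sequence | None = None,
    epsilon: float | Literal["auto"] = "auto",
    policy: Literal["clamp", "strict"] = "clamp",
) -> CouplingResult:
    """RCR, q, eta_opt and set-point band per sample.

    The batch offset rule is applied first; q is then computed from the
    offset-adjusted states so that q and RCR describe the same adjusted
    readings (q = sqrt(1 - 1/RCR) holds exactly, offset or not).
    """
    s3 = np.asarray(state3, dtype=float)
    s4 = np.asarray(state4o, dtype=float)
    if samples is None:
        samples = np.arange(len(s3))
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        rcr, c = respiratory_control_ratio(s3, s4, epsilon=epsilon)
        q = coupling_degree(s3 + c, s4 + c, policy=policy)
        collected = [str(w.message) for w in wrec]
    eta = optimal_efficiency(q)
    sp = stucki_setpoints()
    band = classify_coupling(q, sp)
    table = pd.DataFrame(
        {
            "sample": list(samples),
            "rcr": rcr,
            "offset": c,
            "q": np.atleast_1d(q),
            "eta_opt": np.atleast_1d(eta),
            "band": np.atleast_1d(band),
        }
    )
    return CouplingResult(table=table, offset=c, setpoints=sp, warnings=collected)
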