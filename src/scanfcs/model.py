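"""Compartmental ODE model of SHR/SCR dynamics.

Six state variables: SHR in the vasculature (Sv), SHR monomer in the
endodermis (Se), SHR homodimer (S2e), SCR (C), the 1:1 SHR-SCR complex (SC)
and the 2:1 complex (S2C).  SHR is produced constitutively in the
vasculature and moves to the endodermis with an active-transport rate
``a1 = D1/A1`` (measured diffusion coefficient over cell area); reverse
movement ``a2`` is zero in wild type and ``D2/A2`` when SCR is knocked down.
Homodimer formation switches on logistically once SCR passes a threshold
C0, reflecting the observation that the dimer requires SCR.  SCR production
is a Hill-type function activated by both complexes and by SCR itself; in
the knockdown variant SCR is clamped (dC/dt = 0).

The printed monomer equation carries no consumption terms for dimerisation
or complex formation; this is kept exactly as formulated (a modelling
simplification, not corrected here).

Time unit: hours.  Transport rates measured in 1/s are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "Trajectory",
    "STATE_NAMES",
    "default_params",
    "load_params",
    "k2_of_C",
    "transport_rate",
    "rhs",
    "simulate",
    "steady_state_metrics",
]

STATE_NAMES = ("Sv", "Se", "S2e", "C", "SC", "S2C")

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ModelParams:
    """All rate constants of Models 1 (wild type) and 2 (SCR knockdown).

    ``a1``/``a2`` are stored in 1/hr; ``transport_rate`` derives them from a
    diffusion coefficient (um^2/s) and a cell area (um^2).
    """

    k1: float = 500.0
    a1: float = 88.2
    a2: float = 0.0
    d1: float = 1.0
    d2: float = 2.0
    d3: float = 0.6
    d4: float = 0.35
    d5: float = 0.6
    d6: float = 0.54284
    L: float = 0.5
    k: float = 0.1
    C0: float = 360.0
    k3: float = 260.0
    K1D: float = 10.0
    K2D: float = 90.0
    k4: float = 0.002
    k5: float = 0.004

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        for name in ("L", "k", "C0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Trajectory:
    """Integrated model trajectory on an hourly-resolution grid."""

    times: np.ndarray          # hr, strictly increasing
    states: np.ndarray         # (n_times, 6)
    mode: str
    params: ModelParams

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def terminal(self) -> dict:
        return dict(zip(STATE_NAMES, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_hr", self.times)
        return df


def transport_rate(D: float, A: float, per: str = "hr") -> float:
    """Active-transport rate a = D/A; ``per`` selects 1/s or 1/hr."""
    if A <= 0:
        raise ValueError("cell area must be > 0")
    a = D / A
    return a * SECONDS_PER_HOUR if per == "hr" else a


def load_params(path=None) -> tuple[ModelParams, pd.DataFrame]:
    """Model parameters from a structured-text (TSV) table.

    Returns the ModelParams plus the raw table (with provenance flags).
    Transport rates a1/a2 are derived from the tabulated D and A values;
    a2 stays 0 in the wild-type parameter set.
    """
    if path is None:
        src = resources.files("scanfcs").joinpath("data/model1_params.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    vals = dict(zip(table["name"], table["value"].astype(float)))
    a1 = transport_rate(vals.pop("D1"), vals.pop("A1"))
    vals.pop("D2", None)
    vals.pop("A2", None)
    known = {f.name for f in fields(ModelParams)}
    params = ModelParams(a1=a1, a2=0.0,
                         **{k: v for k, v in vals.items() if k in known})
    return params, table


def default_params() -> ModelParams:
    """Packaged wild-type default parameter set."""
    return load_params()[0]


def scri_params(base: ModelParams | None = None) -> ModelParams:
    """Parameter set of the SCR-knockdown variant: reverse transport on."""
    base = base or default_params()
    _, table = load_params()
    vals = dict(zip(table["name"], table["value"].astype(float)))
    a2 = transport_rate(vals["D2"], vals["A2"])
    return base.replace(a2=a2)


def k2_of_C(C, L: float, k: float, C0: float):
    """Logistic homodimer-formation rate L / (1 + exp(-k (C - C0)))."""
    z = np.clip(-k * (np.asarray(C, float) - C0), -700, 700)
    return L / (1.0 + np.exp(z))


def rhs(state, params: ModelParams, mode: str = "wildtype") -> np.ndarray:
    """Time derivatives of (Sv, Se, S2e, C, SC, S2C)."""
    p = params
    Sv, Se, S2e, C, SC, S2C = state
    k2 = k2_of_C(C, p.L, p.k, p.C0)
    dSv = p.k1 - p.a1 * Sv + p.a2 * Se - p.d1 * Sv
    dSe = p.a1 * Sv - p.a2 * Se - p.d2 * Se
    dS2e = k2 * Se ** 2 - p.d3 * S2e
    if mode == "wildtype":
        num = p.K1D ** 2 * C + p.K1D * SC + S2C
        den = (p.K1D ** 2 * p.K2D + p.K1D * p.K2D * Sv
               + p.K1D ** 2 * C + p.K1D * SC + S2C)
        dC = p.k3 * (num / den if den > 0 else 0.0) - p.d4 * C
    elif mode == "scri":
        dC = 0.0
    else:
        raise ValueError("mode must be 'wildtype' or 'scri'")
    dSC = p.k4 * Se * C - p.d5 * SC
    dS2C = p.k5 * S2e * C - p.d6 * S2C
    return np.array([dSv, dSe, dS2e, dC, dSC, dS2C])


#: default initial condition: empty system with a small SCR seed (SCR
#: production is autocatalytic through the Hill term, so C(0) must be > 0
#: for the wild-type system to leave the origin)
DEFAULT_INIT = (0.0, 0.0, 0.0, 10.0, 0.0, 0.0)


def simulate(params: ModelParams, init=DEFAULT_INIT, t_end: float = 48.0,
             mode: str = "wildtype", rtol: float = 1e-8, atol: float = 1e-10,
             n_eval: int = 2001) -> Trajectory:
    """Integrate the model with a stiff-capable solver (LSODA).

    Nonnegativity comes from tight tolerances, never from clipping.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = np.asarray(init, float)
    if (y0 < 0).any():
        raise ValueError("initial state must be nonnegative")
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(lambda t, y: rhs(y, params, mode), (0.0, t_end), y0,
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t = {sol.t[-1]:.3f} hr: "
                           f"{sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, mode=mode, params=params)


def steady_state_metrics(traj: Trajectory, tol: float = 0.01) -> dict:
    """Steady-state time and terminal composition percentages.

    ``steady_state_time`` is the earliest time after which every variable
    stays within ``tol`` (relative) of its terminal value; None with a
    warning flag if the trajectory has not settled by its end.
    ``homodimer_pct`` is 100*S2e/(Se+S2e) (entities, matching the pixel-wise
    N&B percentage); ``complex21_pct`` is 100*S2C/(SC+S2C).
    """
    y = traj.states
    terminal = y[-1]
    scale = np.maximum(np.abs(terminal), 1e-9 + 1e-6 * np.abs(terminal).max())
    dev = np.abs(y - terminal) / scale
    bad = (dev > tol).any(axis=1)
    if bad[-5:].any():
        sst = None
        converged = False
    else:
        last_bad = int(np.max(np.nonzero(bad)[0])) if bad.any() else -1
        sst = float(traj.times[last_bad + 1])
        converged = True

    Se, S2e = terminal[1], terminal[2]
    SC, S2C = terminal[4], terminal[5]
    homodimer_pct = 100.0 * S2e / (Se + S2e) if (Se + S2e) > 0 else np.nan
    complex21_pct = 100.0 * S2C / (SC + S2C) if (SC + S2C) > 0 else np.nan
    return {
        "steady_state_time": sst,
        "converged": converged,
        "homodimer_pct": float(homodimer_pct),
        "complex21_pct": float(complex21_pct),
        "terminal": dict(zip(STATE_NAMES, terminal)),
    }
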