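"""Variance-based global sensitivity analysis (Sobol total effects).

Radial Monte-Carlo design: two independent N x 15 draws A and B from the
parameter space, plus matrices C_i equal to A with column i taken from B.
The total-effect index of parameter i against a scalar outcome Y is
estimated with the Jansen form

    S_Ti = [ (1/2N) sum_j (f(A)_j - f(C_i)_j)^2 ] / V(Y),

one of the most accurate estimators of E(V(Y|X~i)).  Model outcomes are the
time-integrals of the six state variables over the simulated interval.
Replicated runs are z-normalised across parameters within each replicate
before averaging, and parameters are flagged influential by pairwise
Wilcoxon rank-sum tests with the Steel-Dwass critical-range adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, studentized_range

from .model import STATE_NAMES, ModelParams, simulate

__all__ = [
    "SOBOL_PARAMETERS",
    "SobolDesign",
    "SobolResult",
    "default_bounds",
    "generate_design",
    "evaluate_outcomes",
    "total_effect_indices",
    "normalize_and_rank",
    "run_replicates",
    "steel_dwass_flags",
]

#: the 15 varied parameters of Model 1 (the logistic shape constants k and
#: C0 are held fixed; a2 is varied even though the wild type sets it to 0,
#: since the question is how reverse transport would matter if present)
SOBOL_PARAMETERS = ("k1", "a1", "a2", "d1", "d2", "d3", "d4", "d5", "d6",
                    "k3", "k4", "k5", "K1D", "K2D", "L")


@dataclass
class SobolDesign:
    """A/B sample matrices (N x 15) plus bounds and sampling metadata."""

    A: np.ndarray
    B: np.ndarray
    bounds: dict
    parameters: tuple
    seed: int
    log_scale: tuple

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def radial_matrix(self, i: int) -> np.ndarray:
        """C_i: identical to A except column i is taken from B."""
        c = self.A.copy()
        c[:, i] = self.B[:, i]
        return c


@dataclass
class SobolResult:
    """Total-effect indices for one replicate: (15 params x 6 outcomes)."""

    st: np.ndarray
    variance: np.ndarray       # V(Y) per outcome
    parameters: tuple
    outcomes: tuple
    n: int
    n_failed: int = 0
    replicate: int = 0


#: transport rates are the least constrained quantities (they fold in cell
#: geometry); they are explored log-uniformly over a wider span
TRANSPORT_PARAMETERS = ("a1", "a2")
TRANSPORT_SPAN = 8.0
DEFAULT_LOG_SCALE = TRANSPORT_PARAMETERS


def default_bounds(params: ModelParams, lo: float = 0.25, hi: float = 4.0,
                   a2_reference: float = 57.6,
                   transport_span: float = TRANSPORT_SPAN) -> dict:
    """Bounds [lo x, hi x] around each default parameter value.

    a2 defaults to 0 in wild type; its bounds are taken around the measured
    reverse-transport rate of the knockdown (D2/A2) instead.  The transport
    rates get a wider (log-explored) span.
    """
    out = {}
    for name in SOBOL_PARAMETERS:
        ref = getattr(params, name)
        if name == "a2":
            ref = a2_reference
        if name in TRANSPORT_PARAMETERS:
            out[name] = (ref / transport_span, ref * transport_span)
        else:
            out[name] = (lo * ref, hi * ref)
    return out


def generate_design(bounds: dict, n: int = 1000, seed: int = 0,
                    log_scale: tuple = ()) -> SobolDesign:
    """Sample the A and B matrices uniformly (optionally log-uniformly).

    Each row is an independent draw of all 15 parameters from the stated
    bounds; parameters named in ``log_scale`` are drawn log-uniformly
    (appropriate for rates spanning decades).
    """
    parameters = tuple(bounds)
    lo = np.array([bounds[p][0] for p in parameters], float)
    hi = np.array([bounds[p][1] for p in parameters], float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with lower < upper")
    rng = np.random.default_rng(seed)
    is_log = np.array([p in log_scale for p in parameters])
    if is_log.any() and np.any(lo[is_log] <= 0):
        raise ValueError("log-scale parameters need positive lower bounds")

    def draw():
        u = rng.uniform(size=(n, len(parameters)))
        x = lo + u * (hi - lo)
        if is_log.any():
            llo, lhi = np.log(lo[is_log]), np.log(hi[is_log])
            x[:, is_log] = np.exp(llo + u[:, is_log] * (lhi - llo))
        return x

    return SobolDesign(A=draw(), B=draw(), bounds=dict(bounds),
                       parameters=parameters, seed=seed,
                       log_scale=tuple(log_scale))


def _integrated_outcomes(row: np.ndarray, parameters: tuple,
                         base: ModelParams, t_end: float, rtol: float,
                         init) -> np.ndarray:
    p = base.replace(**dict(zip(parameters, row)))
    try:
        traj = simulate(p, init=init, t_end=t_end, mode="wildtype",
                        rtol=rtol, atol=1e-8, n_eval=241)
    except Exception:
        return np.full(len(STATE_NAMES), np.nan)
    return np.trapezoid(traj.states, traj.times, axis=0)


def evaluate_outcomes(matrix: np.ndarray, parameters: tuple,
                      base: ModelParams, t_end: float = 24.0,
                      rtol: float = 1e-6, init=(0, 0, 0, 10, 0, 0)) -> np.ndarray:
    """Six scalar outcomes per design row: integral of each state over time.

    Rows where the solver fails come back as NaN and are excluded pairwise
    by the estimator.
    """
    out = np.empty((matrix.shape[0], len(STATE_NAMES)))
    for j, row in enumerate(matrix):
        out[j] = _integrated_outcomes(row, parameters, base, t_end, rtol, init)
    return out


def total_effect_indices(f_a: np.ndarray, f_c: dict | list,
                         parameters: tuple = SOBOL_PARAMETERS,
                         replicate: int = 0) -> SobolResult:
    """Jansen total-effect estimator for every (parameter, outcome) pair."""
    f_a = np.asarray(f_a, float)
    if isinstance(f_c, dict):
        f_c_list = [f_c[p] for p in parameters]
    else:
        f_c_list = list(f_c)
    n_params = len(f_c_list)
    n_out = f_a.shape[1]
    st = np.full((n_params, n_out), np.nan)
    n_failed = int(np.isnan(f_a).any(axis=1).sum())
    used = 0
    for i, fc in enumerate(f_c_list):
        fc = np.asarray(fc, float)
        if fc.shape != f_a.shape:
            raise ValueError("f(A) and f(C_i) must have identical shapes")
        ok = ~(np.isnan(f_a).any(axis=1) | np.isnan(fc).any(axis=1))
        used = max(used, int(ok.sum()))
        fa_ok, fc_ok = f_a[ok], fc[ok]
        var = fa_ok.var(axis=0)
        if np.any(var <= 0):
            raise ValueError("outcome variance is zero: indices undefined")
        st[i] = 0.5 * np.mean((fa_ok - fc_ok) ** 2, axis=0) / var
    var_all = f_a[~np.isnan(f_a).any(axis=1)].var(axis=0)
    if f_a.shape[0] and n_failed > 0.05 * f_a.shape[0]:
        import warnings
        warnings.warn(f"{n_failed}/{f_a.shape[0]} design rows failed to "
                      "integrate", stacklevel=2)
    return SobolResult(st=st, variance=var_all, parameters=tuple(parameters),
                       outcomes=STATE_NAMES, n=used, n_failed=n_failed,
                       replicate=replicate)


def run_replicates(base: ModelParams, bounds: dict | None = None,
                   n: int = 1000, n_replicates: int = 10, seed: int = 0,
                   t_end: float = 24.0, rtol: float = 1e-6,
                   log_scale: tuple = DEFAULT_LOG_SCALE) -> list:
    """Full radial-design Sobol runs, one SobolResult per replicate."""
    if bounds is None:
        bounds = default_bounds(base)
    results = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_replicates)
    for r, s in enumerate(child_seeds):
        design = generate_design(bounds, n=n, seed=int(s) % (2 ** 31),
                                 log_scale=log_scale)
        f_a = evaluate_outcomes(design.A, design.parameters, base, t_end, rtol)
        f_c = {}
        for i, p in enumerate(design.parameters):
            f_c[p] = evaluate_outcomes(design.radial_matrix(i),
                                       design.parameters, base, t_end, rtol)
        results.append(total_effect_indices(f_a, f_c, design.parameters,
                                            replicate=r))
    return results


# ---------------------------------------------------------------------------
# normalisation and ranking


def _z_normalize(st: np.ndarray) -> np.ndarray:
    """Mean-0, variance-1 normalisation across parameters, per outcome."""
    mu = st.mean(axis=0, keepdims=True)
    sd = st.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (st - mu) / sd


def steel_dwass_flags(groups: np.ndarray, alpha: float = 0.10) -> np.ndarray:
    """All-pairs Wilcoxon rank-sum with the Steel-Dwass adjustment.

    ``groups`` is (n_groups, n_obs).  A group is flagged when it is
    significantly greater than more than half of the other groups and not
    significantly smaller than any.
    """
    k, n = groups.shape
    if n < 2:
        raise ValueError("need at least two replicates per group")
    crit = studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    greater = np.zeros((k, k), bool)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pooled = np.concatenate([groups[i], groups[j]])
            ranks = rankdata(pooled)
            r_i = ranks[:n].sum()
            m = 2 * n
            mean = n * (m + 1) / 2.0
            # tie-corrected variance of the rank sum
            _, counts = np.unique(pooled, return_counts=True)
            tie = np.sum(counts ** 3 - counts)
            var = n * n / (m * (m - 1)) * ((m ** 3 - m - tie) / 12.0)
            if var <= 0:
                continue
            z = (r_i - mean) / np.sqrt(var)
            if z > crit:
                greater[i, j] = True
    flags = np.zeros(k, bool)
    for i in range(k):
        beats = greater[i].sum()
        beaten = greater[:, i].sum()
        flags[i] = beats > (k - 1) / 2 and beaten == 0
    return flags


def normalize_and_rank(results: list, alpha: float = 0.10) -> dict:
    """Average z-normalised indices over replicates and flag influential
    parameters per outcome.

    With a single replicate only the normalisation is performed.
    """
    if not results:
        raise ValueError("no Sobol results given")
    parameters = results[0].parameters
    outcomes = results[0].outcomes
    z = np.stack([_z_normalize(r.st) for r in results])   # (reps, 15, 6)
    mean_z = z.mean(axis=0)
    sem_z = (z.std(axis=0, ddof=1) / np.sqrt(len(results))
             if len(results) > 1 else np.zeros_like(mean_z))
    influential = {}
    if len(results) >= 2:
        for oi, out in enumerate(outcomes):
            flags = steel_dwass_flags(z[:, :, oi].T, alpha=alpha)
            influential[out] = tuple(p for p, f in zip(parameters, flags) if f)
    return {
        "parameters": parameters,
        "outcomes": outcomes,
        "mean_normalized": mean_z,
        "sem_normalized": sem_z,
        "influential": influential,
    }
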