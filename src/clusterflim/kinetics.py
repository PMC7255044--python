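"""Endocytosis kinetics: four-pool transport model and binding-curve fits.

Nanocarrier uptake is modeled as a closed first-order compartment chain

    membrane receptor-bound (cyan)  <->  membrane caveolae (yellow)
        -> cytoplasmic caveolar vesicles (yellow) -> lysosomes (red)

with time constants tau1 (capture into caveolae), tau_m1 (back reaction),
tau2 (internalization) and tau3 (lysosomal transport), all in minutes:

    dc/dt  = -c/tau1 + y_pm/tau_m1
    dy_pm/dt =  c/tau1 - y_pm/tau_m1 - y_pm/tau2
    dy_cp/dt =  y_pm/tau2 - y_cp/tau3
    dr/dt  =  y_cp/tau3

The system is linear, so trajectories are available exactly through the
matrix exponential; a numerical integrator is provided as a cross-check.
Imaging usually cannot separate the two yellow pools, so fitting targets
the observable triple (cyan, yellow_total, red) by default.

Also provided: a Michaelis-Menten-like saturation fit for concentration-
dependent uptake, I = I_max [S] / (K50 + [S]), and a modified Hill
displacement fit for competition of membrane binding,
A = A_max + (A_min - A_max) [S]^n / (K50^n + [S]^n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "KineticState",
    "KineticFit",
    "SaturationFit",
    "HillFit",
    "kinetic_rhs",
    "kinetic_matrix",
    "simulate_kinetics",
    "fit_kinetics",
    "fit_saturation",
    "fit_displacement_hill",
    "KineticFitError",
]

POOLS = ("c_pm", "y_pm", "y_cp", "r_cp")


class KineticFitError(RuntimeError):
    """Raised on degenerate or non-converging kinetic fits."""


@dataclass
class KineticState:
    """Fractions of material in the four pools (closed system, sum 1)."""

    c_pm: float  # receptor-bound at the plasma membrane (cyan)
    y_pm: float  # caveolae at the plasma membrane (yellow)
    y_cp: float  # caveolar vesicles in the cytoplasm (yellow)
    r_cp: float  # lysosomal compartments (red)

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12):
            raise ValueError("pool fractions must be non-negative")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("pool fractions must sum to 1 (closed system)")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_pm, self.y_pm, self.y_cp, self.r_cp], dtype=float)


@dataclass
class KineticFit:
    """Fitted time constants (minutes) of the transport chain."""

    tau1: float
    tau_m1: float
    tau2: float
    tau3: float
    stderr: dict
    y0: np.ndarray
    residual_norm: float
    converged: bool = True

    def taus(self) -> tuple:
        return (self.tau1, self.tau_m1, self.tau2, self.tau3)


@dataclass
class SaturationFit:
    """I = I_max [S] / (K50 + [S])."""

    I_max: float
    K50: float
    stderr: dict

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.I_max * conc / (self.K50 + conc)


@dataclass
class HillFit:
    """A = A_max + (A_min - A_max) [S]^n / (K50^n + [S]^n)."""

    A_max: float
    A_min: float
    K50: float
    n_hill: float
    stderr: dict

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        cn = conc ** self.n_hill
        return self.A_max + (self.A_min - self.A_max) * cn / (
            self.K50 ** self.n_hill + cn
        )


def _check_taus(taus) -> np.ndarray:
    taus = np.asarray(taus, dtype=float)
    if taus.shape != (4,):
        raise ValueError("need four time constants (tau1, tau_m1, tau2, tau3)")
    if np.any(taus <= 0):
        raise ValueError("all time constants must be positive")
    return taus


def kinetic_matrix(taus) -> np.ndarray:
    """System matrix A with dx/dt = A x for the four-pool chain."""
    t1, tm1, t2, t3 = _check_taus(taus)
    return np.array(
        [
            [-1 / t1, 1 / tm1, 0, 0],
            [1 / t1, -1 / tm1 - 1 / t2, 0, 0],
            [0, 1 / t2, -1 / t3, 0],
            [0, 0, 1 / t3, 0],
        ]
    )


def kinetic_rhs(state, taus) -> np.ndarray:
    """Per-pool time derivatives; columns of the system matrix sum to 0."""
    vec = state.as_array() if isinstance(state, KineticState) else np.asarray(state, float)
    return kinetic_matrix(taus) @ vec


def simulate_kinetics(
    taus, y0, times, method: str = "expm"
) -> np.ndarray:
    """Trajectory of the four pools at the requested times (minutes).

    ``method="expm"`` evaluates the exact matrix-exponential solution;
    ``method="ivp"`` integrates numerically (used as a cross-check).
    Returns an array of shape ``(len(times), 4)``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be sorted and non-negative")
    y0v = y0.as_array() if isinstance(y0, KineticState) else np.asarray(y0, float)
    A = kinetic_matrix(taus)
    if method == "expm":
        return np.stack([expm(A * t) @ y0v for t in times])
    if method == "ivp":
        t_span = (0.0, float(times[-1]) if times.size else 0.0)
        sol = solve_ivp(
            lambda t, y: A @ y, t_span, y0v, t_eval=times,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise KineticFitError(f"ODE integration failed: {sol.message}")
        return sol.y.T
    raise ValueError("method must be 'expm' or 'ivp'")


def observed_fractions(taus, y0, times) -> np.ndarray:
    """(cyan, yellow_total, red) trajectory — the imaging observables."""
    traj = simulate_kinetics(taus, y0, times)
    return np.column_stack([traj[:, 0], traj[:, 1] + traj[:, 2], traj[:, 3]])


_DEFAULT_Y0 = np.array([1.0, 0.0, 0.0, 0.0])


def fit_kinetics(
    times,
    observed,
    y0=None,
    four_channel: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> KineticFit:
    """Least-squares fit of the four time constants to cluster fractions.

    Parameters
    ----------
    times
        Observation times in minutes (>= 4 points for 4 free parameters).
    observed
        Array of shape ``(len(times), 3)`` with columns (cyan, yellow,
        red) fractions — observed yellow is the sum of the membrane and
        cytoplasmic caveolar pools — or ``(len(times), 4)`` with
        ``four_channel=True`` when membrane/cytoplasm segmentation
        resolves the two yellow pools.
    y0
        Initial state; default all material receptor-bound, (1, 0, 0, 0).

    Fitting runs multi-start over log-spaced time constants; standard
    errors come from the Jacobian at the optimum (weak identifiability of
    the back-reaction constant shows up as a large SE).
    """
    times = np.asarray(times, dtype=float)
    obs = np.asarray(observed, dtype=float)
    n_obs_cols = 4 if four_channel else 3
    if obs.shape != (times.size, n_obs_cols):
        raise ValueError(f"observed must have shape ({times.size}, {n_obs_cols})")
    if times.size < 4:
        raise ValueError("need at least 4 time points for 4 free parameters")
    if np.any(obs < -1e-9) or np.any(obs > 1 + 1e-9):
        raise ValueError("observed fractions must lie in [0, 1]")
    if np.allclose(obs, obs[0], atol=1e-12):
        raise KineticFitError("observations carry no dynamics; fit is unbounded")
    y0v = _DEFAULT_Y0 if y0 is None else (
        y0.as_array() if isinstance(y0, KineticState) else np.asarray(y0, float)
    )

    def residuals(log_taus):
        # clamp wild optimizer excursions to a physically sane range
        taus = np.exp(np.clip(log_taus, np.log(1e-3), np.log(1e6)))
        traj = simulate_kinetics(taus, y0v, times)
        if four_channel:
            model = traj
        else:
            model = np.column_stack(
                [traj[:, 0], traj[:, 1] + traj[:, 2], traj[:, 3]]
            )
        return (model - obs).ravel()

    rng = np.random.default_rng(seed)
    span = np.log([1.0, 300.0])  # minutes
    starts = [np.log([10.0, 30.0, 90.0, 100.0])]
    starts += [rng.uniform(span[0], span[1], size=4) for _ in range(n_starts - 1)]

    best = None
    for s in starts:
        try:
            res = least_squares(
                residuals, s, method="lm", max_nfev=2000, x_scale="jac"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise KineticFitError("kinetic fit failed for every start")

    taus = np.exp(best.x)
    # SEs via the Jacobian: cov = s^2 (J^T J)^-1 on the log scale
    m, p = best.jac.shape
    dof = max(m - p, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(4, np.inf)
    se = taus * se_log
    return KineticFit(
        tau1=float(taus[0]),
        tau_m1=float(taus[1]),
        tau2=float(taus[2]),
        tau3=float(taus[3]),
        stderr={"tau1": se[0], "tau_m1": se[1], "tau2": se[2], "tau3": se[3]},
        y0=y0v,
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )


def fit_saturation(concentrations, intensities) -> SaturationFit:
    """Michaelis-Menten-like fit of concentration-dependent uptake."""
    conc = np.asarray(concentrations, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if conc.size != inten.size or conc.size < 3:
        raise ValueError("need >= 3 matching (concentration, intensity) points")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if np.allclose(inten, inten[0]):
        raise KineticFitError("degenerate data: intensities are constant")

    def model(c, imax, k50):
        return imax * c / (k50 + c)

    imax0 = max(inten.max(), 1e-9)
    k0 = max(np.median(conc[conc > 0]) if np.any(conc > 0) else 1.0, 1e-9)
    popt, pcov = curve_fit(
        model, conc, inten, p0=[imax0, k0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return SaturationFit(
        I_max=float(popt[0]), K50=float(popt[1]),
        stderr={"I_max": float(se[0]), "K50": float(se[1])},
    )


def fit_displacement_hill(
    concentrations, areas, fix_n: float | None = None
) -> HillFit:
    """Modified Hill fit of displacement of membrane binding.

    ``fix_n`` pins the Hill coefficient (e.g. 1 for a hyperbolic
    displacement curve); otherwise it is a free parameter.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.size != area.size or conc.size < 4:
        raise ValueError("need >= 4 matching (concentration, area) points")
    if np.allclose(area, area[0]):
        raise KineticFitError("degenerate data: areas are constant")

    k0 = max(np.median(conc[conc > 0]) if np.any(conc > 0) else 1.0, 1e-9)
    if fix_n is None:
        def model(c, amax, amin, k50, n):
            cn = np.power(np.clip(c, 0, None), n)
            return amax + (amin - amax) * cn / (k50 ** n + cn)
        p0 = [area.max(), area.min(), k0, 1.0]
        bounds = ([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, np.inf, 20.0])
        names = ("A_max", "A_min", "K50", "n_hill")
    else:
        def model(c, amax, amin, k50):
            cn = np.power(np.clip(c, 0, None), fix_n)
            return amax + (amin - amax) * cn / (k50 ** fix_n + cn)
        p0 = [area.max(), area.min(), k0]
        bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])
        names = ("A_max", "A_min", "K50")
    popt, pcov = curve_fit(model, conc, area, p0=p0, bounds=bounds, maxfev=20000)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    stderr = {name: float(s) for name, s in zip(names, se)}
    n_hill = float(popt[3]) if fix_n is None else float(fix_n)
    if fix_n is not None:
        stderr["n_hill"] = 0.0
    return HillFit(
        A_max=float(popt[0]), A_min=float(popt[1]), K50=float(popt[2]),
        n_hill=n_hill, stderr=stderr,
    )
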