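"""Most probable transition paths by discretized least action.

Under weak state-independent noise (diffusion matrix D = I), the probability
of a fluctuation-driven transition between attractors is dominated by the
path minimizing the Freidlin–Wentzell-type action

    S[x] = (1/4) \\int_{0}^{T} || dx/dt - f(x) ||^2 dt ,

discretized on N equal subintervals with the trapezoidal drift average

    S = (dt/4) * sum_k sum_i | (x_i^{k+1} - x_i^k)/dt - (f_i^{k+1} + f_i^k)/2 |^2 .

Paths that follow the deterministic flow (downhill) cost ~0; uphill exits
pay the quasi-potential barrier.  Endpoints are hard-clamped and the
(N-1) x G interior coordinates are optimized by L-BFGS with the analytic
gradient, starting from the straight line between the endpoints.

The underlying stochastic-decomposition theory (an A-type SDE
dx = f dt + B * dW with B B^T = 2 eps D, the splitting of f into a
symmetric-dissipative part D, an antisymmetric circulation Q and a
potential U with steady state rho_ss ~ exp(-U/eps)) motivates this action
but is not computed here: only the D = I action above is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .equilibria import EquilibriumAtlas
from .network import GeneNetwork, HillParams, jacobian, rhs

__all__ = [
    "MPPConfig",
    "PathSolution",
    "action",
    "action_gradient",
    "minimize_action",
    "refinement_check",
    "lineage_mpp_suite",
    "ENDOCRINE_CHAIN",
    "DUCTAL_CHAIN",
    "ACINAR_CHAIN_1",
    "ACINAR_CHAIN_2",
]

# Consecutive maturation stages whose pairwise transitions the suite solves.
ENDOCRINE_CHAIN = ("MP", "TrP", "EEP", "LEP", "Ibeta")
ENDOCRINE_CHAIN_ALPHA = ("MP", "TrP", "EEP", "LEP", "Ialpha")
DUCTAL_CHAIN = ("MP", "TrP", "trunk", "ductal")
ACINAR_CHAIN_1 = ("MP", "TiP", "AciP", "acinar")
ACINAR_CHAIN_2 = ("MP", "TiP", "AciP2", "acinar")


@dataclass(frozen=True)
class MPPConfig:
    """Discretization and optimizer settings: path duration T split into N
    equal steps (dt = T/N); D is fixed to the identity."""

    T: float = 10.0
    N: int = 100
    gtol: float = 1e-8
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def dt(self) -> float:
        return self.T / self.N


@dataclass
class PathSolution:
    points: np.ndarray          # (N+1, G)
    action: float
    converged: bool
    config: MPPConfig
    start_label: str | None = None
    end_label: str | None = None
    n_iterations: int = 0
    initial_action: float = np.nan
    message: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.config.T, self.points.shape[0])


def _residuals(network: GeneNetwork, params: HillParams, path: np.ndarray,
               dt: float) -> tuple[np.ndarray, np.ndarray]:
    f = rhs(network, path, params, permissive=True)
    r = (path[1:] - path[:-1]) / dt - 0.5 * (f[1:] + f[:-1])
    return r, f


def action(network: GeneNetwork, path: np.ndarray,
           params: HillParams | None = None, dt: float | None = None,
           config: MPPConfig | None = None) -> float:
    """Discrete action of a path given as an (N+1, G) array."""
    params = params or HillParams()
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path must be a 2-D array with at least 2 points")
    if not np.all(np.isfinite(path)):
        raise ValueError("path contains non-finite values")
    if dt is None:
        cfg = config or MPPConfig(N=path.shape[0] - 1)
        dt = cfg.T / (path.shape[0] - 1)
    if dt <= 0:
        raise ValueError("dt must be positive")
    r, _ = _residuals(network, params, path, dt)
    return float(0.25 * dt * np.sum(r ** 2))


def action_gradient(network: GeneNetwork, path: np.ndarray, params: HillParams,
                    dt: float) -> np.ndarray:
    """Analytic gradient of the action w.r.t. INTERIOR points, (N-1, G).

    Each interior point x^m enters the residuals of segments m-1 and m, both
    directly through the finite difference and through f(x^m):
    grad_m = (r^{m-1} - r^m)/2 - (dt/4) J(x^m)^T (r^{m-1} + r^m).
    """
    r, _ = _residuals(network, params, path, dt)
    J = jacobian(network, path[1:-1], params, permissive=True)
    JT_sum = np.einsum("kji,kj->ki", J, r[:-1] + r[1:])
    return 0.5 * (r[:-1] - r[1:]) - 0.25 * dt * JT_sum


def _line_segment(x_start: np.ndarray, x_end: np.ndarray, N: int) -> np.ndarray:
    w = np.linspace(0.0, 1.0, N + 1)[:, None]
    return (1 - w) * x_start + w * x_end


def minimize_action(network: GeneNetwork, x_start: np.ndarray, x_end: np.ndarray,
                    params: HillParams | None = None,
                    config: MPPConfig | None = None,
                    atlas: EquilibriumAtlas | None = None,
                    initial_path: np.ndarray | None = None) -> PathSolution:
    """Minimize the discrete action between two states.

    Endpoints are clamped; the straight line is the initial path.  When an
    atlas is supplied, endpoints that are not close to any atlas equilibrium
    trigger a warning (the action principle concerns attractor-to-attractor
    transitions).
    """
    import warnings

    params = params or HillParams()
    cfg = config or MPPConfig()
    x_start = np.asarray(x_start, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    if np.allclose(x_start, x_end):
        raise ValueError("x_start and x_end coincide: nothing to transition")
    if atlas is not None:
        coords = atlas.coordinates()
        for name, pt in (("start", x_start), ("end", x_end)):
            if np.min(np.linalg.norm(coords - pt, axis=1)) > 1e-3:
                warnings.warn(f"{name} point is not an atlas equilibrium", stacklevel=2)
    G = x_start.size
    dt = cfg.dt
    path0 = _line_segment(x_start, x_end, cfg.N) if initial_path is None else np.asarray(initial_path, float)
    s0 = action(network, path0, params, dt=dt)

    def pack(interior: np.ndarray) -> np.ndarray:
        return np.vstack([x_start, interior.reshape(cfg.N - 1, G), x_end])

    def fun(z: np.ndarray) -> tuple[float, np.ndarray]:
        path = pack(z)
        r, _ = _residuals(network, params, path, dt)
        val = 0.25 * dt * np.sum(r ** 2)
        grad = action_gradient(network, path, params, dt)
        return float(val), grad.ravel()

    res = minimize(fun, path0[1:-1].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.max_iter, "gtol": cfg.gtol,
                            "ftol": 1e-14, "maxfun": 10 * cfg.max_iter})
    path = pack(res.x)
    s = action(network, path, params, dt=dt)
    if s > s0:  # optimizer failure: keep the initial path (never degrade)
        path, s = path0, s0
    return PathSolution(points=path, action=s,
                        converged=bool(res.success) and s <= s0 + 1e-12,
                        config=cfg, n_iterations=int(res.nit),
                        initial_action=s0, message=str(res.message))


def refinement_check(network: GeneNetwork, x_start: np.ndarray, x_end: np.ndarray,
                     params: HillParams | None = None,
                     base_config: MPPConfig | None = None,
                     refined_config: MPPConfig | None = None) -> dict:
    """Re-solve the same transition at a finer discretization and report the
    change in minimized action and the max pointwise path deviation (after
    interpolating both paths onto a common normalized time grid)."""
    base = base_config or MPPConfig(T=10.0, N=100)
    fine = refined_config or MPPConfig(T=20.0, N=200)
    if fine.N < base.N or fine.T < base.T:
        raise ValueError("refined config must not be coarser than the base config")
    sol_a = minimize_action(network, x_start, x_end, params, base)
    sol_b = minimize_action(network, x_start, x_end, params, fine)
    # time-rescaled comparison on the base grid
    ta = sol_a.times / base.T
    tb = sol_b.times / fine.T
    interp = np.stack([np.interp(ta, tb, sol_b.points[:, g])
                       for g in range(sol_b.points.shape[1])], axis=1)
    return {
        "action_base": sol_a.action,
        "action_refined": sol_b.action,
        "action_deviation": abs(sol_a.action - sol_b.action),
        "path_deviation": float(np.max(np.abs(sol_a.points - interp))),
        "solutions": (sol_a, sol_b),
    }


def lineage_mpp_suite(network: GeneNetwork, atlas: EquilibriumAtlas,
                      named_state_map: dict[str, str],
                      params: HillParams | None = None,
                      config: MPPConfig | None = None,
                      chains: dict[str, tuple[str, ...]] | None = None
                      ) -> dict[str, list[PathSolution]]:
    """Most probable paths along the maturation chains.

    ``named_state_map`` maps lineage-stage names (MP, TrP, EEP, LEP, Ibeta,
    Ialpha, TiP, AciP, AciP2, acinar, trunk, ductal) to atlas labels.  The
    default chains cover the endocrine beta path, the ductal path and the
    two alternative acinar paths.
    """
    params = params or atlas.params
    cfg = config or MPPConfig()
    if chains is None:
        chains = {"endocrine_beta": ENDOCRINE_CHAIN, "ductal": DUCTAL_CHAIN,
                  "acinar_via_AciP": ACINAR_CHAIN_1, "acinar_via_AciP2": ACINAR_CHAIN_2}
    needed = {stage for chain in chains.values() for stage in chain}
    missing = sorted(needed - set(named_state_map))
    if missing:
        raise KeyError(f"named_state_map is missing lineage stages: {missing}")
    out: dict[str, list[PathSolution]] = {}
    for chain_name, chain in chains.items():
        sols = []
        for a, b in zip(chain[:-1], chain[1:]):
            sa = atlas.get(named_state_map[a])
            sb = atlas.get(named_state_map[b])
            sol = minimize_action(network, sa.x, sb.x, params, cfg, atlas=atlas)
            sol.start_label, sol.end_label = a, b
            sols.append(sol)
        out[chain_name] = sols
    return out
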