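"""Topological adaptive landscape of the attractor atlas.

Each saddle (transition or hyper-transition state) is perturbed along its
unstable subspace — the span of Jacobian eigenvectors with positive real
part — with squared amplitude below delta1 (0.25e-8), the trajectory is
integrated forward, and the equilibrium it settles at (squared distance
below delta2 = 1e-6) becomes a landscape edge saddle -> target.  The
resulting directed graph is the topological landscape: stable states are
valleys, transition states the saddles between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .equilibria import EquilibriumAtlas, EquilibriumState
from .network import GeneNetwork, HillParams, rhs

__all__ = [
    "LandscapeConfig",
    "unstable_perturbations",
    "integrate_trajectory",
    "integrate_batch",
    "reachable_state",
    "build_landscape_graph",
    "write_graphml",
    "write_dot",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Perturbation and integration settings.

    delta1 and delta2 bound SQUARED Euclidean norms (inner products), so the
    default perturbation radius is sqrt(0.25e-8) = 5e-5.  The integrator is
    fixed-step RK4 by default; an explicit-Euler mode is available for
    fidelity comparisons.
    """

    delta1: float = 0.25e-8
    delta2: float = 1e-6
    dt: float = 0.01
    t_max: float = 500.0
    n_directions: int = 8
    seed: int = 0
    speed_tol: float = 1e-8
    method: str = "rk4"
    check_every: int = 10

    def __post_init__(self) -> None:
        if self.delta1 <= 0 or self.delta2 <= 0 or self.dt <= 0:
            raise ValueError("delta1, delta2 and dt must be positive")
        if self.method not in ("rk4", "euler"):
            raise ValueError("method must be 'rk4' or 'euler'")


def _unstable_basis(state: EquilibriumState, network: GeneNetwork,
                    params: HillParams, sign_tol: float = 1e-8) -> np.ndarray:
    from .network import jacobian

    J = jacobian(network, state.x, params, permissive=True)
    ev, V = np.linalg.eig(J)
    cols = np.flatnonzero(ev.real > sign_tol)
    # real representative per direction; complex pairs contribute Re and Im
    vecs: list[np.ndarray] = []
    for c in cols:
        v = V[:, c]
        cand = np.real(v) if np.max(np.abs(np.real(v))) > 1e-12 else np.imag(v)
        vecs.append(cand / np.linalg.norm(cand))
    basis = np.array(vecs)
    # orthonormalize (complex pairs give nearly parallel Re parts)
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep].T


def unstable_perturbations(state: EquilibriumState, network: GeneNetwork,
                           params: HillParams | None = None,
                           config: LandscapeConfig | None = None) -> np.ndarray:
    """Perturbed start points around a saddle, all within the delta1 ball.

    For a 1-dimensional unstable subspace the two axis directions +v, -v are
    returned; for k >= 2 dimensions, the 2k axis directions plus
    ``n_directions`` seeded random unit combinations inside the subspace.
    """
    params = params or HillParams()
    cfg = config or LandscapeConfig()
    if state.unstable_dim < 1:
        raise ValueError(f"state {state.label or ''} has no unstable subspace")
    basis = _unstable_basis(state, network, params)
    k = basis.shape[0]
    radius = 0.9 * np.sqrt(cfg.delta1)
    dirs = [v for b in basis for v in (b, -b)]
    if k >= 2:
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_directions):
            w = rng.normal(size=k)
            w /= np.linalg.norm(w)
            dirs.append(w @ basis)
    deltas = radius * np.array(dirs)
    assert np.all(np.einsum("ij,ij->i", deltas, deltas) < cfg.delta1)
    return state.x + deltas


def _step(network: GeneNetwork, x: np.ndarray, params: HillParams, dt: float,
          method: str) -> np.ndarray:
    if method == "euler":
        return x + dt * rhs(network, x, params, permissive=True)
    k1 = rhs(network, x, params, permissive=True)
    k2 = rhs(network, x + 0.5 * dt * k1, params, permissive=True)
    k3 = rhs(network, x + 0.5 * dt * k2, params, permissive=True)
    k4 = rhs(network, x + dt * k3, params, permissive=True)
    return x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_batch(network: GeneNetwork, x0: np.ndarray, params: HillParams,
                    config: LandscapeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of starts until each is at rest or t_max is hit.

    Returns (final states, final speeds).  States that stop early are frozen
    while the rest continue, so the batch cost tracks the slowest trajectory.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    B = x.shape[0]
    active = np.ones(B, dtype=bool)
    n_steps = int(np.ceil(config.t_max / config.dt))
    for step_i in range(n_steps):
        if not active.any():
            break
        x[active] = _step(network, x[active], params, config.dt, config.method)
        if not np.all(np.isfinite(x[active])):
            raise FloatingPointError("non-finite state during integration (step size too large?)")
        if step_i % config.check_every == 0:
            sp = np.max(np.abs(rhs(network, x[active], params, permissive=True)), axis=-1)
            idx = np.flatnonzero(active)[sp < config.speed_tol]
            active[idx] = False
    speeds = np.max(np.abs(rhs(network, x, params, permissive=True)), axis=-1)
    return x, speeds


def integrate_trajectory(network: GeneNetwork, x0: np.ndarray,
                         params: HillParams | None = None,
                         config: LandscapeConfig | None = None,
                         record_every: int = 10) -> np.ndarray:
    """Integrate one trajectory, returning recorded points (first = x0).

    Terminates when the speed ||rhs||_inf drops below speed_tol or t_max is
    reached; a start already at rest yields a single-point trajectory.
    """
    params = params or HillParams()
    cfg = config or LandscapeConfig()
    x = np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite initial state")
    points = [x.copy()]
    if np.max(np.abs(rhs(network, x, params, permissive=True))) < cfg.speed_tol:
        return np.array(points)
    n_steps = int(np.ceil(cfg.t_max / cfg.dt))
    for step_i in range(1, n_steps + 1):
        x = _step(network, x, params, cfg.dt, cfg.method)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite state during integration (step size too large?)")
        if step_i % record_every == 0 or step_i == n_steps:
            points.append(x.copy())
            if np.max(np.abs(rhs(network, x, params, permissive=True))) < cfg.speed_tol:
                break
    return np.array(points)


def reachable_state(trajectory: np.ndarray, atlas: EquilibriumAtlas,
                    config: LandscapeConfig | None = None,
                    exclude: str | None = None) -> str | None:
    """First atlas state whose squared distance to any trajectory point is
    below delta2; None when the trajectory never comes close to one.

    ``exclude`` skips a label (the perturbed saddle itself, which the first
    trajectory points necessarily hug).
    """
    cfg = config or LandscapeConfig()
    traj = np.atleast_2d(np.asarray(trajectory))
    if traj.size == 0:
        raise ValueError("empty trajectory")
    labels = [s.label for s in atlas.states]
    coords = atlas.coordinates()
    for pt in traj:
        d2 = np.sum((coords - pt) ** 2, axis=1)
        hits = np.flatnonzero(d2 < cfg.delta2)
        for j in hits[np.argsort(d2[hits])]:
            if labels[j] != exclude:
                return labels[j]
    return None


def build_landscape_graph(network: GeneNetwork, atlas: EquilibriumAtlas,
                          params: HillParams | None = None,
                          config: LandscapeConfig | None = None) -> nx.DiGraph:
    """Directed graph saddle -> reached equilibrium over all saddles.

    Node attributes: class, unstable_dim, per-gene coordinates.  Edge
    attribute ``directions`` lists the perturbation direction indices that
    produced the edge; hyper-transition sources are flagged so the main
    (transition-state-only) landscape can be filtered out.
    """
    params = params or atlas.params
    cfg = config or LandscapeConfig()
    saddles = atlas.saddles()
    if not saddles:
        raise ValueError("atlas contains no saddles")
    g = nx.DiGraph()
    for s in atlas.states:
        g.add_node(s.label, classification=s.classification, unstable_dim=s.unstable_dim,
                   **{gene: float(v) for gene, v in zip(atlas.genes, s.x)})
    coords = atlas.coordinates()
    labels = [s.label for s in atlas.states]
    for s in saddles:
        starts = unstable_perturbations(s, network, params, cfg)
        finals, speeds = integrate_batch(network, starts, params, cfg)
        for d_idx, (xf, sp) in enumerate(zip(finals, speeds)):
            d2 = np.sum((coords - xf) ** 2, axis=1)
            order = np.argsort(d2)
            target = None
            for j in order:
                if d2[j] < cfg.delta2 and labels[j] != s.label:
                    target = labels[j]
                    break
            if target is None:
                continue
            if g.has_edge(s.label, target):
                g.edges[s.label, target]["directions"].append(d_idx)
            else:
                g.add_edge(s.label, target, directions=[d_idx],
                           from_hyper=s.classification == "hyper_transition")
    return g


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        data["directions"] = ",".join(map(str, data["directions"]))
    nx.write_graphml(g, path)


def write_dot(graph: nx.DiGraph, path: str | Path) -> None:
    lines = ["digraph landscape {"]
    for node, data in graph.nodes(data=True):
        shape = {"stable": "circle", "transition": "diamond"}.get(
            data.get("classification", ""), "box")
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v in graph.edges:
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
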