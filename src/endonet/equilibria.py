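"""Equilibrium atlas of the Hill ODE: multistart Newton search, eigenvalue
classification, robustness sweep over the Hill coefficient, and a limit-cycle
scan.

An equilibrium x* satisfies rhs(x*) = 0.  Its class follows the real parts of
the Jacobian eigenvalues: all negative -> stable (an attractor, interpreted as
a cell type); exactly one positive -> transition state (a saddle mediating a
spontaneous switch between two attractors); two or more positive ->
hyper-transition state.  Any eigenvalue real part within the sign tolerance of
zero marks the state degenerate and it is reported as such rather than
silently classified.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import GeneNetwork, HillParams, jacobian, rhs

__all__ = [
    "SearchConfig",
    "EquilibriumState",
    "EquilibriumAtlas",
    "classify_equilibrium",
    "find_equilibria",
    "robustness_sweep",
    "limit_cycle_scan",
]

CLASS_ORDER = {"stable": 0, "transition": 1, "hyper_transition": 2, "degenerate": 3}
_CLASS_PREFIX = {"stable": "S", "transition": "T", "hyper_transition": "H", "degenerate": "D"}


@dataclass(frozen=True)
class SearchConfig:
    """Multistart Newton search configuration.

    grid_values spans every on/half/off combination per gene, giving
    3^G deterministic starts for a G-gene network; random starts (seeded)
    can be added on top.  Roots outside the slightly inflated unit box are
    numerical artifacts (the box [0,1]^G is forward-invariant) and dropped.
    """

    grid_values: tuple[float, ...] = (0.0, 0.5, 1.0)
    n_random_starts: int = 0
    seed: int = 0
    root_tol: float = 1e-10
    max_iter: int = 200
    max_halvings: int = 50
    dedup_tol: float = 1e-6
    sign_tol: float = 1e-8
    box_margin: float = 0.05


@dataclass
class EquilibriumState:
    """A verified root of the ODE with its local linearization."""

    x: np.ndarray
    residual_norm: float
    eigenvalues: np.ndarray
    classification: str
    unstable_dim: int
    label: str | None = None

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        return (self.x >= threshold).astype(int)

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class EquilibriumAtlas:
    states: list[EquilibriumState]
    params: HillParams
    config: SearchConfig
    genes: list[str]
    n_starts: int = 0
    n_converged: int = 0

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def by_class(self, classification: str) -> list[EquilibriumState]:
        return [s for s in self.states if s.classification == classification]

    @property
    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in CLASS_ORDER}
        for s in self.states:
            c[s.classification] += 1
        return c

    def get(self, label: str) -> EquilibriumState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"no atlas state labeled {label!r}")

    def saddles(self) -> list[EquilibriumState]:
        return [s for s in self.states if s.unstable_dim >= 1]

    def coordinates(self) -> np.ndarray:
        return np.array([s.x for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            row = {"label": s.label, "class": s.classification,
                   "unstable_dim": s.unstable_dim, "max_re_eig": s.max_real_eigenvalue,
                   "residual_norm": s.residual_norm}
            row.update({g: v for g, v in zip(self.genes, s.x)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": self.genes,
            "hill_n": self.params.n,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "counts": self.counts,
            "states": [
                {
                    "label": s.label,
                    "class": s.classification,
                    "unstable_dim": s.unstable_dim,
                    "x": [float(v) for v in s.x],
                    "residual_norm": s.residual_norm,
                    "eigenvalues_re": [float(v) for v in s.eigenvalues.real],
                    "eigenvalues_im": [float(v) for v in s.eigenvalues.imag],
                }
                for s in self.states
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_equilibrium(eigenvalues: Sequence[complex], sign_tol: float = 1e-8
                         ) -> tuple[str, int]:
    """Classify an equilibrium by its Jacobian spectrum.

    Returns (class, unstable_dim) with class in {stable, transition,
    hyper_transition, degenerate}.
    """
    ev = np.asarray(eigenvalues)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    re = ev.real
    if np.any(np.abs(re) <= sign_tol):
        return "degenerate", int(np.sum(re > sign_tol))
    unstable = int(np.sum(re > sign_tol))
    if unstable == 0:
        return "stable", 0
    if unstable == 1:
        return "transition", 1
    return "hyper_transition", unstable


def _newton_batch(network: GeneNetwork, params: HillParams, starts: np.ndarray,
                  cfg: SearchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton from every start simultaneously.

    Returns (roots, converged_mask).  Non-converged starts are reported so the
    caller can log them; failure of individual starts is expected and benign.
    """
    x = starts.astype(float).copy()
    B = x.shape[0]
    converged = np.zeros(B, dtype=bool)
    active = np.ones(B, dtype=bool)
    for _ in range(cfg.max_iter):
        if not active.any():
            break
        xa = x[active]
        F = rhs(network, xa, params, permissive=True)
        fn = np.max(np.abs(F), axis=-1)
        done = fn < cfg.root_tol
        if done.any():
            idx = np.flatnonzero(active)[done]
            converged[idx] = True
            active[idx] = False
            keep = ~done
            xa, F, fn = xa[keep], F[keep], fn[keep]
            if xa.shape[0] == 0:
                continue
        J = jacobian(network, xa, params, permissive=True)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("bij,bj->bi", np.linalg.pinv(J), F)
        # damping: halve the step until the residual decreases
        alpha = np.ones(xa.shape[0])
        trial = xa - step
        for _h in range(cfg.max_halvings):
            Ft = rhs(network, trial, params, permissive=True)
            ok = np.max(np.abs(Ft), axis=-1) <= fn
            if ok.all():
                break
            alpha[~ok] *= 0.5
            trial = xa - alpha[:, None] * step
        x[active] = trial
    # last convergence check
    if active.any():
        F = rhs(network, x[active], params, permissive=True)
        conv = np.max(np.abs(F), axis=-1) < cfg.root_tol
        converged[np.flatnonzero(active)[conv]] = True
    return x, converged


def _grid_starts(n_genes: int, cfg: SearchConfig) -> np.ndarray:
    grid = np.array(list(itertools.product(cfg.grid_values, repeat=n_genes)))
    if cfg.n_random_starts:
        rng = np.random.default_rng(cfg.seed)
        grid = np.vstack([grid, rng.uniform(0.0, 1.0, size=(cfg.n_random_starts, n_genes))])
    return grid


def find_equilibria(network: GeneNetwork, params: HillParams | None = None,
                    config: SearchConfig | None = None) -> EquilibriumAtlas:
    """Find, deduplicate and classify all equilibria reached from the
    multistart grid.

    States are sorted by class (stable, transition, hyper-transition,
    degenerate) then lexicographically by coordinates, and labeled S1..,
    T1.., H1.. in that order so labels are stable across runs.
    """
    params = params or HillParams()
    cfg = config or SearchConfig()
    if not cfg.grid_values:
        raise ValueError("search grid is empty")
    if cfg.root_tol <= 0 or cfg.dedup_tol <= 0:
        raise ValueError("tolerances must be positive")
    starts = _grid_starts(network.n_genes, cfg)
    roots, conv = _newton_batch(network, params, starts, cfg)
    roots = roots[conv]
    # discard artifacts outside the inflated unit box
    lo, hi = -cfg.box_margin, 1.0 + cfg.box_margin
    inside = np.all((roots >= lo) & (roots <= hi), axis=1)
    roots = roots[inside]
    # dedup
    unique: list[np.ndarray] = []
    for r in roots:
        if not unique or np.min(np.linalg.norm(np.array(unique) - r, axis=1)) > cfg.dedup_tol:
            unique.append(r)
    if not unique:
        raise RuntimeError("no equilibria found (the origin always exists: this is a bug)")
    states = []
    for r in unique:
        res = float(np.max(np.abs(rhs(network, r, params, permissive=True))))
        ev = np.linalg.eigvals(jacobian(network, r, params, permissive=True))
        classification, udim = classify_equilibrium(ev, cfg.sign_tol)
        states.append(EquilibriumState(x=r, residual_norm=res, eigenvalues=ev,
                                       classification=classification, unstable_dim=udim))
    states.sort(key=lambda s: (CLASS_ORDER[s.classification], tuple(np.round(s.x, 9))))
    counters = {k: 0 for k in CLASS_ORDER}
    for s in states:
        counters[s.classification] += 1
        s.label = f"{_CLASS_PREFIX[s.classification]}{counters[s.classification]}"
    return EquilibriumAtlas(states=states, params=params, config=cfg,
                            genes=list(network.genes), n_starts=len(starts),
                            n_converged=int(conv.sum()))


def robustness_sweep(network: GeneNetwork, n_values: Sequence[int],
                     config: SearchConfig | None = None,
                     threshold: float = 0.5) -> dict:
    """Atlases for several Hill coefficients plus a cross-n matching report.

    Stable states of consecutive n are matched by nearest neighbour; a match
    "preserves" a state when the binarized on/off patterns agree.
    """
    if any(n < 2 for n in n_values):
        raise ValueError("all Hill coefficients must be >= 2")
    atlases = {n: find_equilibria(network, HillParams(n=n), config) for n in n_values}
    matches = []
    n_values = list(n_values)
    for n_a, n_b in zip(n_values[:-1], n_values[1:]):
        a, b = atlases[n_a], atlases[n_b]
        xb = np.array([s.x for s in b.by_class("stable")])
        for s in a.by_class("stable"):
            d = np.linalg.norm(xb - s.x, axis=1)
            j = int(np.argmin(d))
            partner = b.by_class("stable")[j]
            preserved = bool(np.array_equal(s.binarize(threshold), partner.binarize(threshold)))
            matches.append({"n_from": n_a, "n_to": n_b, "label_from": s.label,
                            "label_to": partner.label, "distance": float(d[j]),
                            "preserved": preserved})
    report = pd.DataFrame(matches) if matches else pd.DataFrame(
        columns=["n_from", "n_to", "label_from", "label_to", "distance", "preserved"])
    all_preserved = bool(report["preserved"].all()) if len(report) else True
    return {"atlases": atlases, "matches": report, "all_stable_preserved": all_preserved}


def limit_cycle_scan(network: GeneNetwork, params: HillParams | None = None,
                     atlas: EquilibriumAtlas | None = None, n_starts: int = 200,
                     t_max: float = 500.0, dt: float = 0.01, seed: int = 0,
                     speed_tol: float = 1e-8, delta2: float = 1e-6) -> dict:
    """Integrate seeded random initial states and test whether every
    trajectory settles at a known equilibrium.

    A non-empty ``non_convergent`` list would flag a possible limit cycle or
    an insufficient atlas.
    """
    from .landscape import LandscapeConfig, integrate_batch

    if t_max <= 0:
        raise ValueError("t_max must be positive")
    params = params or HillParams()
    if atlas is None:
        atlas = find_equilibria(network, params)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 1.0, size=(n_starts, network.n_genes))
    cfg = LandscapeConfig(dt=dt, t_max=t_max, speed_tol=speed_tol, delta2=delta2)
    finals, speeds = integrate_batch(network, starts, params, cfg)
    coords = atlas.coordinates()
    non_convergent = []
    reached = []
    for i, (xf, sp) in enumerate(zip(finals, speeds)):
        d2 = np.sum((coords - xf) ** 2, axis=1)
        j = int(np.argmin(d2))
        if sp < speed_tol and d2[j] < delta2:
            reached.append(atlas.states[j].label)
        else:
            non_convergent.append(i)
    return {"n_starts": n_starts, "n_converged": n_starts - len(non_convergent),
            "non_convergent": non_convergent, "reached_labels": reached}
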