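"""Synchronous Boolean model with dominant inhibition.

Each gene is on (1) or off (0); the next state is
``x_i(t+1) = 1 iff sum_j w_ij x_j(t) > 0`` with weights +1 for activators
and -100 for inhibitors, so a single active inhibitor overrides any number
of activators.  The model is parameter-free apart from that convention and
serves as a cross-check on the ODE attractors: every stable ODE state,
binarized at 0.5, should reappear as a Boolean fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import EquilibriumAtlas
from .network import GeneNetwork

__all__ = [
    "BooleanModel",
    "boolean_weights",
    "boolean_step",
    "enumerate_fixed_points",
    "compare_ode_boolean",
]

INHIBITION_WEIGHT = -100

_ENUM_GUARD = 24


@dataclass(frozen=True)
class BooleanModel:
    genes: tuple[str, ...]
    W: np.ndarray  # target x regulator, entries in {0, +1, inhibition weight}

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def boolean_weights(network: GeneNetwork, inhibition_weight: int = INHIBITION_WEIGHT
                    ) -> BooleanModel:
    """Build the weight matrix W (rows = targets, columns = regulators)."""
    if inhibition_weight != INHIBITION_WEIGHT:
        warnings.warn(
            f"inhibition weight {inhibition_weight} departs from the dominant-"
            f"inhibition convention ({INHIBITION_WEIGHT}); inhibition may no "
            "longer override activation", stacklevel=2)
    W = (network.activator_mask().astype(int)
         + inhibition_weight * network.inhibitor_mask().astype(int))
    return BooleanModel(genes=tuple(network.genes), W=W)


def boolean_step(model: BooleanModel, state: np.ndarray) -> np.ndarray:
    """Synchronous update: bit i flips on iff its weighted input sum is > 0."""
    s = np.asarray(state)
    if s.shape[-1] != model.n_genes:
        raise ValueError("state length does not match gene count")
    return (s @ model.W.T > 0).astype(int)


def enumerate_fixed_points(model: BooleanModel) -> tuple[np.ndarray, int]:
    """Exhaustively enumerate all 2^G states and return the fixed points.

    Returns (fixed_points sorted lexicographically, number of candidate
    states visited).  Guarded at 24 genes; beyond that exhaustive
    enumeration is impractical and a sampling strategy should be used
    instead.
    """
    G = model.n_genes
    if G > _ENUM_GUARD:
        raise ValueError(f"{G} genes exceeds the exhaustive-enumeration guard "
                         f"({_ENUM_GUARD}); use sampled exploration instead")
    n_states = 2 ** G
    bits = ((np.arange(n_states)[:, None] >> np.arange(G)[::-1]) & 1).astype(int)
    nxt = boolean_step(model, bits)
    fixed = bits[np.all(nxt == bits, axis=1)]
    order = np.lexsort(fixed.T[::-1])
    return fixed[order], n_states


def compare_ode_boolean(atlas: EquilibriumAtlas, fixed_points: np.ndarray,
                        threshold: float = 0.5) -> pd.DataFrame:
    """Per-state consistency of binarized ODE attractors with Boolean fixed
    points, plus Boolean fixed points lacking an ODE counterpart."""
    if len(atlas) == 0:
        raise ValueError("empty atlas")
    fp_set = {tuple(fp) for fp in np.atleast_2d(fixed_points)}
    rows = []
    seen = set()
    for s in atlas.by_class("stable"):
        pat = tuple(s.binarize(threshold))
        seen.add(pat)
        rows.append({"label": s.label, "pattern": "".join(map(str, pat)),
                     "source": "ode_stable", "is_boolean_fixed_point": pat in fp_set})
    for fp in sorted(fp_set):
        if fp not in seen:
            rows.append({"label": None, "pattern": "".join(map(str, fp)),
                         "source": "boolean_only", "is_boolean_fixed_point": True})
    return pd.DataFrame(rows)
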