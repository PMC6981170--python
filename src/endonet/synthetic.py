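"""Synthetic single-cell expression matrices and toy dynamical fixtures.

The generator emulates droplet scRNA-seq counts for cells sitting at the
predicted binary states: per cell, each core gene draws a negative-binomial
count with mean ``on_mean`` (default 50) or ``off_mean`` (default 0.5)
according to the cell's state pattern, on-genes additionally drop to zero
with probability ``dropout_prob`` (default 0.1), and ``n_background_genes``
filler genes draw from the off distribution so gene-resolution code paths
are exercised.  It makes no attempt to match real datasets' library-size,
batch or gene-count structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GeneNetwork, pancreas_network
from .state_matching import StateCatalog

__all__ = ["GeneratorSpec", "generate_cells", "generate_toy_networks", "ToyNetwork"]


@dataclass(frozen=True)
class GeneratorSpec:
    catalog: StateCatalog
    cells_per_state: dict[str, int] | int = 200
    on_mean: float = 50.0
    off_mean: float = 0.5
    dispersion: float = 2.0
    dropout_prob: float = 0.1
    n_background_genes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.on_mean > 0 and self.off_mean > 0):
            raise ValueError("negative-binomial means must be positive")
        if self.on_mean <= self.off_mean:
            raise ValueError("on_mean must exceed off_mean")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be a probability")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size) -> np.ndarray:
    # numpy parameterization: n = dispersion, p = n / (n + mean)
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mean), size=size)


def generate_cells(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a genes x cells count matrix plus the true state label per cell.

    Reproducible: the same spec (including seed) yields bit-identical output.
    """
    catalog = spec.catalog
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    if isinstance(spec.cells_per_state, int):
        per_state = {lab: spec.cells_per_state for lab in catalog.labels}
    else:
        unknown = sorted(set(spec.cells_per_state) - set(catalog.labels))
        if unknown:
            raise KeyError(f"cells_per_state references unknown state labels: {unknown}")
        per_state = dict(spec.cells_per_state)
    rng = np.random.default_rng(spec.seed)
    core_genes = list(catalog.genes)
    bg_genes = [f"BG{i + 1}" for i in range(spec.n_background_genes)]
    blocks, labels = [], []
    for lab, pattern in zip(catalog.labels, catalog.patterns):
        n_cells = per_state.get(lab, 0)
        if n_cells == 0:
            continue
        on = pattern.astype(bool)
        counts = np.empty((len(core_genes), n_cells), dtype=int)
        counts[on] = _nb_counts(rng, spec.on_mean, spec.dispersion, (int(on.sum()), n_cells))
        counts[~on] = _nb_counts(rng, spec.off_mean, spec.dispersion, (int((~on).sum()), n_cells))
        drop = rng.random((len(core_genes), n_cells)) < spec.dropout_prob
        counts = np.where(drop & on[:, None], 0, counts)
        bg = _nb_counts(rng, spec.off_mean, spec.dispersion, (spec.n_background_genes, n_cells))
        blocks.append(np.vstack([counts, bg]))
        labels.extend([lab] * n_cells)
    matrix = pd.DataFrame(np.hstack(blocks), index=core_genes + bg_genes,
                          columns=[f"cell{i + 1}" for i in range(len(labels))])
    return matrix, pd.Series(labels, index=matrix.columns, name="true_state")


@dataclass(frozen=True)
class ToyNetwork:
    """A fixture network with its documented dynamical expectations."""

    name: str
    network: GeneNetwork
    expected: dict


def _self_activator_roots(n: int) -> list[float]:
    """Bisection on the closed-form fixed-point condition of the 1-gene
    self-activator: nonzero roots solve (2x)^n (1 - x) = x / x = ... i.e.
    2^n x^(n-1) (1 - x) = 1; 0 is always a root."""
    from scipy.optimize import brentq

    g = lambda x: 2 ** n * x ** (n - 1) * (1.0 - x) - 1.0
    roots = [0.0, brentq(g, 1e-6, 0.75), brentq(g, 0.75, 1.0 - 1e-12)]
    return roots


def generate_toy_networks() -> dict[str, ToyNetwork]:
    """Fixture set: 1-gene self-activator, 2-gene toggle (self-activation +
    mutual inhibition), and the canonical and variant pancreas networks."""
    from .network import RegulatoryEdge

    one = GeneNetwork([RegulatoryEdge("A", "A", 1)])
    toggle = GeneNetwork([
        RegulatoryEdge("A", "A", 1), RegulatoryEdge("B", "B", 1),
        RegulatoryEdge("A", "B", -1), RegulatoryEdge("B", "A", -1),
    ])
    out = {
        "self_activator": ToyNetwork(
            "self_activator", one,
            {"roots_by_n": {n: _self_activator_roots(n) for n in (4, 5, 6, 7)},
             "boolean_fixed_points": [(0,), (1,)]}),
        "toggle": ToyNetwork(
            "toggle", toggle,
            # origin + the two mirror-image winner-take-all attractors; the
            # saddles sit on the axes at (0, 1/2) and (1/2, 0): with the
            # shared-Hill inhibition there is no equilibrium on the diagonal
            # other than the origin (P(1-P) = x has no root in (0, 1]).
            {"n_stable": 3,
             "saddles": [(0.0, 0.5), (0.5, 0.0)],
             "boolean_fixed_points": [(0, 0), (0, 1), (1, 0)]}),
        "pancreas": ToyNetwork(
            "pancreas", pancreas_network(),
            {"n_activations": 12, "n_inhibitions": 10}),
        "pancreas_ptf1a_pdx1": ToyNetwork(
            "pancreas_ptf1a_pdx1", pancreas_network("ptf1a_pdx1"),
            {"n_activations": 13, "n_inhibitions": 10}),
        "pancreas_nkx61_arx": ToyNetwork(
            "pancreas_nkx61_arx", pancreas_network("nkx61_arx"),
            {"n_activations": 12, "n_inhibitions": 11}),
    }
    return out
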