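"""Signed regulatory networks and the coarse-grained Hill-ODE vector field.

The model treats each transcription factor's normalized concentration
``x_i in [0, 1]`` and couples the factors through a shared-Hill production
term with dominant multiplicative inhibition:

    dx_i/dt = [ 2^n * A_i / (1 + 2^n * A_i) ] * [ 1 / (1 + 2^n * R_i) ] - x_i

where ``A_i = sum_{u in activators(i)} x_u^n`` and
``R_i = sum_{r in inhibitors(i)} x_r^n``.  The normalization absorbs the
production and decay rates (eta = tau = 1) and fixes the dissociation
constant at K = 0.5, so 2^n = 1/K^n.  A gene with no activators can only
decay; a gene with no inhibitors has inhibition factor 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegulatoryEdge",
    "GeneNetwork",
    "HillParams",
    "load_network",
    "pancreas_network",
    "rhs",
    "jacobian",
]

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activation": 1, "activate": 1, "act": 1,
    "-1": -1, "-": -1, "inhibition": -1, "inhibit": -1, "inh": -1,
}


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed regulation: ``source`` activates (+1) or inhibits (-1) ``target``."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if not self.source or not self.target:
            raise ValueError("edge source and target must be non-empty gene names")


class GeneNetwork:
    """Ordered gene list with per-gene activator and inhibitor sets.

    Self-edges are allowed (the pancreas network has self-activation loops
    on PDX1, PTF1A, NKX6.1, SOX9 and NGN3).  Gene order is significant: it
    fixes the coordinate order of state vectors, Jacobians and catalogs.
    """

    def __init__(self, edges: Iterable[RegulatoryEdge], genes: Sequence[str] | None = None):
        edges = list(edges)
        if not edges:
            raise ValueError("no edges")
        seen: set[tuple[str, str, int]] = set()
        for e in edges:
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise ValueError(f"duplicate edge {e.source} -> {e.target} (sign {e.sign:+d})")
            seen.add(key)
        if genes is None:
            order: list[str] = []
            for e in edges:
                for g in (e.source, e.target):
                    if g not in order:
                        order.append(g)
            genes = order
        else:
            genes = list(genes)
            known = set(genes)
            for e in edges:
                if e.source not in known or e.target not in known:
                    raise ValueError(f"edge {e.source}->{e.target} references a gene missing from the declared gene list")
        self.genes: list[str] = list(genes)
        self.edges: list[RegulatoryEdge] = edges
        self.activators: dict[str, set[str]] = {g: set() for g in self.genes}
        self.inhibitors: dict[str, set[str]] = {g: set() for g in self.genes}
        for e in edges:
            bucket = self.activators if e.sign == 1 else self.inhibitors
            bucket[e.target].add(e.source)
        idx = {g: i for i, g in enumerate(self.genes)}
        G = len(self.genes)
        # boolean regulator masks, row = target, column = regulator
        self._act_mask = np.zeros((G, G), dtype=bool)
        self._inh_mask = np.zeros((G, G), dtype=bool)
        for e in edges:
            m = self._act_mask if e.sign == 1 else self._inh_mask
            m[idx[e.target], idx[e.source]] = True

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_activations(self) -> int:
        return int(self._act_mask.sum())

    @property
    def n_inhibitions(self) -> int:
        return int(self._inh_mask.sum())

    def index(self, gene: str) -> int:
        return self.genes.index(gene)

    def activator_mask(self) -> np.ndarray:
        return self._act_mask.copy()

    def inhibitor_mask(self) -> np.ndarray:
        return self._inh_mask.copy()

    def with_edge(self, source: str, target: str, sign: int) -> "GeneNetwork":
        """Return a new network with one extra regulation appended."""
        return GeneNetwork(self.edges + [RegulatoryEdge(source, target, sign)], genes=self.genes)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "activators": {g: sorted(self.activators[g]) for g in self.genes},
            "inhibitors": {g: sorted(self.inhibitors[g]) for g in self.genes},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneNetwork":
        edges = []
        for g in payload["genes"]:
            for src in payload["activators"].get(g, []):
                edges.append(RegulatoryEdge(src, g, 1))
            for src in payload["inhibitors"].get(g, []):
                edges.append(RegulatoryEdge(src, g, -1))
        return cls(edges, genes=payload["genes"])

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "GeneNetwork":
        s = str(text_or_path)
        if not s.lstrip().startswith("{"):
            s = Path(text_or_path).read_text()
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:
        return (f"GeneNetwork({self.n_genes} genes, {self.n_activations} activations, "
                f"{self.n_inhibitions} inhibitions)")


@dataclass(frozen=True)
class HillParams:
    """Hill kinetics parameters.

    n is the Hill coefficient (steepness; the network needs n >= 4 for the
    production term to span most of [0, 1]).  K, eta and tau are exposed but
    default-locked to the normalization the simplified ODE assumes
    (K = 0.5, eta = tau = 1); the fast evaluation path requires them.
    """

    n: int = 4
    K: float = 0.5
    eta: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("Hill coefficient n must be >= 2")
        if not (self.K > 0 and self.eta > 0 and self.tau > 0):
            raise ValueError("K, eta, tau must be positive")

    @property
    def gain(self) -> float:
        """The prefactor multiplying summed x^n: 1/K^n (= 2^n at K = 0.5)."""
        return self.K ** (-self.n)


def load_network(path_or_table: str | Path | pd.DataFrame,
                 genes: Sequence[str] | None = None) -> GeneNetwork:
    """Load a signed edge table (TSV columns: source, target, sign).

    Sign tokens ``+1/-1/activation/inhibition`` are accepted.  Genes are
    ordered by first appearance unless an explicit order is declared.
    """
    if isinstance(path_or_table, pd.DataFrame):
        df = path_or_table
    else:
        df = pd.read_csv(path_or_table, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise ValueError("no edges")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("source", "target", "sign") if c not in cols]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    edges = []
    for row_i, row in df.iterrows():
        token = str(row[cols["sign"]]).strip().lower()
        if token not in _SIGN_TOKENS:
            raise ValueError(f"unknown sign token {token!r} in row {row_i}")
        edges.append(RegulatoryEdge(str(row[cols["source"]]).strip(),
                                    str(row[cols["target"]]).strip(),
                                    _SIGN_TOKENS[token]))
    return GeneNetwork(edges, genes=genes)


_PANCREAS_GENES = ["PDX1", "PTF1A", "NKX6.1", "SOX9", "HES1", "NGN3", "ARX", "PAX4"]


def pancreas_network(variant: str | None = None) -> GeneNetwork:
    """The canonical 8-TF pancreas core network (12 activations, 10 inhibitions).

    ``variant="ptf1a_pdx1"`` adds the PTF1A -> PDX1 activation;
    ``variant="nkx61_arx"`` adds the NKX6.1 -| ARX inhibition.  Both extra
    regulations are reported in the literature but excluded from the
    canonical model for lacking uniform effect across developmental stages.
    """
    names = {None: "pancreas_core.tsv",
             "ptf1a_pdx1": "pancreas_variant_ptf1a_pdx1.tsv",
             "nkx61_arx": "pancreas_variant_nkx61_arx.tsv"}
    if variant not in names:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(k for k in names if k)}")
    with resources.as_file(resources.files("endonet.data") / names[variant]) as p:
        return load_network(p, genes=_PANCREAS_GENES)


# -- vector field ------------------------------------------------------------

def _validate_state(x: np.ndarray, n_genes: int, permissive: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != n_genes:
        raise ValueError(f"state has {x.shape[-1]} components, network has {n_genes} genes")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite values")
    if not permissive and np.any(x < 0):
        raise ValueError("negative concentrations are outside the model domain "
                         "(pass permissive=True to evaluate anyway)")
    return x


def _hill_factors(network: GeneNetwork, x: np.ndarray, params: HillParams):
    """Production factor P and inhibition factor Q per gene (batched)."""
    c = params.gain
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xn = x ** params.n                 # (..., G)
        A = xn @ network._act_mask.T       # summed activator x^n per target
        R = xn @ network._inh_mask.T
        P = c * A / (1.0 + c * A)
        Q = 1.0 / (1.0 + c * R)
        # far outside the unit box (wild Newton trial steps) the fractions
        # saturate; the limits are the correct values
        P = np.where(np.isnan(P) & (A > 1), 1.0, P)
        Q = np.where(np.isnan(Q) & (R > 1), 0.0, Q)
    return P, Q, xn


def rhs(network: GeneNetwork, x: np.ndarray, params: HillParams | None = None,
        *, permissive: bool = False) -> np.ndarray:
    """Velocity dx/dt of the Hill ODE.  Accepts a single state or a batch
    of states stacked along the leading axes."""
    params = params or HillParams()
    x = _validate_state(x, network.n_genes, permissive)
    P, Q, _ = _hill_factors(network, x, params)
    with np.errstate(invalid="ignore"):
        return params.eta * P * Q - params.tau * x


def jacobian(network: GeneNetwork, x: np.ndarray, params: HillParams | None = None,
             *, permissive: bool = False) -> np.ndarray:
    """Analytic Jacobian d(rhs)/dx, shape (..., G, G)."""
    params = params or HillParams()
    x = _validate_state(x, network.n_genes, permissive)
    c = params.gain
    n = params.n
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xn = x ** n
        A = xn @ network._act_mask.T
        R = xn @ network._inh_mask.T
        P = c * A / (1.0 + c * A)
        Q = 1.0 / (1.0 + c * R)
        dP = c / (1.0 + c * A) ** 2        # dP/dA
        dQ = -c / (1.0 + c * R) ** 2       # dQ/dR
        dxn = n * x ** (n - 1)             # d(x_j^n)/dx_j
        P = np.where(np.isnan(P) & (A > 1), 1.0, P)
    G = network.n_genes
    # J_ij = eta * [ dP_i * Q_i * act[i,j] + P_i * dQ_i * inh[i,j] ] * n x_j^(n-1) - tau * delta_ij
    act = network._act_mask.astype(float)
    inh = network._inh_mask.astype(float)
    J = params.eta * ((dP * Q)[..., :, None] * act + (P * dQ)[..., :, None] * inh)
    J = J * dxn[..., None, :]
    J = J - params.tau * np.eye(G)
    return J
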