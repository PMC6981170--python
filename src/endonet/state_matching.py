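"""Cell-state catalog and single-cell assignment.

The equilibrium atlas is turned into a catalog of binary on/off patterns
over the core genes; cells in an expression matrix are binarized and
assigned to the catalog entry whose pattern they match EXACTLY (cells that
match no pattern are "unmatched").  Expression is shifted by a pseudocount
(Exp = Count + 1 for raw counts, Exp = TPM + 1 for TPM), optionally
log2-transformed, and a gene counts as "on" when transformed expression
exceeds 1 — i.e. at least one observed count — unless a per-gene quantile
rule is requested.  Hierarchical clustering on the correlation distance
(1 - Pearson r, average linkage) reproduces the coarse grouping used to
explore heterogeneous datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .equilibria import EquilibriumAtlas

__all__ = [
    "StateCatalog",
    "StateAssignment",
    "catalog_from_atlas",
    "annotate_pancreas_atlas",
    "PANCREAS_CELL_TYPES",
    "transform_expression",
    "binarize_expression",
    "assign_cells",
    "correlation_cluster",
]


@dataclass
class StateCatalog:
    """Binary state patterns over the core genes, one per catalog entry."""

    genes: list[str]
    labels: list[str]
    patterns: np.ndarray  # (n_states, n_genes) of 0/1
    annotations: dict[str, str] = field(default_factory=dict)
    threshold: float = 0.5

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns, columns=self.genes)
        df.insert(0, "label", self.labels)
        df["annotation"] = [self.annotations.get(l, "") for l in self.labels]
        return df


@dataclass
class StateAssignment:
    cell_ids: list[str]
    labels: list[str]               # catalog label or "unmatched"
    patterns: np.ndarray            # per-cell binarized core-gene pattern
    summary: pd.DataFrame           # per-state cell counts


def catalog_from_atlas(atlas: EquilibriumAtlas, threshold: float = 0.5,
                       annotations: dict[str, str] | None = None,
                       include_transition: bool = False) -> StateCatalog:
    """Binarize atlas states at the threshold into a catalog.

    Stable states always enter; transition states can be included (the
    multipotent-progenitor and early-endocrine-progenitor cell types are
    saddles, not attractors).  Colliding patterns are kept, with a warning.
    """
    states = atlas.by_class("stable")
    if include_transition:
        states = states + atlas.by_class("transition")
    if not states:
        raise ValueError("atlas has no stable states")
    labels = [s.label for s in states]
    patterns = np.array([s.binarize(threshold) for s in states])
    seen: dict[tuple, str] = {}
    for lab, pat in zip(labels, patterns):
        key = tuple(pat)
        if key in seen:
            warnings.warn(f"states {seen[key]} and {lab} collapse to the same "
                          "binary pattern", stacklevel=2)
        else:
            seen[key] = lab
    return StateCatalog(genes=list(atlas.genes), labels=labels, patterns=patterns,
                        annotations=dict(annotations or {}), threshold=threshold)


# Marker-defined pancreatic cell types among the STABLE states, as on/off
# status over (PDX1, PTF1A, NKX6.1, SOX9, HES1, NGN3, ARX, PAX4).
# Identities follow the marker literature: TiP and TrP keep the early
# progenitor markers PDX1/SOX9/HES1 with PTF1A vs NKX6.1 exclusively on;
# AciP pairs PTF1A with the progenitor markers SOX9/HES1; AciP2 is
# PDX1+PTF1A+; acinar (= mature tip) retains PTF1A alone; trunk keeps
# NKX6.1/SOX9/HES1 and ductal SOX9/HES1; immature beta co-expresses
# PDX1/NKX6.1/NGN3/PAX4 and immature alpha NGN3/ARX.  Two attractors carry
# no lineage marker combination (NKX6.1 alone; everything off) and belong
# to no lineage.
PANCREAS_STABLE_TYPES: dict[str, tuple[int, ...]] = {
    "acinar":      (0, 1, 0, 0, 0, 0, 0, 0),
    "tip":         (0, 1, 0, 0, 0, 0, 0, 0),  # same core pattern as acinar
    "AciP":        (0, 1, 0, 1, 1, 0, 0, 0),
    "AciP2":       (1, 1, 0, 0, 0, 0, 0, 0),
    "TiP":         (1, 1, 0, 1, 1, 0, 0, 0),
    "TrP":         (1, 0, 1, 1, 1, 0, 0, 0),
    "trunk":       (0, 0, 1, 1, 1, 0, 0, 0),
    "ductal":      (0, 0, 0, 1, 1, 0, 0, 0),
    "Ialpha":      (0, 0, 0, 0, 0, 1, 1, 0),
    "Ibeta":       (1, 0, 1, 0, 0, 1, 0, 1),
    "NKX61_only":  (0, 0, 1, 0, 0, 0, 0, 0),
    "unexpressed": (0, 0, 0, 0, 0, 0, 0, 0),
}

# kept for backwards compatibility of the public name
PANCREAS_CELL_TYPES = PANCREAS_STABLE_TYPES


def annotate_pancreas_atlas(atlas: EquilibriumAtlas, threshold: float = 0.5,
                            graph=None) -> dict[str, str]:
    """Map pancreatic cell-type names to atlas labels.

    Stable cell types are matched by exact binary pattern (the 11 stable
    patterns are pairwise distinct, so this is unambiguous).  The three
    progenitor types that are saddles rather than attractors — MP, EEP and
    LEP — share binarized patterns with attractors, so they are identified
    by their connectivity when a landscape graph is supplied:

    * LEP is the transition state whose perturbed trajectories reach the
      two immature islet attractors (Ialpha and Ibeta);
    * EEP is the transition state bridging TrP and LEP;
    * MP is the transition state bridging TiP and TrP.
    """
    mapping: dict[str, str] = {}
    for name, pattern in PANCREAS_STABLE_TYPES.items():
        pat = np.array(pattern)
        for s in atlas.by_class("stable"):
            if np.array_equal(s.binarize(threshold), pat):
                mapping[name] = s.label
                break
    if graph is not None:
        succ = {s.label: set(graph.successors(s.label))
                for s in atlas.by_class("transition") if graph.has_node(s.label)}
        def find(*names: str) -> str | None:
            if not all(n in names_to_labels for n in names):
                return None
            targets = {names_to_labels[n] for n in names}
            for lab, out in succ.items():
                if targets <= out:
                    return lab
            return None

        names_to_labels = dict(mapping)
        lep = find("Ialpha", "Ibeta")
        if lep:
            mapping["LEP"] = names_to_labels["LEP"] = lep
        eep = find("TrP", "LEP")
        if eep:
            mapping["EEP"] = eep
        mp = find("TiP", "TrP")
        if mp:
            mapping["MP"] = mp
    return mapping


def transform_expression(matrix: pd.DataFrame, mode: str = "count",
                         log2: bool = False) -> pd.DataFrame:
    """Pseudocount shift Exp = value + 1 (counts or TPM), optional log2."""
    if mode not in ("count", "tpm"):
        raise ValueError("mode must be 'count' or 'tpm'")
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    out = values + 1.0
    if log2:
        out = np.log2(out)
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    result.attrs["transform"] = {"mode": mode, "pseudocount": 1, "log2": log2}
    return result


DETECTION_MIN = 5.0


def binarize_expression(matrix: pd.DataFrame, rule: str = "detection",
                        quantile: float = 0.5,
                        detection_min: float = DETECTION_MIN) -> pd.DataFrame:
    """Binary on/off calls per gene and cell.

    ``detection``: on iff the RAW value is >= detection_min (default 5
    counts/TPM — an order of magnitude above typical off-state leakage and
    an order of magnitude below a typical expressed level, so the call is
    insensitive to the exact cut).  Pseudocounted input (marked by the
    transform_expression metadata) is handled by shifting the cut.
    ``quantile``: on iff the value exceeds the per-gene quantile.
    """
    v = matrix.to_numpy(dtype=float)
    if rule == "detection":
        t = matrix.attrs.get("transform") or {}
        thr = detection_min + t.get("pseudocount", 0)
        if t.get("log2"):
            thr = np.log2(thr)
        bits = v >= thr
    elif rule == "quantile":
        thr = np.quantile(v, quantile, axis=1, keepdims=True)
        bits = v > thr
    else:
        raise ValueError("rule must be 'detection' or 'quantile'")
    return pd.DataFrame(bits.astype(int), index=matrix.index, columns=matrix.columns)


def assign_cells(matrix: pd.DataFrame, catalog: StateCatalog,
                 binarize_rule: str = "detection",
                 gene_map: dict[str, str] | None = None) -> StateAssignment:
    """Assign each cell to the catalog state whose binary pattern its
    binarized core-gene vector equals exactly.

    ``matrix`` is genes x cells; ``gene_map`` translates catalog gene names
    to matrix row names when they differ.  Cells matching no catalog pattern
    are labeled "unmatched".
    """
    gene_map = gene_map or {}
    rows = []
    for g in catalog.genes:
        name = gene_map.get(g, g)
        if name not in matrix.index:
            raise KeyError(f"core gene {g!r} (matrix row {name!r}) not found in the matrix")
        rows.append(name)
    core = matrix.loc[rows]
    bits = binarize_expression(core, rule=binarize_rule).to_numpy()
    pattern_index = {tuple(p): lab for p, lab in
                     zip(catalog.patterns[::-1], catalog.labels[::-1])}
    labels = [pattern_index.get(tuple(bits[:, j]), "unmatched")
              for j in range(bits.shape[1])]
    counts = pd.Series(labels).value_counts()
    summary = pd.DataFrame({
        "state": list(catalog.labels) + ["unmatched"],
        "n_cells": [int(counts.get(l, 0)) for l in catalog.labels]
                   + [int(counts.get("unmatched", 0))],
    })
    return StateAssignment(cell_ids=list(matrix.columns), labels=labels,
                           patterns=bits.T, summary=summary)


def correlation_cluster(matrix: pd.DataFrame, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of cells on 1 - Pearson r.

    Constant-profile cells have undefined correlation; they are placed at
    zero distance from each other and maximal distance from the rest, with
    a warning.  Returns integer group labels 1..k per cell (column order).
    """
    if matrix.shape[1] < k:
        raise ValueError(f"need at least k={k} cells, got {matrix.shape[1]}")
    if k == 1:
        return np.ones(matrix.shape[1], dtype=int)
    X = matrix.to_numpy(dtype=float).T  # cells x genes
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn("constant-profile cells: correlation undefined; placing "
                      "them at zero distance from each other and distance 1 "
                      "from all other cells", stacklevel=2)
    d = squareform(pdist(X, metric="correlation"), checks=False)
    d[const, :] = d[:, const] = 1.0
    d[np.ix_(const, const)] = 0.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")
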