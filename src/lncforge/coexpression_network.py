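"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, module detection, eigengenes, kME, trait correlation, enrichment and
hub-lncRNA selection.

The network is unsigned: a_ij = |cor(x_i, x_j)|^beta with soft power beta = 9.
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where l_ij counts shared
neighbors and k is connectivity excluding the diagonal.  Modules come from
average-linkage hierarchical clustering of 1 - TOM with a static tree cut
(deterministic by construction), merged while their eigengenes correlate
above 0.70.  Module enrichment uses the upper-tail hypergeometric test with
BH FDR.  Hub lncRNAs are the top-k by degree among the first neighbors of a
sub-network's annotated proteins; a hub in >= 2 sub-networks is inter-network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from .expression_specificity import bh_fdr

__all__ = [
    "AdjacencyMatrix",
    "adjacency_from_expression",
    "tom_matrix",
    "detect_modules",
    "module_eigengene_and_merge",
    "kme_and_trait_correlation",
    "hypergeometric_enrichment",
    "hub_selection",
    "CoexpressionModule",
    "HubGene",
    "MODULE_COLORS",
]

# WGCNA-style color labels, assigned to modules in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)

UNASSIGNED = "grey"


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-thresholded adjacency with its transcript ids."""

    values: np.ndarray
    ids: list[str]
    beta: float

    def __post_init__(self) -> None:
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.min() < 0 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{u != i} a_iu."""
        return self.values.sum(axis=1) - np.diag(self.values)


def adjacency_from_expression(expr: pd.DataFrame, beta: float = 9.0
                              ) -> AdjacencyMatrix:
    """Unsigned adjacency |cor|^beta from a transcripts x samples table.

    Zero-variance transcripts are removed with a warning before correlation.
    """
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} zero-variance transcript(s)")
        x = x[keep]
        expr = expr.loc[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 transcripts with variance")
    cor = np.corrcoef(x)
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(a, list(expr.index), beta)


def tom_matrix(adjacency: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency (TOM_ii = 1).

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj.
    """
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)  # diagonal excluded from l and k
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray, ids: list[str], min_module_size: int = 30,
                   cut_height: float = 0.995) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` fall into the unassigned 'grey'
    bin.  Labels are WGCNA-style colors in decreasing cluster-size order.
    """
    n = tom.shape[0]
    if n != len(ids):
        raise ValueError("ids do not match TOM dimension")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], c))
    color_of = {c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
                for i, c in enumerate(big)}
    labels = [color_of.get(c, UNASSIGNED) for c in raw]
    return pd.Series(labels, index=ids, name="module")


def _eigengene(x: np.ndarray) -> np.ndarray:
    """First PC over samples of a members x samples block, standardized rows,
    unit norm, oriented so the mean member correlation is positive."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if z.shape[0] == 1:
        me = z[0]
        norm = np.linalg.norm(me)
        return me / norm if norm else me
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    cors = z @ me / (np.linalg.norm(z, axis=1) * np.linalg.norm(me) + 1e-300)
    if cors.sum() < 0:
        me = -me
    return me


@dataclass
class CoexpressionModule:
    module_id: str
    members: list[str]
    eigengene: np.ndarray
    kme: dict = field(default_factory=dict)
    trait_correlations: dict = field(default_factory=dict)
    hubs: list = field(default_factory=list)


def module_eigengene_and_merge(expr: pd.DataFrame, assignment: pd.Series,
                               merge_cor: float = 0.70
                               ) -> tuple[pd.Series, pd.DataFrame]:
    """Eigengenes per module; iteratively merge pairs correlated > merge_cor.

    Returns the (possibly relabeled) assignment and a samples x modules
    eigengene table.  The most correlated pair merges first; eigengenes are
    recomputed and the loop repeats to a fixed point.  The merged pair keeps
    the larger module's label.
    """
    assignment = assignment.copy()
    modules = [m for m in assignment.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no non-grey module to compute eigengenes for")
    while True:
        modules = sorted(assignment[assignment != UNASSIGNED].unique(),
                         key=lambda m: (-(assignment == m).sum(), m))
        mes = {m: _eigengene(expr.loc[assignment[assignment == m].index].to_numpy())
               for m in modules}
        if len(modules) < 2:
            break
        best_pair, best_cor = None, merge_cor
        for i, mi in enumerate(modules):
            for mj in modules[i + 1:]:
                c = float(np.corrcoef(mes[mi], mes[mj])[0, 1])
                if c > best_cor:
                    best_pair, best_cor = (mi, mj), c
        if best_pair is None:
            break
        keep, absorb = best_pair  # modules sorted by size: keep the larger
        assignment[assignment == absorb] = keep
    me_table = pd.DataFrame({m: mes[m] for m in modules}, index=expr.columns)
    return assignment, me_table


def kme_and_trait_correlation(expr: pd.DataFrame, eigengenes: pd.DataFrame,
                              traits: pd.DataFrame
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME (transcripts x modules correlations) and module-trait (r, p).

    p-values come from the two-sided t test with n - 2 degrees of freedom,
    t = r sqrt(n - 2) / sqrt(1 - r^2).
    """
    if not eigengenes.index.equals(traits.index):
        traits = traits.loc[eigengenes.index]
    n = eigengenes.shape[0]
    x = expr.to_numpy(dtype=float)
    kme = pd.DataFrame(index=expr.index, columns=eigengenes.columns, dtype=float)
    for m in eigengenes.columns:
        me = eigengenes[m].to_numpy()
        me_c = me - me.mean()
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(me_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[m] = np.where(denom > 0, xc @ me_c / denom, np.nan)
    rows = []
    for m in eigengenes.columns:
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            if tv.std() == 0:
                raise ValueError(f"trait {trait!r} is constant")
            r = float(np.corrcoef(eigengenes[m], tv)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
                p = float(2 * t_dist.sf(abs(tstat), n - 2))
            rows.append({"module": m, "trait": trait, "r": r, "p": p})
    return kme, pd.DataFrame(rows)


def hypergeometric_enrichment(module_members, term_to_genes: dict,
                              universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in a module, BH FDR.

    p = P(X >= k) with k term members in the module, K the term size, N the
    universe size and n the module size.  Every term gene must be in the
    universe.
    """
    universe = set(universe)
    module = set(module_members)
    if not module <= universe:
        raise ValueError("module members must be a subset of the universe")
    n_universe, n_module = len(universe), len(module)
    rows = []
    for term in sorted(term_to_genes):
        genes = set(term_to_genes[term])
        missing = genes - universe
        if missing:
            raise ValueError(f"term {term!r}: gene(s) absent from universe: {sorted(missing)[:3]}")
        k = len(genes & module)
        p = float(hypergeom.sf(k - 1, n_universe, len(genes), n_module))
        rows.append({"term": term, "k": k, "term_size": len(genes), "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "k", "term_size", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["enriched"] = df["q"] < 0.05
    else:
        df["q"] = []
        df["enriched"] = []
    return df


@dataclass(frozen=True)
class HubGene:
    lncrna_id: str
    subnetwork: str
    degree: int
    hub_class: str  # intra / inter


def hub_selection(weights: pd.DataFrame, edge_threshold: float,
                  lnc_ids, annotated_protein_sets: dict[str, list[str]],
                  top_k: int = 5) -> list[HubGene]:
    """Top-k lncRNAs by degree among first neighbors of each sub-network's
    annotated proteins; a lncRNA selected in >= 2 sub-networks is an
    inter-network hub.

    ``weights`` is a square TOM/adjacency DataFrame over all node ids; edges
    are pairs with weight >= edge_threshold.  Degree is counted within the
    graph induced by the sub-network's proteins plus its candidate lncRNAs;
    ties break by total degree in the full graph, then id.
    """
    ids = list(weights.index)
    if list(weights.columns) != ids:
        raise ValueError("weights must be square with matching index/columns")
    w = weights.to_numpy(dtype=float)
    adj = w >= edge_threshold
    np.fill_diagonal(adj, False)
    pos = {g: i for i, g in enumerate(ids)}
    lnc_set = [g for g in lnc_ids if g in pos]
    total_degree = adj.sum(axis=1)

    selected: dict[str, list[tuple[str, int]]] = {}
    for label in sorted(annotated_protein_sets):
        proteins = [p for p in annotated_protein_sets[label] if p in pos]
        if not proteins:
            raise ValueError(f"sub-network {label!r} has no proteins in the graph")
        prot_idx = np.array([pos[p] for p in proteins])
        candidates = [g for g in lnc_set if adj[pos[g], prot_idx].any()]
        if not candidates:
            warnings.warn(f"sub-network {label!r}: no neighboring lncRNA above threshold")
            continue
        induced = prot_idx.tolist() + [pos[g] for g in candidates]
        induced_mask = np.zeros(len(ids), dtype=bool)
        induced_mask[induced] = True
        ranked = sorted(
            candidates,
            key=lambda g: (-int(adj[pos[g], induced_mask].sum()),
                           -int(total_degree[pos[g]]), g),
        )
        for g in ranked[:top_k]:
            selected.setdefault(g, []).append((label, int(adj[pos[g], induced_mask].sum())))

    hubs = []
    for g in sorted(selected):
        cls = "inter" if len(selected[g]) >= 2 else "intra"
        for label, deg in selected[g]:
            hubs.append(HubGene(g, label, deg, cls))
    return hubs
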