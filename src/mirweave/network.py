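"""Weighted gene-coexpression network: zero-count filtering, power-6 soft
thresholding, topological overlap, average-linkage module detection with a
static cut, module eigengenes, connectivity and hub-centred subnetworks.

The adjacency is unsigned by default, a_ij = |cor(x_i, x_j)|^power, which is
what a WGCNA run with default arguments builds; module labels follow the
WGCNA colour convention with unassigned genes in "grey".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import get_logger

log = get_logger(__name__)

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"


def filter_genes(counts: pd.DataFrame, max_zeros: int = 4) -> pd.DataFrame:
    """Drop genes with more than ``max_zeros`` zero values across samples and
    log2(x+1)-transform the survivors."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = (counts == 0).sum(axis=1) <= max_zeros
    if not keep.any():
        raise ValueError("no genes survive the zero-count filter")
    dropped = int((~keep).sum())
    if dropped:
        log.info("zero-count filter removed %d of %d genes", dropped, len(counts))
    return np.log2(counts.loc[keep].astype(float) + 1.0)


def adjacency(expr: pd.DataFrame, power: int = 6, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency a_ij = |cor|^power (unsigned) or
    ((1+cor)/2)^power (signed); unit diagonal; constant genes get zero
    correlation to everything."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for meaningful correlation")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        log.warning("%d zero-variance genes get zero correlation", int((sd == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    a = ((1 + cor) / 2) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij) with the sum over u != i, j; TOM_ii = 1."""
    A = adj.to_numpy(dtype=float)
    k = A.sum(axis=1) - 1.0  # connectivity excludes the unit diagonal
    shared = A @ A - 2.0 * A  # removes u=i and u=j terms (diagonal is 1)
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, min_size: int = 30,
                   cut_height: float = 0.95) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut; clusters below
    ``min_size`` fall into "grey"; labels are assigned by size rank (largest
    first) following the WGCNA colour sequence."""
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry for squareform
    if len(d) < 2:
        return pd.Series([GREY] * len(d), index=tom.index, name="module")
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    mapping = {}
    nxt = 0
    for c in order:
        if sizes[c] >= min_size:
            mapping[c] = MODULE_COLORS[nxt] if nxt < len(MODULE_COLORS) else f"module{nxt + 1}"
            nxt += 1
        else:
            mapping[c] = GREY
    return pd.Series([mapping[c] for c in raw], index=tom.index, name="module")


@dataclass
class ModuleEigengene:
    module: str
    eigengene: pd.Series        # one value per sample, unit norm
    variance_explained: float


def eigengene(expr: pd.DataFrame, module: str = "") -> ModuleEigengene:
    """First principal component of the standardised module submatrix
    (samples as observations), sign-oriented to correlate positively with the
    module mean profile."""
    if len(expr) < 2:
        raise ValueError("module must contain at least 2 genes")
    X = expr.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd                      # genes x samples, standardised
    try:
        _u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        e = vt[0]
        var_explained = float(s[0] ** 2 / (s ** 2).sum()) if s.sum() > 0 else 0.0
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate module
        log.warning("rank-deficient module %s: eigengene = standardised mean", module)
        e = Xs.mean(axis=0)
        e = e / np.linalg.norm(e)
        var_explained = 0.0
    mean_profile = Xs.mean(axis=0)
    if e @ mean_profile < 0:
        e = -e
    return ModuleEigengene(module, pd.Series(e, index=expr.columns), var_explained)


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Eigengene table (module x samples) with a variance_explained column."""
    rows = {}
    var = {}
    for label in sorted(modules.unique()):
        if label == GREY:
            continue
        eg = eigengene(expr.loc[modules[modules == label].index], label)
        rows[label] = eg.eigengene
        var[label] = eg.variance_explained
    df = pd.DataFrame(rows).T
    df.index.name = "module"
    df["variance_explained"] = pd.Series(var)
    return df


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-gene whole-network connectivity k_i = sum_{j != i} a_ij."""
    return adj.sum(axis=1) - 1.0


def intramodular_connectivity(adj: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """Connectivity restricted to each gene's own module."""
    out = pd.Series(0.0, index=adj.index)
    for label in modules.unique():
        idx = modules[modules == label].index
        sub = adj.loc[idx, idx]
        out[idx] = sub.sum(axis=1) - 1.0
    return out


def hub_subnetwork(adj: pd.DataFrame, hubs: list[str],
                   edge_threshold: float = 0.1) -> tuple[pd.DataFrame, set]:
    """Edges (hub, gene, weight) with a_ij >= edge_threshold, undirected and
    deduplicated, plus the neighbour set shared by every hub."""
    unknown = [h for h in hubs if h not in adj.index]
    if unknown:
        raise ValueError(f"unknown hub ids {unknown}; known ids include "
                         f"{list(adj.index[:5])}...")
    rows, seen = [], set()
    neighbour_sets = []
    for hub in hubs:
        w = adj.loc[hub]
        neigh = set(w.index[(w >= edge_threshold) & (w.index != hub)])
        neighbour_sets.append(neigh)
        for g in sorted(neigh):
            key = frozenset((hub, g))
            if key in seen:
                continue
            seen.add(key)
            rows.append({"gene1": hub, "gene2": g, "weight": float(adj.loc[hub, g])})
    shared = set.intersection(*neighbour_sets) if neighbour_sets else set()
    return pd.DataFrame(rows, columns=["gene1", "gene2", "weight"]), shared
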