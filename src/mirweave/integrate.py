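"""Joining differentially expressed miRNAs with their degradome-validated,
differentially expressed targets; classifying the expression-correlation
direction over the time course; generic gene-set term enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr, zscore
from .io import get_logger

log = get_logger(__name__)


def pair_de(de_mirnas: pd.DataFrame, target_hits: pd.DataFrame,
            de_genes: pd.DataFrame) -> pd.DataFrame:
    """miRNA-target pairs where the miRNA is strict-DE, the pair is degradome
    validated, and the target passes the gene DE thresholds in at least one
    comparison; deduplicated on (miRNA, target)."""
    strict = set(de_mirnas.loc[de_mirnas["strict"], "feature"])
    de_t = set(de_genes.loc[de_genes["significant"], "feature"])
    mask = target_hits["small_rna"].isin(strict) & target_hits["target"].isin(de_t)
    pairs = (target_hits.loc[mask]
             .sort_values(["small_rna", "alignment_score", "target"], kind="mergesort")
             .drop_duplicates(subset=["small_rna", "target"], keep="first")
             .reset_index(drop=True))
    return pairs


def correlate_pairs(pairs: pd.DataFrame, mirna_profiles: pd.DataFrame,
                    gene_profiles: pd.DataFrame,
                    negative_threshold: float = -0.5) -> pd.DataFrame:
    """Pearson correlation of each pair's Z-scored profiles and its direction.

    direction = negative if r <= negative_threshold, positive if
    r >= |negative_threshold|, else uncorrelated; a constant profile yields
    r = 0 (uncorrelated).  Both profile tables must share the sample order.
    """
    if list(mirna_profiles.columns) != list(gene_profiles.columns):
        raise ValueError("miRNA and gene profiles must share the sample order")
    mz = zscore(mirna_profiles)
    gz = zscore(gene_profiles)
    k = mirna_profiles.shape[1]
    rs, directions = [], []
    for _, row in pairs.iterrows():
        m = mz.loc[row["small_rna"]].to_numpy()
        g = gz.loc[row["target"]].to_numpy()
        if not m.any() or not g.any():  # constant profile was zeroed out
            r = 0.0
        else:
            r = float(m @ g / (k - 1))  # Pearson of z-scored vectors
        rs.append(r)
        if r <= negative_threshold:
            directions.append("negative")
        elif r >= abs(negative_threshold):
            directions.append("positive")
        else:
            directions.append("uncorrelated")
    out = pairs.copy()
    out["r"] = rs
    out["direction"] = directions
    return out


def term_enrichment(selected: set | list, background: set | list,
                    gene2term: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric (upper tail, equivalent to one-sided Fisher)
    enrichment of each term in the selected set against the background.

    ``gene2term`` needs columns (gene, term); the significance flag gates on
    the raw p at ``alpha``; a BH column is reported but not gating.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    g2t = gene2term[gene2term["gene"].isin(background)]
    names = (g2t.drop_duplicates("term").set_index("term")["name"].to_dict()
             if "name" in g2t.columns else {})
    M = len(background)
    N = len(selected)
    rows = []
    for term, genes in g2t.groupby("term")["gene"]:
        term_genes = set(genes)
        n = len(term_genes)
        k = len(term_genes & selected)
        # P(overlap >= k) drawing N from M with n successes
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"term": term, "name": names.get(term, ""), "overlap": k,
                     "selected": N, "term_size": n, "background": M,
                     "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "name", "overlap", "selected",
                                     "term_size", "background", "p_value"])
    if len(df):
        df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
        df["bh_fdr"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["p_value"] < alpha
    else:
        df["bh_fdr"] = np.nan
        df["significant"] = False
    return df
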