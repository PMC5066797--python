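"""Digital-expression statistics: RPKM, the Audic-Claverie exact tag-count
test, Benjamini-Hochberg FDR, the pairwise differential-expression caller for
genes (p<0.005, FDR<=0.001, |log2 ratio|>=1) and the looser miRNA caller
(p<0.05, with a strict tier additionally requiring total abundance >10), and
Z-score profile normalisation for heatmaps.

Under the Audic-Claverie model the distribution of the second library's count
y given x reads in the first is negative binomial with r = x+1 and success
probability N1/(N1+N2); tail probabilities are therefore delegated to
scipy.stats.nbinom (log-scale internals), and the two-sided p-value doubles
the smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import get_logger

log = get_logger(__name__)


@dataclass
class Thresholds:
    """Significance defaults for the whole pipeline (all configurable)."""

    gene_p: float = 0.005
    gene_fdr: float = 0.001
    gene_lfc: float = 1.0
    mirna_p: float = 0.05
    mirna_abundance: int = 10
    network_power: int = 6
    score_cutoff: float = 4.0
    corr_negative: float = -0.5

    def __post_init__(self):
        for name in ("gene_p", "gene_fdr", "gene_lfc", "mirna_p",
                     "mirna_abundance", "network_power", "score_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def zscore(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature (x - mean)/sd across samples; constant rows map to zeros."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 samples to Z-score")
    mean = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=1)
    out = profiles.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# Audic-Claverie exact test
# ---------------------------------------------------------------------------

def ac_test(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value for counts x (library size n1) and
    y (library size n2).  Vectorised over array inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p_succ = n1 / (n1 + n2)           # P(y|x) is NB(x+1, n1/(n1+n2))
    lower = stats.nbinom.cdf(y, x + 1, p_succ)
    upper = stats.nbinom.sf(y - 1, x + 1, p_succ)
    p = 2.0 * np.minimum(lower, upper)
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Callers
# ---------------------------------------------------------------------------

LFC_EPSILON = 0.01  # RPKM pseudocount for log2 ratios


def call_deg(counts: pd.DataFrame, lengths: pd.Series, control: str = "S1",
             thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Pairwise differential expression of every sample against the control.

    The exact test runs on raw counts with the library totals; the log2 ratio
    on RPKM with a pseudocount; FDR is computed per comparison across
    features.  Significance is the conjunction p < gene_p AND fdr <= gene_fdr
    AND |log2 ratio| >= gene_lfc.
    """
    th = thresholds or Thresholds()
    if control not in counts.columns:
        raise ValueError(f"control sample {control!r} not in counts")
    missing = lengths.reindex(counts.index).isna()
    if missing.any():
        log.warning("excluding %d features without length", int(missing.sum()))
        counts = counts.loc[~missing.values]
    lib_sizes = counts.sum(axis=0)
    expr = rpkm(counts, lengths.reindex(counts.index), lib_sizes)
    frames = []
    for sample in counts.columns:
        if sample == control:
            continue
        p = ac_test(counts[control].to_numpy(), counts[sample].to_numpy(),
                    float(lib_sizes[control]), float(lib_sizes[sample]))
        fdr = bh_fdr(p)
        lfc = np.log2((expr[sample] + LFC_EPSILON) / (expr[control] + LFC_EPSILON))
        frames.append(pd.DataFrame({
            "feature": counts.index, "comparison": f"{sample}_vs_{control}",
            "p_value": p, "fdr": fdr, "log2_ratio": lfc.to_numpy(),
            "significant": (p < th.gene_p) & (fdr <= th.gene_fdr)
                           & (np.abs(lfc.to_numpy()) >= th.gene_lfc),
        }))
    return pd.concat(frames, ignore_index=True)


def call_de_mirna(counts: pd.DataFrame, control: str = "S1",
                  thresholds: Thresholds | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA differential-expression flags plus per-comparison up/down tallies.

    The loose set holds miRNAs with any pairwise p < mirna_p; the strict set
    additionally requires total abundance across libraries > mirna_abundance.
    Returns (per-miRNA table, per-comparison up/down tally table).
    """
    th = thresholds or Thresholds()
    if control not in counts.columns:
        raise ValueError(f"control sample {control!r} not in counts")
    lib_sizes = counts.sum(axis=0)
    total = counts.sum(axis=1)
    min_p = pd.Series(1.0, index=counts.index)
    tallies = []
    updown = {}
    for sample in counts.columns:
        if sample == control:
            continue
        p = ac_test(counts[control].to_numpy(), counts[sample].to_numpy(),
                    float(lib_sizes[control]), float(lib_sizes[sample]))
        sig = p < th.mirna_p
        # direction on library-size-normalised abundance
        cpm_c = counts[control] / lib_sizes[control]
        cpm_s = counts[sample] / lib_sizes[sample]
        up = sig & (cpm_s.to_numpy() > cpm_c.to_numpy())
        down = sig & (cpm_s.to_numpy() < cpm_c.to_numpy())
        updown[sample] = (p, up, down)
        min_p = np.minimum(min_p, p)
        tallies.append({"comparison": f"{sample}_vs_{control}",
                        "up": int(up.sum()), "down": int(down.sum())})
    loose = min_p < th.mirna_p
    strict = loose & (total > th.mirna_abundance)
    table = pd.DataFrame({
        "feature": counts.index, "total": total.to_numpy(),
        "min_p": np.asarray(min_p), "loose": np.asarray(loose),
        "strict": np.asarray(strict),
    }).reset_index(drop=True)
    return table, pd.DataFrame(tallies)
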