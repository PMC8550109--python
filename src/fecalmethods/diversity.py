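"""Feature hygiene, transforms and diversity metrics for abundance tables.

Five metrics summarize each profile level: observed richness, Shannon entropy
(natural log) and the Simpson index for alpha diversity, plus the first
principal coordinate of Bray-Curtis and of abundance-based Jaccard distances
for beta diversity. Three levels (species, gene, pathway) x five metrics give
the fifteen diversity metrics fed to the reliability analysis, alongside the
square-root abundances of the top phyla.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable

__all__ = [
    "filter_low_prevalence",
    "sqrt_abundance",
    "alpha_diversity",
    "beta_distance",
    "pcoa_pc1",
    "diversity_table",
    "top_k_features",
    "PCoAResult",
]

log = logging.getLogger(__name__)

ALPHA_METRICS = ("richness", "shannon", "simpson")
DIVERSITY_METRICS = ALPHA_METRICS + ("bc_pc1", "jac_pc1")


def filter_low_prevalence(table: AbundanceTable, min_samples: int = 4) -> AbundanceTable:
    """Drop features present (nonzero) in fewer than ``min_samples`` samples.

    The default of four operationalizes a <5%-of-samples prevalence cut for an
    88-sample study; removed feature ids are logged. Idempotent.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.data > 0).sum(axis=1)
    keep = prevalence >= min_samples
    removed = list(table.data.index[~keep])
    if removed:
        log.info("filter_low_prevalence removed %d features: %s", len(removed), removed[:10])
    if keep.sum() == 0:
        warnings.warn("prevalence filter removed every feature")
    return AbundanceTable(table.data.loc[keep], level=table.level, closed=False)


def sqrt_abundance(table: AbundanceTable) -> AbundanceTable:
    """Element-wise square root; closure is intentionally not restored."""
    if (table.data.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    return AbundanceTable(np.sqrt(table.data), level=table.level, closed=False)


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Observed richness, Shannon H (nats) and Simpson index per sample.

    Columns are re-normalized internally so transformed input is handled;
    all-zero samples report 0 for all three metrics with a warning.
    """
    x = table.data.to_numpy(dtype=float)
    sums = x.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s): diversity reported as 0")
        sums = np.where(zero, 1.0, sums)
    p = x / sums
    richness = (x > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (p**2).sum(axis=0)
    out = pd.DataFrame(
        {"richness": richness, "shannon": shannon, "simpson": simpson},
        index=table.sample_ids,
    )
    out.loc[np.asarray(zero), ["shannon", "simpson"]] = 0.0
    return out


def beta_distance(table: AbundanceTable, metric: str = "BRAY_CURTIS", binary: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis or Jaccard distances between samples.

    Quantitative Jaccard is the Bray-Curtis-derived form 2B/(1+B); the binary
    flag switches Jaccard to presence/absence set dissimilarity. Pairs of
    all-zero samples get distance 0 with a warning.
    """
    if table.data.shape[1] < 2:
        raise ValueError("need at least two samples")
    metric = metric.upper()
    x = table.data.to_numpy(dtype=float).T
    if metric == "JACCARD" and binary:
        d = pdist((x > 0).astype(float), metric="jaccard")
    else:
        with np.errstate(invalid="ignore"):
            d = pdist(x, metric="braycurtis")
        if np.isnan(d).any():
            warnings.warn("all-zero sample pair(s): distance set to 0")
            d = np.nan_to_num(d, nan=0.0)
        if metric == "JACCARD":
            d = 2.0 * d / (1.0 + d)
        elif metric != "BRAY_CURTIS":
            raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PCoAResult:
    """First principal coordinate of classical metric scaling."""

    pc1: pd.Series
    eigenvalue_share: float
    eigenvalues: np.ndarray
    n_negative_eigenvalues: int


def pcoa_pc1(distance: pd.DataFrame) -> PCoAResult:
    """Classical scaling (Torgerson) PC1 with a fixed sign convention.

    Double-centers -D^2/2, eigendecomposes, and scales the leading eigenvector
    by sqrt(lambda_1). The sign is fixed so the first sample's coordinate is
    >= 0. Negative eigenvalues (non-Euclidean distances) are reported, not
    corrected.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam1 = evals[0]
    if lam1 <= 0:  # all samples coincide (or worse): flat embedding
        pc1 = np.zeros(n)
        share = 0.0
    else:
        pc1 = evecs[:, 0] * np.sqrt(lam1)
        if pc1[0] < 0:
            pc1 = -pc1
        share = float(lam1 / evals[evals > 0].sum())
    return PCoAResult(
        pc1=pd.Series(pc1, index=distance.index, name="pc1"),
        eigenvalue_share=share,
        eigenvalues=evals,
        n_negative_eigenvalues=int((evals < -1e-10).sum()),
    )


def diversity_table(table: AbundanceTable, run_id: str | None = None) -> pd.DataFrame:
    """The five per-sample diversity metrics for one profile level.

    The two PC1 columns are defined relative to one ordination over exactly the
    samples in ``table`` (the run id records which); use one call per
    comparison sample set.
    """
    out = alpha_diversity(table)
    for metric, col in (("BRAY_CURTIS", "bc_pc1"), ("JACCARD", "jac_pc1")):
        out[col] = pcoa_pc1(beta_distance(table, metric)).pc1
    out.attrs["level"] = table.level
    out.attrs["ordination_run"] = run_id or f"{table.level}:{'|'.join(table.sample_ids)}"
    return out


def top_k_features(table: AbundanceTable, k: int) -> list[str]:
    """Feature ids ranked by mean abundance (desc), ties broken lexically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    means = table.data.mean(axis=1)
    if k > len(means):
        warnings.warn(f"k={k} exceeds feature count {len(means)}; returning all")
        k = len(means)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return order[:k]
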