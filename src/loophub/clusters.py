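"""Differential-gene selection, z-scored K-means clustering, and
cluster-level covariate annotation.

Genes passing the adjusted-p / fold-change thresholds are z-scored across
samples and clustered with Euclidean K-means (seeded restarts, lowest
inertia).  Cluster labels are renumbered deterministically by descending
mean condition-B minus condition-A z-profile difference so "cluster k" is
stable across seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .core.genes import GeneModel
from .core.intervals import GenomicInterval, IntervalIndex
from .core.tracks import SignalTrack, map_binned_signal


def select_differential_genes(
    expression: pd.DataFrame,
    p_adj_max: float = 0.05,
    lfc_min: float = 0.5,
    padj_col: str = "padj_B_vs_A",
    lfc_col: str = "log2fc_B_vs_A",
) -> pd.DataFrame:
    """Genes with adjusted p < p_adj_max and |log2 fold-change| > lfc_min.

    Genes with missing statistics are excluded (count reported via warning).
    """
    stats_ok = expression[padj_col].notna() & expression[lfc_col].notna()
    n_missing = int((~stats_ok).sum())
    if n_missing:
        warnings.warn(f"{n_missing} genes lack differential statistics; excluded")
    sel = (
        stats_ok
        & (expression[padj_col] < p_adj_max)
        & (expression[lfc_col].abs() > lfc_min)
    )
    return expression.loc[sel].reset_index(drop=True)


def zscore_rows(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row z-scores and a validity mask (zero-variance rows are invalid)."""
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (matrix - mean) / sd
    return z, valid


def cluster_genes(
    expression: pd.DataFrame,
    sample_cols: Sequence[str],
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    condition_of_sample: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Z-scored Euclidean K-means over the given sample columns.

    Returns the input rows (zero-variance rows dropped with a warning) with
    ``cluster`` (1..k, deterministically ordered) and ``cluster_order``
    (distance to centroid within cluster, for heatmap ordering) columns.
    """
    mat = expression[list(sample_cols)].to_numpy(dtype=float)
    z, valid = zscore_rows(mat)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} zero-variance gene rows dropped")
    kept = expression.loc[valid].reset_index(drop=True)
    z = z[valid]
    if len(kept) < k:
        raise ValueError(f"only {len(kept)} genes for K={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(z)

    if condition_of_sample is None:
        condition_of_sample = {
            s: ("B" if s.startswith("B") else "A") for s in sample_cols
        }
    is_b = np.array([condition_of_sample[s] == "B" for s in sample_cols])
    centroid_diff = km.cluster_centers_[:, is_b].mean(axis=1) - km.cluster_centers_[
        :, ~is_b
    ].mean(axis=1)
    order = np.argsort(-centroid_diff, kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}

    out = kept.copy()
    out["cluster"] = [relabel[int(l)] for l in raw_labels]
    dist = np.linalg.norm(z - km.cluster_centers_[raw_labels], axis=1)
    out["cluster_order"] = dist
    return out.sort_values(["cluster", "cluster_order"], kind="stable").reset_index(
        drop=True
    )


def annotate_clusters(
    clustered: pd.DataFrame,
    peaks: pd.DataFrame,
    track: SignalTrack,
    peak_logfc_col: str = "chip_logfc",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster covariates: mean peak fold-change on member genes and the
    per-gene speckle-signal distribution, with pairwise rank-sum tests.

    Peaks are mapped to genes by interval overlap.  Clusters whose genes
    carry no overlapping peak get a missing fold-change covariate.
    """
    gene_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, name=r.gene_id)
        for r in clustered.itertuples()
    ]
    peak_index = IntervalIndex(
        [GenomicInterval(r.chrom, r.start, r.end) for r in peaks.itertuples()]
    )
    logfc = peaks[peak_logfc_col].to_numpy(dtype=float)
    gene_speckle = map_binned_signal(track, gene_ivs)

    per_gene_peak_fc = np.full(len(gene_ivs), np.nan)
    for i, iv in enumerate(gene_ivs):
        hits = peak_index.query(iv.chrom, iv.start, iv.end)
        if hits and np.isfinite(logfc[hits]).any():
            per_gene_peak_fc[i] = float(np.nanmean(logfc[hits]))

    table = clustered.copy()
    table["gene_peak_logfc"] = per_gene_peak_fc
    table["gene_speckle_signal"] = gene_speckle

    rows = []
    for c, grp in table.groupby("cluster"):
        fc = grp["gene_peak_logfc"].dropna()
        sp = grp["gene_speckle_signal"].dropna()
        rows.append(
            dict(
                cluster=int(c),
                n_genes=int(len(grp)),
                mean_peak_logfc=float(fc.mean()) if len(fc) else np.nan,
                mean_speckle_signal=float(sp.mean()) if len(sp) else np.nan,
                median_speckle_signal=float(sp.median()) if len(sp) else np.nan,
            )
        )
    summary = pd.DataFrame.from_records(rows)

    pvals = []
    clusters = sorted(table["cluster"].unique())
    for i, ci in enumerate(clusters):
        for cj in clusters[i + 1 :]:
            a = table.loc[table["cluster"] == ci, "gene_speckle_signal"].dropna()
            b = table.loc[table["cluster"] == cj, "gene_speckle_signal"].dropna()
            if len(a) and len(b):
                p = float(
                    sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue
                )
            else:
                p = np.nan
            pvals.append(dict(cluster_a=int(ci), cluster_b=int(cj), p_speckle=p))
    summary.attrs["pairwise_speckle_p"] = pd.DataFrame.from_records(pvals)
    return table, summary
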