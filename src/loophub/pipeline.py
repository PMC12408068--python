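"""End-to-end orchestration on a (synthetic or loaded) dataset.

``run_all`` executes simulate -> peaks -> topology -> diffloops -> signal ->
pileup -> clusters and writes per-stage tables plus a machine-readable
summary JSON.  Every decision-bearing threshold is logged and echoed into
the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import clusters as clu
from . import diffloops as dfl
from . import peaks as pk
from . import pileup as plp
from . import signal as sig
from . import topology as tp
from .core.intervals import GenomicInterval
from .simulate import (
    SimulationConfig,
    SyntheticDataset,
    expression_samples,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger("loophub")


@dataclass
class Thresholds:
    loop_fdr_max: float = 0.01
    loop_min_pets: int = 5
    diff_fdr_max: float = 0.01
    diff_min_total_pets: int = 8
    diff_strong_pets: int = 5
    cpm_pseudocount: float = 0.5
    de_padj_max: float = 0.05
    de_lfc_min: float = 0.5
    speckle_percentile: float = 90.0
    pileup_half_width: int = 10
    kmeans_k: int = 4
    kmeans_restarts: int = 10


def _round(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        if not np.isfinite(obj):
            return None
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(
    config: SimulationConfig,
    outdir,
    thresholds: Optional[Thresholds] = None,
    with_matrix: bool = True,
    write_inputs: bool = True,
) -> Dict:
    """Run the full analysis narrative on a seeded synthetic dataset."""
    th = thresholds or Thresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"seed": config.seed, "thresholds": _round(vars(th))}

    log.info("simulate: seed=%d", config.seed)
    ds = simulate_dataset(config, with_matrix=with_matrix)
    if write_inputs:
        write_dataset(ds, outdir / "inputs")

    # --- peaks stage -------------------------------------------------------
    peaks_a = ds.peak_intervals("A")
    peaks_b = ds.peak_intervals("B")
    specific = pk.condition_specific_peaks(peaks_a, peaks_b)
    specific_ids = {iv.name for iv in specific}
    log.info("peaks: %d condition-specific of %d in B", len(specific), len(peaks_b))

    peak_table = ds.peaks.copy()
    peak_table["specific"] = peak_table["id"].isin(specific_ids)
    ivs_b = peaks_b
    peak_table_b = peak_table[peak_table["called_B"]].reset_index(drop=True)
    categories = pk.annotate_peaks(ivs_b, ds.genes)
    peak_table_b["category"] = categories
    summary["n_condition_specific_peaks"] = len(specific)

    # --- topology stage ----------------------------------------------------
    log.info(
        "topology: filter FDR<%g, PETs>=%d (condition B)",
        th.loop_fdr_max, th.loop_min_pets,
    )
    stats, elbow = tp.peak_loop_stats(
        ivs_b, ds.loops, condition="B",
        fdr_max=th.loop_fdr_max, min_pets=th.loop_min_pets,
    )
    peak_table_b = peak_table_b.merge(stats, on="id", how="left")
    summary["fraction_looping"] = float(peak_table_b["looping"].mean())
    if elbow is not None:
        summary["highly_looping"] = {
            "cutoff_rank": elbow.cutoff_rank,
            "cutoff_count": elbow.cutoff_count,
            "n_flagged": int(peak_table_b["highly_looping"].sum()),
        }
        elbow_df = pd.DataFrame(
            {"rank": np.arange(elbow.n), "scaled_rank": elbow.x, "scaled_count": elbow.y}
        )
        elbow_df.to_csv(outdir / "elbow.tsv", sep="\t", index=False)

    # --- diffloops stage ---------------------------------------------------
    log.info(
        "diffloops: FDR<%g, total PETs>=%d, strong-replicate rule >%d vs 0",
        th.diff_fdr_max, th.diff_min_total_pets, th.diff_strong_pets,
    )
    flags = dfl.differential_filters(
        ds.loops, th.diff_fdr_max, th.diff_min_total_pets, th.diff_strong_pets
    )
    kept_ids = set(flags.loc[flags["passed"], "id"])
    kept_loops = [lp for lp in ds.loops if lp.id in kept_ids]
    diff = dfl.loop_cpm_logfc(kept_loops, pseudocount=th.cpm_pseudocount)
    table, group_summary, p = dfl.stratify_logfc(diff, kept_loops, specific)
    table.to_csv(outdir / "diffloops.tsv", sep="\t", index=False)
    summary["loops"] = {
        "n_total": len(ds.loops),
        "n_passed_filters": len(kept_loops),
        "logfc_specific_mean": float(
            group_summary.loc[group_summary["group"], "mean"].iloc[0]
        ),
        "logfc_other_mean": float(
            group_summary.loc[~group_summary["group"], "mean"].iloc[0]
        ),
        "mannwhitney_p": p,
    }

    # --- signal stage ------------------------------------------------------
    track = ds.tracks["B"]
    log.info("signal: speckle rule >=%gth percentile", th.speckle_percentile)
    speckle_flags, threshold = sig.speckle_associated_peaks(
        ivs_b, track, th.speckle_percentile
    )
    peak_table_b["speckle_associated"] = speckle_flags
    # deciles use the baseline (condition-A) track, association flags the
    # condition-B track
    cov = sig.loop_signal(kept_loops, ds.tracks["A"])
    r, decile_table = sig.correlate_looping_with_signal(
        diff["mean_log_cpm"].to_numpy(), cov
    )
    decile_table.to_csv(outdir / "deciles.tsv", sep="\t", index=False)
    summary["signal"] = {
        "speckle_threshold": threshold,
        "n_speckle_associated": int(speckle_flags.sum()),
        "pearson_r_logcpm_vs_signal": r,
        "decile_median_logcpm": decile_table["median"].tolist(),
    }

    # --- pileup stage ------------------------------------------------------
    if ds.matrices:
        log.info("pileup: half-width %d bins", th.pileup_half_width)
        pileups = {}
        subsets = {
            "specific": peak_table_b["specific"],
            "highly": peak_table_b["highly_looping"].fillna(False).astype(bool),
            "speckle": peak_table_b["speckle_associated"],
            "all": pd.Series(True, index=peak_table_b.index),
        }
        for name, mask in subsets.items():
            sub = peak_table_b.loc[mask]
            if sub.empty:
                pileups[name] = None
                continue
            centers = plp.prepare_centers(
                sub, ds.config.matrix_bin, ds.blacklist
            )
            res = plp.pileup(ds.matrices, centers, th.pileup_half_width)
            w = th.pileup_half_width
            central = res.log2_mean_oe[w - 1 : w + 2, w - 1 : w + 2].copy()
            central[1, 1] = np.nan  # diagonal cell has no expected value
            pileups[name] = {
                "n_used": res.n_used,
                "center_log2_mean_oe": (
                    float(np.nanmean(central))
                    if np.isfinite(central).any()
                    else None
                ),
                "n_dropped_edge": res.n_dropped_edge,
                "n_blacklisted": res.n_blacklisted,
                "n_deduplicated": res.n_deduplicated,
            }
            np.savetxt(
                outdir / f"pileup_{name}.tsv", res.log2_mean_oe,
                delimiter="\t", fmt="%.6g",
            )
        summary["pileup"] = pileups

    # --- clusters stage ----------------------------------------------------
    log.info(
        "clusters: padj<%g, |lfc|>%g, K=%d", th.de_padj_max, th.de_lfc_min, th.kmeans_k
    )
    selected = clu.select_differential_genes(
        ds.expression, th.de_padj_max, th.de_lfc_min
    )
    samples = expression_samples(config)
    cond_of = {s: s.split("_")[0] for s in samples}
    clustered = clu.cluster_genes(
        selected, samples, k=th.kmeans_k, n_restarts=th.kmeans_restarts,
        seed=config.seed, condition_of_sample=cond_of,
    )
    ctable, csummary = clu.annotate_clusters(clustered, peak_table_b, ds.tracks["A"])
    ctable.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    summary["clusters"] = {
        "n_selected_genes": len(selected),
        "sizes": csummary.set_index("cluster")["n_genes"].to_dict(),
        "mean_peak_logfc": csummary.set_index("cluster")["mean_peak_logfc"].to_dict(),
        "mean_speckle_signal": csummary.set_index("cluster")[
            "mean_speckle_signal"
        ].to_dict(),
    }

    peak_table_b.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    summary = _round(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
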