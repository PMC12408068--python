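"""Cross-condition loop filtering and strength statistics.

The original association model behind published loop fold-changes is a
count GLM inside a dedicated package; here loop strength is summarized by
a transparent pseudocount CPM: CPM_s = PET_s / total_s * 1e6 per sample,
logCPM is the mean over samples of log2(CPM + pseudocount), and the fold
change is the difference of per-condition means of log2(CPM + pseudocount).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core.intervals import GenomicInterval, IntervalIndex
from .core.loops import Loop


def _samples(loops: Sequence[Loop]) -> List[str]:
    out: List[str] = []
    for lp in loops:
        for s in lp.pets:
            if s not in out:
                out.append(s)
    return out


def differential_filters(
    loops: Sequence[Loop],
    fdr_max: float = 0.01,
    min_total_pets: int = 8,
    strong_pets: int = 5,
) -> pd.DataFrame:
    """Replicate-consistency filter flags.

    A loop passes iff FDR < fdr_max, total PETs across all samples is at
    least ``min_total_pets``, and within no condition is one replicate
    strong (> ``strong_pets`` PETs) while another replicate has 0.  With
    more than two replicates the rule generalizes to (max > strong_pets
    and min == 0).
    """
    rows = []
    for lp in loops:
        total = lp.total_pets()
        passed_pet = lp.fdr < fdr_max and total >= min_total_pets
        consistent = True
        conditions = {s.split(":")[0] for s in lp.pets}
        for cond in conditions:
            reps = [lp.pets[s] for s in lp.condition_samples(cond)]
            if len(reps) >= 2 and max(reps) > strong_pets and min(reps) == 0:
                consistent = False
        rows.append(
            dict(
                id=lp.id,
                total_pets=total,
                passed_pet_filter=passed_pet,
                passed_consistency_filter=consistent,
                passed=passed_pet and consistent,
            )
        )
    return pd.DataFrame.from_records(rows)


def loop_cpm_logfc(
    loops: Sequence[Loop],
    conditions: Tuple[str, str] = ("A", "B"),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-loop CPM, mean logCPM across samples, and log2 fold-change (B vs A).

    Per-sample totals are computed over the loop list passed in; a sample
    with zero total PETs is an error.
    """
    samples = _samples(loops)
    totals = {s: sum(lp.pets.get(s, 0) for lp in loops) for s in samples}
    for s, t in totals.items():
        if t == 0:
            raise ValueError(f"sample {s!r} has zero total PETs")
    cond_a, cond_b = conditions
    rows = []
    for lp in loops:
        log_cpm = {}
        for s in samples:
            cpm = lp.pets.get(s, 0) / totals[s] * 1e6
            log_cpm[s] = np.log2(cpm + pseudocount)
        a = [log_cpm[s] for s in samples if s.split(":")[0] == cond_a]
        b = [log_cpm[s] for s in samples if s.split(":")[0] == cond_b]
        row = dict(
            id=lp.id,
            mean_log_cpm=float(np.mean(list(log_cpm.values()))),
            log2fc=float(np.mean(b) - np.mean(a)) if a and b else np.nan,
        )
        for s in samples:
            row[f"cpm:{s}"] = lp.pets.get(s, 0) / totals[s] * 1e6
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def stratify_logfc(
    differentials: pd.DataFrame,
    loops: Sequence[Loop],
    group_peaks: Sequence[GenomicInterval],
    group_name: str = "specific_anchor",
) -> Tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split per-loop fold-changes by anchor overlap with a peak set.

    Returns (table with the group flag, per-group summary, two-sided
    Mann-Whitney p-value between the groups' log2fc distributions; NaN
    when a group is empty).
    """
    index = IntervalIndex(group_peaks)
    flags = {}
    for lp in loops:
        hit = index.any_overlap(lp.anchor1) or index.any_overlap(lp.anchor2)
        flags[lp.id] = bool(hit)
    table = differentials.copy()
    table[group_name] = table["id"].map(flags).fillna(False).astype(bool)

    summaries = []
    for value in (True, False):
        sub = table.loc[table[group_name] == value, "log2fc"].dropna()
        summaries.append(
            dict(
                group=value,
                n=int(len(sub)),
                mean=float(sub.mean()) if len(sub) else np.nan,
                median=float(sub.median()) if len(sub) else np.nan,
            )
        )
    summary = pd.DataFrame.from_records(summaries)

    in_group = table.loc[table[group_name], "log2fc"].dropna()
    out_group = table.loc[~table[group_name], "log2fc"].dropna()
    if len(in_group) and len(out_group):
        p = float(
            sps.mannwhitneyu(
                in_group, out_group, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    else:
        p = np.nan
    return table, summary, p
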