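"""Jackknife (leave-one-subject-out) stability of thresholded group results.

Re-runs the one-sample group analysis with subjects removed one at a time
down to a minimum group size, tabulates surviving cluster counts per stage,
and compares all stages under both similarity lenses: Dice overlap of the
surviving-cluster masks (what strict thresholding preserves) and Pearson
correlation of the unthresholded t maps (what the data actually contain).
Cluster counts are reported as observed — never smoothed or
monotonicity-corrected, since instability of counts under small group-size
changes is precisely the behavior being measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .group_stats import GroupDataset, one_sample_ttest
from .similarity import SimilarityMatrix, build_similarity_matrix_from_pairs
from .thresholding import (NullSimConfig, ThresholdSpec,
                           estimate_cluster_extent_fwe, extract_clusters,
                           resolve_threshold)
from .volumes import MaskVolume, StatVolume


@dataclass
class StabilityReport:
    """Per-stage cluster counts plus cross-stage similarity matrices.

    Row 0 of ``table`` is the full group; ``n_subj`` strictly decreases
    down the rows.  Both matrices share the row ordering/labels.
    """

    table: pd.DataFrame
    dice_matrix: SimilarityMatrix
    pearson_matrix: SimilarityMatrix
    stage_tmaps: list[StatVolume]
    stage_masks: list[MaskVolume]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["removed_ids"] = out["removed_ids"].map(",".join)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def jackknife_analysis(group: GroupDataset, tspec: ThresholdSpec,
                       nullcfg: NullSimConfig | None = None,
                       n_min: int = 2,
                       removal_order: str | list[str] = "subject_id_order",
                       recalibrate: bool = True) -> StabilityReport:
    """Leave-one-out stability analysis across decreasing group sizes.

    For each group size from n down to ``n_min``, runs the one-sample
    t-test, resolves the df-appropriate voxelwise threshold, optionally
    recalibrates the cluster-extent threshold on null fields (same seed at
    every stage, so stages differ only through df), extracts clusters, and
    records the count.  Removal defaults to ascending subject-ID order.
    """
    n = group.n_subjects
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    if n_min > n:
        raise ValueError(f"n_min={n_min} exceeds group size {n}")

    if removal_order == "subject_id_order":
        order = sorted(group.subject_ids)
    else:
        order = list(removal_order)
        unknown = set(order) - set(group.subject_ids)
        if unknown:
            raise ValueError(f"unknown removal ids: {sorted(unknown)}")

    full_theta = None
    full_k = tspec.min_cluster_size
    rows = []
    tmaps: list[StatVolume] = []
    masks: list[MaskVolume] = []
    labels: list[str] = []

    for stage in range(n - n_min + 1):
        removed = order[:stage]
        sub = group.drop(removed) if removed else group
        _, tmap, _ = one_sample_ttest(sub)
        theta = resolve_threshold(tspec, "t", tmap.df)
        if full_theta is None:
            full_theta = theta

        if nullcfg is not None and (recalibrate or stage == 0):
            cal = estimate_cluster_extent_fwe(nullcfg, stat_threshold=theta)
            k = cal.k_min
            if stage == 0:
                full_k = k
        elif nullcfg is not None and not recalibrate:
            theta, k = full_theta, full_k
        else:
            k = tspec.min_cluster_size

        stage_spec = ThresholdSpec(stat_threshold=theta,
                                   connectivity=tspec.connectivity,
                                   min_cluster_size=k)
        clusters = extract_clusters(tmap, stage_spec, sub.mask)
        rows.append({"n_subj": sub.n_subjects, "removed_ids": list(removed),
                     "n_clusters": clusters.n_clusters, "k_used": k,
                     "theta_used": theta})
        tmaps.append(tmap)
        masks.append(clusters.mask_volume())
        labels.append(f"n{sub.n_subjects:02d}")

    table = pd.DataFrame(rows)
    dice = build_similarity_matrix_from_pairs(masks=masks, labels=labels)
    pearson = build_similarity_matrix_from_pairs(stat_maps=tmaps,
                                                 labels=labels,
                                                 mask=group.mask)
    return StabilityReport(table=table, dice_matrix=dice,
                           pearson_matrix=pearson, stage_tmaps=tmaps,
                           stage_masks=masks)


def write_report(report: StabilityReport, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out_dir / "stability_report.tsv",
        "dice": out_dir / "similarity_dice.tsv",
        "pearson": out_dir / "similarity_pearson.tsv",
    }
    report.to_tsv(paths["report"])
    report.dice_matrix.to_tsv(paths["dice"])
    report.pearson_matrix.to_tsv(paths["pearson"])
    return paths
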