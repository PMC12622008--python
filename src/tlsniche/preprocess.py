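"""Droplet demultiplexing and quality-control filters.

Hashtag demultiplexing assigns each droplet to the hashtag with the highest
count, provided that count is at least ``min_count`` (default 10) and
*strictly more than* ``ratio`` times (default double) the second most
abundant hashtag; droplets flagged as doublets are excluded.  CITE-seq QC
excludes droplets with fewer than 500 RNA counts, over 10% mitochondrial
counts, fewer than 500 surface-antibody (ADT) counts, or positivity for two
isotype controls.  Spatial QC drops cells with fewer than 10 transcripts.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd


def demux_hashtags(
    hashtag_counts: pd.DataFrame,
    min_count: int = 10,
    ratio: float = 2.0,
    doublet_flags: pd.Series | np.ndarray | None = None,
    naive_doublet_detection: bool = False,
) -> pd.DataFrame:
    """Assign droplets to hashtags.

    Parameters
    ----------
    hashtag_counts
        Nonnegative integer droplet × hashtag count matrix; the index holds
        droplet/cell ids.  At least two hashtag columns are required (the
        runner-up signal is otherwise undefined).
    min_count
        Minimum top-hashtag count for assignment.
    ratio
        The top count must be strictly greater than ``ratio`` times the
        second-highest count.
    doublet_flags
        Optional boolean per-droplet flags from an external doublet caller;
        flagged droplets are labeled ``doublet`` regardless of counts.
    naive_doublet_detection
        Stand-in heuristic used only when no external flags are given: a
        droplet whose two top hashtags each reach ``min_count`` and lie
        within ``ratio`` of each other is called a doublet instead of
        unassigned.  Off by default.

    Returns
    -------
    DataFrame indexed by cell id with columns ``label`` (hashtag id,
    ``"doublet"`` or ``"unassigned"``), ``top_count`` and ``second_count``.
    Ties for the top hashtag are broken toward the lowest column index, so
    the result is invariant to hashtag column order up to that rule.
    """
    if hashtag_counts.shape[1] < 2:
        raise ValueError(
            "demultiplexing requires at least 2 hashtags; "
            f"got {hashtag_counts.shape[1]} (second-highest signal undefined)"
        )
    counts = hashtag_counts.to_numpy()
    if (counts < 0).any():
        raise ValueError("hashtag counts must be nonnegative")

    # canonical column order for order-invariance; ties then break toward
    # the lexicographically lowest hashtag id
    order = np.argsort(hashtag_counts.columns)
    counts = counts[:, order]
    names = hashtag_counts.columns.to_numpy()[order]

    top_idx = counts.argmax(axis=1)  # first (lowest-index) maximum
    top = counts[np.arange(len(counts)), top_idx]
    masked = counts.copy()
    masked[np.arange(len(counts)), top_idx] = -1
    second = masked.max(axis=1)
    second = np.maximum(second, 0)

    assignable = (top >= min_count) & (top > ratio * second)
    labels = np.where(assignable, names[top_idx], "unassigned").astype(object)

    if doublet_flags is not None:
        flags = np.asarray(doublet_flags, dtype=bool)
        labels[flags] = "doublet"
    elif naive_doublet_detection:
        naive = (top >= min_count) & (second >= min_count) & (top <= ratio * second)
        labels[naive] = "doublet"

    return pd.DataFrame(
        {"label": labels, "top_count": top, "second_count": second},
        index=hashtag_counts.index,
    )


def qc_filter_cite(
    records: pd.DataFrame,
    rna_min: int = 500,
    mito_max: float = 0.10,
    adt_min: int = 500,
    isotype_max: int = 1,
) -> tuple[set, pd.DataFrame]:
    """Apply the CITE-seq droplet QC rules.

    ``records`` needs columns ``rna_counts``, ``mito_fraction``,
    ``adt_counts`` and ``isotype_positive_count`` and a cell-id index.  A
    droplet is kept iff rna_counts >= ``rna_min`` AND mito_fraction <=
    ``mito_max`` AND adt_counts >= ``adt_min`` AND isotype_positive_count <=
    ``isotype_max``.  The exclusions are strict readings of "fewer than 500
    counts", "over 10% mitochondrial", and "positivity for two isotype
    controls", so boundary droplets (exactly 500 counts, exactly 10%, one
    positive isotype) pass.

    Returns the kept cell-id set and a per-cell log frame with a boolean
    ``kept`` column and one boolean column per exclusion reason.
    """
    required = {"rna_counts", "mito_fraction", "adt_counts", "isotype_positive_count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"QC records missing columns: {sorted(missing)}")
    if ((records["mito_fraction"] < 0) | (records["mito_fraction"] > 1)).any():
        raise ValueError("mito_fraction must lie in [0, 1]")

    low_rna = records["rna_counts"] < rna_min
    high_mito = records["mito_fraction"] > mito_max
    low_adt = records["adt_counts"] < adt_min
    isotype = records["isotype_positive_count"] > isotype_max
    kept = ~(low_rna | high_mito | low_adt | isotype)
    log = pd.DataFrame(
        {
            "kept": kept,
            "low_rna": low_rna,
            "high_mito": high_mito,
            "low_adt": low_adt,
            "isotype_positive": isotype,
        },
        index=records.index,
    )
    return set(records.index[kept]), log


def qc_filter_spatial(expression: ad.AnnData, min_counts: int = 10) -> set:
    """Keep cells whose total transcript count is at least ``min_counts``.

    Implements the imaging spatial-transcriptomics QC rule of removing cells
    with fewer than 10 transcripts.
    """
    totals = np.asarray(expression.X.sum(axis=1)).ravel()
    if (totals < 0).any():
        raise ValueError("counts must be nonnegative")
    return set(expression.obs_names[totals >= min_counts])
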