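"""Hashtag demultiplexing and quality-control filtering.

The nucleus filters implement the stated raw-count rules with their literal
boundary semantics: keep a nucleus iff it expresses at least
``min_genes_per_nucleus`` genes, its mitochondrial count fraction does not
exceed ``max_mito_fraction`` (strictly-more is removed), its summed hashtag
counts do not exceed ``max_hashtag_counts`` and its raw TDP-43 antibody
counts do not exceed ``max_tdp43_counts``. Gene filtering (detected in at
least ``min_nuclei_per_gene`` nuclei) applies after nucleus filtering.

The demultiplexer is a deliberately simple ratio rule — a documented
stand-in for model-based hashtag deconvolution (DemuxEM-style ambient
modelling is out of scope): a nucleus is assigned its top hashtag when the
top count clears an absolute floor and dominates the runner-up by a
configurable ratio; otherwise it is ``negative`` or ``ambiguous``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    GeneCountMatrix,
    ProteinCaptureMatrix,
    QCThresholds,
)

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
NEGATIVE = "negative"


def demultiplex_hashes(
    adt: ProteinCaptureMatrix,
    min_top_counts: float = 50,
    min_ratio: float = 3.0,
) -> pd.DataFrame:
    """Assign each nucleus to a hashtag, or to ``ambiguous``/``negative``.

    Returns a frame indexed by nucleus with columns ``assignment``,
    ``top_hash``, ``top_counts`` and ``ratio`` (top/runner-up counts;
    infinite when the runner-up is zero).
    """
    hashes = adt.hashtag_names
    if len(hashes) < 2:
        raise ConfigurationError("demultiplexing needs >= 2 hashtag antibodies")
    counts = adt.columns(hashes).astype(float)
    order = np.argsort(counts, axis=1)
    top_idx = order[:, -1]
    top = counts[np.arange(len(counts)), top_idx]
    second = counts[np.arange(len(counts)), order[:, -2]]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, top / np.maximum(second, 1e-300), np.inf)
    ratio = np.where(top == 0, 1.0, ratio)  # all-zero nucleus: no dominance

    assignment = np.array([hashes[i] for i in top_idx], dtype=object)
    assignment[ratio < min_ratio] = AMBIGUOUS
    assignment[top < min_top_counts] = NEGATIVE
    return pd.DataFrame(
        {
            "assignment": assignment,
            "top_hash": [hashes[i] for i in top_idx],
            "top_counts": top,
            "ratio": ratio,
        },
        index=pd.Index(adt.nucleus_ids, name="nucleus_id"),
    )


def mito_fraction(gex: GeneCountMatrix, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-nucleus fraction of counts mapping to mitochondrial genes."""
    is_mito = np.array([g.startswith(mito_prefix) for g in gex.gene_names])
    total = np.asarray(gex.values.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(gex.values[:, np.flatnonzero(is_mito)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_nuclei(
    gex: GeneCountMatrix,
    adt: ProteinCaptureMatrix,
    meta: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
):
    """Apply the nucleus-level QC rules.

    Returns ``(gex, adt, meta, report)`` where ``report`` gives the number
    of nuclei failing each rule (a nucleus may count toward several) and the
    kept total.
    """
    n = gex.n_nuclei
    genes_detected = np.asarray((gex.values > 0).sum(axis=1)).ravel()
    keep_genes = genes_detected >= thresholds.min_genes_per_nucleus

    mito = mito_fraction(gex, thresholds.mito_prefix)
    keep_mito = mito <= thresholds.max_mito_fraction  # "more than" is removed

    hash_total = adt.columns(adt.hashtag_names).sum(axis=1)
    keep_hash = hash_total <= thresholds.max_hashtag_counts

    if thresholds.tdp43_antibody in adt.antibody_names:
        tdp = adt.columns([thresholds.tdp43_antibody]).ravel()
        keep_tdp = tdp <= thresholds.max_tdp43_counts
    else:
        logger.warning(
            "TDP-43 antibody %r absent from panel; ceiling rule skipped",
            thresholds.tdp43_antibody,
        )
        keep_tdp = np.ones(n, dtype=bool)

    keep = keep_genes & keep_mito & keep_hash & keep_tdp
    report = {
        "n_input": int(n),
        "removed_low_genes": int((~keep_genes).sum()),
        "removed_high_mito": int((~keep_mito).sum()),
        "removed_high_hashtag": int((~keep_hash).sum()),
        "removed_high_tdp43": int((~keep_tdp).sum()),
        "n_kept": int(keep.sum()),
    }
    idx = np.flatnonzero(keep)
    return gex.take_nuclei(idx), adt.take_nuclei(idx), meta.iloc[idx], report


def filter_genes(
    gex: GeneCountMatrix, thresholds: QCThresholds = QCThresholds()
) -> GeneCountMatrix:
    """Keep genes detected (count > 0) in at least ``min_nuclei_per_gene`` nuclei."""
    detected_in = np.asarray((gex.values > 0).sum(axis=0)).ravel()
    return gex.take_genes(np.flatnonzero(detected_in >= thresholds.min_nuclei_per_gene))


def flag_doublet_heuristic(
    adt: ProteinCaptureMatrix,
    demux: pd.DataFrame,
    total_counts: np.ndarray,
    pct: float = 99.0,
) -> np.ndarray:
    """Optional plumbing heuristic: ambiguous hashtag AND extreme total counts.

    Not equivalent to transcriptome-based doublet detection; synthetic
    cohorts carry ground-truth doublet flags which the pipeline honours by
    default.
    """
    cut = np.percentile(total_counts, pct)
    return (demux["assignment"].to_numpy() == AMBIGUOUS) & (total_counts > cut)


def drop_nuclei(gex, adt, meta, drop_mask: np.ndarray):
    """Remove nuclei flagged in ``drop_mask`` from all three containers."""
    idx = np.flatnonzero(~np.asarray(drop_mask))
    return gex.take_nuclei(idx), adt.take_nuclei(idx), meta.iloc[idx]
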