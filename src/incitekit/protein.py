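"""Nuclear protein quantification: H3 normalization, nCLR, strata, density.

Antibody capture counts are first divided by the same nucleus's histone-H3
counts (``h3_ratio``) to control for antibody access to the nuclear
compartment, then transformed to centered natural log ratios (``nclr``):
each target's log ratio to the per-nucleus geometric mean across the target
panel (hashtags and the normalizer are excluded from the panel). The nCLR
of a nucleus therefore sums to zero across targets, and both quantities are
invariant to scaling the nucleus's whole antibody vector (capture depth).

Because nCLR components are linearly dependent, pairwise protein-vs-protein
analyses (the stoichiometry module) default to the per-protein additive
log-ratio ln(target/H3) provided here as :func:`log_h3_ratio`; nCLR is the
scale for stratification, quintiles and embedding-density visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .datatypes import ProteinCaptureMatrix

#: percentile strata used throughout: highest / high / low nuclei, plus the
#: top quartile used by the stoichiometry analysis. Bins are (lo, hi]
#: percentile intervals (the bottom bin includes 0).
TOP10_MID_BOTTOM = {"top10": (90, 100), "mid10_25": (75, 90), "bottom25": (0, 25)}
TOP25_BOTTOM10 = {"top25": (75, 100), "bottom10": (0, 10)}
QUINTILES = {f"Q{i + 1}": (20 * i, 20 * (i + 1)) for i in range(5)}
UNASSIGNED = "unassigned"


@dataclass
class NormalizedProteinMatrix:
    """Per-nucleus H3-ratio, nCLR and log-H3 values for each target."""

    h3_ratio: pd.DataFrame
    nclr: pd.DataFrame
    log_h3: pd.DataFrame
    dropped_h3_zero: list[str]


def normalize_to_h3(adt: ProteinCaptureMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Divide each target's counts by the nucleus's H3 counts.

    Nuclei with zero H3 counts cannot be normalized; they are dropped from
    the protein analyses (their ids are returned so the caller can keep
    them for RNA analyses) with a logged count.
    """
    normalizer = adt.normalizer_names[0]
    h3 = adt.columns([normalizer]).ravel().astype(float)
    targets = adt.target_names
    counts = adt.columns(targets).astype(float)
    ok = h3 > 0
    dropped = [adt.nucleus_ids[i] for i in np.flatnonzero(~ok)]
    if dropped:
        warnings.warn(f"{len(dropped)} nuclei with zero H3 counts dropped")
    ratio = counts[ok] / h3[ok][:, None]
    index = pd.Index(
        [adt.nucleus_ids[i] for i in np.flatnonzero(ok)], name="nucleus_id"
    )
    return pd.DataFrame(ratio, index=index, columns=targets), dropped


def clr_transform(h3_ratio: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio across the target panel.

    ``nclr_ij = ln((x_ij + eps) / gmean_j(x_ij + eps))``; each nucleus's
    values sum to zero across targets by construction.
    """
    if h3_ratio.shape[1] < 2:
        raise ValueError("CLR is undefined for a single-target panel")
    x = h3_ratio.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("nonpositive values after pseudocount; increase it")
    logx = np.log(x)
    return pd.DataFrame(
        logx - logx.mean(axis=1, keepdims=True),
        index=h3_ratio.index,
        columns=h3_ratio.columns,
    )


def log_h3_ratio(h3_ratio: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Per-protein additive log-ratio ln(target/H3 + eps)."""
    return np.log(h3_ratio + pseudocount)


def quantify(adt: ProteinCaptureMatrix, pseudocount: float = 1e-6) -> NormalizedProteinMatrix:
    """H3-normalize and transform in one step."""
    ratio, dropped = normalize_to_h3(adt)
    return NormalizedProteinMatrix(
        h3_ratio=ratio,
        nclr=clr_transform(ratio, pseudocount),
        log_h3=log_h3_ratio(ratio, pseudocount),
        dropped_h3_zero=dropped,
    )


def percentile_ranks(values: pd.Series) -> pd.Series:
    """Percentile of each nucleus in (0, 100], ties broken by stable order.

    Ordinal (first-come) ranks keep bin occupancies at their nominal widths
    even under ties; a warning is emitted when ties straddle work because
    equal values may then land in different bins.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty population")
    if len(np.unique(v)) < len(v):
        warnings.warn("ties in protein values resolved by stable ordinal ranks")
    ranks = st.rankdata(v, method="ordinal")
    return pd.Series(100.0 * ranks / len(v), index=values.index)


def stratify(
    nclr: pd.DataFrame,
    protein: str,
    scheme: dict[str, tuple[float, float]] = TOP10_MID_BOTTOM,
) -> pd.Series:
    """Label each nucleus with its percentile stratum for one protein.

    Percentiles are computed over the supplied population (pool the nuclei
    of the cell type under analysis before calling, or pass per-donor
    slices for donor-wise referencing). Bins are (lo, hi] with the bottom
    bin closed at 0; nuclei outside every bin are ``unassigned``.
    """
    if protein not in nclr.columns:
        raise KeyError(f"protein {protein!r} not in panel {list(nclr.columns)}")
    pct = percentile_ranks(nclr[protein])
    labels = pd.Series(UNASSIGNED, index=nclr.index, dtype=object, name="stratum")
    for name, (lo, hi) in scheme.items():
        sel = (pct > lo) & (pct <= hi) if lo > 0 else (pct <= hi)
        labels[sel] = name
    return labels


def quintile_labels(nclr: pd.DataFrame, protein: str) -> pd.Series:
    """Equal-frequency quintile (Q1 lowest ... Q5 highest) per nucleus."""
    return stratify(nclr, protein, QUINTILES).rename("quintile")


def embedding_density(
    embedding: np.ndarray,
    stratum_mask: np.ndarray,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Relative density of a stratum over the 2-D embedding.

    Gaussian kernel sum over stratum members, ``sum_m exp(-d^2 / (2 h^2))``,
    evaluated at every nucleus and normalized to [0, 1] by its maximum.
    ``bandwidth=None`` uses Scott's rule on the stratum members
    (``h = n^(-1/6) * rms standard deviation``); pass a fixed bandwidth for
    exact reproducibility across strata.
    """
    emb = np.asarray(embedding, dtype=float)
    mask = np.asarray(stratum_mask, dtype=bool)
    members = emb[mask]
    if len(members) == 0:
        raise ValueError("stratum is empty")
    if len(members) == 1:
        warnings.warn("stratum of size 1: density is a single kernel peak")
    dens = _kernel_sum(emb, members, bandwidth)
    return dens / dens.max()


def _kernel_sum(emb: np.ndarray, members: np.ndarray,
                bandwidth: float | None) -> np.ndarray:
    if bandwidth is None:
        bandwidth = 1.0
        if len(members) > 1:
            scott = len(members) ** (-1 / 6) * float(
                np.sqrt(members.var(axis=0, ddof=1).mean())
            )
            if scott > 0:
                bandwidth = scott
    d2 = ((emb[:, None, :] - members[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2 * bandwidth**2)).sum(axis=1)


def embedding_density_ratio(
    embedding: np.ndarray,
    stratum_mask: np.ndarray,
    bandwidth: float = 1.0,
) -> np.ndarray:
    """Stratum density relative to the overall embedding density.

    The alternative normalization mode: the per-member mean kernel density
    of the stratum divided by that of the full population (same fixed
    bandwidth for both), so a uniformly sampled stratum scores ~1
    everywhere.
    """
    emb = np.asarray(embedding, dtype=float)
    mask = np.asarray(stratum_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("stratum is empty")
    num = _kernel_sum(emb, emb[mask], bandwidth) / mask.sum()
    den = _kernel_sum(emb, emb, bandwidth) / len(emb)
    return num / den
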