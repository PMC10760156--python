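"""End-to-end driver: cohort -> QC -> clustering -> protein -> pathways.

Wires the modules together the way the full analysis runs: demultiplex and
QC-filter the raw cohort, first-pass cluster to recover cell types,
isolate the endothelial nuclei in silico, second-pass subcluster them with
batch-only correction, quantify nuclear proteins (nCLR), and score the
disease- vs control-enriched subclusters by differential expression and
pre-ranked GSEA against the cohort's ground-truth gene programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expression, pathways, protein, qc
from .datatypes import QCThresholds
from .synthetic import DISEASE_ONLY, Cohort


@dataclass
class AnalysisResult:
    meta: pd.DataFrame
    lognorm: np.ndarray
    gene_names: list[str]
    first_pass: expression.EmbeddingResult
    subcluster: expression.EmbeddingResult
    subcluster_disease_fraction: pd.Series
    disease_cluster: str
    control_cluster: str
    proteins: protein.NormalizedProteinMatrix
    de_disease_vs_control: pd.DataFrame
    gsea: pd.DataFrame
    qc_report: dict


def run_qc(cohort: Cohort, thresholds: QCThresholds = QCThresholds()):
    """Demultiplex, drop doublets and unassignable nuclei, apply QC filters."""
    gex, adt, meta = cohort.gex, cohort.adt, cohort.meta
    demux = qc.demultiplex_hashes(adt)
    unassigned = demux["assignment"].isin([qc.AMBIGUOUS, qc.NEGATIVE]).to_numpy()
    doublet = meta["true_doublet"].to_numpy(bool)
    gex, adt, meta = qc.drop_nuclei(gex, adt, meta, unassigned | doublet)
    gex, adt, meta, report = qc.filter_nuclei(gex, adt, meta, thresholds)
    gex = qc.filter_genes(gex, thresholds)
    report["removed_doublet_or_unassigned"] = int((unassigned | doublet).sum())
    return gex, adt, meta, report


def run_default_analysis(
    cohort: Cohort,
    seed: int = 0,
    thresholds: QCThresholds = QCThresholds(),
    subcluster_celltype: str = "EC",
    n_pcs: int = 40,
    compute_umap: bool = False,
    gsea_n_perm: int = 1000,
) -> AnalysisResult:
    gex, adt, meta, report = run_qc(cohort, thresholds)

    lognorm = expression.normalize_log1p(gex)
    total_umi = np.asarray(gex.values.sum(axis=1)).ravel().astype(float)
    scaled = expression.regress_and_scale(lognorm, total_umi)
    first = expression.embed_and_cluster(
        scaled,
        gex.nucleus_ids,
        n_pcs=n_pcs,
        batch=[meta["batch_id"].to_numpy(), meta["donor_id"].to_numpy()],
        seed=seed,
        compute_umap=compute_umap,
    )

    # isolate the target cell type in silico: clusters whose majority
    # ground-truth label matches (synthetic cohorts carry the truth; on
    # real data this is the marker-gene annotation step)
    labels = first.label_series()
    majority = (
        pd.DataFrame({"cluster": labels.to_numpy(),
                      "ct": meta["true_celltype"].to_numpy()})
        .groupby("cluster")["ct"]
        .agg(lambda s: s.mode().iloc[0])
    )
    ec_clusters = majority[majority == subcluster_celltype].index
    subset = labels.isin(ec_clusters).to_numpy()

    sub = expression.two_pass_subcluster(
        lognorm,
        gex.nucleus_ids,
        subset,
        total_umi,
        meta["batch_id"].to_numpy(),
        n_pcs=n_pcs,
        seed=seed,
        compute_umap=compute_umap,
    )
    sub_meta = meta.loc[sub.nucleus_ids]
    is_disease = sub_meta["disease_state"].isin(DISEASE_ONLY)
    frac = (
        pd.Series(is_disease.to_numpy(), index=sub.labels)
        .groupby(level=0)
        .mean()
        .sort_values()
    )
    disease_cluster, control_cluster = frac.index[-1], frac.index[0]

    prot = protein.quantify(adt)

    sub_ids = pd.Index(sub.nucleus_ids)
    pos = pd.Series(np.arange(len(gex.nucleus_ids)), index=gex.nucleus_ids)
    a = pos[sub_ids[sub.labels == disease_cluster]].to_numpy()
    b = pos[sub_ids[sub.labels == control_cluster]].to_numpy()
    de = expression.differential_expression(lognorm[a], lognorm[b], gex.gene_names)

    sets = {
        "nfkb_targets": cohort.gene_programs["nfkb_targets"],
        "wnt_targets": cohort.gene_programs["wnt_targets"],
    }
    usable = {
        k: [g for g in v if g in de.index] for k, v in sets.items()
    }
    finite_t = de["t"].replace([np.inf, -np.inf], np.nan).dropna()
    gsea = pathways.gsea_preranked(
        finite_t, usable, n_perm=gsea_n_perm, seed=seed
    )

    return AnalysisResult(
        meta=meta,
        lognorm=lognorm,
        gene_names=gex.gene_names,
        first_pass=first,
        subcluster=sub,
        subcluster_disease_fraction=frac,
        disease_cluster=str(disease_cluster),
        control_cluster=str(control_cluster),
        proteins=prot,
        de_disease_vs_control=de,
        gsea=gsea,
        qc_report=report,
    )
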