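"""Reading and writing the standard on-disk formats.

Cohorts are written 10x-style: one Matrix Market triplet file holding both
feature types (features x barcodes, 1-based indices on disk per the Matrix
Market standard), a ``features.tsv`` with a ``feature_type`` column
distinguishing ``Gene Expression`` from ``Antibody Capture`` rows (plus an
``antibody_role`` column for the capture panel), a ``barcodes.tsv``, a
metadata CSV and a ground-truth JSON for synthetic cohorts. Gene-set
collections use the GMT convention (one set per line: name, description,
members, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datatypes import (
    FormatError,
    GeneCountMatrix,
    ProteinCaptureMatrix,
    check_metadata,
)
from .synthetic import Cohort

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
METADATA_FILE = "metadata.csv"
GROUND_TRUTH_FILE = "ground_truth.json"


def write_counts(path, gex: GeneCountMatrix, adt: ProteinCaptureMatrix) -> None:
    """Write the joint counts as a 10x-style feature-barcode directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if gex.nucleus_ids != adt.nucleus_ids:
        raise FormatError("RNA and antibody matrices have different barcodes")

    features = pd.DataFrame(
        {
            "feature_id": gex.gene_names + adt.antibody_names,
            "feature_name": gex.gene_names + adt.antibody_names,
            "feature_type": [GENE_EXPRESSION] * gex.n_genes
            + [ANTIBODY_CAPTURE] * len(adt.antibody_names),
            "antibody_role": [""] * gex.n_genes
            + [adt.roles[a] for a in adt.antibody_names],
        }
    )
    features.to_csv(path / FEATURES_FILE, sep="\t", header=False, index=False)
    pd.Series(gex.nucleus_ids).to_csv(
        path / BARCODES_FILE, sep="\t", header=False, index=False
    )
    stacked = sp.vstack([gex.values.T.tocsr(), adt.values.T.tocsr()]).tocoo()
    mmwrite(path / MATRIX_FILE, stacked, field="integer")


def read_counts(path) -> tuple[GeneCountMatrix, ProteinCaptureMatrix]:
    """Read a feature-barcode directory back into the count containers."""
    path = Path(path)
    features = pd.read_csv(
        path / FEATURES_FILE,
        sep="\t",
        header=None,
        names=["feature_id", "feature_name", "feature_type", "antibody_role"],
        keep_default_na=False,
    )
    barcodes = pd.read_csv(
        path / BARCODES_FILE, sep="\t", header=None
    )[0].astype(str).tolist() if (path / BARCODES_FILE).stat().st_size else []
    mat = sp.csr_matrix(mmread(path / MATRIX_FILE))
    if mat.shape[0] != len(features) or mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix {mat.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    cells = mat.T.tocsr()  # nuclei x features
    is_gene = (features["feature_type"] == GENE_EXPRESSION).to_numpy()
    is_ab = (features["feature_type"] == ANTIBODY_CAPTURE).to_numpy()
    gex = GeneCountMatrix(
        cells[:, np.flatnonzero(is_gene)],
        features.loc[is_gene, "feature_name"].tolist(),
        barcodes,
    )
    ab = features[is_ab]
    adt = ProteinCaptureMatrix(
        cells[:, np.flatnonzero(is_ab)],
        ab["feature_name"].tolist(),
        dict(zip(ab["feature_name"], ab["antibody_role"])),
        barcodes,
    )
    return gex, adt


def write_cohort(path, cohort: Cohort) -> None:
    """Write a full synthetic cohort (counts, metadata, ground truth)."""
    path = Path(path)
    write_counts(path, cohort.gex, cohort.adt)
    cohort.meta.to_csv(path / METADATA_FILE)
    truth = {"gene_programs": cohort.gene_programs}
    (path / GROUND_TRUTH_FILE).write_text(json.dumps(truth, indent=1))


def read_cohort(path):
    """Read back ``(gex, adt, meta, gene_programs)`` from :func:`write_cohort`."""
    path = Path(path)
    gex, adt = read_counts(path)
    meta = pd.read_csv(path / METADATA_FILE, index_col=0)
    check_metadata(meta)
    programs = json.loads((path / GROUND_TRUTH_FILE).read_text())["gene_programs"]
    return gex, adt, meta, programs


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with <3 fields: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path, gene_sets: dict[str, list[str]],
              descriptions: dict[str, str] | None = None) -> None:
    lines = [
        "\t".join([name, (descriptions or {}).get(name, "na"), *members])
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
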