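"""Core in-memory containers for joint nuclear-protein / transcript data.

The package works on three aligned objects: a nuclei x genes integer count
matrix (RNA), a nuclei x antibodies integer count matrix (antibody capture,
whose panel mixes measurement targets, one normalizer and donor hashtags),
and a per-nucleus metadata table. All three share nucleus order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

DISEASE_GROUPS = ("young_ctrl", "old_ctrl", "AD", "ALS", "FTD")
CONTROL_GROUPS = ("young_ctrl", "old_ctrl")

TARGET = "target"
NORMALIZER = "normalizer"
HASHTAG = "hashtag"


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk representation is internally inconsistent."""


def _as_csr(values) -> sp.csr_matrix:
    m = sp.csr_matrix(values)
    m.eliminate_zeros()
    return m


@dataclass
class GeneCountMatrix:
    """Sparse nuclei x genes nonnegative integer RNA counts."""

    values: sp.csr_matrix
    gene_names: list[str]
    nucleus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values)
        self.gene_names = list(self.gene_names)
        self.nucleus_ids = list(self.nucleus_ids)
        n, g = self.values.shape
        if n != len(self.nucleus_ids) or g != len(self.gene_names):
            raise FormatError(
                f"count matrix {self.values.shape} inconsistent with "
                f"{len(self.nucleus_ids)} nuclei / {len(self.gene_names)} genes"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def take_nuclei(self, index) -> "GeneCountMatrix":
        index = np.asarray(index)
        return GeneCountMatrix(
            self.values[index],
            self.gene_names,
            [self.nucleus_ids[i] for i in index],
        )

    def take_genes(self, index) -> "GeneCountMatrix":
        index = np.asarray(index)
        return GeneCountMatrix(
            self.values[:, index],
            [self.gene_names[i] for i in index],
            self.nucleus_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.nucleus_ids, columns=self.gene_names
        )


@dataclass
class ProteinCaptureMatrix:
    """Nuclei x antibodies nonnegative integer capture counts.

    ``roles`` maps each antibody to one of ``target`` (a measured nuclear
    protein), ``normalizer`` (the histone-H3 loading control; exactly one) or
    ``hashtag`` (a donor-identifying tag).
    """

    values: sp.csr_matrix
    antibody_names: list[str]
    roles: dict[str, str]
    nucleus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values)
        self.antibody_names = list(self.antibody_names)
        self.nucleus_ids = list(self.nucleus_ids)
        if set(self.roles) != set(self.antibody_names):
            raise FormatError("roles must cover exactly the antibody panel")
        bad = set(self.roles.values()) - {TARGET, NORMALIZER, HASHTAG}
        if bad:
            raise FormatError(f"unknown antibody roles: {sorted(bad)}")
        if len(self.normalizer_names) != 1:
            raise FormatError("panel must contain exactly one normalizer antibody")
        if not self.target_names:
            raise FormatError("panel must contain at least one target antibody")
        n, a = self.values.shape
        if n != len(self.nucleus_ids) or a != len(self.antibody_names):
            raise FormatError("antibody matrix shape inconsistent with names")

    def _names_with_role(self, role: str) -> list[str]:
        return [a for a in self.antibody_names if self.roles[a] == role]

    @property
    def target_names(self) -> list[str]:
        return self._names_with_role(TARGET)

    @property
    def normalizer_names(self) -> list[str]:
        return self._names_with_role(NORMALIZER)

    @property
    def hashtag_names(self) -> list[str]:
        return self._names_with_role(HASHTAG)

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """Dense counts for the given antibodies, in the given order."""
        idx = [self.antibody_names.index(n) for n in names]
        return np.asarray(self.values[:, idx].todense())

    def take_nuclei(self, index) -> "ProteinCaptureMatrix":
        index = np.asarray(index)
        return ProteinCaptureMatrix(
            self.values[index],
            self.antibody_names,
            dict(self.roles),
            [self.nucleus_ids[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.nucleus_ids, columns=self.antibody_names
        )


#: Metadata columns every cohort carries. Ground-truth columns (``true_*``)
#: exist only for synthetic cohorts.
METADATA_COLUMNS = (
    "donor_id",
    "disease_state",
    "donor_age",
    "batch_id",
)


def check_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta.index.has_duplicates:
        raise FormatError("nucleus_id index has duplicates")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    bad = set(meta["disease_state"]) - set(DISEASE_GROUPS)
    if bad:
        raise FormatError(f"unknown disease states: {sorted(bad)}")
    return meta


@dataclass
class QCThresholds:
    """Nucleus- and gene-level QC cut-offs.

    Boundary semantics are read literally from the stated rules: a nucleus
    must express *at least* ``min_genes_per_nucleus`` genes (inclusive), is
    excluded for *more than* ``max_mito_fraction`` mitochondrial content
    (strict), for hashtag counts *exceeding* ``max_hashtag_counts`` (strict)
    and for TDP-43 antibody counts *above* ``max_tdp43_counts`` (strict);
    a gene must be detected in a *minimum of* ``min_nuclei_per_gene`` nuclei
    (inclusive).
    """

    min_genes_per_nucleus: int = 50
    min_nuclei_per_gene: int = 5
    max_mito_fraction: float = 0.05
    max_hashtag_counts: float = 4000
    max_tdp43_counts: float = 3000
    tdp43_antibody: str = "TDP43"
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        for name in (
            "min_genes_per_nucleus",
            "min_nuclei_per_gene",
            "max_hashtag_counts",
            "max_tdp43_counts",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ConfigurationError("max_mito_fraction must lie in [0, 1]")
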