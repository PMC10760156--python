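"""Synthetic multiplexed single-nucleus cohorts with protein capture.

The generator emulates the statistical structure of a hashed, cell-type
sorted snRNA-seq experiment with intranuclear antibody capture across five
donor groups (young and aged cognitively-normal controls, AD, ALS, FTD):

* RNA counts are negative binomial around cell-type signatures, with
  mitochondrial genes, per-nucleus library sizes, and ground-truth gene
  programs (NF-kB targets, Wnt targets, DAM and homeostatic microglial
  markers) whose activity shifts with the simulated disease biology.
* Nuclear protein levels (p65/NF-kB, beta-Catenin, TDP-43) live on a
  natural-log latent scale. TDP-43 is coupled to NF-kB
  (``tdp43 = intercept + coupling_slope * nfkb + noise``); in disease-group
  nuclei whose NF-kB exceeds the ``decoupling_percentile`` of their donor's
  distribution, ``decoupling_delta`` (<= 0) is added, reproducing the
  stoichiometric breakdown at the top of the NF-kB range.
* Antibody capture counts are Poisson around ``depth * scale * exp(latent)``
  with a shared per-nucleus capture depth, so the histone-H3 normalizer
  cancels depth exactly in expectation.
* A fraction of disease-donor endothelial nuclei enter a "disease" state:
  Wnt targets down, NF-kB targets up, and lower nuclear beta-Catenin and
  TDP-43 — the transcriptional/protein signature of the disease-enriched
  capillary subcluster. Disease-donor microglia enter a DAM-like state at a
  configurable rate.
* Each singlet carries one dominant hashtag at ``hash_signal_to_noise``
  times the ambient hashtag level; doublets are sums of two nuclei and can
  carry two strong hashtags.

Every stochastic choice flows from ``CohortConfig.seed``; identical configs
give byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    CONTROL_GROUPS,
    DISEASE_GROUPS,
    HASHTAG,
    NORMALIZER,
    TARGET,
    ConfigurationError,
    GeneCountMatrix,
    ProteinCaptureMatrix,
    check_metadata,
)

DISEASE_ONLY = ("AD", "ALS", "FTD")

#: age ranges (years) per group; controls follow the cohort description
#: (15-29 young, 67-95 aged), disease donors share the aged range.
AGE_RANGES = {
    "young_ctrl": (15, 29),
    "old_ctrl": (67, 95),
    "AD": (67, 95),
    "ALS": (55, 85),
    "FTD": (55, 85),
}

DEFAULT_CELLTYPE_FRACTIONS = {
    "EC": 0.50,
    "microglia": 0.25,
    "neuron": 0.15,
    "other": 0.10,
}

#: cell-type mean shift of the latent NF-kB level (log scale); microglia run
#: higher (inflammatory signalling), neurons lower.
NFKB_CELLTYPE_SHIFT = {"EC": 0.0, "microglia": 0.3, "neuron": -0.2, "other": 0.0}


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Size parameters are deliberately desk-scale; the statistical structure,
    not the magnitude, is what downstream analyses consume.
    """

    n_donors_per_group: int = 3
    nuclei_per_donor: int = 300
    celltype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_FRACTIONS)
    )
    n_genes: int = 400
    mito_gene_fraction: float = 0.03
    mito_expression_fraction: float = 0.02
    doublet_rate: float = 0.05
    hash_signal_to_noise: float = 20.0
    protein_panel: tuple[str, ...] = ("NFkB", "bCatenin", "TDP43")
    normalizer_name: str = "H3"
    # latent protein model (natural-log scale)
    coupling_intercept: float = 0.0
    coupling_slope: float = 0.8
    coupling_noise_sd: float = 0.3
    nfkb_sd: float = 0.5
    bcatenin_sd: float = 0.4
    donor_effect_sd: float = 0.05
    decoupling_delta: float = -0.5
    decoupling_percentile: float = 75.0
    # disease-state program effects (natural-log fold)
    target_program_effect: float = 1.0
    wnt_program_effect: float = -1.0
    dam_program_effect: float = 1.0
    disease_ec_state_fraction: float = 0.6
    bcatenin_state_delta: float = -0.5
    tdp43_state_delta: float = -0.5
    dam_state_fraction: dict[str, float] = field(
        default_factory=lambda: {"young_ctrl": 0.05, "old_ctrl": 0.2,
                                 "AD": 0.6, "ALS": 0.6, "FTD": 0.6}
    )
    # count model
    nb_dispersion: float = 10.0
    mean_umi: float = 2000.0
    library_sd: float = 0.35
    mito_spread_sd: float = 0.5
    antibody_scale: float = 300.0
    h3_scale: float = 1000.0
    capture_depth_sd: float = 0.3
    hash_ambient_mean: float = 10.0
    donors_per_batch: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.celltype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"celltype_fractions sum to {total}, expected 1"
            )
        if any(f < 0 for f in self.celltype_fractions.values()):
            raise ConfigurationError("celltype_fractions must be nonnegative")
        for name in ("n_donors_per_group", "nuclei_per_donor", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.doublet_rate < 0.5:
            raise ConfigurationError("doublet_rate must lie in [0, 0.5)")
        if self.hash_signal_to_noise <= 0:
            raise ConfigurationError("hash_signal_to_noise must be positive")
        if self.decoupling_delta > 0:
            raise ConfigurationError("decoupling_delta must be <= 0")
        if not 0 < self.decoupling_percentile < 100:
            raise ConfigurationError("decoupling_percentile must lie in (0, 100)")
        if len(self.protein_panel) < 2:
            raise ConfigurationError("protein panel needs >= 2 targets for CLR")


def celltype_cohort_config(**overrides) -> CohortConfig:
    """A cohort with all disease effects switched off.

    Cell-type structure is the only signal; used to measure clustering
    fidelity against ground-truth labels without within-type substructure.
    """
    base = dict(
        decoupling_delta=0.0,
        target_program_effect=0.0,
        wnt_program_effect=0.0,
        dam_program_effect=0.0,
        disease_ec_state_fraction=0.0,
        bcatenin_state_delta=0.0,
        tdp43_state_delta=0.0,
        dam_state_fraction={g: 0.0 for g in DISEASE_GROUPS},
    )
    base.update(overrides)
    return CohortConfig(**base)


def stoichiometry_cohort_config(decoupling_delta: float = -0.5,
                                **overrides) -> CohortConfig:
    """A protein-focused cohort isolating the NF-kB/TDP-43 decoupling.

    The decoupling shift is the *only* disease effect on TDP-43 (the
    disease-state protein deltas are off), so the decoupling statistic's
    estimand equals the injected parameter. RNA is kept minimal: these
    cohorts exist to validate the stoichiometry estimator.
    """
    base = dict(
        decoupling_delta=decoupling_delta,
        disease_ec_state_fraction=0.0,
        bcatenin_state_delta=0.0,
        tdp43_state_delta=0.0,
        target_program_effect=0.0,
        wnt_program_effect=0.0,
        dam_program_effect=0.0,
        n_genes=40,
        mean_umi=300.0,
        doublet_rate=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class Cohort:
    """A generated cohort: counts, antibody capture, metadata, ground truth.

    Iterates as the ``(gex, adt, meta)`` triple for convenience.
    """

    gex: GeneCountMatrix
    adt: ProteinCaptureMatrix
    meta: pd.DataFrame
    gene_programs: dict[str, list[str]]
    config: CohortConfig

    def __iter__(self):
        return iter((self.gex, self.adt, self.meta))


def _donor_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in DISEASE_GROUPS:
        lo, hi = AGE_RANGES[group]
        for d in range(config.n_donors_per_group):
            rows.append(
                {
                    "donor_id": f"{group}_d{d + 1:02d}",
                    "disease_state": group,
                    "donor_age": int(rng.integers(lo, hi + 1)),
                }
            )
    donors = pd.DataFrame(rows)
    # interleave groups so every 10x well mixes controls with disease donors
    donors = (
        donors.assign(_rank=donors.groupby("disease_state").cumcount())
        .sort_values(["_rank", "disease_state"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    donors["batch_id"] = [
        f"well{i // config.donors_per_batch + 1}" for i in range(len(donors))
    ]
    donors["hashtag"] = [
        f"Hash{i % config.donors_per_batch + 1}" for i in range(len(donors))
    ]
    return donors


def _gene_panel(config: CohortConfig, rng: np.random.Generator):
    """Gene names, base relative-expression weights and program index sets."""
    g = config.n_genes
    n_mito = max(1, int(round(config.mito_gene_fraction * g)))
    celltypes = list(config.celltype_fractions)

    blocks: dict[str, np.ndarray] = {}
    cursor = n_mito
    n_marker = min(25, max(5, (g - n_mito) // (len(celltypes) + 4) - 2))

    def take(k):
        nonlocal cursor
        idx = np.arange(cursor, min(cursor + k, g))
        cursor += len(idx)
        return idx

    for ct in celltypes:
        blocks[f"{ct}_markers"] = take(n_marker)
    blocks["nfkb_targets"] = take(n_marker)
    blocks["wnt_targets"] = take(n_marker)
    blocks["dam_markers"] = take(max(5, n_marker // 2))
    blocks["homeostatic_markers"] = take(max(5, n_marker // 2))

    names = [f"MT-{i + 1}" for i in range(n_mito)]
    names += [f"GENE{i + 1:05d}" for i in range(g - n_mito)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    weights = {ct: base.copy() for ct in celltypes}
    for ct in celltypes:
        for other in celltypes:
            w = weights[ct]
            marker_idx = blocks[f"{other}_markers"]
            w[marker_idx] = base[marker_idx] * (10.0 if other == ct else 0.2)
    # Wnt targets sit mainly in endothelium; DAM/homeostatic in microglia.
    for ct in celltypes:
        w = weights[ct]
        w[blocks["wnt_targets"]] *= 3.0 if ct == "EC" else 0.5
        w[blocks["dam_markers"]] *= 3.0 if ct == "microglia" else 0.5
        w[blocks["homeostatic_markers"]] *= 3.0 if ct == "microglia" else 0.5

    mito_idx = np.arange(n_mito)
    f = config.mito_expression_fraction
    for ct in celltypes:
        w = weights[ct]
        w[mito_idx] = 0.0
        w /= w.sum()
        w *= 1.0 - f
        w[mito_idx] = f / n_mito
    programs = {k: [names[i] for i in v] for k, v in blocks.items()}
    programs["mito_genes"] = names[:n_mito]
    return names, weights, blocks, mito_idx, programs


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort. Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    donors = _donor_table(config, rng)
    names, weights, blocks, mito_idx, programs = _gene_panel(config, rng)
    celltypes = list(config.celltype_fractions)
    fractions = np.array([config.celltype_fractions[c] for c in celltypes])

    per_donor = config.nuclei_per_donor
    n = per_donor * len(donors)

    donor_idx = np.repeat(np.arange(len(donors)), per_donor)
    meta = donors.iloc[donor_idx].reset_index(drop=True)
    meta.index = pd.Index(
        [f"N{i + 1:06d}" for i in range(n)], name="nucleus_id"
    )
    meta = meta.rename(columns={"hashtag": "true_hash"})

    ct_codes = rng.choice(len(celltypes), size=n, p=fractions)
    meta["true_celltype"] = [celltypes[c] for c in ct_codes]
    meta["true_doublet"] = False

    is_disease = meta["disease_state"].isin(DISEASE_ONLY).to_numpy()
    is_ec = meta["true_celltype"].eq("EC").to_numpy()
    is_mg = meta["true_celltype"].eq("microglia").to_numpy()

    # --- latent nuclear protein levels (natural log scale) ---------------
    donor_shift = rng.normal(0.0, config.donor_effect_sd, size=len(donors))
    ct_shift = np.array(
        [NFKB_CELLTYPE_SHIFT.get(c, 0.0) for c in celltypes]
    )[ct_codes]
    nfkb = ct_shift + donor_shift[donor_idx] + rng.normal(0, config.nfkb_sd, n)

    # disease-state endothelial nuclei (the disease-enriched subcluster)
    ec_state = np.full(n, "", dtype=object)
    ec_state[is_ec] = "healthy"
    state_draw = rng.random(n)
    in_state = is_ec & is_disease & (state_draw < config.disease_ec_state_fraction)
    ec_state[in_state] = "disease"

    dam_state = np.zeros(n, dtype=bool)
    dam_p = meta["disease_state"].map(config.dam_state_fraction).to_numpy(float)
    dam_state[is_mg] = rng.random(is_mg.sum()) < dam_p[is_mg]

    # per-donor decoupling rule on the latent NF-kB distribution
    decoupled = np.zeros(n, dtype=bool)
    for d in range(len(donors)):
        sel = donor_idx == d
        cut = np.percentile(nfkb[sel], config.decoupling_percentile)
        decoupled[sel] = nfkb[sel] > cut
    decoupled &= is_disease

    tdp43 = (
        config.coupling_intercept
        + config.coupling_slope * nfkb
        + rng.normal(0, config.coupling_noise_sd, n)
    )
    tdp43[decoupled] += config.decoupling_delta
    tdp43[in_state] += config.tdp43_state_delta

    bcat = rng.normal(0, config.bcatenin_sd, n)
    bcat[in_state] += config.bcatenin_state_delta

    latents = {"NFkB": nfkb, "bCatenin": bcat, "TDP43": tdp43}

    meta["true_nfkb_level"] = nfkb
    meta["true_tdp43_level"] = tdp43
    meta["true_bcatenin_level"] = bcat
    meta["true_decoupled"] = decoupled
    meta["true_ec_state"] = ec_state
    meta["true_dam_state"] = dam_state

    # --- RNA counts: gamma-Poisson around cell-type signatures ------------
    base_w = np.stack([weights[c] for c in celltypes])[ct_codes]  # n x g
    mult = np.ones_like(base_w)
    eff = {
        "nfkb_targets": np.where(decoupled | in_state,
                                 config.target_program_effect, 0.0),
        "wnt_targets": np.where(in_state, config.wnt_program_effect, 0.0),
        "dam_markers": np.where(dam_state, config.dam_program_effect, 0.0),
        "homeostatic_markers": np.where(dam_state,
                                        -config.dam_program_effect, 0.0),
    }
    for block, per_nucleus in eff.items():
        mult[:, blocks[block]] *= np.exp(per_nucleus)[:, None]
    mito_mult = rng.lognormal(
        -0.5 * config.mito_spread_sd**2, config.mito_spread_sd, size=n
    )
    mult[:, mito_idx] *= mito_mult[:, None]

    p = base_w * mult
    p /= p.sum(axis=1, keepdims=True)
    lib = rng.lognormal(
        math.log(config.mean_umi) - 0.5 * config.library_sd**2,
        config.library_sd,
        size=n,
    )
    mu = p * lib[:, None]
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)
    gex = GeneCountMatrix(sp.csr_matrix(counts), names, list(meta.index))

    # --- antibody capture --------------------------------------------------
    depth = rng.lognormal(-0.5 * config.capture_depth_sd**2,
                          config.capture_depth_sd, size=n)
    ab_names = list(config.protein_panel) + [config.normalizer_name]
    cols = [
        rng.poisson(depth * config.antibody_scale * np.exp(latents[t]))
        for t in config.protein_panel
    ]
    cols.append(rng.poisson(depth * config.h3_scale))
    hash_names = sorted(set(donors["hashtag"]))
    ambient = config.hash_ambient_mean
    signal = config.hash_signal_to_noise * ambient
    true_hash = meta["true_hash"].to_numpy()
    for h in hash_names:
        lam_h = np.where(true_hash == h, signal, ambient) * depth
        cols.append(rng.poisson(lam_h))
    ab_names += hash_names
    roles = {t: TARGET for t in config.protein_panel}
    roles[config.normalizer_name] = NORMALIZER
    roles.update({h: HASHTAG for h in hash_names})
    adt = ProteinCaptureMatrix(
        sp.csr_matrix(np.column_stack(cols)), ab_names, roles, list(meta.index)
    )

    check_metadata(meta)
    cohort = Cohort(gex, adt, meta, programs, config)
    if config.doublet_rate > 0:
        gex2, adt2, meta2 = inject_doublets(
            gex, adt, meta, config.doublet_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        cohort = Cohort(gex2, adt2, meta2, programs, config)
    return cohort


def inject_doublets(
    gex: GeneCountMatrix,
    adt: ProteinCaptureMatrix,
    meta: pd.DataFrame,
    rate: float,
    seed: int = 0,
):
    """Merge ``floor(rate * n)`` random nucleus pairs into doublet barcodes.

    Each doublet barcode carries the summed RNA and antibody counts of its
    two constituents (so a cross-donor doublet carries two strong hashtags),
    keeps the first constituent's metadata and is flagged ``true_doublet``.
    The output has ``n - floor(rate * n)`` barcodes.
    """
    if not 0 <= rate < 0.5:
        raise ConfigurationError("doublet rate must lie in [0, 0.5)")
    n = gex.n_nuclei
    k = int(math.floor(rate * n))
    if k == 0:
        return gex, adt, meta
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=2 * k, replace=False)
    first, second = chosen[:k], chosen[k:]
    keep = np.setdiff1d(np.arange(n), second)

    def merge(mat: sp.csr_matrix) -> sp.csr_matrix:
        out = mat.tolil(copy=True)
        out[first] = mat[first] + mat[second]
        return sp.csr_matrix(out)[keep]

    meta2 = meta.copy()
    meta2.loc[meta2.index[first], "true_doublet"] = True
    partner = pd.Series(index=meta.index, dtype=object)
    partner.iloc[first] = meta.index[second]
    meta2["true_doublet_partner"] = partner
    meta2 = meta2.iloc[keep]

    gex2 = GeneCountMatrix(merge(gex.values), gex.gene_names, list(meta2.index))
    adt2 = ProteinCaptureMatrix(
        merge(adt.values), adt.antibody_names, dict(adt.roles), list(meta2.index)
    )
    return gex2, adt2, meta2
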