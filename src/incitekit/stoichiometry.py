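"""NF-kB / TDP-43 stoichiometry: curves, strata comparisons, decoupling.

The analysis asks whether the nuclear level of one protein (TDP-43) keeps
rising proportionally with another (NF-kB) at the top of the second
protein's range, or drops away in disease. Three tools:

* :func:`stoich_curve` — per-group binned means of y over equal-frequency
  bins of x (bins computed on the pooled population so curves are
  comparable across groups).
* :func:`stratified_comparison` — one-way ANOVA with Tukey HSD of protein
  levels across disease groups within percentile strata.
* :func:`decoupling_statistic` — the explicit formalization of the
  breakdown: fit OLS of y on x over pooled control nuclei *below* the top
  stratum, then measure, per group, the mean observed-minus-predicted y in
  the top stratum (``delta``), with a bootstrap confidence interval and
  ANOVA/Tukey comparisons of the residuals across groups.

Values are expected on a per-protein log scale. The package default is
ln(target/H3) (:func:`incitekit.protein.log_h3_ratio`): centered log-ratio
components are linearly dependent across the panel, so regressing one CLR
component on another mixes in the remaining proteins through the shared
geometric mean — the classic compositional-data artifact — whereas the
additive log-ratio to the H3 reference isolates the pair under study.
Any per-nucleus value matrix (including nCLR) is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .datatypes import CONTROL_GROUPS


def significance_stars(p: float) -> str:
    """Convention: *** P<0.001, ** P<0.01, * P<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def stoich_curve(
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Binned y-vs-x relationship per group.

    Equal-frequency bin edges are computed on the pooled x so every group
    is evaluated over the same x ranges. Returns one row per (group, bin)
    with the pooled bin center, the group's mean and standard error of y,
    and the group's n in that bin.
    """
    x, y, groups = x.align(y)[0], y, groups.loc[x.index]
    xv = x.to_numpy(dtype=float)
    edges = np.quantile(xv, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_idx = np.clip(np.searchsorted(edges, xv, side="left") - 1, 0, n_bins - 1)
    centers = pd.Series(xv).groupby(bin_idx).mean()

    rows = []
    for g in pd.unique(groups):
        sel = (groups == g).to_numpy()
        if sel.sum() < 5 * n_bins:
            warnings.warn(f"group {g!r} has <5 nuclei per bin on average")
        for b in range(n_bins):
            yy = y.to_numpy(dtype=float)[sel & (bin_idx == b)]
            rows.append(
                {
                    "group": g,
                    "bin": b,
                    "bin_center": centers.get(b, np.nan),
                    "mean": yy.mean() if len(yy) else np.nan,
                    "se": yy.std(ddof=1) / np.sqrt(len(yy)) if len(yy) > 1 else np.nan,
                    "n": len(yy),
                }
            )
    return pd.DataFrame(rows)


def anova_tukey(values: pd.Series, groups: pd.Series) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F/p plus Tukey HSD pairwise table.

    Groups with fewer than 2 observations are excluded with a warning.
    Returns ``(F, p, tukey_frame)`` where the frame has one row per pair
    with the mean difference, adjusted p and significance stars.
    """
    names, samples = [], []
    for g in pd.unique(groups):
        v = values[groups == g].to_numpy(dtype=float)
        if len(v) < 2:
            warnings.warn(f"group {g!r} has <2 observations; excluded")
            continue
        names.append(g)
        samples.append(v)
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    F, p = st.f_oneway(*samples)
    hsd = st.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pij = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": samples[i].mean() - samples[j].mean(),
                    "p_adj": pij,
                    "stars": significance_stars(pij),
                }
            )
    return float(F), float(p), pd.DataFrame(rows)


def stratified_comparison(
    values: pd.Series,
    strata: pd.Series,
    groups: pd.Series,
) -> dict[str, dict]:
    """Per-stratum group means with ANOVA/Tukey across disease groups.

    ``strata`` holds stratum labels (e.g. from ``protein.stratify`` with
    the bottom10/top25 scheme); every stratum except ``unassigned`` is
    analysed. Returns ``{stratum: {means, anova_F, anova_p, tukey}}``.
    """
    out = {}
    for stratum in [s for s in pd.unique(strata) if s != "unassigned"]:
        sel = strata == stratum
        v, g = values[sel], groups[sel]
        F, p, tukey = anova_tukey(v, g)
        out[stratum] = {
            "means": v.groupby(g).mean(),
            "anova_F": F,
            "anova_p": p,
            "tukey": tukey,
        }
    return out


@dataclass
class DecouplingResult:
    """Per-group departure of y from the control-predicted level.

    ``delta[g]`` is the mean over group-g top-stratum nuclei of
    (observed y - control-fit prediction at the same x), measured relative
    to the same departure in the pooled controls; ``ci`` holds the
    percentile bootstrap interval per group.
    """

    delta: pd.Series
    ci: pd.DataFrame  # columns lo, hi
    control_fit: tuple[float, float]  # intercept, slope
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame
    n_top: pd.Series


def _top_stratum_mask(
    x: pd.Series, donors: pd.Series | None, top_pct: float, scope: str
) -> np.ndarray:
    xv = x.to_numpy(dtype=float)
    if scope == "per_donor":
        if donors is None:
            raise ValueError("per_donor scope needs donor labels")
        mask = np.zeros(len(xv), dtype=bool)
        d = donors.to_numpy()
        for donor in pd.unique(d):
            sel = d == donor
            mask[sel] = xv[sel] > np.percentile(xv[sel], top_pct)
        return mask
    if scope == "pooled":
        return xv > np.percentile(xv, top_pct)
    raise ValueError(f"unknown stratum scope {scope!r}")


def decoupling_statistic(
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series,
    donors: pd.Series | None = None,
    control_groups=CONTROL_GROUPS,
    top_pct: float = 75.0,
    guard_pct: float = 5.0,
    n_boot: int = 500,
    seed: int = 0,
    stratum_scope: str = "per_donor",
    hierarchical: bool = True,
) -> DecouplingResult:
    """Quantify the drop of y relative to x in the top x-stratum per group.

    Procedure: (1) mark each nucleus as top-stratum when its x exceeds the
    ``top_pct`` percentile (computed within its donor by default, or
    pooled); (2) fit OLS of y on x over pooled control nuclei *below* the
    stratum cut; (3) per group, delta = mean residual (observed minus
    predicted y) over its top-stratum nuclei, minus the same quantity over
    the pooled-control top stratum; (4) seeded percentile bootstrap of
    delta over nuclei (over donors, then nuclei within donor, when
    ``hierarchical``); (5) one-way ANOVA and Tukey HSD of the top-stratum
    residuals across groups.

    Two robustness devices, both disabled by setting them to zero:
    referencing each group's departure to the pooled-control departure
    cancels any shared bias of the linear control fit extrapolated into the
    top stratum (mild nonlinearity of E[y|x] under heteroscedastic counting
    noise affects every group's stratum equally, since the x-distributions
    match); and ``guard_pct`` excludes a thin band just above the stratum
    cut from the *evaluation* (not the fit), because measurement noise
    makes membership ambiguous there — nuclei near the cut are a mixture of
    truly-above and truly-below populations, diluting any shift confined to
    the top stratum.
    """
    idx = x.index
    y, groups = y.loc[idx], groups.loc[idx]
    donors = donors.loc[idx] if donors is not None else None
    is_control = groups.isin(control_groups).to_numpy()
    if is_control.sum() < 100:
        raise ValueError("need >= 100 pooled control nuclei")

    top = _top_stratum_mask(x, donors, top_pct, stratum_scope)
    if guard_pct > 0:
        eval_top = _top_stratum_mask(x, donors, top_pct + guard_pct, stratum_scope)
    else:
        eval_top = top
    fit_sel = is_control & ~top
    xv, yv = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    if np.var(xv[fit_sel]) == 0:
        raise ValueError("degenerate fit: x has zero variance in controls")
    slope, intercept = np.polyfit(xv[fit_sel], yv[fit_sel], 1)
    resid = yv - (intercept + slope * xv)

    rng = np.random.default_rng(seed)
    gv = groups.to_numpy()
    group_names = [g for g in pd.unique(gv) if (eval_top & (gv == g)).any()]
    for g in pd.unique(gv):
        if g not in group_names:
            warnings.warn(f"group {g!r} has no top-stratum nuclei; skipped")

    def one_group(g):
        return resid[eval_top & (gv == g)]

    ctrl_names = [g for g in group_names if g in set(control_groups)]
    if not ctrl_names:
        raise ValueError("no control nuclei in the evaluation stratum")

    def sampler(r, rng_):
        return r[rng_.integers(0, len(r), len(r))]

    def sampler_hier(r, dsub, rng_):
        uniq = pd.unique(dsub)
        picked = uniq[rng_.integers(0, len(uniq), len(uniq))]
        parts = [r[dsub == d] for d in picked]
        parts = [p[rng_.integers(0, len(p), len(p))] for p in parts]
        return np.concatenate(parts)

    res_by_group = {g: one_group(g) for g in group_names}
    donors_by_group = (
        {g: donors.to_numpy()[eval_top & (gv == g)] for g in group_names}
        if donors is not None
        else None
    )
    ctrl_pool = np.concatenate([res_by_group[g] for g in ctrl_names])
    point = {
        g: float(res_by_group[g].mean() - ctrl_pool.mean()) for g in group_names
    }

    boots = {g: np.empty(n_boot) for g in group_names}
    for b in range(n_boot):
        if hierarchical and donors_by_group is not None:
            samples = {
                g: sampler_hier(res_by_group[g], donors_by_group[g], rng)
                for g in group_names
            }
        else:
            samples = {g: sampler(res_by_group[g], rng) for g in group_names}
        ref = np.concatenate([samples[g] for g in ctrl_names]).mean()
        for g in group_names:
            boots[g][b] = samples[g].mean() - ref
    ci_rows = {}
    for g in group_names:
        if hierarchical and donors_by_group is not None:
            # few-cluster correction: with a handful of donors the cluster
            # bootstrap percentile interval is anti-conservative, so use a
            # t interval on the bootstrap SE with donor-level dof
            d = max(len(pd.unique(donors_by_group[g])) - 1, 2)
            half = st.t.ppf(0.975, d) * float(boots[g].std(ddof=1))
            lo, hi = point[g] - half, point[g] + half
        else:
            lo, hi = np.percentile(boots[g], [2.5, 97.5]).tolist()
        ci_rows[g] = {"lo": float(lo), "hi": float(hi)}
    delta = point
    n_top = {g: int(len(res_by_group[g])) for g in group_names}

    top_groups = pd.Series(gv[eval_top], index=idx[eval_top])
    F, p, tukey = anova_tukey(
        pd.Series(resid[eval_top], index=idx[eval_top]), top_groups
    )
    return DecouplingResult(
        delta=pd.Series(delta, name="delta"),
        ci=pd.DataFrame.from_dict(ci_rows, orient="index"),
        control_fit=(float(intercept), float(slope)),
        anova_F=F,
        anova_p=p,
        tukey=tukey,
        n_top=pd.Series(n_top, name="n_top"),
    )


def nfkb_high_de_contrast(
    lognorm: np.ndarray,
    gene_names,
    strata: pd.Series,
    clusters: pd.Series,
    cluster,
    high: str = "top10",
    low: str = "bottom25",
) -> pd.DataFrame:
    """Differential expression of high- vs low-NF-kB nuclei within a cluster.

    ``strata`` are per-nucleus percentile labels for the stratifying
    protein; the contrast is ``high`` minus ``low`` within ``cluster``.
    """
    from .expression import differential_expression

    nucleus_ids = strata.index
    in_cluster = clusters.loc[nucleus_ids] == cluster
    a = (strata == high) & in_cluster
    b = (strata == low) & in_cluster
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError(
            f"stratum empty within cluster {cluster!r}: "
            f"{high}={int(a.sum())}, {low}={int(b.sum())}"
        )
    X = np.asarray(lognorm)
    return differential_expression(X[a.to_numpy()], X[b.to_numpy()], gene_names)
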