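"""Longitudinal and group statistics for chip-level measurements.

Two statistical procedures are implemented:

1. A repeated-measures linear mixed model for the per-chip projected lumen
   widths.  Each chip contributes one width series over the observation
   days; the model has a saturated fixed-effect mean (day, group, and
   day×group — equivalently one free mean per (day, group) cell), no
   random effects, and a single *unstructured* covariance matrix across
   days shared by all chips.  Chips that drop out contribute their
   observed days through the direct (observed-data) likelihood, valid
   under ignorable (MAR) missingness.  Estimation is restricted maximum
   likelihood via an EM iteration; confidence intervals are Wald with
   normal quantiles.  Group divergence is declared at the first day whose
   95% confidence intervals no longer overlap (closed intervals: exact
   touching still counts as overlap — conservative).

2. Kruskal–Wallis one-way ANOVA on ranks with Dunn's post-hoc pairwise
   comparisons (tie-corrected, Bonferroni-adjusted by default) for the
   morphometric descriptors pooled over chips.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    SingularCovarianceError,
)

__all__ = [
    "LmmFit",
    "DivergenceResult",
    "KwDunnResult",
    "validate_cohort",
    "fit_lmm",
    "ci_divergence_day",
    "kruskal_dunn",
    "describe_widths",
    "significance_stars",
]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy cohort table (chip_id, group, day, width_um).

    Enforces unique (chip_id, day) pairs and a single group per chip.
    """
    required = {"chip_id", "group", "day", "width_um"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    if cohort.duplicated(["chip_id", "day"]).any():
        raise ValueError("duplicate (chip_id, day) rows in cohort table")
    ngroups = cohort.groupby("chip_id")["group"].nunique()
    if (ngroups > 1).any():
        bad = ngroups[ngroups > 1].index.tolist()
        raise ValueError(f"chips assigned to multiple groups: {bad}")
    return cohort


@dataclass(frozen=True)
class LmmFit:
    """Fitted repeated-measures model.

    ``predictions`` has one row per (group, day) cell: the model mean, its
    Wald confidence bounds, and the number of observed chips.
    ``covariance`` is the REML estimate of the shared unstructured
    covariance across days (index/columns = days).
    """

    predictions: pd.DataFrame
    covariance: pd.DataFrame
    days: tuple[int, ...]
    groups: tuple[str, ...]
    method: str
    ci_level: float
    converged: bool
    n_iter: int

    def cell_mean(self, group: str, day: int) -> float:
        sel = self.predictions[
            (self.predictions["group"] == group) & (self.predictions["day"] == day)
        ]
        return float(sel["mean_um"].iloc[0])


@dataclass(frozen=True)
class DivergenceResult:
    """First day at which the two groups' confidence intervals separate."""

    first_divergence_day: Optional[int]
    overlap_by_day: Mapping[int, bool]


@dataclass(frozen=True)
class KwDunnResult:
    """Kruskal–Wallis H test plus Dunn's pairwise post-hoc comparisons."""

    h_statistic: float
    p_value: float
    n_by_group: Mapping[str, int]
    pairwise: pd.DataFrame  # group1, group2, z, p_unadjusted, p_adjusted, stars
    adjustment: str


# ---------------------------------------------------------------------------
# Linear mixed model (saturated means, shared unstructured covariance)


def _pattern_blocks(cohort: pd.DataFrame, days: Sequence[int], groups: Sequence[str]):
    """Group chips by (group, observation pattern); return sufficient stats.

    Yields tuples (group index, boolean day mask, Y) where Y is the
    (n_chips_in_block × n_observed_days) matrix of widths.
    """
    day_pos = {d: k for k, d in enumerate(days)}
    wide = cohort.pivot(index="chip_id", columns="day", values="width_um")
    wide = wide.reindex(columns=list(days))
    chip_group = cohort.drop_duplicates("chip_id").set_index("chip_id")["group"]
    blocks = []
    for (g, pattern), chips in wide.notna().groupby(
        [chip_group.reindex(wide.index), wide.notna().apply(tuple, axis=1)]
    ):
        mask = np.array(pattern, dtype=bool)
        if not mask.any():
            continue
        Y = wide.loc[chips.index].to_numpy()[:, mask]
        blocks.append((groups.index(g), mask, Y))
    return blocks


def fit_lmm(
    cohort: pd.DataFrame,
    reml: bool = True,
    ci_level: float = 0.95,
    max_iter: int = 10000,
    tol: float = 1e-7,
) -> LmmFit:
    """Fit the repeated-measures model to a cohort table.

    Maximizes the (restricted) likelihood of the multivariate-normal model
    with one free mean per (day, group) cell and a common unstructured
    covariance across days, using an EM iteration that imputes each chip's
    unobserved days from the current parameters.  With ``reml=True``
    (default) the covariance update includes the fixed-effect uncertainty
    term, so the balanced-complete-data fixed point is the pooled sample
    covariance with an N − G denominator.

    Raises
    ------
    ConvergenceError
        If the EM iteration does not converge within ``max_iter`` steps.
    SingularCovarianceError
        If the covariance estimate loses positive definiteness (e.g. a day
        observed on too few chips); no regularization is attempted.
    """
    validate_cohort(cohort)
    days = tuple(sorted(cohort["day"].unique()))
    groups = tuple(sorted(cohort["group"].unique()))
    D, G = len(days), len(groups)
    blocks = _pattern_blocks(cohort, days, list(groups))
    N = sum(Y.shape[0] for _, _, Y in blocks)
    if N < 1:
        raise ValueError("empty cohort")

    # n observed per (group, day) cell
    n_cell = np.zeros((G, D), dtype=int)
    for gi, mask, Y in blocks:
        n_cell[gi, mask] += Y.shape[0]
    if (n_cell.sum(axis=0) == 0).any():
        raise SingularCovarianceError("a design day has no observations at all")

    # Initialize: per-day pooled variance, zero correlation; cell means.
    mu = np.zeros((G, D))
    var0 = np.zeros(D)
    for k, d in enumerate(days):
        v = cohort.loc[cohort["day"] == d, "width_um"]
        var0[k] = v.var(ddof=1) if len(v) > 1 else max(v.abs().iloc[0] * 1e-3, 1.0) ** 2
        if not np.isfinite(var0[k]) or var0[k] <= 0:
            var0[k] = 1.0
    sigma = np.diag(var0)

    converged = False
    V_groups: list[np.ndarray] = [np.zeros((D, D)) for _ in range(G)]
    for it in range(1, max_iter + 1):
        # GLS mean step given sigma
        A = [np.zeros((D, D)) for _ in range(G)]
        b = [np.zeros(D) for _ in range(G)]
        inv_oo: dict[int, np.ndarray] = {}
        for bi, (gi, mask, Y) in enumerate(blocks):
            s_oo = sigma[np.ix_(mask, mask)]
            try:
                k_oo = np.linalg.inv(s_oo)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    "observed-day covariance block is singular"
                ) from exc
            inv_oo[bi] = k_oo
            A[gi][np.ix_(mask, mask)] += Y.shape[0] * k_oo
            b[gi][mask] += k_oo @ Y.sum(axis=0)
        mu_new = np.zeros((G, D))
        for gi in range(G):
            obs_days = n_cell[gi] > 0
            Ag = A[gi][np.ix_(obs_days, obs_days)]
            try:
                Vg = np.linalg.inv(Ag)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    f"mean model not estimable for group {groups[gi]!r}"
                ) from exc
            mu_new[gi, obs_days] = Vg @ b[gi][obs_days]
            V_full = np.zeros((D, D))
            V_full[np.ix_(obs_days, obs_days)] = Vg
            V_groups[gi] = V_full
        mu = mu_new

        # Covariance EM step
        S = np.zeros((D, D))
        for bi, (gi, mask, Y) in enumerate(blocks):
            k_oo = inv_oo[bi]
            n_b = Y.shape[0]
            R = Y - mu[gi, mask][None, :]
            S_oo = R.T @ R
            if reml:
                S_oo = S_oo + n_b * V_groups[gi][np.ix_(mask, mask)]
            if mask.all():
                S += S_oo
                continue
            miss = ~mask
            P = sigma[np.ix_(miss, mask)] @ k_oo  # regression of missing on observed
            T = np.zeros((D, mask.sum()))
            T[mask, :] = np.eye(int(mask.sum()))
            T[miss, :] = P
            C = sigma[np.ix_(miss, miss)] - P @ sigma[np.ix_(mask, miss)]
            contrib = T @ S_oo @ T.T
            contrib[np.ix_(miss, miss)] += n_b * C
            S += contrib
        sigma_new = S / N
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        delta = np.max(np.abs(sigma_new - sigma)) / (1.0 + np.max(np.abs(sigma)))
        sigma = sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations (last delta {delta:.3g})"
        )
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "converged covariance estimate is not positive definite"
        ) from exc

    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for gi, g in enumerate(groups):
        se = np.sqrt(np.diag(V_groups[gi]))
        for k, d in enumerate(days):
            if n_cell[gi, k] == 0:
                continue
            rows.append(
                {
                    "group": g,
                    "day": int(d),
                    "mean_um": mu[gi, k],
                    "ci_lower_um": mu[gi, k] - z * se[k],
                    "ci_upper_um": mu[gi, k] + z * se[k],
                    "se_um": se[k],
                    "n": int(n_cell[gi, k]),
                }
            )
    predictions = pd.DataFrame(rows)
    covariance = pd.DataFrame(sigma, index=list(days), columns=list(days))
    return LmmFit(
        predictions=predictions,
        covariance=covariance,
        days=days,
        groups=groups,
        method="EM-REML" if reml else "EM-ML",
        ci_level=ci_level,
        converged=converged,
        n_iter=it,
    )


def ci_divergence_day(
    fit: Union[LmmFit, pd.DataFrame],
) -> DivergenceResult:
    """First day at which the two groups' confidence intervals separate.

    Accepts a fitted model or any predictions table with columns
    ``group, day, ci_lower_um, ci_upper_um`` covering exactly two groups.
    Intervals are closed: exact touching counts as overlap.

    Raises
    ------
    ValueError
        If the fit does not contain exactly two groups on a shared day grid.
    """
    pred = fit.predictions if isinstance(fit, LmmFit) else fit
    groups = sorted(pred["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"divergence requires exactly 2 groups, got {groups}")
    a = pred[pred["group"] == groups[0]].set_index("day")
    b = pred[pred["group"] == groups[1]].set_index("day")
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("groups share no days")
    overlap: dict[int, bool] = {}
    first: Optional[int] = None
    for d in shared:
        lo = max(a.loc[d, "ci_lower_um"], b.loc[d, "ci_lower_um"])
        hi = min(a.loc[d, "ci_upper_um"], b.loc[d, "ci_upper_um"])
        ok = bool(lo <= hi)
        overlap[int(d)] = ok
        if not ok and first is None:
            first = int(d)
    return DivergenceResult(first_divergence_day=first, overlap_by_day=overlap)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn


def significance_stars(p: float) -> str:
    """Star code at the 0.05 / 0.01 / 0.001 levels ('' when n.s.)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def kruskal_dunn(
    samples: Mapping[str, Sequence[float]],
    adjustment: str = "bonferroni",
) -> KwDunnResult:
    """Kruskal–Wallis ANOVA on ranks with Dunn's post-hoc test.

    The global H statistic and its chi-square p-value are tie-corrected.
    Dunn's pairwise z statistics use the pooled mid-ranks with the tie
    correction ``Σ(t³−t) / (12(N−1))`` in the standard error; pairwise
    p-values are two-sided normal and adjusted for multiplicity
    (Bonferroni by default; ``adjustment='none'`` disables).  Unadjusted
    p-values are always reported alongside.

    Raises
    ------
    DegenerateDataError
        If all pooled observations are identical (no ranking possible).
    ValueError
        If fewer than two groups or an empty group is supplied.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    names = list(samples.keys())
    arrays = [np.asarray(samples[name], dtype=float) for name in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError(
            "all observations identical; tie correction denominator vanishes"
        )
    h, p_global = sps.kruskal(*arrays)

    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = {
        name: ranks[offsets[i] : offsets[i + 1]].mean() for i, name in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
        p_un = 2.0 * sps.norm.sf(abs(zij))
        p_adj = min(1.0, m * p_un) if adjustment == "bonferroni" else p_un
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "z": zij,
                "p_unadjusted": p_un,
                "p_adjusted": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return KwDunnResult(
        h_statistic=float(h),
        p_value=float(p_global),
        n_by_group={name: int(s) for name, s in zip(names, sizes)},
        pairwise=pd.DataFrame(rows),
        adjustment=adjustment,
    )


def describe_widths(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-(day, group) mean ± sample sd (n−1) table of the cohort widths.

    Cells with a single chip report an undefined (NaN) sd, never zero.
    """
    validate_cohort(cohort)
    out = (
        cohort.groupby(["group", "day"])["width_um"]
        .agg(n="count", mean_um="mean", sd_um=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out
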