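"""Inference on in vivo MOS estimates.

Two procedures are provided:

* an empirical-Bayes adaptive-shrinkage model identifying *oxidation-prone*
  methionines — sites whose pooled (interage) stoichiometry exceeds the
  global median. Effects (distances above the median) are modeled with a
  unimodal half-uniform prior with only positive mass,
  ``pi0*delta_0 + sum_m pi_m*Uniform(0, b_m)``, fitted by EM over a
  geometric grid of scales; significance is assigned by q-value (running
  mean of sorted local false-sign rates) at q <= 0.01;

* two-sample age contrasts: per-peptide differences between old and young
  in vivo estimates, a t statistic from the pooled standard errors with
  Welch–Satterthwaite degrees of freedom, and step-down Holm–Bonferroni
  family-wise error control.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ShrinkageResult",
    "AgeContrast",
    "shrinkage_fit",
    "flag_oxidation_prone",
    "age_contrast",
    "age_contrast_table",
    "holm_adjust",
]

Q_THRESHOLD = 0.01


@dataclass
class ShrinkageResult:
    """Fitted mixture weights plus per-record posterior summaries."""

    grid: np.ndarray            # uniform-component upper bounds b_m
    pi: np.ndarray              # mixture weights, pi[0] is the point null
    lfsr: np.ndarray            # local false-sign rate per record
    qvalue: np.ndarray
    posterior_mean: np.ndarray
    n_iter: int


def _default_grid(effects: np.ndarray, ses: np.ndarray) -> np.ndarray:
    lo = ses.min() / 10.0
    hi = 2.0 * max(np.abs(effects).max(), lo * 2)
    n = max(int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0)))) + 1, 2)
    return lo * np.sqrt(2.0) ** np.arange(n)


def shrinkage_fit(
    effects: np.ndarray,
    ses: np.ndarray,
    grid: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> ShrinkageResult:
    """Fit the half-uniform (positive effects only) adaptive shrinkage model.

    The observed effect x_i is Normal(theta_i, se_i^2); theta_i is drawn
    from ``pi0*delta_0 + sum_m pi_m*U(0, b_m)``. EM maximizes the marginal
    likelihood over the weights with the grid held fixed. The local
    false-sign rate of a record is its posterior probability of a
    non-positive effect, which under this prior is the posterior null
    responsibility; q-values are the cumulative mean of the sorted rates.
    """
    x = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if x.shape != s.shape:
        raise ValueError("effects and SEs must have the same length")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    if grid is None:
        grid = _default_grid(x, s)
    grid = np.asarray(grid, dtype=float)
    M = len(grid)

    # likelihood matrix: column 0 = point null, columns 1..M = U(0, b_m)
    L = np.empty((len(x), M + 1))
    L[:, 0] = sps.norm.pdf(x, 0.0, s)
    for m, b in enumerate(grid):
        # integral of N(x; theta, s^2) dtheta / b over theta in (0, b)
        L[:, m + 1] = (sps.norm.cdf(x / s) - sps.norm.cdf((x - b) / s)) / b
    L = np.maximum(L, 1e-300)

    pi = np.full(M + 1, 1.0 / (M + 1))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = L * pi
        w /= w.sum(axis=1, keepdims=True)
        new_pi = w.mean(axis=0)
        if np.abs(new_pi - pi).max() < tol:
            pi = new_pi
            break
        pi = new_pi
    resp = L * pi
    resp /= resp.sum(axis=1, keepdims=True)

    lfsr = resp[:, 0]  # prior has no negative mass: P(theta <= 0 | x) = P(null | x)
    order = np.argsort(lfsr, kind="stable")
    q_sorted = np.cumsum(lfsr[order]) / np.arange(1, len(x) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # enforce monotone
    qvalue = np.empty_like(lfsr)
    qvalue[order] = np.minimum(q_sorted, 1.0)

    # posterior mean: truncated-normal mean within each uniform component
    post = np.zeros(len(x))
    for m, b in enumerate(grid):
        alpha = (0.0 - x) / s
        beta = (b - x) / s
        z = sps.norm.cdf(beta) - sps.norm.cdf(alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            tn_mean = x + s * (sps.norm.pdf(alpha) - sps.norm.pdf(beta)) / z
        tn_mean = np.where(z > 1e-300, tn_mean, np.clip(x, 0.0, b))
        post += resp[:, m + 1] * np.clip(tn_mean, 0.0, b)
    return ShrinkageResult(
        grid=grid, pi=pi, lfsr=lfsr, qvalue=qvalue, posterior_mean=post, n_iter=n_iter
    )


def flag_oxidation_prone(
    estimates: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    se_floor: float = 1e-6,
) -> pd.DataFrame:
    """Identify oxidation-prone methionines from interage MOS estimates.

    Effects are the distances of each peptide's in vivo MOS from the global
    median of the (QC-passing) set; standard errors come from the titration
    fits. Records with q-value <= ``q_threshold`` are flagged.
    """
    est = estimates.reset_index(drop=True)
    if len(est) < 50:
        warnings.warn(
            f"only {len(est)} records: shrinkage grid may be unstable", stacklevel=2
        )
    if len(est) == 0:
        return est.assign(effect=[], se=[], lfsr=[], qvalue=[], significant=[])
    median = float(est["mos_invivo"].median())
    effects = est["mos_invivo"].to_numpy() - median
    ses = np.maximum(est["sem"].to_numpy(dtype=float), se_floor)
    fit = shrinkage_fit(effects, ses)
    out = est.copy()
    out["effect"] = effects
    out["se"] = ses
    out["lfsr"] = fit.lfsr
    out["qvalue"] = fit.qvalue
    out["posterior_mean"] = fit.posterior_mean
    out["significant"] = fit.qvalue <= q_threshold
    out.attrs["global_median"] = median
    return out


@dataclass
class AgeContrast:
    peptide: str
    effect: float        # MOS_old - MOS_young
    pooled_se: float
    t_stat: float
    df: float
    pvalue: float
    pvalue_adjusted: float = np.nan


def age_contrast(
    young_mos: float,
    old_mos: float,
    young_sem: float,
    old_sem: float,
    n_young: int,
    n_old: int,
    peptide: str = "",
    min_df: float = 3.0,
) -> AgeContrast:
    """Two-sample contrast of in vivo MOS between age groups.

    t = (old - young) / sqrt(sem_old^2 + sem_young^2), with
    Welch–Satterthwaite degrees of freedom from the per-group residual
    counts of the titration fits (one parameter each).
    """
    v_y, v_o = young_sem**2, old_sem**2
    pooled = np.sqrt(v_y + v_o)
    if pooled == 0:
        raise ValueError("zero pooled standard error")
    df_y, df_o = max(n_young - 1, 1), max(n_old - 1, 1)
    df = (v_y + v_o) ** 2 / (v_y**2 / df_y + v_o**2 / df_o)
    df = max(df, min_df)
    t = (old_mos - young_mos) / pooled
    p = 2.0 * sps.t.sf(abs(t), df)
    return AgeContrast(
        peptide=peptide, effect=old_mos - young_mos, pooled_se=pooled,
        t_stat=t, df=df, pvalue=min(p, 1.0),
    )


def age_contrast_table(
    estimates: pd.DataFrame,
    young_label: str = "young",
    old_label: str = "old",
) -> pd.DataFrame:
    """Per-peptide age contrasts with Holm–Bonferroni adjusted p-values.

    ``estimates`` holds QC-passing per-group MOSEstimates (long format with
    a ``grouping`` column); only peptides with both groups passing enter.
    """
    y = estimates[estimates["grouping"] == young_label].set_index("peptide")
    o = estimates[estimates["grouping"] == old_label].set_index("peptide")
    shared = sorted(set(y.index) & set(o.index))
    rows = []
    for pep in shared:
        c = age_contrast(
            y.loc[pep, "mos_invivo"], o.loc[pep, "mos_invivo"],
            y.loc[pep, "sem"], o.loc[pep, "sem"],
            int(y.loc[pep, "n_valid"]), int(o.loc[pep, "n_valid"]),
            peptide=pep,
        )
        rows.append(c.__dict__)
    table = pd.DataFrame(rows)
    if len(table):
        table["pvalue_adjusted"] = holm_adjust(table["pvalue"].to_numpy())
    return table


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Step-down Holm–Bonferroni adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]
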