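"""Two-statistic cancer-specificity screen over (drug, pathway, cancer) triplets.

For each candidate triplet the screen computes

* ``T1`` — a robust one-vs-rest t statistic (Yuen-style trimmed Welch t,
  one-sided for overactivation of the target cancer relative to the pooled
  remaining cancers), and
* ``T2`` — a one-way heterogeneity statistic over the *remaining* cancers,
  ``T2 = sum_c n_c (m_c - m_bar)^2 / s2_pooled``, compared against a
  chi-square reference with (#remaining cancers - 1) degrees of freedom.

A triplet is called a druggable cancer-specific pathway (DCSP) when its
BH-adjusted T1 p-value clears the FDR threshold, its T2 lies within the first
quartile of the T2 values of the FDR-passing family (the remaining cancers are
mutually homogeneous), every cancer entering the comparison has more than five
samples, and at least three cancers enter the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "robust_t_one_vs_rest",
    "chi2_homogeneity",
    "bh_fdr",
    "screen",
]


@dataclass
class ScreenConfig:
    """Thresholds and options of the DCSP screen.

    fdr
        BH-adjusted p-value cutoff on T1 (default 0.01).
    t2_quartile
        Quantile of the family's T2 values a DCSP must not exceed (default
        0.25, the first quartile).
    min_samples
        Minimum samples per supporting cancer; 6 encodes the strict
        "larger than 5" rule.
    min_cancers
        Minimum number of supporting cancers (default 3).
    trim
        Per-group trimming fraction of the robust t (0 gives plain Welch).
    family
        Multiple-testing family: ``"per_cancer"`` (all drug-pathway candidates
        of one target cancer, default) or ``"global"``.
    t2_quartile_scope
        ``"fdr_pass"`` (default): the T2 quartile is taken among the family
        members that already pass the FDR filter — the filters apply
        sequentially.  ``"family"``: quartile over the full family before any
        FDR filtering.
    """

    fdr: float = 0.01
    t2_quartile: float = 0.25
    min_samples: int = 6
    min_cancers: int = 3
    trim: float = 0.1
    family: str = "per_cancer"
    t2_quartile_scope: str = "fdr_pass"


def _trimmed_moments(x: np.ndarray, trim: float) -> tuple[float, float, int]:
    """Trimmed mean, Yuen variance term d = (n-1) s_w^2 / (h (h-1)), and h."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValidationError(f"group of size {n} too small for trim={trim}")
    tmean = float(x[g:n - g].mean())
    xw = np.clip(x, x[g], x[n - g - 1])  # winsorized sample
    sw2 = float(xw.var(ddof=1))
    d = (n - 1) * sw2 / (h * (h - 1))
    return tmean, d, h


def robust_t_one_vs_rest(values_by_cancer: Mapping[str, Sequence[float]],
                         target: str, trim: float = 0.1) -> tuple[float, float]:
    """Yuen-style trimmed Welch t of the target cancer against the pooled rest.

    Returns ``(T1, p1)`` with a one-sided p-value for overactivation (target
    trimmed mean above the rest's).  ``trim=0`` reduces exactly to the Welch
    unequal-variance t.  Zero winsorized variance in both groups yields
    ``T1=0, p1=1`` for equal means and ``+/-inf`` with p of 0/1 otherwise.
    """
    if target not in values_by_cancer:
        raise ValidationError(f"target cancer {target!r} not present")
    x = np.asarray(values_by_cancer[target], dtype=float)
    rest = np.concatenate([np.asarray(v, dtype=float)
                           for c, v in values_by_cancer.items() if c != target])
    if x.size < 2 or rest.size < 2:
        raise ValidationError("both target and rest need >= 2 samples")
    m1, d1, h1 = _trimmed_moments(x, trim)
    m2, d2, h2 = _trimmed_moments(rest, trim)
    se2 = d1 + d2
    if se2 == 0:
        if m1 == m2:
            logger.debug("degenerate robust t: zero variance, equal means")
            return 0.0, 1.0
        t = np.inf if m1 > m2 else -np.inf
        return float(t), float(stats.norm.sf(t))
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / (d1 ** 2 / (h1 - 1) + d2 ** 2 / (h2 - 1))
    p = float(stats.t.sf(t, df))
    return float(t), p


def chi2_homogeneity(values_by_cancer: Mapping[str, Sequence[float]],
                     excluded: str) -> tuple[float, int]:
    """Heterogeneity of per-cancer mean PAS among the non-target cancers.

    ``T2 = sum_c n_c (m_c - m_bar)^2 / s2_pooled`` with the sample-size
    weighted grand mean and the pooled within-cancer variance; reference
    distribution chi-square with (#groups - 1) df.  A zero pooled variance
    with unequal means yields ``T2 = +inf`` (maximal heterogeneity).

    Returns ``(T2, df)``.
    """
    groups = [np.asarray(v, dtype=float)
              for c, v in values_by_cancer.items() if c != excluded]
    if len(groups) < 2:
        raise ValidationError("chi2 homogeneity needs >= 2 remaining cancers")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every remaining cancer needs >= 2 samples")
    n = np.array([g.size for g in groups])
    m = np.array([g.mean() for g in groups])
    s2 = np.array([g.var(ddof=1) for g in groups])
    pooled = float(((n - 1) * s2).sum() / (n - 1).sum())
    grand = float((n * m).sum() / n.sum())
    between = float((n * (m - grand) ** 2).sum())
    df = len(groups) - 1
    if pooled == 0:
        return (0.0 if between == 0 else np.inf), df
    return between / pooled, df


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(pas_table: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Run the DCSP screen on a PAS table.

    ``pas_table`` needs columns ``sample``, ``cancer``, ``drug``, ``pathway``
    and ``PAS``.  Cancers failing the sample-size rule are excluded from both
    the rest pool of T1 and from T2 before any statistic is computed.  Returns
    one row per eligible (drug, pathway, cancer) triplet with T1, p1, the
    BH-adjusted FDR, T2 and its df, the filter flags and ``is_dcsp``.
    """
    cfg = config or ScreenConfig()
    required = {"sample", "cancer", "drug", "pathway", "PAS"}
    missing = required - set(pas_table.columns)
    if missing:
        raise ValidationError(f"PAS table missing columns {sorted(missing)}")

    sample_counts = (pas_table[["sample", "cancer"]].drop_duplicates()
                     .groupby("cancer")["sample"].size())
    eligible_cancers = sorted(sample_counts.index[sample_counts >= cfg.min_samples])
    if len(sample_counts) < 3:
        raise ValidationError("the screen needs a PAS table spanning >= 3 cancers")
    if len(eligible_cancers) < cfg.min_cancers:
        logger.warning("only %d cancer(s) pass the sample-size rule; "
                       "no triplet is eligible", len(eligible_cancers))
        eligible_cancers = []

    rows: list[dict] = []
    grouped = pas_table.groupby(["drug", "pathway"], sort=True)
    for (drug, pathway), grp in grouped:
        by_cancer = {c: sub["PAS"].to_numpy(float)
                     for c, sub in grp.groupby("cancer") if c in eligible_cancers}
        for cancer in eligible_cancers:
            if cancer not in by_cancer:
                continue
            t1, p1 = robust_t_one_vs_rest(by_cancer, cancer, trim=cfg.trim)
            t2, t2_df = chi2_homogeneity(by_cancer, cancer)
            rows.append({
                "drug": drug, "pathway": pathway, "cancer": cancer,
                "n_target": int(by_cancer[cancer].size),
                "n_rest_cancers": len(by_cancer) - 1,
                "T1": t1, "p1": p1, "T2": t2, "t2_df": t2_df,
                "eligible": len(by_cancer) >= cfg.min_cancers,
            })

    out = pd.DataFrame(rows, columns=["drug", "pathway", "cancer", "n_target",
                                      "n_rest_cancers", "T1", "p1", "T2", "t2_df",
                                      "eligible"])
    if out.empty:
        out["fdr"] = out["t2_pass"] = out["is_dcsp"] = pd.Series(dtype=float)
        return out

    out["fdr"] = np.nan
    out["t2_pass"] = False
    family_keys = out["cancer"] if cfg.family == "per_cancer" else pd.Series(0, index=out.index)
    for _, idx in out.groupby(family_keys).groups.items():
        fam = out.loc[idx]
        out.loc[idx, "fdr"] = bh_fdr(fam["p1"].to_numpy())
        fdr_pass = out.loc[idx, "fdr"] < cfg.fdr
        if cfg.t2_quartile_scope == "fdr_pass":
            pool = out.loc[idx, "T2"][fdr_pass]
        else:
            pool = out.loc[idx, "T2"]
        if len(pool):
            cutoff = float(np.quantile(pool, cfg.t2_quartile))
            out.loc[idx, "t2_pass"] = out.loc[idx, "T2"] <= cutoff
    out["is_dcsp"] = (out["eligible"] & (out["fdr"] < cfg.fdr) & out["t2_pass"])
    return out
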