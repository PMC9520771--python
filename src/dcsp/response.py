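"""PAS vs drug-response statistics: normal-score correlation, rediscovery-rate
curves, and the label-permutation specificity test.

Drug sensitivity is an area under the dose-survival curve (AUC): smaller AUC =
stronger response, so a *negative* cor(PAS, AUC) supports the hypothesis that
activation of a druggable pathway predicts response.  Both PAS and AUC are put
on normal scores (rank-based inverse normal, van der Waerden) before Pearson
correlation, making the association measure invariant to monotone rescalings
of either assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "RDRCurve",
    "PermutationResult",
    "normal_score_transform",
    "pas_auc_correlation",
    "correlate_table",
    "rdr_curve",
    "permutation_specificity_test",
]

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 1.00)


@dataclass(frozen=True)
class CorrelationRecord:
    drug: str
    pathway: str
    cancer: str
    n: int
    r: float
    p: float
    direction: str
    computable: bool = True


@dataclass(frozen=True)
class RDRCurve:
    fractions: tuple[float, ...]
    rdr: tuple[float, ...]
    alpha: float
    sign: str
    n_records: int


@dataclass(frozen=True)
class PermutationResult:
    comparison: str
    observed_t: float
    n_perm: int
    p_empirical: float
    n_group: int
    n_comparison: int


def normal_score_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform Phi^-1(r_i / (n + 1)).

    Ties receive average ranks (van der Waerden scores); the map is
    order-preserving and invariant to strictly increasing recodings of the
    input.  A constant input maps to all zeros (every value at the mid-rank).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("normal score transform needs >= 2 values")
    if not np.isfinite(x).all():
        raise ValidationError("values must be finite")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (x.size + 1))


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pas_auc_correlation(pas: pd.Series | Sequence[float],
                        auc: pd.Series | Sequence[float],
                        direction: str = "upstream",
                        positive_only: bool = True,
                        drug: str = "", pathway: str = "",
                        cancer: str = "") -> CorrelationRecord:
    """Pearson correlation of normal-scored PAS and AUC for one triplet.

    ``pas`` and ``auc`` must be aligned per sample (equal length, same order,
    or two pandas Series sharing a sample index).  With ``positive_only`` only
    samples whose activation is positive enter: PAS > 0 for the upstream
    direction, -PAS > 0 for the downstream one.  At least 3 samples must
    remain; otherwise the record is flagged not-computable.
    """
    if direction not in ("upstream", "downstream"):
        raise ValidationError(f"unknown direction {direction!r}")
    if isinstance(pas, pd.Series) and isinstance(auc, pd.Series):
        joined = pd.concat([pas.rename("pas"), auc.rename("auc")], axis=1, join="inner")
        x = joined["pas"].to_numpy(float)
        y = joined["auc"].to_numpy(float)
    else:
        x = np.asarray(pas, dtype=float)
        y = np.asarray(auc, dtype=float)
        if x.size != y.size:
            raise ValidationError("pas and auc must have equal length")
    signed = x if direction == "upstream" else -x
    if positive_only:
        mask = signed > 0
        signed, y = signed[mask], y[mask]
    if signed.size < 3:
        return CorrelationRecord(drug, pathway, cancer, int(signed.size),
                                 np.nan, np.nan, direction, computable=False)
    r, p = _pearson_with_p(normal_score_transform(signed), normal_score_transform(y))
    return CorrelationRecord(drug, pathway, cancer, int(signed.size), r, p, direction)


def correlate_table(pas_table: pd.DataFrame, response: pd.DataFrame,
                    direction: str = "upstream",
                    positive_only: bool = True) -> pd.DataFrame:
    """Per-(drug, pathway, cancer) PAS-AUC correlations.

    ``pas_table`` is a PAS matrix (columns sample, cancer, drug, pathway, PAS)
    and ``response`` a drug-response table (sample, drug, auc).  Rows are
    matched on (sample, drug).
    """
    merged = pas_table.merge(response, on=["sample", "drug"], how="inner")
    rows = []
    for (drug, pathway, cancer), grp in merged.groupby(["drug", "pathway", "cancer"],
                                                       sort=True):
        rec = pas_auc_correlation(grp["PAS"].to_numpy(float), grp["auc"].to_numpy(float),
                                  direction=direction, positive_only=positive_only,
                                  drug=drug, pathway=pathway, cancer=cancer)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows, columns=["drug", "pathway", "cancer", "n", "r", "p",
                                       "direction", "computable"])


def _one_sided_p(r: float, n: int, sign: str) -> float:
    """One-sided p-value of a Pearson r in the given direction."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = float(np.clip(r, -0.9999999999, 0.9999999999))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(stats.t.cdf(t, n - 2) if sign == "negative" else stats.t.sf(t, n - 2))


def rdr_curve(discovery: pd.DataFrame, validation: pd.DataFrame,
              alpha: float = 0.05, sign: str = "negative",
              fractions: Iterable[float] = DEFAULT_FRACTIONS) -> RDRCurve:
    """Rediscovery-rate curve of discovery-set DCSP correlations.

    Both inputs are correlation tables with at least columns ``drug``,
    ``pathway``, ``r`` and (for the validation set) ``n``; records are matched
    on (drug, pathway).  The discovery records with the requested correlation
    sign are ranked by r (most extreme first); for each fraction ``f``,
    ``RDR(f)`` is the share of the top ``ceil(f * m)`` records whose one-sided
    validation p-value (in the discovery direction) is below ``alpha``.
    """
    if sign not in ("negative", "positive"):
        raise ValidationError(f"unknown sign {sign!r}")
    merged = discovery.merge(validation, on=["drug", "pathway"],
                             suffixes=("_disc", "_val"))
    merged = merged.dropna(subset=["r_disc", "r_val"])
    if sign == "negative":
        merged = merged[merged["r_disc"] < 0].sort_values("r_disc", ascending=True)
    else:
        merged = merged[merged["r_disc"] > 0].sort_values("r_disc", ascending=False)
    m = len(merged)
    if m == 0:
        raise ValidationError("no matched (drug, pathway) records with the requested sign")
    p_val = np.array([_one_sided_p(r, int(n), sign)
                      for r, n in zip(merged["r_val"], merged["n_val"])])
    significant = p_val < alpha
    fractions = tuple(float(f) for f in fractions)
    rdr = []
    for f in fractions:
        k = int(np.ceil(f * m))
        rdr.append(float(significant[:k].sum()) / k)
    return RDRCurve(fractions=fractions, rdr=tuple(rdr), alpha=alpha, sign=sign,
                    n_records=m)


_COMPARISONS = ("Dbar_P", "D_Pbar", "Dbar_Pbar")


def _comparison_mask(table: pd.DataFrame, drug: str, pathway: str,
                     comparison: str) -> pd.Series:
    same_d = table["drug"] == drug
    same_p = table["pathway"] == pathway
    if comparison == "Dbar_P":
        return ~same_d & same_p
    if comparison == "D_Pbar":
        return same_d & ~same_p
    return ~same_d & ~same_p


def _pooled_t(g1: np.ndarray, g2: np.ndarray) -> float:
    n1, n2 = g1.size, g2.size
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0
    return float((g1.mean() - g2.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def permutation_specificity_test(pas_table: pd.DataFrame, drug: str, pathway: str,
                                 comparison: str = "Dbar_Pbar",
                                 n_perm: int = 10_000, seed: int | None = None,
                                 cancer: str | None = None,
                                 chunk: int = 2_000) -> PermutationResult:
    """Label-permutation test of the (drug, pathway) PAS group against a
    comparison group.

    ``comparison`` selects the PAS of (i) the same pathway under other drugs
    (``"Dbar_P"``), (ii) the same drug on other pathways (``"D_Pbar"``), or
    (iii) other drugs and other pathways (``"Dbar_Pbar"``).  The observed
    statistic is the pooled-variance two-sample t; the null is built by
    shuffling the pooled PAS values across the two groups ``n_perm`` times
    (exchangeability makes the plain t exact under permutation).  The
    one-sided empirical p-value is ``(1 + #{t* >= t_obs}) / (n_perm + 1)`` —
    one-sided because specificity claims the DCSP group's PAS is higher.
    """
    if comparison not in _COMPARISONS:
        raise ValidationError(f"comparison must be one of {_COMPARISONS}")
    if n_perm < 1000:
        raise ValidationError("n_perm must be >= 1000")
    table = pas_table if cancer is None else pas_table[pas_table["cancer"] == cancer]
    g1 = table.loc[(table["drug"] == drug) & (table["pathway"] == pathway),
                   "PAS"].to_numpy(float)
    g2 = table.loc[_comparison_mask(table, drug, pathway, comparison),
                   "PAS"].to_numpy(float)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("both the DCSP group and the comparison group must be nonempty")
    pool = np.concatenate([g1, g2])
    if np.ptp(pool) == 0:
        logger.debug("degenerate permutation test: all PAS values identical")
        return PermutationResult(comparison, 0.0, n_perm, 1.0, g1.size, g2.size)
    t_obs = _pooled_t(g1, g2)
    rng = np.random.default_rng(seed)
    n1, n = g1.size, pool.size
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        mat = np.tile(pool, (b, 1))
        rng.permuted(mat, axis=1, out=mat)
        a, rest = mat[:, :n1], mat[:, n1:]
        m1, m2 = a.mean(axis=1), rest.mean(axis=1)
        v1, v2 = a.var(axis=1, ddof=1), rest.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n - n1 - 1) * v2) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / (n - n1)))
        t_null = np.where(sp2 == 0, 0.0, t_null)
        exceed += int((t_null >= t_obs).sum())
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(comparison, t_obs, n_perm, float(p), g1.size, g2.size)
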