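"""Expression quantification and negative-binomial differential expression.

Counts are normalised two ways: RPTM (reads per ten million,
``count / total mapped reads * 1e7``) for reporting expression levels, and
median-of-ratios size factors for the differential test. The test itself
is a defined NB Wald test (not a re-implementation of any particular
package): per-locus group means on normalised counts, method-of-moments
dispersion shrunk halfway toward a fitted mean-dispersion trend, delta-
method standard error of the log2 fold change, two-sided normal p-value,
Benjamini-Hochberg adjustment, and the study's call thresholds
(|log2FC| > 1.5, adjusted p < 0.05, both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RPTM_SCALE = 1e7
DISPERSION_FLOOR = 1e-8


@dataclass
class ExpressionMatrix:
    """Raw counts and RPTM per locus x sample."""

    locus_ids: list[str]
    sample_ids: list[str]
    raw_counts: np.ndarray
    total_mapped: np.ndarray

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
        self.total_mapped = np.asarray(self.total_mapped, dtype=np.int64)
        n_loci, n_samples = self.raw_counts.shape
        if n_loci != len(self.locus_ids) or n_samples != len(self.sample_ids):
            raise ValueError("count matrix shape does not match id lists")
        if np.any(self.raw_counts < 0):
            raise ValueError("negative counts")
        if np.any(self.total_mapped < self.raw_counts.sum(axis=0)):
            raise ValueError("total_mapped below column count sums")

    @property
    def rptm(self) -> np.ndarray:
        return compute_rptm(self.raw_counts, self.total_mapped)

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.rptm if normalized else self.raw_counts
        return pd.DataFrame(data, index=self.locus_ids, columns=self.sample_ids)


def compute_rptm(raw_counts: np.ndarray, total_mapped: np.ndarray) -> np.ndarray:
    """Reads per ten million: ``counts / total_mapped * 1e7`` elementwise."""
    raw_counts = np.asarray(raw_counts, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(total_mapped <= 0):
        raise ValueError("total mapped reads must be positive for every sample")
    return raw_counts / total_mapped[np.newaxis, :] * RPTM_SCALE


def estimate_size_factors(
    raw_counts: np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors.

    For each locus with nonzero counts in all samples, the ratio of each
    sample's count to the locus's geometric mean is formed; the per-sample
    factor is the median of those ratios. With ``pseudo_reference`` the
    all-nonzero requirement is relaxed by adding a 0.5 pseudo-count.
    """
    counts = np.asarray(raw_counts, dtype=float)
    if pseudo_reference:
        counts = counts + 0.5
    all_nonzero = np.all(counts > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no locus with nonzero counts in all samples; "
            "retry with pseudo_reference=True"
        )
    sub = counts[all_nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geomean)[:, np.newaxis]
    return np.median(ratios, axis=0)


@dataclass
class DEResult:
    """Per-locus differential-expression call (group X over group P)."""

    locus_id: str
    base_mean_x: float
    base_mean_p: float
    log2fc: float
    p_value: float
    padj: float
    direction: str  # up / down / ns
    flagged: bool = False


@dataclass
class DEResults:
    """Fitted differential-expression results for a count matrix."""

    results: list[DEResult]
    size_factors: np.ndarray
    dispersions: np.ndarray
    lfc_threshold: float
    alpha: float
    n_excluded: int = 0

    @property
    def n_up(self) -> int:
        return sum(r.direction == "up" for r in self.results)

    @property
    def n_down(self) -> int:
        return sum(r.direction == "down" for r in self.results)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": r.locus_id,
                    "baseMeanX": r.base_mean_x,
                    "baseMeanP": r.base_mean_p,
                    "log2fc": r.log2fc,
                    "p": r.p_value,
                    "padj": r.padj,
                    "direction": r.direction,
                }
                for r in self.results
            ]
        )


def _group_masks(groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g = np.asarray(groups)
    mask_x = g == labels[0]
    mask_p = g == labels[1]
    if mask_x.sum() < 2 or mask_p.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return mask_x, mask_p


def nb_wald_test(
    raw_counts: np.ndarray,
    groups: Sequence[str],
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-locus NB Wald test of group X (first label) over group P.

    Returns a DataFrame with columns mean_x, mean_p, log2fc, se, p,
    dispersion, flagged. Loci where one group has all-zero counts get a
    signed-infinity log2fc sentinel with the p-value computed on a
    +0.5 pseudo-count path and ``flagged`` set.
    """
    counts = np.asarray(raw_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count matrix must be 2-D")
    mask_x, mask_p = _group_masks(groups)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    s = np.asarray(size_factors, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")

    q = counts / s[np.newaxis, :]
    qx, qp = q[:, mask_x], q[:, mask_p]
    nx, np_ = qx.shape[1], qp.shape[1]
    mean_x, mean_p = qx.mean(axis=1), qp.mean(axis=1)

    # Method-of-moments dispersion, pooled across groups.
    var_x = qx.var(axis=1, ddof=1)
    var_p = qp.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_x = np.where(mean_x > 0, (var_x - mean_x) / mean_x**2, 0.0)
        a_p = np.where(mean_p > 0, (var_p - mean_p) / mean_p**2, 0.0)
    alpha_raw = ((nx - 1) * a_x + (np_ - 1) * a_p) / (nx + np_ - 2)
    alpha_raw = np.maximum(alpha_raw, DISPERSION_FLOOR)

    # Mean-dispersion trend a0 + a1/mu, then 50% shrinkage toward it.
    mu = q.mean(axis=1)
    ok = mu > 0
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
        trend = np.maximum(trend, DISPERSION_FLOOR)
    else:  # pragma: no cover - degenerate tiny input
        trend = np.full_like(alpha_raw, DISPERSION_FLOOR)
    dispersion = np.maximum(0.5 * alpha_raw + 0.5 * trend, DISPERSION_FLOOR)

    inv_s_x = (1.0 / s[mask_x]).sum()
    inv_s_p = (1.0 / s[mask_p]).sum()

    def _se(mx: np.ndarray, mp: np.ndarray) -> np.ndarray:
        # Var(mean_g) = (1/n^2) sum_j (mu_g / s_j + alpha mu_g^2)
        var_mx = (mx * inv_s_x + nx * dispersion * mx**2) / nx**2
        var_mp = (mp * inv_s_p + np_ * dispersion * mp**2) / np_**2
        ln2sq = np.log(2.0) ** 2
        return np.sqrt(var_mx / (mx**2 * ln2sq) + var_mp / (mp**2 * ln2sq))

    zero_x = mean_x == 0
    zero_p = mean_p == 0
    flagged = zero_x | zero_p

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_x / mean_p)
        se = _se(mean_x, mean_p)
    # Pseudo-count path for zero groups (and its p-value).
    mx_ps = mean_x + 0.5
    mp_ps = mean_p + 0.5
    lfc_ps = np.log2(mx_ps / mp_ps)
    se_ps = _se(mx_ps, mp_ps)
    log2fc = np.where(flagged, np.where(zero_p, np.inf, -np.inf), log2fc)
    log2fc = np.where(zero_x & zero_p, 0.0, log2fc)
    wald = np.where(flagged, lfc_ps / se_ps, np.where(se > 0, np.divide(
        log2fc, se, out=np.zeros_like(se), where=se > 0), 0.0))
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "mean_x": mean_x,
            "mean_p": mean_p,
            "log2fc": log2fc,
            "se": np.where(flagged, se_ps, se),
            "p": p,
            "dispersion": dispersion,
            "flagged": flagged,
        }
    )


def call_de(
    test_table: pd.DataFrame,
    locus_ids: Sequence[str] | None = None,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> DEResults:
    """BH-adjust the Wald p-values and call DE with strict thresholds.

    ``direction`` is ``up`` iff log2FC > lfc_threshold AND padj < alpha
    (both strict), ``down`` for the mirrored condition, else ``ns``.
    """
    p = np.asarray(test_table["p"], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    if locus_ids is None:
        locus_ids = [f"locus_{i+1}" for i in range(len(p))]
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    results = []
    for i, locus in enumerate(locus_ids):
        lfc = float(test_table["log2fc"].iloc[i])
        direction = "ns"
        if padj[i] < alpha:
            if lfc > lfc_threshold:
                direction = "up"
            elif lfc < -lfc_threshold:
                direction = "down"
        results.append(
            DEResult(
                locus_id=str(locus),
                base_mean_x=float(test_table["mean_x"].iloc[i]),
                base_mean_p=float(test_table["mean_p"].iloc[i]),
                log2fc=lfc,
                p_value=float(p[i]),
                padj=float(padj[i]),
                direction=direction,
                flagged=bool(test_table["flagged"].iloc[i]),
            )
        )
    return DEResults(
        results=results,
        size_factors=np.asarray(size_factors) if size_factors is not None else np.array([]),
        dispersions=np.asarray(dispersions)
        if dispersions is not None
        else np.asarray(test_table.get("dispersion", [])),
        lfc_threshold=lfc_threshold,
        alpha=alpha,
    )


class NBDifferentialExpression:
    """Model object for two-group NB differential expression.

    Statsmodels-style usage::

        model = NBDifferentialExpression.from_dataframe(counts_df, groups)
        res = model.fit()
        res.summary()

    All-zero loci are excluded before testing (and from the BH family).
    """

    def __init__(
        self,
        raw_counts: np.ndarray,
        groups: Sequence[str],
        locus_ids: Sequence[str] | None = None,
    ):
        self.raw_counts = np.asarray(raw_counts, dtype=np.int64)
        self.groups = list(groups)
        if self.raw_counts.shape[1] != len(self.groups):
            raise ValueError("one group label per sample required")
        self.locus_ids = (
            list(locus_ids)
            if locus_ids is not None
            else [f"locus_{i+1}" for i in range(self.raw_counts.shape[0])]
        )

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, groups: Sequence[str]
    ) -> "NBDifferentialExpression":
        return cls(counts.to_numpy(), groups, locus_ids=list(counts.index))

    def fit(
        self, lfc_threshold: float = 1.5, alpha: float = 0.05
    ) -> DEResults:
        expressed = self.raw_counts.sum(axis=1) > 0
        counts = self.raw_counts[expressed]
        ids = [l for l, keep in zip(self.locus_ids, expressed) if keep]
        size_factors = estimate_size_factors(self.raw_counts)
        table = nb_wald_test(counts, self.groups, size_factors)
        res = call_de(
            table,
            locus_ids=ids,
            lfc_threshold=lfc_threshold,
            alpha=alpha,
            size_factors=size_factors,
            dispersions=table["dispersion"].to_numpy(),
        )
        res.n_excluded = int((~expressed).sum())
        return res
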