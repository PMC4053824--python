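"""Differential relative-usage testing for exons, introns and junctions.

Each feature is tested for a change, between two conditions, in its usage
proportion within its gene: per sample the feature contributes k reads out
of m = k + (rest of the gene's exonic reads).  Replicate-to-replicate
variability beyond binomial sampling is absorbed by a beta-binomial model
with a per-gene overdispersion rho estimated by the method of moments
(floored at 1e-8, at which the model collapses to a plain binomial).  The
test is a likelihood-ratio test of "one usage proportion" against "one per
condition", referred to chi-square with 1 df, followed by Benjamini-
Hochberg FDR control within each feature class.

Count filters are applied per class before testing: exonic and intronic
features need a total of at least 10 reads over all samples, junctions at
least 2.

Usage proportions are depth-free, so no explicit normalization enters the
test itself; per-sample size factors (median-of-ratios over gene totals)
are computed only as a diagnostic guard.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_COUNT_EXON_INTRON = 10
MIN_COUNT_JUNCTION = 2
DEFAULT_FDR_ALPHA = 0.1
RHO_FLOOR = 1e-8
RHO_CEIL = 0.95
_P_EPS = 1e-9


def filter_features(counts: pd.DataFrame, feature_class: str) -> pd.Index:
    """Features passing the per-class total-count filter.

    ``feature_class`` is one of ``exon``, ``intron``, ``junction``; the
    threshold is a minimum total over all samples (>= 10 for exons and
    introns, >= 2 for junctions).
    """
    if feature_class in ("exon", "intron"):
        min_total = MIN_COUNT_EXON_INTRON
    elif feature_class == "junction":
        min_total = MIN_COUNT_JUNCTION
    else:
        raise ValueError(f"unknown feature class {feature_class!r}")
    totals = counts.sum(axis=1)
    return counts.index[totals >= min_total]


def size_factors(gene_totals: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over per-gene exonic totals."""
    vals = gene_totals.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_vals = np.log(vals)
    finite = np.isfinite(log_vals).all(axis=1)
    if not finite.any():
        return pd.Series(1.0, index=gene_totals.columns)
    geo = log_vals[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_vals[finite] - geo, axis=0))
    return pd.Series(sf, index=gene_totals.columns)


# ---------------------------------------------------------------------------
# Beta-binomial machinery (vectorized across features)
# ---------------------------------------------------------------------------

def _betabin_loglik(k: np.ndarray, m: np.ndarray, p: np.ndarray,
                    rho: np.ndarray) -> np.ndarray:
    """Row sums of the beta-binomial log-likelihood.

    k, m: (F, S) counts and trials (entries with m == 0 are ignored);
    p: (F,) success probability; rho: (F,) overdispersion in (0, 1).
    """
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)[:, None]
    rho = np.clip(rho, RHO_FLOOR, RHO_CEIL)[:, None]
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    valid = m > 0
    kk = np.where(valid, k, 0.0)
    mm = np.where(valid, m, 0.0)
    ll = (gammaln(mm + 1.0) - gammaln(kk + 1.0) - gammaln(mm - kk + 1.0)
          + betaln(kk + a, mm - kk + b) - betaln(a, b))
    return np.where(valid, ll, 0.0).sum(axis=1)


def _mle_p(k: np.ndarray, m: np.ndarray, rho: np.ndarray,
           iters: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of the loglik over p per row.

    Returns (p_hat, loglik at p_hat).  The likelihood is unimodal in p at
    fixed rho, so golden section converges; 80 iterations shrink the
    bracket far below any practical tolerance.
    """
    inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
    lo = np.full(k.shape[0], _P_EPS)
    hi = np.full(k.shape[0], 1.0 - _P_EPS)
    x1 = hi - inv_phi * (hi - lo)
    x2 = lo + inv_phi * (hi - lo)
    f1 = _betabin_loglik(k, m, x1, rho)
    f2 = _betabin_loglik(k, m, x2, rho)
    for _ in range(iters):
        take_left = f1 >= f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
        x1_new = hi - inv_phi * (hi - lo)
        x2_new = lo + inv_phi * (hi - lo)
        x1, x2 = x1_new, x2_new
        f1 = _betabin_loglik(k, m, x1, rho)
        f2 = _betabin_loglik(k, m, x2, rho)
    p_hat = (lo + hi) / 2.0
    return p_hat, _betabin_loglik(k, m, p_hat, rho)


def _moment_dispersion(k: np.ndarray, m: np.ndarray,
                       groups: list[np.ndarray]) -> np.ndarray:
    """Per-row method-of-moments overdispersion estimates.

    For each condition group with >= 2 replicates, Var(k/m) = p(1-p)/m *
    (1 + (m-1) rho) is inverted for rho using the empirical replicate
    variance; estimates are averaged (unclipped, so sampling noise cancels
    rather than biasing upward) across groups.  Rows with no usable group
    return NaN.
    """
    ests = np.full((k.shape[0], len(groups)), np.nan)
    for gi, idx in enumerate(groups):
        if idx.size < 2:
            continue
        kk, mm = k[:, idx], m[:, idx]
        ok = (mm > 0).all(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            phat = np.where(mm > 0, kk / np.maximum(mm, 1), np.nan)
            pbar = kk.sum(axis=1) / np.maximum(mm.sum(axis=1), 1)
            s2 = np.nanvar(phat, axis=1, ddof=1)
            nbar = mm.mean(axis=1)
            denom = pbar * (1.0 - pbar)
            rho = (s2 * nbar / denom - 1.0) / np.maximum(nbar - 1.0, 1e-12)
        usable = ok & (denom > 0) & (nbar > 1)
        ests[usable, gi] = rho[usable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(ests, axis=1)


DISPERSION_PRIOR_WEIGHT = 20


def estimate_gene_dispersion(k: np.ndarray, m: np.ndarray,
                             gene_ids: np.ndarray,
                             groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature rho: moderated per-gene method-of-moments estimates.

    Per-feature moment estimates are averaged within genes, then shrunk
    toward the global mean with a prior weight equivalent to
    ``DISPERSION_PRIOR_WEIGHT`` feature-level estimates (few-replicate
    moment estimates are individually very noisy; unmoderated per-gene
    values inflate the test's type-I error).  The result is floored at
    ``RHO_FLOOR`` (where the model collapses to binomial) and capped at
    ``RHO_CEIL``; genes with no estimable feature use the global mean.
    """
    raw = _moment_dispersion(k, m, groups)
    df = pd.DataFrame({"gene": gene_ids, "raw": raw})
    grp = df.groupby("gene")["raw"]
    gene_mean = grp.transform("mean").to_numpy()
    gene_n = grp.transform("count").to_numpy().astype(float)
    global_mean = np.nanmean(raw) if np.isfinite(raw).any() else RHO_FLOOR
    gene_mean = np.where(np.isfinite(gene_mean), gene_mean, global_mean)
    n0 = DISPERSION_PRIOR_WEIGHT
    shrunk = (gene_n * gene_mean + n0 * global_mean) / (gene_n + n0)
    return np.clip(shrunk, RHO_FLOOR, RHO_CEIL)


# ---------------------------------------------------------------------------
# The usage test
# ---------------------------------------------------------------------------

def test_usage(counts: pd.DataFrame,
               gene_totals: pd.DataFrame,
               feature_genes: pd.Series,
               conditions: dict[str, str],
               feature_class: str,
               condition_a: str | None = None,
               condition_b: str | None = None,
               subtract_self: bool | None = None) -> pd.DataFrame:
    """Beta-binomial LRT of equal usage proportion across two conditions.

    Parameters
    ----------
    counts : feature x sample counts (already filtered by ``filter_features``).
    gene_totals : gene x sample totals over the gene's exonic parts.
    feature_genes : feature id -> gene id.
    conditions : sample id -> condition; exactly two conditions required.
    feature_class : ``exon``, ``intron`` or ``junction``.  For exonic parts
        the feature's own count is removed from the gene total so the
        contrast is "this feature vs the rest of the gene".
    condition_a, condition_b : which condition is the baseline; direction is
        the sign of usage(b) - usage(a).  Defaults to sorted order.

    Returns a DataFrame with usage proportions, p_value and direction; rows
    where both conditions lack usable samples carry NaN p-values.
    """
    samples = [s for s in counts.columns if s in conditions]
    conds = sorted(set(conditions[s] for s in samples))
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    if condition_a is None or condition_b is None:
        condition_a, condition_b = conds
    group_a = np.array([i for i, s in enumerate(samples)
                        if conditions[s] == condition_a])
    group_b = np.array([i for i, s in enumerate(samples)
                        if conditions[s] == condition_b])
    if min(group_a.size, group_b.size) < 2:
        logger.warning("fewer than 2 replicates in a condition; "
                       "dispersion estimates will be unreliable")

    k = counts[samples].to_numpy(dtype=float)
    genes = feature_genes.reindex(counts.index).to_numpy()
    gt = gene_totals.reindex(genes)[samples].to_numpy(dtype=float)
    gt = np.nan_to_num(gt, nan=0.0)
    if subtract_self is None:
        subtract_self = feature_class == "exon"
    rest = gt - k if subtract_self else gt
    rest = np.maximum(rest, 0.0)
    m = k + rest
    # samples where the gene has no reads at all are dropped per feature
    m = np.where(gt > 0, m, 0.0)
    k = np.where(gt > 0, k, 0.0)

    rho = estimate_gene_dispersion(k, m, genes, [group_a, group_b])

    _, ll_null = _mle_p(k, m, rho)
    _, ll_a = _mle_p(k[:, group_a], m[:, group_a], rho)
    _, ll_b = _mle_p(k[:, group_b], m[:, group_b], rho)
    stat = np.maximum(2.0 * (ll_a + ll_b - ll_null), 0.0)
    pvals = chi2.sf(stat, df=1)

    ma, mb = m[:, group_a].sum(axis=1), m[:, group_b].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        usage_a = np.where(ma > 0, k[:, group_a].sum(axis=1) / np.maximum(ma, 1), np.nan)
        usage_b = np.where(mb > 0, k[:, group_b].sum(axis=1) / np.maximum(mb, 1), np.nan)
    untested = (ma == 0) | (mb == 0)
    pvals = np.where(untested, np.nan, pvals)
    direction = np.sign(usage_b - usage_a)

    return pd.DataFrame({
        "feature_class": feature_class,
        "gene_id": genes,
        "total_count": counts[samples].sum(axis=1).to_numpy(),
        "usage_a": usage_a,
        "usage_b": usage_b,
        "dispersion": rho,
        "stat": stat,
        "p_value": pvals,
        "direction": direction,
    }, index=counts.index)


def adjust_fdr(results: pd.DataFrame,
               alpha: float = DEFAULT_FDR_ALPHA) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within each feature class.

    Adds ``fdr_adjusted_p`` and ``significant`` (adjusted p < alpha)
    columns; untested rows (NaN p) stay NaN and are never significant.
    """
    out = results.copy()
    out["fdr_adjusted_p"] = np.nan
    out["significant"] = False
    for fclass, idx in out.groupby("feature_class").groups.items():
        sub = out.loc[idx]
        tested = sub.index[sub["p_value"].notna()]
        if len(tested) == 0:
            continue
        _, padj, _, _ = multipletests(out.loc[tested, "p_value"],
                                      method="fdr_bh")
        out.loc[tested, "fdr_adjusted_p"] = padj
        out.loc[tested, "significant"] = padj < alpha
        logger.info("%s: %d tested, %d significant at FDR %.2g",
                    fclass, len(tested),
                    int((padj < alpha).sum()), alpha)
    return out


def write_results_tsv(results: pd.DataFrame, path: str) -> None:
    results.to_csv(path, sep="\t")
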