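"""Expression quantification and negative-binomial differential testing.

The two-group test is an exact-style conditional NB test: size factors by
median-of-ratios, a method-of-moments common dispersion per feature class,
and per-feature p-values from the conditional distribution of the group
count split given the pooled total, with group sums modelled as negative
binomials matched in mean and variance.  Features are called up/down at
|log2 fold change| >= 1 and BH-adjusted FDR < 0.05 (fold change >= 2,
FDR < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOG2FC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-4
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass
class CountMatrix:
    """Integer feature-by-sample counts with lengths and a sample sheet.

    ``samples`` is indexed by sample_id with at least a ``condition``
    column (Ctrl/KO); an optional ``state`` column records primed/naive.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            if not np.allclose(self.counts.values, np.round(self.counts.values)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every feature needs a length")
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ValueError("every count column needs a sample-sheet row")
        conds = self.samples.loc[list(self.counts.columns), "condition"]
        if conds.nunique() < 1 or (conds.value_counts() < 1).any():
            raise ValueError("need at least one sample per condition")

    def condition_columns(self, condition: str) -> list[str]:
        mask = self.samples.loc[list(self.counts.columns), "condition"] == condition
        return [c for c, m in zip(self.counts.columns, mask) if m]


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads, per sample."""
    libsize = cm.counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    kb = cm.lengths.values[:, None] / 1e3
    millions = libsize.values[None, :] / 1e6
    return cm.counts / kb / millions


def filter_expressed(cm: CountMatrix, threshold: int = 10) -> pd.Index:
    """Features with raw count strictly greater than ``threshold`` in >= 1 sample."""
    keep = (cm.counts > threshold).any(axis=1)
    return cm.counts.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.values.astype(float))
    with np.errstate(invalid="ignore"):
        ref = logc.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        # no feature observed in every sample: fall back to library-size ratios
        lib = counts.sum(axis=0).astype(float)
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns)
    ratios = logc[usable] - ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: list[list[str]] | None = None,
) -> float:
    """Quantile-matched method-of-moments common NB dispersion.

    Per feature the NB moment relation  var(z) = q * mean(1/s) + alpha * q**2
    holds for the normalized counts z = k/s with overall mean q; the pooled
    within-group variance w (so planted condition effects do not inflate
    the estimate) is compared against its expectation.  Because w is a
    right-skewed chi-square-like statistic at small replicate numbers, a
    plain median of per-feature alpha estimates is biased down; instead
    the common alpha is chosen so that the median of
    w / (q * mean(1/s) + alpha * q**2) matches the median of
    chi2(df)/df, its null distribution under the normal approximation.
    Floored at 1e-4.
    """
    s = sf.loc[list(counts.columns)].values.astype(float)
    z = counts.values / s[None, :]
    q = z.mean(axis=1)
    if groups is None:
        groups = [list(counts.columns)]
    col_pos = {c: i for i, c in enumerate(counts.columns)}
    ss = np.zeros(len(counts))
    df = 0
    for grp in groups:
        idx = [col_pos[c] for c in grp]
        sub = z[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    if df == 0:
        return DISPERSION_FLOOR
    w = ss / df
    xi = np.mean(1.0 / s)
    ok = q > 0
    q, w = q[ok], w[ok]
    if len(q) == 0:
        return DISPERSION_FLOOR
    target = stats.chi2.median(df) / df
    lo, hi = 0.0, 100.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.median(w / (q * xi + mid * q**2)) > target:
            lo = mid
        else:
            hi = mid
    return float(max((lo + hi) / 2, DISPERSION_FLOOR))


def _group_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log PMF of a group count sum, NB matched in mean/variance (Poisson limit)."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    size = mean**2 / (var - mean)
    p = size / (size + mean)
    return stats.nbinom.logpmf(k, size, p)


def nb_exact_test(
    ka: int, kb: int, sa: np.ndarray, sb: np.ndarray, alpha: float
) -> float:
    """Two-sided conditional test of equal normalized means between groups.

    Conditions on the pooled total K = ka + kb and sums the probabilities
    of all splits (a, K - a) no more probable than the observed one.
    """
    K = ka + kb
    if K == 0:
        return 1.0
    q = K / (sa.sum() + sb.sum())
    mean_a, var_a = q * sa.sum(), q * sa.sum() + alpha * q**2 * np.sum(sa**2)
    mean_b, var_b = q * sb.sum(), q * sb.sum() + alpha * q**2 * np.sum(sb**2)
    a = np.arange(K + 1)
    logp = _group_logpmf(a, mean_a, var_a) + _group_logpmf(K - a, mean_b, var_b)
    logp -= logp.max()
    p = np.exp(logp)
    obs = p[ka]
    return float(min(1.0, p[p <= obs * (1 + 1e-8)].sum() / p.sum()))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _log2fc(mean_ctrl: np.ndarray, mean_ko: np.ndarray) -> np.ndarray:
    pc = LOG2FC_PSEUDOCOUNT
    return np.log2((mean_ko + pc) / (mean_ctrl + pc))


def differential_test(
    cm: CountMatrix,
    *,
    ctrl: str = "Ctrl",
    ko: str = "KO",
    expressed_threshold: int | None = 10,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    dispersion: float | None = None,
    feature_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB differential test over all (expressed) features.

    Returns a frame indexed by feature_id with columns base_mean_ctrl,
    base_mean_ko, log2fc, pvalue, fdr, status.  ``feature_classes`` (e.g.
    TE vs gene) selects a separate common dispersion per class; when
    ``dispersion`` is given it overrides estimation.  Features failing the
    expressed filter are not tested (set ``expressed_threshold=None`` to
    test everything).
    """
    cols_a = cm.condition_columns(ctrl)
    cols_b = cm.condition_columns(ko)
    if not cols_a or not cols_b:
        raise ValueError(f"both conditions {ctrl!r} and {ko!r} need samples")
    if expressed_threshold is not None:
        tested = filter_expressed(cm, expressed_threshold)
    else:
        tested = cm.counts.index
    counts = cm.counts.loc[tested]
    sf = size_factors(cm.counts)
    sa = sf[cols_a].values.astype(float)
    sb = sf[cols_b].values.astype(float)

    if feature_classes is None:
        classes = pd.Series("all", index=tested)
    else:
        classes = feature_classes.reindex(tested).fillna("all")
    alphas: dict[str, float] = {}
    for cls in classes.unique():
        sub = counts.loc[classes == cls]
        alphas[cls] = (
            dispersion
            if dispersion is not None
            else estimate_dispersion(sub, sf, groups=[cols_a, cols_b])
        )

    ka = counts[cols_a].sum(axis=1).values
    kb = counts[cols_b].sum(axis=1).values
    mean_a = (counts[cols_a].values / sa[None, :]).mean(axis=1)
    mean_b = (counts[cols_b].values / sb[None, :]).mean(axis=1)
    pvals = np.ones(len(counts))
    cls_arr = classes.values
    for i in range(len(counts)):
        pvals[i] = nb_exact_test(int(ka[i]), int(kb[i]), sa, sb, alphas[cls_arr[i]])
    fdr = benjamini_hochberg(pvals)
    log2fc = _log2fc(mean_a, mean_b)
    lfc_cut = np.log2(fc_threshold)
    status = np.where(
        (log2fc >= lfc_cut) & (fdr < fdr_threshold),
        "up",
        np.where((log2fc <= -lfc_cut) & (fdr < fdr_threshold), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "base_mean_ctrl": mean_a,
            "base_mean_ko": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "status": status,
        },
        index=pd.Index(tested, name="feature_id"),
    )


def classify_bound(
    elements,
    chip_peaks,
    expressed: set[str] | pd.Index,
    min_bp: int = 1,
) -> pd.Series:
    """Bound flag per element: expressed AND overlapping >= 1 ChIP peak."""
    from .genome import IntervalIndex

    expressed = set(expressed)
    idx = IntervalIndex([p.interval for p in chip_peaks])
    flags = {}
    for el in elements:
        flags[el.element_id] = el.element_id in expressed and idx.any_overlap(
            el.interval, min_bp
        )
    return pd.Series(flags, name="bound")


def bound_counts_by_family(elements, bound: pd.Series) -> pd.Series:
    fam = pd.Series({el.element_id: el.family for el in elements})
    return bound.groupby(fam).sum().astype(int)


def family_enrichment(
    diff: pd.DataFrame,
    elements,
    rpkm: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    ctrl: str = "Ctrl",
    ko: str = "KO",
) -> pd.DataFrame:
    """Per-subfamily DETE enrichment: expression ratio and over-representation.

    ``expr_fold`` is log2 of the (0.5-pseudocounted) mean KO over mean Ctrl
    RPKM across the subfamily's differentially expressed members;
    ``representation_p`` is the hypergeometric upper tail of drawing
    ``n_dete`` subfamily members among all DETEs from the expressed-TE
    universe, BH-corrected across subfamilies.
    """
    sub = pd.Series({el.element_id: el.subfamily for el in elements})
    tested = diff.index.intersection(sub.index)
    if len(tested) == 0:
        raise ValueError("no TE features in differential results")
    sub = sub.loc[tested]
    is_dete = diff.loc[tested, "status"] != "unchanged"
    n_dete_total = int(is_dete.sum())
    if n_dete_total == 0:
        raise ValueError("no differentially expressed TEs")
    M = len(tested)
    ctrl_cols = [s for s in rpkm.columns if samples.loc[s, "condition"] == ctrl]
    ko_cols = [s for s in rpkm.columns if samples.loc[s, "condition"] == ko]

    rows = []
    for name, members in sub.groupby(sub).groups.items():
        members = pd.Index(members)
        n_total = len(members)
        dete_members = members[is_dete.loc[members]]
        n_dete = len(dete_members)
        if n_dete == 0:
            continue
        mc = rpkm.loc[dete_members, ctrl_cols].values.mean()
        mk = rpkm.loc[dete_members, ko_cols].values.mean()
        expr_fold = float(
            np.log2((mk + LOG2FC_PSEUDOCOUNT) / (mc + LOG2FC_PSEUDOCOUNT))
        )
        p = float(stats.hypergeom.sf(n_dete - 1, M, n_total, n_dete_total))
        rows.append(
            {
                "subfamily": name,
                "n_dete": n_dete,
                "n_total": n_total,
                "expr_fold": expr_fold,
                "representation_p": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("subfamily").sort_index()
    out["representation_fdr"] = benjamini_hochberg(out["representation_p"].values)
    return out
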