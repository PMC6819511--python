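"""Group statistics on nodal connectivity metrics and subject metadata.

The battery mirrors a standard two-group neuroimaging workflow: Box's M
check of covariance homogeneity, a two-group MANOVA (Wilks' lambda with
Rao's F) per subnetwork, Bonferroni-protected follow-up ANOVAs per ROI,
Spearman correlations with clinical scores under Benjamini-Hochberg FDR,
partial correlation controlling for corticospinal-tract integrity (the
ipsilesional PLIC mean FA), a 2x2 chi-square / Fisher test for gender
distribution, and cohort summarization.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    roi: object
    score: str
    rho: float
    p_raw: float
    p_fdr: float
    n: int
    partial_r: float | None = None
    partial_p: float | None = None
    control_variable: str | None = None


def boxs_m(groups: Sequence[np.ndarray], criterion: float = 0.001) -> dict:
    """Box's M test of equality of covariance matrices across groups.

    ``M = (N - g) ln|S_pooled| - sum (n_i - 1) ln|S_i|`` with the standard
    chi-square scaling; the homogeneity assumption is flagged as violated
    when p < ``criterion`` (0.001 by convention for this check).
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    p = groups[0].shape[1]
    ns = np.array([gr.shape[0] for gr in groups])
    if np.any(ns <= p):
        raise ValueError("each group needs more observations than variables")
    N = int(ns.sum())
    covs = [np.cov(gr, rowvar=False).reshape(p, p) for gr in groups]
    logdets = []
    for i, S in enumerate(covs):
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(
                f"group {i} covariance is singular; reduce the number of variables"
            )
        logdets.append(ld)
    S_pooled = sum((n - 1) * S for n, S in zip(ns, covs)) / (N - g)
    sign, ld_pooled = np.linalg.slogdet(S_pooled)
    if sign <= 0:
        raise ValueError("pooled covariance is singular; reduce the number of variables")
    M = (N - g) * ld_pooled - float(np.sum((ns - 1) * np.array(logdets)))
    c = ((2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))) * (
        np.sum(1.0 / (ns - 1)) - 1.0 / (N - g)
    )
    chi2 = M * (1.0 - c)
    df = p * (p + 1) * (g - 1) / 2.0
    p_value = float(sps.chi2.sf(max(chi2, 0.0), df))
    return {
        "M": float(M), "chi2": float(chi2), "df": df, "p": p_value,
        "homogeneous": p_value >= criterion,
    }


def manova_wilks(group1: np.ndarray, group2: np.ndarray) -> ManovaResult:
    """Two-group MANOVA: Wilks' lambda = det(E)/det(E+H) with Rao's exact F.

    For two groups Rao's approximation is exact (it equals the F from
    Hotelling's T^2): ``F = ((1 - L)/L) * (N - p - 1)/p`` on ``(p, N-p-1)``
    degrees of freedom; with a single variable it reduces to the one-way
    ANOVA F.
    """
    X1 = np.atleast_2d(np.asarray(group1, dtype=float))
    X2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if X1.ndim == 2 and X1.shape[1] == 1 and X1.shape[0] == 1:
        X1, X2 = X1.T, X2.T
    p = X1.shape[1]
    n1, n2 = X1.shape[0], X2.shape[0]
    N = n1 + n2
    if N <= p + 2:
        raise ValueError("total n must exceed p + number of groups")
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / N
    E = (X1 - m1).T @ (X1 - m1) + (X2 - m2).T @ (X2 - m2)
    H = n1 * np.outer(m1 - grand, m1 - grand) + n2 * np.outer(m2 - grand, m2 - grand)
    sign_e, ld_e = np.linalg.slogdet(E)
    sign_t, ld_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_t <= 0:
        raise ValueError(
            "singular within-group SSCP: too many ROIs in this subnetwork "
            "for the available sample size"
        )
    lam = float(np.exp(ld_e - ld_t))
    df1 = float(p)
    df2 = float(N - p - 1)
    f = ((1.0 - lam) / lam) * (df2 / df1) if lam > 0 else np.inf
    p_value = float(sps.f.sf(f, df1, df2))
    return ManovaResult(wilks_lambda=lam, f_stat=float(f), df1=df1, df2=df2,
                        p_value=p_value)


def anova_bonferroni(
    metrics: np.ndarray,
    group_labels: Sequence,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way two-group ANOVA per column with Bonferroni-protected flags.

    ``metrics`` is (n_subjects, n_rois); the per-test level is
    ``alpha / n_tests`` where ``n_tests`` defaults to the number of columns
    (the ANOVAs run within one subnetwork).
    """
    X = np.atleast_2d(np.asarray(metrics, dtype=float))
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = X[labels == uniq[0]], X[labels == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 subjects per group")
    n_tests = n_tests or X.shape[1]
    thr = alpha / n_tests
    rows = []
    for j in range(X.shape[1]):
        a, b = g1[:, j], g2[:, j]
        sw = ((a - a.mean())**2).sum() + ((b - b.mean())**2).sum()
        degenerate = sw == 0
        if degenerate:
            f, pv = np.inf, 0.0
        else:
            f, pv = sps.f_oneway(a, b)
        rows.append({
            "roi_index": j, "F": float(f), "p": float(pv),
            "significant": bool(pv < thr), "degenerate": degenerate,
        })
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_threshold"] = thr
    df.attrs["n_tests"] = n_tests
    return df


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 10)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(rx, ry[list(perm)]).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_fdr(
    metrics: pd.DataFrame,
    scores: Mapping[str, Sequence[float]],
    exact: bool = False,
    family: str = "per_score",
) -> list[CorrelationResult]:
    """Spearman rho per (ROI column, score) with Benjamini-Hochberg FDR.

    ``family`` controls the BH correction family: ``"per_score"`` (default)
    adjusts across the candidate ROIs separately for each clinical score —
    each metric-by-score analysis is its own family — while ``"global"``
    pools every (ROI, score) pair.  Missing values are dropped pairwise.
    ``exact=True`` switches to the exact permutation p-value for n <= 10
    (the default is the t approximation, adequate at the study's n = 13).
    Constant inputs yield an undefined (NaN) rho reported as missing.
    """
    if family not in ("per_score", "global"):
        raise ValueError("family must be 'per_score' or 'global'")
    results = []
    for score_name, svals in scores.items():
        s = np.asarray(svals, dtype=float)
        for col in metrics.columns:
            m = np.asarray(metrics[col], dtype=float)
            ok = ~(np.isnan(m) | np.isnan(s))
            n = int(ok.sum())
            if n < 4:
                raise ValueError(f"fewer than 4 complete pairs for {col}/{score_name}")
            mm, ss = m[ok], s[ok]
            if np.all(mm == mm[0]) or np.all(ss == ss[0]):
                logger.warning("constant input for %s/%s; rho undefined", col, score_name)
                results.append((col, score_name, np.nan, np.nan, n))
                continue
            res = sps.spearmanr(mm, ss)
            rho, pv = float(res.statistic), float(res.pvalue)
            if exact and n <= 10:
                pv = _spearman_exact_p(mm, ss, rho)
            results.append((col, score_name, rho, pv, n))
    pvals = np.array([r[3] for r in results])
    fams = np.array([r[1] for r in results]) if family == "per_score" \
        else np.zeros(len(results))
    p_fdr = np.full_like(pvals, np.nan)
    for f in np.unique(fams):
        ok = (fams == f) & ~np.isnan(pvals)
        if ok.any():
            p_fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return [
        CorrelationResult(roi=col, score=sname, rho=rho, p_raw=pv,
                          p_fdr=float(pf), n=n)
        for (col, sname, rho, pv, n), pf in zip(results, p_fdr)
    ]


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    method: str = "spearman",
) -> dict:
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with a
    t test on n - 3 df.  ``method="spearman"`` (default) rank-transforms
    all three variables first, matching a Spearman-based zero-order
    analysis; ``method="pearson"`` uses raw values.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[ok], y[ok], z[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need >= 5 complete triples")
    if method == "spearman":
        x, y, z = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        logger.warning("degenerate control variable (|r|=1); partial r undefined")
        return {"partial_r": np.nan, "p": np.nan, "n": n, "method": method}
    pr = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    pr = float(np.clip(pr, -1.0, 1.0))
    df = n - 3
    if abs(pr) == 1.0:
        pv = 0.0
    else:
        t = pr * np.sqrt(df / (1 - pr**2))
        pv = float(2 * sps.t.sf(abs(t), df))
    return {"partial_r": pr, "p": pv, "n": n, "method": method}


def chi_square_2x2(table: np.ndarray) -> dict:
    """Pearson X^2 (with and without Yates correction) and Fisher exact p's.

    All variants are reported because small-sample 2x2 analyses are
    sensitive to the choice and published values rarely say which was run.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    chi2_plain = sps.chi2_contingency(t, correction=False)
    chi2_yates = sps.chi2_contingency(t, correction=True)
    f_two = sps.fisher_exact(t, alternative="two-sided")
    f_less = sps.fisher_exact(t, alternative="less")
    f_greater = sps.fisher_exact(t, alternative="greater")
    return {
        "chi2": float(chi2_plain.statistic), "p_chi2": float(chi2_plain.pvalue),
        "chi2_yates": float(chi2_yates.statistic), "p_chi2_yates": float(chi2_yates.pvalue),
        "p_fisher_two_sided": float(f_two.pvalue),
        "p_fisher_one_sided": float(min(f_less.pvalue, f_greater.pvalue)),
    }


def summarize_cohort(records: Iterable[SubjectRecord]) -> dict:
    """Cohort summary: per-score mean +/- sample SD, lesion tabulations.

    SDs use the n-1 denominator; missing scores are excluded pairwise with
    a count; each lesion location is counted once per patient and sorted by
    descending frequency.
    """
    stroke = [r for r in records if r.group == "stroke"]
    if not stroke:
        raise ValueError("no stroke records to summarize")
    summary: dict = {"n": len(stroke), "scores": {}, "lesion_side_counts": {},
                     "lesion_location_counts": {}}
    for score in ("arat", "fma_ue", "fma_se", "fma_wh", "time_since_stroke"):
        vals = np.array([getattr(r, score) for r in stroke
                         if getattr(r, score) is not None], dtype=float)
        entry = {"n": int(len(vals)), "n_missing": len(stroke) - len(vals)}
        if len(vals) >= 1:
            entry["mean"] = float(vals.mean())
            entry["sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else None
        summary["scores"][score] = entry
    side = Counter(r.lesion_side for r in stroke if r.lesion_side in ("L", "R"))
    summary["lesion_side_counts"] = dict(side)
    loc = Counter(l for r in stroke for l in set(r.lesion_locations))
    summary["lesion_location_counts"] = dict(
        sorted(loc.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return summary


def subnetwork_battery(
    metric_values: np.ndarray,
    group_labels: Sequence,
    blocks: Mapping[tuple[str, str], np.ndarray],
    alpha: float = 0.05,
    box_criterion: float = 0.001,
    gate_on_manova: bool = True,
) -> pd.DataFrame:
    """MANOVA per subnetwork block plus Bonferroni-protected follow-up ANOVAs.

    ``metric_values`` is (n_subjects, n_rois) for one nodal metric (CS or
    rFA).  Returns one row per block with Box's M, Wilks' lambda, the
    MANOVA p, and the list of ROIs surviving the 0.05/k follow-up ANOVAs.
    The follow-ups serve to locate a significant multivariate effect, so by
    default (``gate_on_manova``) no ROI is flagged in a block whose MANOVA
    is not itself significant at ``alpha``.
    """
    X = np.asarray(metric_values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for (net, hemi), idx in blocks.items():
        sub = X[:, idx]
        g1, g2 = sub[labels == uniq[0]], sub[labels == uniq[1]]
        try:
            box = boxs_m([g1, g2], criterion=box_criterion)
        except ValueError as exc:
            box = {"M": np.nan, "p": np.nan, "homogeneous": None, "error": str(exc)}
        man = manova_wilks(g1, g2)
        anovas = anova_bonferroni(sub, labels, n_tests=len(idx), alpha=alpha)
        sig_rois = [int(idx[i]) for i in anovas.index[anovas["significant"]]]
        if gate_on_manova and man.p_value >= alpha:
            sig_rois = []
        rows.append({
            "subnetwork": net, "hemisphere": hemi, "n_rois": len(idx),
            "box_m": box["M"], "box_p": box["p"],
            "box_homogeneous": box.get("homogeneous"),
            "wilks_lambda": man.wilks_lambda, "manova_F": man.f_stat,
            "df1": man.df1, "df2": man.df2, "manova_p": man.p_value,
            "bonferroni_threshold": alpha / len(idx),
            "significant_rois": sig_rois,
        })
    return pd.DataFrame(rows)
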