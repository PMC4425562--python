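"""Per-gene differential expression statistics.

Two engines are provided:

* A SAM-style permutation test (two-class unpaired and multiclass) with the
  classic fudge factor ``s0`` in the denominator, pooled-permutation
  p-values and median-false-positive q-values.
* An empirical-Bayes moderated t for small balanced contrasts, with the
  variance-prior hyperparameters ``(d0, s0^2)`` fitted by closed-form
  moment matching on ``log s^2``.

Both return a tidy :class:`pandas.DataFrame` with one row per gene:
``gene, statistic, rfold, p, q, called``.  "R fold" is the linear-scale
fold change ``2**(mean_case - mean_ref)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort

__all__ = [
    "SamConfig",
    "DegenerateDesignError",
    "sam_statistic",
    "estimate_s0",
    "sam_analyze",
    "moderated_t",
    "fit_variance_prior",
    "rfold",
    "benjamini_hochberg",
]

RESULT_COLUMNS = ["gene", "statistic", "rfold", "p", "q", "called"]


class DegenerateDesignError(ValueError):
    """A contrast with too few samples (or residual df) to test."""


@dataclass
class SamConfig:
    """Settings for :func:`sam_analyze`.

    ``n_permutations`` defaults to 100 relabelling cycles and calls are
    made at an FDR below 0.05, the conventional operating point for this
    kind of microarray screen.  ``s0_method`` selects between the
    percentile search for the fudge factor and a fixed user value.
    """

    n_permutations: int = 100
    fdr_cutoff: float = 0.05
    s0_method: str = "percentile_search"  # or "fixed"
    s0_fixed: float | None = None
    mode: str = "two_class_unpaired"  # or "multiclass"
    seed: int = 0
    contrast: tuple[str, str] | None = None  # (reference, case) group labels

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0, 1)")
        if self.s0_method not in ("percentile_search", "fixed"):
            raise ValueError(f"unknown s0_method {self.s0_method!r}")
        if self.s0_method == "fixed" and self.s0_fixed is None:
            raise ValueError("s0_method='fixed' requires s0_fixed")
        if self.mode not in ("two_class_unpaired", "multiclass"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------


def _two_class_rs(X: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    """Numerator (mean_b - mean_a) and Welch standard error, per gene.

    ``X`` is genes x samples; ``ia``/``ib`` are column indices of the
    reference and case group.  Unequal variances are assumed: the
    standard error is ``sqrt(s_a^2/n_a + s_b^2/n_b)``.
    """
    na, nb = len(ia), len(ib)
    if na < 2 or nb < 2:
        raise DegenerateDesignError("each group needs at least 2 samples")
    Xa, Xb = X[:, ia], X[:, ib]
    r = Xb.mean(axis=1) - Xa.mean(axis=1)
    va = Xa.var(axis=1, ddof=1)
    vb = Xb.var(axis=1, ddof=1)
    s = np.sqrt(va / na + vb / nb)
    return r, s


def _multiclass_rs(X: np.ndarray, group_idx: list[np.ndarray]):
    """F-like numerator and pooled within-group scale, per gene.

    ``r = sqrt( (sum_k 1/n_k) * sum_k n_k (xbar_k - xbar)^2 )`` reduces to
    ``|mean_2 - mean_1|`` for two groups;
    ``s = sqrt( (sum_k 1/n_k) / (N - K) * within-SS )`` is the matching
    pooled scale, so ``r/s`` is a between/within variation ratio.
    """
    K = len(group_idx)
    ns = np.array([len(idx) for idx in group_idx])
    if np.any(ns < 2):
        raise DegenerateDesignError("each group needs at least 2 samples")
    N = int(ns.sum())
    inv_sum = float((1.0 / ns).sum())
    grand = X[:, np.concatenate(group_idx)].mean(axis=1)
    between = np.zeros(X.shape[0])
    within = np.zeros(X.shape[0])
    for idx, nk in zip(group_idx, ns):
        mk = X[:, idx].mean(axis=1)
        between += nk * (mk - grand) ** 2
        within += ((X[:, idx] - mk[:, None]) ** 2).sum(axis=1)
    r = np.sqrt(inv_sum * between)
    s = np.sqrt(inv_sum / (N - K) * within)
    return r, s


def sam_statistic(values_g, labels, s0: float):
    """SAM statistic for a single gene.

    Two distinct labels give the two-class ``d = (mean_2 - mean_1)/(se + s0)``
    with a Welch (unequal-variance) standard error; group order follows the
    sorted label order.  More than two labels give the multiclass
    (F-like, non-negative) form.
    """
    x = np.asarray(values_g, dtype=float)[None, :]
    labels = np.asarray(labels)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    uniq = sorted(set(labels.tolist()))
    idx = [np.flatnonzero(labels == u) for u in uniq]
    if len(uniq) < 2:
        raise DegenerateDesignError("need at least two groups")
    if len(uniq) == 2:
        r, s = _two_class_rs(x, idx[0], idx[1])
    else:
        r, s = _multiclass_rs(x, idx)
    return float(r[0] / (s[0] + s0))


# ---------------------------------------------------------------------------
# Fudge factor search
# ---------------------------------------------------------------------------

_S0_PERCENTILES = np.arange(0, 101, 5)


def estimate_s0(per_gene_r, per_gene_s, n_bins: int | None = None) -> float:
    """Percentile search for the SAM fudge factor.

    Candidates are the 0th, 5th, ..., 100th percentiles of the per-gene
    scale ``s``.  For each candidate the genes are split into quantile
    bins of ``s`` and the candidate minimising the coefficient of
    variation of the bin-wise median absolute deviation of ``d = r/(s+s0)``
    is returned (ties break toward the smallest percentile).
    """
    r = np.asarray(per_gene_r, dtype=float)
    s = np.asarray(per_gene_s, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("per_gene_r and per_gene_s must be equal-length vectors")
    if r.size < 10:
        raise ValueError("s0 search needs at least 10 genes")
    candidates = np.percentile(s, _S0_PERCENTILES)
    if np.all(s == 0):
        warnings.warn(
            "all per-gene scales are zero; s0 search is undefined, "
            "returning a nominal positive fudge",
            stacklevel=2,
        )
        return 1e-8
    if n_bins is None:
        n_bins = min(100, max(2, r.size // 10))
    # quantile bins of s (fixed across candidates)
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    cvs = np.empty(len(candidates))
    for j, alpha in enumerate(candidates):
        d = r / (s + alpha)
        mads = np.array(
            [np.median(np.abs(d[b] - np.median(d[b]))) / 0.64 for b in bins]
        )
        m = mads.mean()
        if m == 0:
            cvs[j] = 0.0 if np.all(mads == 0) else np.inf
        else:
            cvs[j] = mads.std(ddof=1) / m
    return float(candidates[int(np.argmin(cvs))])


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _count_distinct_relabelings(labels: np.ndarray) -> int:
    uniq, counts = np.unique(labels, return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _enumerate_relabelings(labels: np.ndarray):
    """All distinct assignments of the label multiset to sample positions."""
    uniq = sorted(set(labels.tolist()))
    n = len(labels)
    counts = {u: int(np.sum(labels == u)) for u in uniq}

    def choose(rest_idx: tuple, ulist: list[str]):
        if len(ulist) == 1:
            yield {ulist[0]: rest_idx}
            return
        u = ulist[0]
        for pick in combinations(rest_idx, counts[u]):
            rest = tuple(i for i in rest_idx if i not in set(pick))
            for tail in choose(rest, ulist[1:]):
                out = {u: pick}
                out.update(tail)
                yield out

    for assign in choose(tuple(range(n)), uniq):
        lab = np.empty(n, dtype=object)
        for u, idxs in assign.items():
            for i in idxs:
                lab[i] = u
        yield lab


def _tail_counts(sorted_pool: np.ndarray, q: np.ndarray) -> np.ndarray:
    """#{pool >= q_i} with inclusive ties, pool pre-sorted ascending."""
    return sorted_pool.size - np.searchsorted(sorted_pool, q, side="left")


def sam_analyze(cohort: ExpressionCohort, config: SamConfig) -> pd.DataFrame:
    """SAM permutation analysis of a whole cohort.

    The observed statistic uses a fudge factor from :func:`estimate_s0`
    (or a fixed value).  The null is built by relabelling the samples
    ``config.n_permutations`` times with the same ``s0``; per-gene
    p-values pool the permuted ``|d|`` across genes, and q-values are the
    median permuted false-positive count at each gene's ``|d|`` divided by
    its observed rank, made monotone.  If fewer distinct relabelings exist
    than permutations requested, the null enumerates them exhaustively.
    """
    X = cohort.values
    labels = np.array([cohort.groups[s] for s in cohort.samples], dtype=object)
    uniq = sorted(set(labels.tolist()))
    if config.mode == "two_class_unpaired":
        if config.contrast is not None:
            ref, case = config.contrast
            if ref not in uniq or case not in uniq:
                raise ValueError(f"contrast groups {config.contrast} not in cohort")
        else:
            if len(uniq) != 2:
                raise ValueError(
                    "two-class mode needs exactly two groups "
                    f"(got {uniq}); pass config.contrast or subset the cohort"
                )
            ref, case = uniq
        keep = np.isin(labels, [ref, case])
        X = X[:, keep]
        labels = labels[keep]
        ia = np.flatnonzero(labels == ref)
        ib = np.flatnonzero(labels == case)
        r_obs, s_obs = _two_class_rs(X, ia, ib)
        lfc = r_obs  # mean(case) - mean(ref), log2

        def stat(lab: np.ndarray) -> np.ndarray:
            ja = np.flatnonzero(lab == ref)
            jb = np.flatnonzero(lab == case)
            r, s = _two_class_rs(X, ja, jb)
            return r / (s + s0)

    else:
        group_idx = [np.flatnonzero(labels == u) for u in uniq]
        r_obs, s_obs = _multiclass_rs(X, group_idx)
        means = np.stack([X[:, idx].mean(axis=1) for idx in group_idx])
        lfc = means.max(axis=0) - means.min(axis=0)  # widest pairwise shift

        def stat(lab: np.ndarray) -> np.ndarray:
            idx = [np.flatnonzero(lab == u) for u in uniq]
            r, s = _multiclass_rs(X, idx)
            return r / (s + s0)

    if config.s0_method == "fixed":
        s0 = float(config.s0_fixed)
    else:
        s0 = estimate_s0(r_obs, s_obs)

    d_obs = r_obs / (s_obs + s0)
    abs_obs = np.abs(d_obs)
    G = X.shape[0]

    distinct = _count_distinct_relabelings(labels)
    if config.n_permutations >= distinct:
        warnings.warn(
            f"{config.n_permutations} permutations requested but only "
            f"{distinct} distinct relabelings exist; enumerating exhaustively",
            stacklevel=2,
        )
        perm_labels = list(_enumerate_relabelings(labels))
    else:
        rng = np.random.default_rng(config.seed)
        perm_labels = [labels[rng.permutation(labels.size)]
                       for _ in range(config.n_permutations)]
    B = len(perm_labels)

    abs_perm = np.empty((B, G))
    for b, lab in enumerate(perm_labels):
        abs_perm[b] = np.abs(stat(lab))

    # pooled p-values (inclusive >=; floored one count to stay positive)
    pool = np.sort(abs_perm, axis=None)
    counts = _tail_counts(pool, abs_obs)
    p = np.maximum(counts, 1) / pool.size

    # q-values: median per-permutation false-positive count / observed rank
    fp = np.empty((B, G))
    for b in range(B):
        fp[b] = _tail_counts(np.sort(abs_perm[b]), abs_obs)
    fp_med = np.median(fp, axis=0)
    rank = _tail_counts(np.sort(abs_obs), abs_obs)  # includes the gene itself
    q = fp_med / rank
    # enforce monotone: a larger |d| never has a larger q
    order = np.argsort(-abs_obs, kind="stable")
    q_sorted = np.maximum.accumulate(q[order])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    q = np.clip(q, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "gene": cohort.genes,
            "statistic": d_obs,
            "rfold": np.exp2(lfc),
            "p": p,
            "q": q,
            "called": q < config.fdr_cutoff,
        }
    )
    out.attrs["s0"] = s0
    out.attrs["n_permutations_used"] = B
    out.attrs["exhaustive"] = config.n_permutations >= distinct
    return out


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y -> trigamma(y), monotone decreasing.
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2, df) -> tuple[float, float]:
    """Moment-matching fit of the scaled inverse-chi-square variance prior.

    Under the hierarchical model ``s2_g ~ s0^2 * F(df_g, d0)``,
    ``log s2_g`` has known mean/variance offsets in terms of digamma and
    trigamma functions; matching the empirical mean and variance of
    ``log s2`` yields closed-form ``(d0, s0^2)``.  Returns
    ``(inf, exp(mean))`` when the empirical spread is no larger than the
    sampling noise (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if not np.all(ok):
        warnings.warn("dropping genes with zero sample variance from prior fit",
                      stacklevel=2)
        s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = math.exp(
        emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0sq


def _moderated_t_arrays(
    Xa: np.ndarray, Xb: np.ndarray, prior: tuple[float, float] | None = None
):
    """Moderated t on raw arrays; returns (t, p, lfc, df_total).

    ``Xa`` is the reference group, ``Xb`` the case (genes x samples each).
    ``prior=(d0, s0sq)`` overrides the moment-matching fit; ``d0=0``
    recovers the ordinary pooled-variance t exactly.
    """
    na, nb = Xa.shape[1], Xb.shape[1]
    if na < 2 or nb < 2:
        raise DegenerateDesignError("each contrasted group needs >= 2 samples")
    dg = na + nb - 2
    if dg <= 0:
        raise DegenerateDesignError("zero residual degrees of freedom")
    ma, mb = Xa.mean(axis=1), Xb.mean(axis=1)
    wss = ((Xa - ma[:, None]) ** 2).sum(axis=1) + ((Xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = wss / dg
    if prior is None:
        d0, s0sq = fit_variance_prior(s2, dg)
    else:
        d0, s0sq = prior
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = math.inf
    else:
        s2_tilde = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    lfc = mb - ma
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, lfc, df_total, (d0, s0sq)


def moderated_t(
    cohort: ExpressionCohort,
    contrast: tuple[str, str],
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t for a two-group contrast.

    ``contrast = (reference, case)``; positive statistics mean higher
    expression in the case group.  q-values are Benjamini-Hochberg.
    """
    ref, case = contrast
    ia = cohort.sample_indices(ref)
    ib = cohort.sample_indices(case)
    t, p, lfc, df_total, fitted = _moderated_t_arrays(
        cohort.values[:, ia], cohort.values[:, ib], prior=prior
    )
    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "gene": cohort.genes,
            "statistic": t,
            "rfold": np.exp2(lfc),
            "p": p,
            "q": q,
            "called": q < 0.05,
        }
    )
    out.attrs["prior"] = fitted
    out.attrs["df_total"] = df_total
    return out


# ---------------------------------------------------------------------------
# Fold change and multiple testing
# ---------------------------------------------------------------------------


def rfold(values_g, labels, case_label=None, ref_label=None) -> float:
    """Linear-scale fold change ``2**(mean_case - mean_ref)`` for one gene.

    With labels given and no explicit case/reference, the sorted label
    order is (reference, case).
    """
    x = np.asarray(values_g, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("rfold needs exactly two groups")
    if ref_label is None:
        ref_label = uniq[0]
    if case_label is None:
        case_label = uniq[1] if uniq[1] != ref_label else uniq[0]
    xc = x[labels == case_label]
    xr = x[labels == ref_label]
    if xc.size == 0 or xr.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(2.0 ** (xc.mean() - xr.mean()))


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up FDR adjustment (delegates to statsmodels)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        idx = int(np.flatnonzero(np.isnan(p))[0])
        raise ValueError(f"NaN p-value at index {idx}")
    if np.any((p < 0) | (p > 1)):
        idx = int(np.flatnonzero((p < 0) | (p > 1))[0])
        raise ValueError(f"p-value out of [0, 1] at index {idx}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
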