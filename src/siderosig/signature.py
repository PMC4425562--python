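"""Consensus gene-signature selection by repeated balanced subsampling.

Rather than trusting one differential-expression run on a small,
unbalanced mutation split, the selector draws many balanced subsets
(``k`` samples per class), runs a moderated-t analysis on each, and
counts how often every gene reaches significance.  Genes are then ranked
by that selection frequency; the top-N list is the consensus signature.
A permutation "global test" checks whether the selected signature as a
whole separates the two classes.

Two presets reproduce the designs this package targets: ``mut200``
(7 vs 7 samples, 10000 contrasts, q < 0.01, top 200 genes) for the
spliceosome-mutated vs unmutated split, and ``rs75`` (4 vs 4, 7425
contrasts, FDR < 0.10, top 75, significant in at least 10 contrasts) for
the within-RARS mutation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ExpressionCohort
from .differential import _moderated_t_arrays, benjamini_hochberg

__all__ = [
    "SubsampleConfig",
    "ConsensusSignature",
    "PRESETS",
    "subsample_signature",
    "global_association_test",
]


@dataclass(frozen=True)
class SubsampleConfig:
    k_per_class: int
    n_contrasts: int
    fdr_cutoff: float
    top_n: int
    min_contrasts: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_class < 2:
            raise ValueError("k_per_class must be >= 2")
        if self.n_contrasts < 1:
            raise ValueError("n_contrasts must be >= 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_contrasts is not None and self.min_contrasts > self.n_contrasts:
            raise ValueError("min_contrasts cannot exceed n_contrasts")


PRESETS: dict[str, SubsampleConfig] = {
    "mut200": SubsampleConfig(k_per_class=7, n_contrasts=10_000,
                              fdr_cutoff=0.01, top_n=200),
    "rs75": SubsampleConfig(k_per_class=4, n_contrasts=7425,
                            fdr_cutoff=0.10, top_n=75, min_contrasts=10),
}


@dataclass
class ConsensusSignature:
    """Per-gene selection frequencies and the ranked top-N gene list."""

    frequency: dict[str, int]
    n_contrasts_run: int
    top_genes: list[str]
    config: SubsampleConfig
    mean_abs_t: dict[str, float] = field(default_factory=dict)


def subsample_signature(
    cohort: ExpressionCohort,
    class_a,
    class_b,
    config: SubsampleConfig,
) -> ConsensusSignature:
    """Count per-gene significance across balanced random subsample contrasts.

    Each contrast draws ``k_per_class`` samples without replacement from
    each class, runs the moderated t on the subset and marks genes with a
    Benjamini-Hochberg q below ``fdr_cutoff``.  Distinct contrasts may
    repeat subsets (the requested number of contrasts can exceed the
    number of distinct subset pairs).  Top-N ties are broken by the mean
    absolute moderated t across contrasts, then by gene ID.
    """
    class_a, class_b = list(class_a), list(class_b)
    if set(class_a) & set(class_b):
        raise ValueError("classes must be disjoint")
    if len(class_a) < config.k_per_class or len(class_b) < config.k_per_class:
        raise ValueError(
            f"k_per_class={config.k_per_class} exceeds a class size "
            f"({len(class_a)} vs {len(class_b)})"
        )
    ia = cohort.indices_of(class_a)
    ib = cohort.indices_of(class_b)
    X = cohort.values
    G = cohort.n_genes
    rng = np.random.default_rng(config.seed)

    counts = np.zeros(G, dtype=int)
    abs_t_sum = np.zeros(G)
    k = config.k_per_class
    for _ in range(config.n_contrasts):
        sa = rng.choice(ia, size=k, replace=False)
        sb = rng.choice(ib, size=k, replace=False)
        t, p, _, _, _ = _moderated_t_arrays(X[:, sa], X[:, sb])
        q = benjamini_hochberg(p)
        counts += q < config.fdr_cutoff
        abs_t_sum += np.abs(t)

    mean_abs_t = abs_t_sum / config.n_contrasts
    eligible = counts > 0
    if config.min_contrasts is not None:
        eligible = counts >= config.min_contrasts
    idx = np.flatnonzero(eligible)
    genes = np.asarray(cohort.genes, dtype=object)
    order = sorted(
        idx.tolist(),
        key=lambda i: (-counts[i], -mean_abs_t[i], genes[i]),
    )
    top = [str(genes[i]) for i in order[: config.top_n]]
    if len(top) < config.top_n and config.min_contrasts is None:
        warnings.warn(
            f"only {len(top)} genes were ever significant; "
            f"returning a shorter list than top_n={config.top_n}",
            stacklevel=2,
        )
    return ConsensusSignature(
        frequency={str(g): int(c) for g, c in zip(genes, counts)},
        n_contrasts_run=config.n_contrasts,
        top_genes=top,
        config=config,
        mean_abs_t={str(g): float(t) for g, t in zip(genes, mean_abs_t)},
    )


def global_association_test(
    cohort: ExpressionCohort,
    signature,
    labels,
    n_permutations: int = 9999,
    seed: int = 0,
) -> float:
    """Permutation test of whether a signature predicts a binary class.

    The statistic is ``Q = sum_g (sum_s x_gs * y~_s)^2`` over the
    signature genes, with class labels centred and each gene's expression
    row standardised (zero-variance rows contribute nothing), so Q is
    scale-free.  The p-value is ``(1 + #{Q_perm >= Q_obs}) /
    (1 + n_permutations)`` over random label permutations.

    ``labels`` maps sample -> class (exactly two distinct values), or is
    a sequence aligned with ``cohort.samples``.
    """
    sig = list(signature)
    missing = set(sig) - set(cohort.genes)
    if missing:
        raise ValueError(f"signature genes not in cohort: {sorted(missing)[:5]}")
    if isinstance(labels, dict):
        y_raw = [labels[s] for s in cohort.samples]
    else:
        y_raw = list(labels)
        if len(y_raw) != cohort.n_samples:
            raise ValueError("labels length does not match cohort samples")
    classes = sorted(set(y_raw))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = np.array([1.0 if v == classes[1] else 0.0 for v in y_raw])
    y = y - y.mean()

    gene_pos = {g: i for i, g in enumerate(cohort.genes)}
    rows = np.array([gene_pos[g] for g in sig], dtype=int)
    X = cohort.values[rows]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / sd, 0.0)

    def q_stat(yv: np.ndarray) -> float:
        return float(((Z @ yv) ** 2).sum())

    q_obs = q_stat(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if q_stat(y[rng.permutation(y.size)]) >= q_obs:
            hits += 1
    return (1 + hits) / (1 + n_permutations)
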