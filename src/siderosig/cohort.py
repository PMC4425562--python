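"""Expression-cohort container shared by all pipeline stages.

An :class:`ExpressionCohort` holds a log2 intensity matrix (genes x samples)
together with sample phenotype labels (group, optional mutation status).
It is the substrate of every differential-expression statistic in the
package and deliberately stays close to an RMA-normalised microarray
matrix: one float per gene and sample, no probe-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionCohort", "CohortError"]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class ExpressionCohort:
    """Log2 expression matrix with sample annotations.

    Parameters
    ----------
    genes
        Ordered gene identifiers (opaque strings; probeset IDs or symbols).
    samples
        Ordered sample identifiers.
    values
        ``(len(genes), len(samples))`` array of finite log2 intensities.
    groups
        Mapping sample ID -> group label; every sample must be present.
    mutation_status
        Optional mapping sample ID -> ``"mutated"`` / ``"unmutated"`` for
        the spliceosome-mutation cohort splits. May cover a subset of
        samples (status is not always known clinically).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    groups: dict[str, str]
    mutation_status: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise CohortError(f"duplicate gene ID: {dup!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise CohortError(f"duplicate sample ID: {dup!r}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise CohortError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise CohortError(f"samples without a group label: {missing[:5]}")
        if self.mutation_status is not None:
            unknown = [s for s in self.mutation_status if s not in set(self.samples)]
            if unknown:
                raise CohortError(
                    f"mutation status for unknown samples: {unknown[:5]}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def sample_indices(self, group: str) -> np.ndarray:
        """Column indices of all samples in *group*."""
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.groups[s] == group],
            dtype=int,
        )
        if idx.size == 0:
            raise CohortError(f"no samples in group {group!r}")
        return idx

    def indices_of(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise CohortError(f"unknown sample ID: {exc.args[0]!r}") from None

    def mutation_split(self) -> tuple[list[str], list[str]]:
        """Sample IDs with ``mutated`` vs ``unmutated`` status."""
        if self.mutation_status is None:
            raise CohortError("cohort carries no mutation status")
        mut = [s for s in self.samples if self.mutation_status.get(s) == "mutated"]
        unmut = [s for s in self.samples if self.mutation_status.get(s) == "unmutated"]
        return mut, unmut

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        idx = self.indices_of(sample_ids)
        return ExpressionCohort(
            genes=self.genes,
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx],
            groups={self.samples[i]: self.groups[self.samples[i]] for i in idx},
            mutation_status=(
                None
                if self.mutation_status is None
                else {
                    self.samples[i]: self.mutation_status[self.samples[i]]
                    for i in idx
                    if self.samples[i] in self.mutation_status
                }
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def _first_duplicate(items) -> str:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover
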