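"""Targeted-capture variant triage and haplotype association.

The triage cascade mirrors how a candidate-gene capture screen is read
out: catalogued SNPs are discarded first, then variants outside any
coding sequence, then coding variants that do not change an amino acid.
Survivors are the candidate missense/nonsense variants.  A companion pair
of operations classifies samples by a two-SNP haplotype (variant allele
at both linked sites = "variant haplotype") and compares carrier
frequencies between cases and controls.

Coordinates are 1-based inclusive throughout (VCF convention).  Only
single-nucleotide substitutions are handled; indels are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .setstats import (
    ContingencyTable2x2,
    chi_square_2x2,
    fisher_exact,
    odds_ratio_ci,
)

__all__ = [
    "VariantRecord",
    "SNPCatalog",
    "TranscriptModel",
    "CascadeReport",
    "HaplotypeCall",
    "AminoAcidChange",
    "ReferenceMismatchError",
    "ModelIntegrityError",
    "filter_known_snps",
    "classify_coding",
    "annotate_amino_acid_change",
    "run_cascade",
    "call_haplotypes",
    "compare_carrier_frequencies",
]

_VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ModelIntegrityError(ValueError):
    """A transcript model is internally inconsistent."""


class ReferenceMismatchError(ValueError):
    """A variant's reference allele disagrees with the CDS sequence."""


@dataclass(frozen=True)
class VariantRecord:
    """A called single-nucleotide substitution in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str
    genotype: str = "het"  # or "hom"
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only single-nucleotide substitutions are supported "
                f"(got {self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos})"
            )
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"genotype must be het/hom, got {self.genotype!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class SNPCatalog:
    """Known-polymorphism lookup by (chrom, pos, alt) key and/or ID."""

    keys: set[tuple[str, int, str]] = field(default_factory=set)
    ids: set[str] = field(default_factory=set)

    def __contains__(self, variant: VariantRecord) -> bool:
        if variant.key in self.keys:
            return True
        return variant.id is not None and variant.id in self.ids

    def __len__(self) -> int:
        return len(self.keys) + len(self.ids)


@dataclass
class TranscriptModel:
    """A CDS model: ordered genomic intervals plus the spliced coding sequence.

    ``cds_sequence`` is on the coding strand; for minus-strand models it is
    the reverse complement of the concatenated genomic intervals.
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]  # 1-based inclusive, genomic order
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelIntegrityError(f"{self.gene}: strand must be + or -")
        self.cds_sequence = self.cds_sequence.upper()
        if set(self.cds_sequence) - _VALID_BASES:
            raise ModelIntegrityError(f"{self.gene}: non-ACGT base in CDS")
        spans = []
        last = 0
        for lo, hi in self.cds_intervals:
            if lo < 1 or hi < lo:
                raise ModelIntegrityError(f"{self.gene}: bad interval ({lo}, {hi})")
            if lo <= last:
                raise ModelIntegrityError(
                    f"{self.gene}: intervals must be sorted and non-overlapping"
                )
            spans.append(hi - lo + 1)
            last = hi
        if sum(spans) != len(self.cds_sequence):
            raise ModelIntegrityError(
                f"{self.gene}: interval lengths sum to {sum(spans)} "
                f"but CDS is {len(self.cds_sequence)} nt"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ModelIntegrityError(f"{self.gene}: CDS length not divisible by 3")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(
            lo <= pos <= hi for lo, hi in self.cds_intervals
        )

    def cds_offset(self, pos: int) -> int:
        """0-based offset within the spliced CDS (strand-aware)."""
        off = 0
        for lo, hi in self.cds_intervals:
            if lo <= pos <= hi:
                forward = off + (pos - lo)
                if self.strand == "+":
                    return forward
                return len(self.cds_sequence) - 1 - forward
            off += hi - lo + 1
        raise ValueError(f"position {pos} not in CDS of {self.gene}")


@dataclass
class CascadeReport:
    """Stage-by-stage accounting of the triage cascade."""

    n_input: int
    n_after_snp_filter: int
    n_after_coding_filter: int
    n_after_nonsyn_filter: int

    def __post_init__(self) -> None:
        counts = [self.n_input, self.n_after_snp_filter,
                  self.n_after_coding_filter, self.n_after_nonsyn_filter]
        if any(x < 0 for x in counts):
            raise ValueError("negative stage count")
        if any(counts[i] < counts[i + 1] for i in range(3)):
            raise ValueError("stage counts must be monotone non-increasing")

    @property
    def discarded(self) -> dict[str, int]:
        return {
            "known_snp": self.n_input - self.n_after_snp_filter,
            "non_coding": self.n_after_snp_filter - self.n_after_coding_filter,
            "synonymous": self.n_after_coding_filter - self.n_after_nonsyn_filter,
        }

    @property
    def discarded_fractions(self) -> dict[str, float]:
        """Within-stage discard fractions (of that stage's input)."""
        stages = [self.n_input, self.n_after_snp_filter, self.n_after_coding_filter]
        out = {}
        for (name, n_disc), n_in in zip(self.discarded.items(), stages):
            out[name] = n_disc / n_in if n_in else 0.0
        return out


@dataclass(frozen=True)
class HaplotypeCall:
    sample: str
    haplotype_class: str  # common / variant / other


@dataclass(frozen=True)
class AminoAcidChange:
    codon_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    consequence: str  # synonymous / missense / nonsense / start_loss


# ---------------------------------------------------------------------------
# Cascade stages
# ---------------------------------------------------------------------------


def filter_known_snps(
    variants: list[VariantRecord], catalog: SNPCatalog
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, discarded) by catalog membership."""
    kept, discarded = [], []
    for v in variants:
        (discarded if v in catalog else kept).append(v)
    return kept, discarded


def _models_by_chrom(models) -> dict[str, list[TranscriptModel]]:
    by: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by.setdefault(m.chrom, []).append(m)
    return by


def classify_coding(variant: VariantRecord, models) -> str:
    """``"coding"`` iff the position lies in some model's CDS intervals."""
    for m in _models_by_chrom(models).get(variant.chrom, []):
        if m.contains(variant.chrom, variant.pos):
            return "coding"
    return "non_coding"


def annotate_amino_acid_change(
    variant: VariantRecord, model: TranscriptModel
) -> AminoAcidChange:
    """Codon-level consequence of a coding substitution.

    Maps the genomic position to its spliced-CDS offset (on the minus
    strand the offset counts from the rightmost CDS base and both alleles
    are complemented), mutates the affected codon and translates both
    versions with the standard nuclear code.
    """
    if not model.contains(variant.chrom, variant.pos):
        raise ValueError(
            f"{variant.chrom}:{variant.pos} is not coding in {model.gene}"
        )
    off = model.cds_offset(variant.pos)
    ref, alt = variant.ref, variant.alt
    if model.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    if model.cds_sequence[off] != ref:
        raise ReferenceMismatchError(
            f"{model.gene} {variant.chrom}:{variant.pos}: reference allele "
            f"{variant.ref!r} does not match CDS base "
            f"{model.cds_sequence[off]!r} at offset {off}"
        )
    codon_index = off // 3 + 1
    start = (codon_index - 1) * 3
    codon = model.cds_sequence[start:start + 3]
    within = off % 3
    mcodon = codon[:within] + alt + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mcodon).translate())
    if alt_aa == ref_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "nonsense"
    elif codon_index == 1 and ref_aa == "M":
        consequence = "start_loss"
    else:
        consequence = "missense"
    return AminoAcidChange(codon_index, ref_aa, alt_aa, consequence)


def run_cascade(
    variants: list[VariantRecord],
    catalog: SNPCatalog,
    models,
) -> tuple[list[VariantRecord], CascadeReport]:
    """Known SNPs -> non-coding -> synonymous; survivors change the protein."""
    models = list(models)
    by_chrom = _models_by_chrom(models)

    after_snp, _ = filter_known_snps(variants, catalog)

    coding_pairs: list[tuple[VariantRecord, TranscriptModel]] = []
    for v in after_snp:
        for m in by_chrom.get(v.chrom, []):
            if m.contains(v.chrom, v.pos):
                coding_pairs.append((v, m))
                break
    survivors = [
        v
        for v, m in coding_pairs
        if annotate_amino_acid_change(v, m).consequence
        in ("missense", "nonsense", "start_loss")
    ]
    report = CascadeReport(
        n_input=len(variants),
        n_after_snp_filter=len(after_snp),
        n_after_coding_filter=len(coding_pairs),
        n_after_nonsyn_filter=len(survivors),
    )
    return survivors, report


# ---------------------------------------------------------------------------
# Two-SNP haplotypes
# ---------------------------------------------------------------------------


def call_haplotypes(
    genotypes: dict[str, tuple[str | None, str | None]],
    site_defs: tuple[tuple[str, str], tuple[str, str]],
) -> list[HaplotypeCall]:
    """Classify each sample by its two-site haplotype.

    ``genotypes`` maps sample -> (genotype at site 1, genotype at site 2),
    each a string of alleles (e.g. ``"TC"`` for a heterozygote); ``None``
    or empty marks a missing call.  ``site_defs`` gives
    (common allele, variant allele) per site.  A sample is ``variant`` iff
    it carries the variant allele at both sites, ``common`` iff at
    neither, ``other`` otherwise; samples with a missing genotype are
    skipped with a warning.
    """
    (c1, v1), (c2, v2) = site_defs
    calls: list[HaplotypeCall] = []
    skipped = 0
    for sample, (g1, g2) in genotypes.items():
        if not g1 or not g2:
            skipped += 1
            continue
        has1 = v1 in g1.upper()
        has2 = v2 in g2.upper()
        if has1 and has2:
            cls = "variant"
        elif not has1 and not has2:
            cls = "common"
        else:
            cls = "other"
        calls.append(HaplotypeCall(sample=sample, haplotype_class=cls))
    if skipped:
        warnings.warn(
            f"{skipped} sample(s) skipped for missing genotypes", stacklevel=2
        )
    return calls


def compare_carrier_frequencies(
    cases: list[HaplotypeCall], controls: list[HaplotypeCall]
) -> tuple[ContingencyTable2x2, float, float, float]:
    """Case/control 2x2 of variant-haplotype carriers, OR and p-values.

    Returns ``(table, odds_ratio, chi-square p, one-sided Fisher p)``.
    The chi-square is uncorrected; heterozygous carriers count as
    carriers; ``other`` (discordant) samples count as non-carriers.
    """
    if not cases or not controls:
        raise ValueError("both case and control lists must be non-empty")
    a = sum(1 for h in cases if h.haplotype_class == "variant")
    c = sum(1 for h in controls if h.haplotype_class == "variant")
    table = ContingencyTable2x2(a=a, b=len(cases) - a, c=c, d=len(controls) - c)
    or_, _, _ = odds_ratio_ci(table)
    _, chi_p = chi_square_2x2(table, yates=False)
    fisher_p = fisher_exact(table, "one_greater")
    return table, or_, chi_p, fisher_p
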