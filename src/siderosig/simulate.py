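"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline (differential expression,
consensus-signature selection, variant triage, haplotype association) can
be exercised against data generated here, so tests and reproduction runs
need no external patient data.  The generator is an idealisation: gene
baselines are Gaussian on the log2 scale with i.i.d. Gaussian residuals,
which matches the rough shape of an RMA-normalised microarray matrix but
makes no claim of full biological realism.

Default parameterisations mirror the study design this package targets:
three expression groups of 30 (RARS), 39 (RCUD) and 31 (controls);
spliceosome-mutation splits of 22 vs 13 and 13 vs 6; a six-sample
targeted-capture variant cohort averaging ~1367 variants per sample of
which ~56% are catalogued SNPs, ~85% of the novel ones are non-coding and
~42% of the coding ones change an amino acid; and a two-SNP haplotype
cohort with carrier frequencies of 12% in cases vs 5% in controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .cohort import ExpressionCohort
from .setstats import GeneSetCollection
from .variants import SNPCatalog, TranscriptModel, VariantRecord

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "DesignError",
    "generate_expression_cohort",
    "generate_variant_cohort",
    "generate_gene_sets",
    "generate_haplotype_cohort",
    "rars_cohort_design",
    "assign_mutation_status",
]

BASELINE_MEAN = 7.0   # log2 units, typical microarray intensity centre
BASELINE_SD = 1.5

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


class DesignError(ValueError):
    """A simulation design violates its invariants (names the field)."""


@dataclass
class CohortDesign:
    """Design of a synthetic expression cohort.

    ``group_sizes`` maps group label -> sample count.  ``n_planted`` genes
    are shifted up by ``effect_log2`` (log2 units) in ``planted_group``
    (default: the first group).  Residuals are Normal(0, ``noise_sd``);
    with ``variance_prior`` set, per-gene variances are drawn instead from
    a scaled inverse-chi-square with ``prior_df`` degrees of freedom and
    scale ``prior_scale`` (so the moderated-t hierarchical model holds
    exactly and its hyperparameters can be recovered).
    """

    group_sizes: dict[str, int]
    n_genes: int = 2000
    n_planted: int = 100
    effect_log2: float = 2.0
    noise_sd: float = 0.7
    seed: int = 0
    planted_group: str | None = None
    variance_prior: bool = False
    prior_df: float = 4.0
    prior_scale: float = 0.25  # s0^2 on the variance scale

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise DesignError("group_sizes: at least one group required")
        for g, n in self.group_sizes.items():
            if int(n) < 1:
                raise DesignError(f"group_sizes[{g!r}]: count must be >= 1")
        if self.n_genes < 1:
            raise DesignError("n_genes: must be >= 1")
        if not 0 <= self.n_planted <= self.n_genes:
            raise DesignError("n_planted: must satisfy 0 <= n_planted <= n_genes")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd: must be > 0")
        if self.planted_group is None:
            self.planted_group = next(iter(self.group_sizes))
        elif self.planted_group not in self.group_sizes:
            raise DesignError(
                f"planted_group: {self.planted_group!r} not in group_sizes"
            )


@dataclass
class GroundTruth:
    """Truth ledger emitted alongside every synthetic dataset."""

    planted_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_haplotype_carriers: set[str] = field(default_factory=set)
    planted_missense: list[tuple[str, VariantRecord]] = field(default_factory=list)


def rars_cohort_design(seed: int = 0, **overrides) -> CohortDesign:
    """The default three-group study design: 30 RARS, 39 RCUD, 31 controls."""
    params = dict(
        group_sizes={"RARS": 30, "RCUD": 39, "CTRL": 31},
        n_genes=2000,
        n_planted=100,
        effect_log2=2.0,
        noise_sd=0.7,
        seed=seed,
        planted_group="RARS",
    )
    params.update(overrides)
    return CohortDesign(**params)


def generate_expression_cohort(
    design: CohortDesign,
) -> tuple[ExpressionCohort, GroundTruth]:
    """Draw a log2 expression matrix with planted up-regulated genes.

    Baseline per-gene means are Normal(7, 1.5) on the log2 scale; the
    planted genes gain ``effect_log2`` in the planted group only.
    Reproducible for a fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    samples: list[str] = []
    groups: dict[str, str] = {}
    for label, n in design.group_sizes.items():
        for j in range(n):
            sid = f"{label}_{j + 1:03d}"
            samples.append(sid)
            groups[sid] = label
    S = len(samples)
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=design.n_genes)
    if design.variance_prior:
        sd = np.sqrt(
            design.prior_df * design.prior_scale
            / rng.chisquare(design.prior_df, size=design.n_genes)
        )
    else:
        sd = np.full(design.n_genes, design.noise_sd)
    values = mu[:, None] + rng.standard_normal((design.n_genes, S)) * sd[:, None]

    planted_idx = rng.choice(design.n_genes, size=design.n_planted, replace=False)
    cols = np.array(
        [i for i, s in enumerate(samples) if groups[s] == design.planted_group]
    )
    if design.n_planted and cols.size:
        values[np.ix_(planted_idx, cols)] += design.effect_log2

    cohort = ExpressionCohort(genes=genes, samples=samples,
                              values=values, groups=groups)
    contrast = f"{design.planted_group}_vs_rest"
    truth = GroundTruth(
        planted_genes={contrast: {genes[i] for i in planted_idx}}
    )
    return cohort, truth


def assign_mutation_status(
    cohort: ExpressionCohort,
    n_mutated: int = 22,
    n_unmutated: int = 13,
    within_groups: tuple[str, ...] = ("RARS", "RCUD"),
    seed: int = 0,
) -> ExpressionCohort:
    """Label a random subset of MDS samples as spliceosome mutated/unmutated.

    Defaults reproduce the 22-mutated vs 13-unmutated split used for the
    top-200 consensus signature.  Returns a new cohort; samples outside
    the chosen groups (or beyond the requested counts) stay unlabeled.
    """
    pool = [s for s in cohort.samples if cohort.groups[s] in within_groups]
    need = n_mutated + n_unmutated
    if len(pool) < need:
        raise DesignError(
            f"n_mutated+n_unmutated: need {need} samples in {within_groups}, "
            f"cohort has {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=need, replace=False)]
    status = {s: "mutated" for s in chosen[:n_mutated]}
    status.update({s: "unmutated" for s in chosen[n_mutated:]})
    return ExpressionCohort(
        genes=cohort.genes,
        samples=cohort.samples,
        values=cohort.values.copy(),
        groups=dict(cohort.groups),
        mutation_status=status,
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    universe,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
) -> GeneSetCollection:
    """Named gene sets sampled without replacement from *universe*."""
    universe = list(universe)
    if not universe and n_sets > 0:
        raise DesignError("universe: must be non-empty to sample gene sets")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise DesignError("set_size_range: need 1 <= lo <= hi")
    if hi > len(universe) and n_sets > 0:
        raise DesignError("set_size_range: sizes exceed universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{k:03d}"] = {universe[i] for i in members}
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# Variant cohort
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal codons (no stops) + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _make_transcript_models(
    rng: np.random.Generator, n_models: int
) -> list[TranscriptModel]:
    models = []
    for k in range(n_models):
        n_codons = int(rng.integers(60, 200))
        cds = _random_cds(rng, n_codons)
        # split the CDS into 1-3 forward-strand exons with intron gaps
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        pieces = np.split(np.arange(len(cds)), cuts)
        start = int(rng.integers(1000, 50_000))
        intervals = []
        pos = start
        for piece in pieces:
            intervals.append((pos, pos + len(piece) - 1))
            pos += len(piece) + int(rng.integers(50, 500))  # intron gap
        models.append(
            TranscriptModel(
                gene=f"GENE{k:03d}",
                chrom=f"chr_GENE{k:03d}",
                strand="+",
                cds_intervals=intervals,
                cds_sequence=cds,
            )
        )
    return models


def _genomic_pos(model: TranscriptModel, offset: int) -> int:
    """Map a 0-based CDS offset to a genomic position (forward strand)."""
    for lo, hi in model.cds_intervals:
        span = hi - lo + 1
        if offset < span:
            return lo + offset
        offset -= span
    raise ValueError("offset beyond CDS")  # pragma: no cover


def _draw_coding_variant(
    rng: np.random.Generator, model: TranscriptModel, want_nonsyn: bool
) -> tuple[int, str, str]:
    """(pos, ref, alt) inside the CDS with the requested synonymy."""
    L = len(model.cds_sequence)
    for _ in range(200):
        off = int(rng.integers(0, L))
        ref = model.cds_sequence[off]
        alts = [b for b in _BASES if b != ref]
        rng.shuffle(alts)
        codon_start = off - off % 3
        codon = model.cds_sequence[codon_start:codon_start + 3]
        aa_ref = str(Seq(codon).translate())
        for alt in alts:
            mcodon = codon[: off % 3] + alt + codon[off % 3 + 1:]
            aa_alt = str(Seq(mcodon).translate())
            if (aa_alt != aa_ref) == want_nonsyn:
                return _genomic_pos(model, off), ref, alt
    raise RuntimeError("could not draw a variant with the requested synonymy")


def _draw_noncoding_variant(
    rng: np.random.Generator, model: TranscriptModel
) -> tuple[int, str, str]:
    lo = model.cds_intervals[0][0]
    hi = model.cds_intervals[-1][1]
    in_cds = lambda p: any(a <= p <= b for a, b in model.cds_intervals)
    while True:
        # flanks and introns of the pseudo-chromosome
        p = int(rng.integers(max(1, lo - 900), hi + 900))
        if not in_cds(p):
            break
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    return p, str(ref), str(alt)


def generate_variant_cohort(
    n_samples: int = 6,
    per_sample_mean: int = 1367,
    frac_known_snp: float = 0.56,
    frac_coding: float = 0.15,
    frac_nonsyn: float = 0.063,
    seed: int = 0,
    n_models: int = 40,
) -> tuple[list[VariantRecord], SNPCatalog, list[TranscriptModel], GroundTruth]:
    """Per-sample variant tables emulating a targeted-capture screen.

    Variant counts per sample are Poisson(``per_sample_mean``); each
    variant is independently a catalogued SNP with probability
    ``frac_known_snp``, coding with probability ``frac_coding`` and
    (unconditionally) amino-acid-changing with probability
    ``frac_nonsyn``, so ``frac_nonsyn/frac_coding`` of coding variants
    are non-synonymous.  The defaults emulate a screen of ~1367 variants
    per sample in which the triage cascade discards ~56% as known SNPs,
    ~85% of the rest as non-coding and ~58% of the coding rest as
    synonymous.  Positions are consistent with the emitted transcript
    models (one forward-strand model per pseudo-chromosome).
    """
    if n_samples < 1:
        raise DesignError("n_samples: must be >= 1")
    if per_sample_mean < 1:
        raise DesignError("per_sample_mean: must be >= 1")
    for name, v in (("frac_known_snp", frac_known_snp),
                    ("frac_coding", frac_coding),
                    ("frac_nonsyn", frac_nonsyn)):
        if not 0.0 <= v <= 1.0:
            raise DesignError(f"{name}: must be in [0, 1]")
    if frac_nonsyn > frac_coding:
        raise DesignError("frac_nonsyn: cannot exceed frac_coding")

    rng = np.random.default_rng(seed)
    models = _make_transcript_models(rng, n_models)
    p_nonsyn_given_coding = frac_nonsyn / frac_coding if frac_coding > 0 else 0.0

    variants: list[VariantRecord] = []
    catalog_keys: set[tuple[str, int, str]] = set()
    truth = GroundTruth()
    snp_serial = 0
    for si in range(n_samples):
        sample = f"S{si + 1:02d}"
        n_var = int(rng.poisson(per_sample_mean))
        for _ in range(n_var):
            model = models[int(rng.integers(0, len(models)))]
            coding = rng.random() < frac_coding
            if coding:
                nonsyn = rng.random() < p_nonsyn_given_coding
                pos, ref, alt = _draw_coding_variant(rng, model, nonsyn)
            else:
                pos, ref, alt = _draw_noncoding_variant(rng, model)
            known = rng.random() < frac_known_snp
            vid = None
            if known:
                snp_serial += 1
                vid = f"rs{900000 + snp_serial}"
                catalog_keys.add((model.chrom, pos, alt))
            rec = VariantRecord(
                chrom=model.chrom, pos=pos, ref=ref, alt=alt,
                sample=sample,
                genotype="het" if rng.random() < 0.8 else "hom",
                id=vid,
            )
            variants.append(rec)
            if coding and nonsyn and not known:
                truth.planted_missense.append((sample, rec))
    catalog = SNPCatalog(keys=catalog_keys)
    return variants, catalog, models, truth


# ---------------------------------------------------------------------------
# Two-SNP haplotype cohort
# ---------------------------------------------------------------------------

# (common allele, variant allele) per site, mirroring two linked exonic SNPs
DEFAULT_SITE_DEFS = (("T", "C"), ("C", "T"))


def generate_haplotype_cohort(
    n_cases: int = 100,
    n_controls: int = 100,
    carrier_freq_cases: float = 0.12,
    carrier_freq_controls: float = 0.05,
    frac_discordant: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, str]], dict[str, tuple[str, str]], GroundTruth]:
    """Two-site genotypes for a case/control haplotype comparison.

    Carriers hold the variant allele (heterozygous) at both linked sites;
    non-carriers hold the common allele at both.  ``frac_discordant``
    samples carry the variant allele at exactly one site ("other" class).
    Returns (case genotypes, control genotypes, truth); genotypes are
    two-character strings per site, e.g. ``("TC", "CT")``.
    """
    for name, v in (("carrier_freq_cases", carrier_freq_cases),
                    ("carrier_freq_controls", carrier_freq_controls),
                    ("frac_discordant", frac_discordant)):
        if not 0.0 <= v <= 1.0:
            raise DesignError(f"{name}: must be in [0, 1]")
    rng = np.random.default_rng(seed)
    (c1, v1), (c2, v2) = DEFAULT_SITE_DEFS
    truth = GroundTruth()

    def draw(prefix: str, n: int, freq: float) -> dict[str, tuple[str, str]]:
        out = {}
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            u = rng.random()
            if u < freq:
                out[sid] = (c1 + v1, c2 + v2)  # het carrier at both sites
                truth.planted_haplotype_carriers.add(sid)
            elif u < freq + frac_discordant:
                out[sid] = (c1 + v1, c2 + c2)  # discordant
            else:
                out[sid] = (c1 + c1, c2 + c2)
        return out

    cases = draw("CASE", n_cases, carrier_freq_cases)
    controls = draw("CTRL", n_controls, carrier_freq_controls)
    return cases, controls, truth
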