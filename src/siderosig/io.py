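"""Readers and writers for the pipeline's file formats.

Formats: expression TSV (first column gene ID, header row of sample IDs)
with a companion phenotype TSV (sample, group, optional mutation status);
GMT gene-set collections; VCF v4.2 (via pysam) for variants and SNP
catalogs (a 3-column chrom/pos/alt TSV is also accepted); transcript
models as a TSV of intervals plus a FASTA of CDS sequences (Biopython);
JSON for ground truth and run manifests.

All TSV writers prepend ``#``-comment header lines recording the seed and
a config hash so deterministic stages can be reproduced byte-identically;
all readers reject malformed input (ragged rows, non-numeric cells,
duplicate IDs) with the offending line number rather than coercing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import CohortError, ExpressionCohort
from .setstats import GeneSetCollection
from .variants import SNPCatalog, TranscriptModel, VariantRecord

__all__ = [
    "ParseError",
    "config_hash",
    "header_lines",
    "write_expression",
    "read_expression",
    "write_gmt",
    "read_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_vcf",
    "read_vcf",
    "read_snp_catalog",
    "write_snp_catalog",
    "write_transcript_models",
    "read_transcript_models",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file (message carries the line number)."""


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for output headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed: int | None = None, params: dict | None = None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# config={config_hash(params)}")
    return lines


# ---------------------------------------------------------------------------
# Expression + phenotype TSV
# ---------------------------------------------------------------------------


def write_expression(
    cohort: ExpressionCohort,
    expr_path,
    pheno_path,
    seed: int | None = None,
    params: dict | None = None,
) -> None:
    head = "\n".join(header_lines(seed, params))
    with open(expr_path, "w") as fh:
        if head:
            fh.write(head + "\n")
        fh.write("gene\t" + "\t".join(cohort.samples) + "\n")
        for g, row in zip(cohort.genes, cohort.values):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    with open(pheno_path, "w") as fh:
        if head:
            fh.write(head + "\n")
        fh.write("sample\tgroup\tmutation_status\n")
        for s in cohort.samples:
            status = (cohort.mutation_status or {}).get(s, "NA")
            fh.write(f"{s}\t{cohort.groups[s]}\t{status}\n")


def read_expression(expr_path, pheno_path) -> ExpressionCohort:
    genes: list[str] = []
    rows: list[list[float]] = []
    samples: list[str] | None = None
    with open(expr_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if samples is None:
                samples = fields[1:]
                if not samples:
                    raise ParseError(f"{expr_path}:{lineno}: header has no samples")
                continue
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    f"{expr_path}:{lineno}: expected {len(samples) + 1} columns, "
                    f"got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError:
                bad = next(f for f in fields[1:] if not _is_float(f))
                raise ParseError(
                    f"{expr_path}:{lineno}: non-numeric cell {bad!r}"
                ) from None
    if samples is None:
        raise ParseError(f"{expr_path}: empty file")

    groups: dict[str, str] = {}
    status: dict[str, str] = {}
    with open(pheno_path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if not header_seen:
                header_seen = True
                continue
            if len(fields) < 2:
                raise ParseError(f"{pheno_path}:{lineno}: need sample and group")
            sid, grp = fields[0], fields[1]
            if sid not in set(samples):
                raise ParseError(
                    f"{pheno_path}:{lineno}: unknown sample {sid!r}"
                )
            groups[sid] = grp
            if len(fields) > 2 and fields[2] not in ("", "NA"):
                status[sid] = fields[2]
    try:
        return ExpressionCohort(
            genes=genes,
            samples=samples,
            values=np.array(rows, dtype=float),
            groups=groups,
            mutation_status=status or None,
        )
    except CohortError as exc:
        raise ParseError(f"{expr_path}: {exc}") from exc


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Gene lists and GMT
# ---------------------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_gene_list(genes, path, seed: int | None = None,
                    params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        for g in genes:
            fh.write(f"{g}\n")


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Standard GMT: name, description, then members (tab-separated).

    The universe defaults to the union of all members unless supplied.
    Duplicate members within a set are deduplicated with a warning.
    """
    import warnings

    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[0].strip()
            if not name:
                raise ParseError(f"{path}:{lineno}: blank set name")
            members = [m for m in fields[2:] if m]
            if len(members) != len(set(members)):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in {name!r}, deduplicated",
                    stacklevel=2,
                )
            sets[name] = set(members)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# VCF (pysam)
# ---------------------------------------------------------------------------


def write_vcf(
    variants: list[VariantRecord],
    path,
    contig_lengths: dict[str, int] | None = None,
    seed: int | None = None,
) -> None:
    """Write per-sample variants as a multi-sample VCF v4.2 (GT only)."""
    samples = sorted({v.sample for v in variants})
    header = pysam.VariantHeader()
    if seed is not None:
        header.add_line(f"##siderosig_seed={seed}")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = contig_lengths or {}
    chroms = sorted({v.chrom for v in variants} | set(contigs))
    for c in chroms:
        header.contigs.add(c, length=contigs.get(c, 10_000_000))
    for s in samples:
        header.add_sample(s)

    # group by site
    sites: dict[tuple[str, int, str, str, str | None], dict[str, str]] = {}
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt, v.id)
        sites.setdefault(key, {})[v.sample] = v.genotype
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt, vid) in sorted(
            sites, key=lambda k: (k[0], k[1], k[3])
        ):
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=(ref, alt), id=vid
            )
            gts = sites[(chrom, pos, ref, alt, vid)]
            for s in samples:
                gt = gts.get(s)
                if gt is None:
                    rec.samples[s]["GT"] = (0, 0)
                elif gt == "hom":
                    rec.samples[s]["GT"] = (1, 1)
                else:
                    rec.samples[s]["GT"] = (0, 1)
            out.write(rec)


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF into per-sample substitution records (carriers only)."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    raise ParseError(
                        f"{path}: indel at {rec.chrom}:{rec.pos} not supported"
                    )
                if not sample_names:
                    continue
                for s in sample_names:
                    gt = rec.samples[s].get("GT")
                    if gt is None or all(g in (0, None) for g in gt):
                        continue
                    genotype = "hom" if all(g == 1 for g in gt if g is not None) \
                        and len([g for g in gt if g is not None]) > 1 else "het"
                    out.append(
                        VariantRecord(
                            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                            sample=s, genotype=genotype, id=rec.id,
                        )
                    )
    return out


def write_snp_catalog(catalog: SNPCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\talt\n")
        for chrom, pos, alt in sorted(catalog.keys):
            fh.write(f"{chrom}\t{pos}\t{alt}\n")
        for vid in sorted(catalog.ids):
            fh.write(f"ID\t0\t{vid}\n")


def read_snp_catalog(path) -> SNPCatalog:
    """SNP catalog from a 3-column TSV (chrom, pos, alt) or a VCF."""
    path = Path(path)
    if path.suffix == ".vcf":
        cat = SNPCatalog()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    cat.keys.add((rec.chrom, rec.pos, alt))
                if rec.id:
                    cat.ids.add(rec.id)
        return cat
    cat = SNPCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] in ("chrom",):
                continue
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            chrom, pos, alt = fields
            if chrom == "ID":
                cat.ids.add(alt)
            else:
                try:
                    cat.keys.add((chrom, int(pos), alt))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer position {pos!r}"
                    ) from None
    return cat


# ---------------------------------------------------------------------------
# Transcript models (TSV + FASTA)
# ---------------------------------------------------------------------------


def write_transcript_models(models: list[TranscriptModel], tsv_path, fasta_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("gene\tchrom\tstrand\tcds_intervals\n")
        for m in models:
            ivals = ",".join(f"{lo}-{hi}" for lo, hi in m.cds_intervals)
            fh.write(f"{m.gene}\t{m.chrom}\t{m.strand}\t{ivals}\n")
    records = [
        SeqRecord(Seq(m.cds_sequence), id=m.gene, description="CDS")
        for m in models
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_transcript_models(tsv_path, fasta_path) -> list[TranscriptModel]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    models = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "gene":
                continue
            if len(fields) != 4:
                raise ParseError(f"{tsv_path}:{lineno}: expected 4 columns")
            gene, chrom, strand, ivals = fields
            if gene not in seqs:
                raise ParseError(
                    f"{tsv_path}:{lineno}: no FASTA sequence for {gene!r}"
                )
            try:
                intervals = [
                    (int(a), int(b))
                    for a, b in (pair.split("-") for pair in ivals.split(","))
                ]
            except ValueError:
                raise ParseError(
                    f"{tsv_path}:{lineno}: malformed intervals {ivals!r}"
                ) from None
            models.append(
                TranscriptModel(
                    gene=gene, chrom=chrom, strand=strand,
                    cds_intervals=intervals, cds_sequence=seqs[gene],
                )
            )
    return models


# ---------------------------------------------------------------------------
# Manifests / results
# ---------------------------------------------------------------------------


def write_manifest(path, command: str, params: dict, seed: int | None) -> None:
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("siderosig")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    payload = {
        "command": command,
        "params": {k: str(v) for k, v in params.items()},
        "seed": seed,
        "config_hash": config_hash(params),
        "siderosig_version": ver,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_de_results(df: pd.DataFrame, path, seed: int | None = None,
                     params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)
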