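"""Readers and writers for the standard formats the pipeline consumes.

Genotypes come in as VCF (pysam), callable masks and regions as 0-based
half-open BED, gene models as GFF3 (gffutils), gene->term maps and all
tabular stage outputs as TSV with ``NA`` marking undefined values.  VCF's
1-based coordinates are converted to the package's 0-based half-open
convention on read and back on write.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .popspec import IntervalSet, PopulationSpec, SiteTable

logger = logging.getLogger(__name__)

NA = "NA"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path, spec: PopulationSpec) -> SiteTable:
    """Read biallelic SNVs for the samples in *spec* into a SiteTable.

    Multiallelic records and indels are dropped (with a logged count), as is
    any site where a sample in the spec has a missing genotype (the
    fully-observed rule).  A sample listed in the spec but absent from the
    VCF, or a ploidy disagreement between spec and genotype field, is fatal.
    """
    vcf_path = str(vcf_path)
    samples = spec.all_samples()
    with pysam.VariantFile(vcf_path) as vf:
        present = set(vf.header.samples)
        for sample, pop, _ in samples:
            if sample not in present:
                raise ValueError(
                    f"sample {sample!r} (population {pop!r}) missing from "
                    f"{vcf_path}")
        contigs, positions = [], []
        alt = {pop: [] for pop in spec.pop_names}
        n_not_snv = n_missing = 0
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or alts[0] not in "ACGT" or rec.ref not in "ACGT":
                n_not_snv += 1
                continue
            counts = {pop: 0 for pop in spec.pop_names}
            ok = True
            for sample, pop, ploidy in samples:
                gt = rec.samples[sample]["GT"]
                if len(gt) != ploidy:
                    raise ValueError(
                        f"sample {sample!r} at {rec.chrom}:{rec.pos}: spec "
                        f"ploidy {ploidy} but genotype has {len(gt)} allele(s)")
                if any(a is None for a in gt):
                    ok = False
                    break
                counts[pop] += sum(1 for a in gt if a == 1)
            if not ok:
                n_missing += 1
                continue
            contigs.append(rec.chrom)
            positions.append(rec.pos - 1)  # to 0-based
            for pop in spec.pop_names:
                alt[pop].append(counts[pop])
    if n_not_snv:
        logger.info("dropped %d non-biallelic-SNV records", n_not_snv)
    if n_missing:
        logger.info("dropped %d sites with missing genotypes", n_missing)
    n = {pop: spec.n_chrom(pop) for pop in spec.pop_names}
    return SiteTable(contigs, positions, alt, n)


def write_vcf(path, sites: SiteTable, spec: PopulationSpec,
              contig_lengths: Mapping[str, int]) -> None:
    """Write a SiteTable as an uncompressed VCF.

    The table stores chromosome counts, not per-sample genotypes, so alleles
    are assigned to each population's chromosomes deterministically (the
    first ``alt_count`` chromosomes in spec order carry the alternate
    allele).  Per-population counts round-trip exactly; individual genotype
    assignments are a canonical realization, not observed phase.
    """
    samples = spec.all_samples()
    lines = ["##fileformat=VCFv4.2",
             "##source=sweepscan",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={int(length)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s for s, _, _ in samples))
    rows = []
    for i in range(sites.n_sites):
        fields = [str(sites.contig[i]), str(int(sites.pos[i]) + 1), ".",
                  "A", "C", ".", "PASS", ".", "GT"]
        remaining = {pop: int(sites.alt[pop][i]) for pop in spec.pop_names}
        for sample, pop, ploidy in samples:
            alleles = []
            for _ in range(ploidy):
                if remaining[pop] > 0:
                    alleles.append("1")
                    remaining[pop] -= 1
                else:
                    alleles.append("0")
            fields.append("/".join(alleles))
        rows.append("\t".join(fields))
    Path(path).write_text("\n".join(lines + rows) + "\n")


def polarize(sites: SiteTable, spec: PopulationSpec) -> SiteTable:
    """Orient alleles as derived vs. ancestral using the outgroup.

    The ancestral allele is the allele fixed in the outgroup; sites where
    the outgroup is polymorphic get ``ancestral_known = False``.
    """
    if spec.outgroup is None:
        raise ValueError("no outgroup configured in the population spec")
    out_alt = sites.alt[spec.outgroup]
    n_out = sites.n[spec.outgroup]
    fixed_ref = out_alt == 0
    fixed_alt = out_alt == n_out
    known = fixed_ref | fixed_alt
    derived_is_alt = fixed_ref  # ancestral = ref -> derived = alt
    return SiteTable(sites.contig, sites.pos, sites.alt, sites.n,
                     derived_is_alt=derived_is_alt, ancestral_known=known)


# ---------------------------------------------------------------------------
# BED / GFF3 / TSV
# ---------------------------------------------------------------------------

def read_mask(bed_path) -> IntervalSet:
    """Read a 0-based half-open BED file into a normalized IntervalSet."""
    records = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{bed_path}:{lineno}: start >= end ({start} >= {end})")
            records.append((contig, start, end))
    return IntervalSet(records)


def write_bed(path, records, scores=None) -> None:
    """Write (contig, start, end[, name, score]) records as BED.

    ``scores``, if given, are values in [0, 1] scaled to the BED convention
    of 0-1000.
    """
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fields = [str(rec[0]), str(int(rec[1])), str(int(rec[2]))]
            if scores is not None:
                fields.append(f"region{i + 1}")
                fields.append(str(int(round(1000 * float(scores[i])))))
            fh.write("\t".join(fields) + "\n")


def read_genes(gff_path) -> pd.DataFrame:
    """Read gene features from GFF3 into (contig, start, end, gene_id).

    Coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        rows.append((gene.seqid, gene.start - 1, gene.end, gene_id))
    if not rows:
        raise ValueError(f"no gene features found in {gff_path}")
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"])
    return df.sort_values(["contig", "start"]).reset_index(drop=True)


def read_term_map(path) -> pd.DataFrame:
    """Read a flat gene->term TSV (gene_id <TAB> term_id [<TAB> term_name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    df = df.iloc[:, :3]
    df.columns = ["gene_id", "term_id", "term_name"][: df.shape[1]]
    if "term_name" not in df:
        df["term_name"] = df["term_id"]
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])
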