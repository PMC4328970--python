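"""Coding-sequence selection-pressure analysis: SNP filtering, per-group
consensus sequences, and Nei-Gojobori (NG86) Ka/Ks estimation.

SNPs called across two groups of individuals (e.g. domestic pigs and wild
boars) are filtered by overall alternate-allele frequency, a majority-rule
consensus coding sequence is built per group, and the two consensus
sequences are compared codon-by-codon.

NG86 counts, for every codon, the expected numbers of synonymous (S) and
nonsynonymous (N) *sites* — each codon position contributes the fraction of
its three possible single-base changes that preserve the amino acid — and
the numbers of synonymous (Sd) and nonsynonymous (Nd) *substitutions*
between the two codons, averaging over all mutational orderings when codons
differ at more than one position (orderings passing through a stop codon
are excluded).  Site counts are averaged over both sequences.  The
proportions pN = Nd/N and pS = Sd/S are corrected for multiple hits with
the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), giving Ka and Ks.

Genes with Ks = 0 but Ka > 0 receive the conventional sentinel ratio 99
(an unreliable omega estimate); genes with no substitutions at all are
"Conserved" when no SNP was observed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "SnpRecord",
    "SelectionResult",
    "KAKS_SENTINEL",
    "CATEGORIES",
    "filter_snps",
    "consensus_sequence",
    "synonymous_site_fraction",
    "count_sites",
    "count_substitutions",
    "ng86_ka_ks",
    "bin_ka_ks",
    "positively_selected_genes",
    "read_snp_vcf",
    "write_snp_vcf",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = ("A", "C", "G", "T")

KAKS_SENTINEL = 99.0
CATEGORIES = ("Conserved", "0", "0-0.1", "0.1-1", ">1", "99")


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


@dataclass
class SnpRecord:
    """A biallelic SNP within a coding sequence, with diploid genotypes.

    ``genotypes`` maps group name -> list of per-individual genotypes, each
    a tuple of 0/1 allele codes (0 = ref, 1 = alt) or ``None`` for missing.
    ``position`` is 1-based within the CDS.
    """

    gene: str
    position: int
    ref: str
    alt: str
    genotypes: dict[str, list[tuple[int, int] | None]]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError("alleles must be single bases A/C/G/T")
        if self.position < 1:
            raise ValueError("position is 1-based")

    def alt_frequency(self, groups: list[str] | None = None) -> float:
        """Alternate-allele frequency over all (or selected) groups,
        missing genotypes excluded from the denominator."""
        groups = groups if groups is not None else list(self.genotypes)
        alt = total = 0
        for g in groups:
            for gt in self.genotypes[g]:
                if gt is None:
                    continue
                alt += sum(gt)
                total += len(gt)
        if total == 0:
            raise ValueError(f"no called genotypes for {self.gene}:{self.position}")
        return alt / total


def filter_snps(records: list[SnpRecord], min_frequency: float = 0.05) -> list[SnpRecord]:
    """Drop SNPs whose overall alternate-allele frequency is below
    ``min_frequency`` (a SNP at exactly the threshold is retained)."""
    if records and not any(r.genotypes for r in records):
        raise ValueError("records carry no genotype groups")
    return [r for r in records if r.alt_frequency() >= min_frequency]


def consensus_sequence(reference: str, records: list[SnpRecord], group: str) -> str:
    """Majority-rule consensus CDS for one group of individuals.

    At each SNP position the allele with within-group frequency > 1/2
    replaces the reference base; at exactly 1/2 the reference is kept.
    """
    seq = list(reference.upper())
    for rec in records:
        if rec.position > len(seq):
            raise ValueError(
                f"SNP position {rec.position} beyond CDS length {len(seq)} ({rec.gene})"
            )
        if seq[rec.position - 1] != rec.ref:
            raise ValueError(
                f"reference base mismatch at {rec.gene}:{rec.position}: "
                f"CDS has {seq[rec.position - 1]}, record says {rec.ref}"
            )
        if group not in rec.genotypes:
            raise ValueError(f"group {group!r} absent from record {rec.gene}:{rec.position}")
        if rec.alt_frequency([group]) > 0.5:
            seq[rec.position - 1] = rec.alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# NG86 machinery
# ---------------------------------------------------------------------------

def synonymous_site_fraction(codon: str, position: int) -> float:
    """Fraction of the three single-base changes at ``position`` (0-based)
    of ``codon`` that are synonymous.  Changes producing a stop codon count
    as nonsynonymous."""
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no defined sites")
    syn = 0
    for base in BASES:
        if base == codon[position]:
            continue
        mutant = codon[:position] + base + codon[position + 1:]
        if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
            syn += 1
    return syn / 3.0


def count_sites(seq: str) -> tuple[float, float]:
    """Total synonymous and nonsynonymous site counts (S, N) of a CDS.

    Every codon contributes S_codon + N_codon = 3.
    """
    _check_cds(seq)
    s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        s += sum(synonymous_site_fraction(codon, p) for p in range(3))
    return s, len(seq) - s


def _codon_step_class(before: str, after: str) -> str:
    """Classify a single-base codon change as 'syn' or 'nonsyn'."""
    return "syn" if translate_codon(before) == translate_codon(after) else "nonsyn"


def count_substitutions(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous substitution counts (Sd, Nd) between two
    codons, averaging over all mutational orderings with equal weight.

    Orderings whose intermediate codons are stops are excluded; if every
    ordering passes through a stop, all orderings are used as a fallback.
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        current = codon1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon2:
                through_stop = True
            if _codon_step_class(current, nxt) == "syn":
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, through_stop))
    valid = [p for p in paths if not p[2]]
    if not valid:
        valid = paths
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _check_cds(seq: str, name: str = "sequence") -> None:
    seq = seq.upper()
    if len(seq) == 0 or len(seq) % 3:
        raise ValueError(f"{name} length {len(seq)} is not a positive multiple of 3")
    if set(seq) - set(BASES):
        raise ValueError(f"{name} contains non-ACGT characters")
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{name} has internal stop codon at codon {i // 3 + 1}")


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class SelectionResult:
    """Per-gene Ka/Ks outcome and selection category."""

    gene: str
    ka: float
    ks: float
    ratio: float | None  # Ka/Ks, the 99.0 sentinel, or None for "Conserved"
    category: str
    nd: float = 0.0
    sd: float = 0.0
    n_sites: float = 0.0
    s_sites: float = 0.0
    flagged: bool = False  # JC correction undefined (p >= 3/4)


def _categorize(ka: float, ks: float, snps_observed: bool) -> tuple[float | None, str]:
    if ka == 0.0 and ks == 0.0:
        if not snps_observed:
            return None, "Conserved"
        return 0.0, "0"
    if ks == 0.0:
        return KAKS_SENTINEL, "99"
    ratio = ka / ks
    if ratio == 0.0:
        return 0.0, "0"
    if ratio <= 0.1:
        return ratio, "0-0.1"
    if ratio <= 1.0:
        return ratio, "0.1-1"
    return ratio, ">1"


def ng86_ka_ks(seq1: str, seq2: str, gene: str = "", snps_observed: bool | None = None) -> SelectionResult:
    """Estimate Ka, Ks and their ratio between two aligned coding sequences
    by the Nei-Gojobori counting method with Jukes-Cantor correction.

    ``snps_observed`` marks whether any variant was seen for the gene before
    consensus building; identical consensus sequences are then categorized
    "0" rather than "Conserved".  When ``None`` it is inferred from sequence
    inequality.

    A result where a substitution proportion reaches 3/4 (correction
    undefined) is returned with ``flagged=True`` and NaN distances.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    _check_cds(seq1, "seq1")
    _check_cds(seq2, "seq2")
    if snps_observed is None:
        snps_observed = seq1 != seq2

    s1, _ = count_sites(seq1)
    s2, _ = count_sites(seq2)
    s_sites = (s1 + s2) / 2.0
    n_sites = len(seq1) - s_sites

    sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        d_s, d_n = count_substitutions(seq1[i : i + 3], seq2[i : i + 3])
        sd += d_s
        nd += d_n

    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    try:
        ka = _jukes_cantor(pn)
        ks = _jukes_cantor(ps)
    except ValueError:
        warnings.warn(
            f"gene {gene or '<unnamed>'}: substitution proportion >= 3/4, "
            "Jukes-Cantor correction undefined",
            stacklevel=2,
        )
        return SelectionResult(
            gene, math.nan, math.nan, None, "flagged", nd, sd, n_sites, s_sites, True
        )
    ratio, category = _categorize(ka, ks, snps_observed)
    return SelectionResult(gene, ka, ks, ratio, category, nd, sd, n_sites, s_sites)


def bin_ka_ks(results: list[SelectionResult]) -> pd.DataFrame:
    """Histogram of selection categories with proportions over all genes.

    Genes with the 99 sentinel are tallied separately and never contribute
    to aggregates over ratios > 0.1 (unreliable omega estimates).
    """
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        if r.flagged:
            continue
        if r.category not in counts:
            raise ValueError(f"uncategorized record {r.gene}: {r.category!r}")
        counts[r.category] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total if total else 0.0 for c in counts.values()],
        }
    )


def positively_selected_genes(
    results: list[SelectionResult],
    module_class: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Genes under positive selection (Ka/Ks > 1, excluding the unreliable
    99 sentinel), grouped by module class when a gene -> class mapping
    (e.g. "prenatal common", "postnatal specific") is given.

    Genes without a module assignment are skipped with a warning.
    """
    if isinstance(module_class, pd.Series):
        module_class = module_class.to_dict()
    rows = []
    for r in results:
        if r.ratio is None or r.flagged:
            continue
        if not (r.ratio > 1.0 and r.ratio != KAKS_SENTINEL):
            continue
        if module_class is not None:
            if r.gene not in module_class:
                warnings.warn(f"gene {r.gene} lacks a module assignment; skipped", stacklevel=2)
                continue
            rows.append({"gene": r.gene, "module_class": module_class[r.gene], "ratio": r.ratio})
        else:
            rows.append({"gene": r.gene, "module_class": "", "ratio": r.ratio})
    return pd.DataFrame(rows, columns=["gene", "module_class", "ratio"])


# ---------------------------------------------------------------------------
# Minimal VCF I/O (uncompressed text; read back through pysam)
# ---------------------------------------------------------------------------

def write_snp_vcf(
    records: list[SnpRecord],
    path: str | Path,
    group_of: dict[str, str],
    contig_lengths: dict[str, int],
) -> None:
    """Write SNP records as a minimal valid VCF with per-individual GT
    columns.  ``group_of`` maps individual id -> group name and fixes the
    column order (sorted by individual id)."""
    individuals = sorted(group_of)
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals)
    )
    # per-record, genotypes are stored per group in the order individuals
    # of that group appear in the sorted individual list
    group_members = {
        g: [i for i in individuals if group_of[i] == g] for g in set(group_of.values())
    }
    for rec in sorted(records, key=lambda r: (r.gene, r.position)):
        gt_of = {}
        for g, members in group_members.items():
            gts = rec.genotypes.get(g, [])
            for ind, gt in zip(members, gts):
                gt_of[ind] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
        fields = [
            rec.gene,
            str(rec.position),
            ".",
            rec.ref,
            rec.alt,
            ".",
            "PASS",
            ".",
            "GT",
        ] + [gt_of.get(ind, "./.") for ind in individuals]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_vcf(path: str | Path, group_of: dict[str, str]) -> list[SnpRecord]:
    """Read a (plain-text) VCF of CDS-relative SNPs into SnpRecords, using
    ``group_of`` to bucket sample columns into groups."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in group_of]
        if unknown:
            raise ValueError(f"VCF samples with no group: {unknown[:5]}")
        groups = sorted(set(group_of.values()))
        members = {g: [s for s in samples if group_of[s] == g] for g in groups}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            genotypes: dict[str, list[tuple[int, int] | None]] = {}
            for g in groups:
                gts = []
                for s in members[g]:
                    gt = rec.samples[s]["GT"]
                    gts.append(None if gt is None or None in gt else (gt[0], gt[1]))
                genotypes[g] = gts
            records.append(
                SnpRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], genotypes)
            )
    return records
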