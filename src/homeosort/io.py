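"""Readers and writers for the formats the pipeline touches.

Dialects, stated once:

* FASTA alignments of phased alleles. Residues are canonicalized to upper
  case and restricted to ``{A, C, G, T, N, -}``; IUPAC ambiguity letters
  beyond ``N`` are rejected on input (they arise only as *output* of the
  IUPAC collapse, which is terminal). Written FASTA wraps at 80 columns
  and uses ``-`` as the only gap character.
* Allele labels follow the convention ``{sample_id}__h{i}`` with 1-based
  ``i``, so alleles group unambiguously into samples in every downstream
  matrix and tree.
* Newick trees must carry branch lengths on all edges (a flag substitutes
  zero instead of raising). Underscores in labels are preserved verbatim.
* VCF positions are 1-based (VCF standard); internal alignment columns are
  0-based and reported columns 1-based.
* Reports are tab-separated with a fixed column order; floats print with
  6 significant digits, infinities as ``inf``, missing values as ``NA``.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AlleleAlignment",
    "SampleConfig",
    "SamplesTable",
    "GeneMap",
    "VariantRow",
    "PhasedVariantTable",
    "ALLELE_LABEL_RE",
    "allele_label",
    "parse_allele_label",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "check_tree_matches_alignment",
    "read_phased_vcf",
    "read_samples_table",
    "read_gene_map",
    "read_config",
    "write_report",
    "REPORT_COLUMNS",
]

VALID_RESIDUES = frozenset("ACGTN-")

ALLELE_LABEL_RE = re.compile(r"^(?P<sample>.+)__h(?P<index>[1-9]\d*)$")


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


def allele_label(sample_id: str, index: int) -> str:
    """Compose the canonical allele label ``{sample_id}__h{index}`` (1-based)."""
    return f"{sample_id}__h{index}"


def parse_allele_label(label: str) -> tuple[str, int] | None:
    """Split a ``{sample}__h{i}`` label into (sample_id, index), else None."""
    m = ALLELE_LABEL_RE.match(label)
    if m is None:
        return None
    return m.group("sample"), int(m.group("index"))


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled aligned nucleotide sequence."""

    label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.label:
            raise FormatError("sequence label must be non-empty")
        if not self.sequence:
            raise FormatError(f"sequence for {self.label!r} is empty")


@dataclass
class AlleleAlignment:
    """One locus's aligned allele sequences: the unit everything operates on."""

    locus_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label in seen:
                raise FormatError(
                    f"duplicate label {rec.label!r} in locus {self.locus_id!r}"
                )
            seen.add(rec.label)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def length(self) -> int:
        """Alignment length; 0 for an empty (flagged) alignment."""
        return len(self.records[0].sequence) if self.records else 0

    @property
    def is_uniform(self) -> bool:
        return len({len(r.sequence) for r in self.records}) <= 1

    def get(self, label: str) -> str:
        for rec in self.records:
            if rec.label == label:
                return rec.sequence
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(r.label == label for r in self.records)

    def sample_alleles(self) -> dict[str, list[str]]:
        """Group allele labels by sample, ordered by 1-based haplotype index.

        Labels not matching ``{sample}__h{i}`` are grouped under their full
        label (a single-sequence "sample", e.g. a masked consensus).
        """
        groups: dict[str, list[tuple[int, str]]] = {}
        for rec in self.records:
            parsed = parse_allele_label(rec.label)
            if parsed is None:
                groups.setdefault(rec.label, []).append((1, rec.label))
            else:
                sample, idx = parsed
                groups.setdefault(sample, []).append((idx, rec.label))
        return {
            s: [lab for _, lab in sorted(pairs)] for s, pairs in groups.items()
        }


@dataclass(frozen=True)
class SampleConfig:
    """One sample's identity, taxon, ploidy and pipeline role."""

    sample_id: str
    taxon: str
    ploidy: int
    role: str  # diploid | tetraploid | outgroup | reference_taxon_member

    VALID_ROLES = ("diploid", "tetraploid", "outgroup", "reference_taxon_member")

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise FormatError(f"ploidy must be 2 or 4, got {self.ploidy}")
        if self.role not in self.VALID_ROLES:
            raise FormatError(f"unknown role {self.role!r}")
        if (self.role == "tetraploid") != (self.ploidy == 4):
            raise FormatError(
                f"sample {self.sample_id}: role {self.role!r} inconsistent "
                f"with ploidy {self.ploidy}"
            )


@dataclass
class SamplesTable:
    """The full sample roster plus the designated maternal reference taxon."""

    samples: list[SampleConfig]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in samples table")
        ref_taxa = {s.taxon for s in self.samples if s.role == "reference_taxon_member"}
        if len(ref_taxa) != 1:
            raise FormatError(
                "exactly one taxon must be designated as the maternal "
                f"reference (roles name {len(ref_taxa)} taxa)"
            )

    @property
    def reference_taxon(self) -> str:
        return next(
            s.taxon for s in self.samples if s.role == "reference_taxon_member"
        )

    @property
    def tetraploids(self) -> list[SampleConfig]:
        return [s for s in self.samples if s.ploidy == 4]

    @property
    def diploids(self) -> list[SampleConfig]:
        return [s for s in self.samples if s.ploidy == 2]

    def by_id(self, sample_id: str) -> SampleConfig:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def taxon_samples(self, taxon: str) -> list[SampleConfig]:
        return [s for s in self.samples if s.taxon == taxon]


@dataclass
class GeneMap:
    """Mapping exon_id -> (gene_id, 1-based ordinal within the gene)."""

    exon_to_gene: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for gene, exons in self.genes().items():
            ordinals = sorted(self.exon_to_gene[e][1] for e in exons)
            if ordinals != list(range(1, len(ordinals) + 1)):
                raise FormatError(
                    f"gene {gene!r}: exon ordinals {ordinals} are not a "
                    "contiguous 1..k sequence"
                )

    def genes(self) -> dict[str, list[str]]:
        """Gene -> exon ids in ordinal order, genes sorted by id."""
        out: dict[str, list[tuple[int, str]]] = {}
        for exon, (gene, ordinal) in self.exon_to_gene.items():
            out.setdefault(gene, []).append((ordinal, exon))
        return {
            g: [e for _, e in sorted(v)] for g, v in sorted(out.items())
        }


@dataclass(frozen=True)
class VariantRow:
    """One phased-VCF record for one sample."""

    position: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    haplotypes: tuple[int, ...]  # allele index per haplotype, length = ploidy
    phase_set: int | None
    phased: bool

    @property
    def is_heterozygous(self) -> bool:
        return len(set(self.haplotypes)) > 1


@dataclass
class PhasedVariantTable:
    """Per-sample ordered variant rows parsed from a phased VCF.

    ``n_skipped_indels`` counts records rejected because REF/ALT were not
    all single bases (the pipeline consumes SNPs only).
    """

    rows: dict[str, list[VariantRow]]
    n_skipped_indels: int = 0

    def __post_init__(self) -> None:
        for sample, rows in self.rows.items():
            positions = [r.position for r in rows]
            if positions != sorted(set(positions)):
                raise FormatError(
                    f"variant positions for sample {sample!r} are not "
                    "strictly increasing"
                )


# ---------------------------------------------------------------------------
# FASTA


def _canonicalize(label: str, raw: str) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise FormatError(
            f"sequence {label!r} contains invalid residues {sorted(bad)}; "
            "allele alignments allow only A,C,G,T,N,-"
        )
    return seq

def read_alignment(
    path: str | Path,
    expected_length_uniform: bool = True,
    locus_id: str | None = None,
) -> AlleleAlignment:
    """Read a FASTA alignment of phased alleles.

    Residues are upper-cased; duplicate labels and (under the uniform-length
    flag, the default) ragged sequence lengths raise :class:`FormatError`.
    """
    path = Path(path)
    if locus_id is None:
        locus_id = path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, _canonicalize(rec.id, str(rec.seq))))
    aln = AlleleAlignment(locus_id, records)
    if expected_length_uniform and not aln.is_uniform:
        raise FormatError(f"ragged sequence lengths in {path}")
    return aln


def write_alignment(alignment: AlleleAlignment, path: str | Path, wrap: int = 80) -> None:
    """Write FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in alignment.records:
            fh.write(f">{rec.label}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path, missing_lengths_as_zero: bool = False) -> dendropy.Tree:
    """Read a single Newick tree, requiring branch lengths on all edges."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # the root's virtual edge
            continue
        if edge.length is None:
            if missing_lengths_as_zero:
                edge.length = 0.0
            else:
                raise FormatError(f"edge without branch length in {path}")
        elif edge.length < 0:
            raise FormatError(f"negative branch length in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def check_tree_matches_alignment(tree: dendropy.Tree, alignment: AlleleAlignment) -> None:
    """Raise FormatError unless the tree's leaf set equals the alignment labels."""
    leaves = set(tree_leaf_labels(tree))
    labels = set(alignment.labels)
    if leaves != labels:
        only_tree = sorted(leaves - labels)
        only_aln = sorted(labels - leaves)
        raise FormatError(
            f"tree/alignment label mismatch for locus {alignment.locus_id!r}: "
            f"tree-only={only_tree}, alignment-only={only_aln}"
        )


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(
    path: str | Path,
    sample_ids: Sequence[str],
    ploidy: Mapping[str, int] | None = None,
) -> PhasedVariantTable:
    """Read the phased-genotype subset of a VCF.

    Only SNP records are kept (every REF and ALT allele a single base);
    indels are skipped and counted. Genotypes must use ``|`` separators to
    count as phased; a PS (phase set) tag identifies the phase block.
    Unphased genotypes are retained with ``phased=False`` — downstream
    haplotype extraction treats their heterozygous sites as maskable.
    """
    rows: dict[str, list[VariantRow]] = {s: [] for s in sample_ids}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        missing = set(sample_ids) - set(vcf.header.samples)
        if missing:
            raise FormatError(f"samples absent from VCF {path}: {sorted(missing)}")
        for rec in vcf:
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if any(a is None or len(a) != 1 for a in alleles):
                n_skipped += 1
                continue
            for sample in sample_ids:
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or any(g is None for g in gt):
                    continue
                if ploidy is not None and len(gt) != ploidy[sample]:
                    raise FormatError(
                        f"GT arity {len(gt)} != ploidy {ploidy[sample]} for "
                        f"sample {sample!r} at {rec.chrom}:{rec.pos}"
                    )
                ps = call.get("PS")
                rows[sample].append(
                    VariantRow(
                        position=rec.pos,
                        ref=rec.ref.upper(),
                        alts=tuple(a.upper() for a in rec.alts or ()),
                        haplotypes=tuple(int(g) for g in gt),
                        phase_set=int(ps) if ps is not None else None,
                        phased=bool(call.phased),
                    )
                )
    return PhasedVariantTable(rows=rows, n_skipped_indels=n_skipped)


# ---------------------------------------------------------------------------
# Tables and config


def read_samples_table(path: str | Path) -> SamplesTable:
    """Read the sample roster TSV: sample_id, taxon, ploidy, role (with header)."""
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "taxon", "ploidy", "role"]
        if header != expected:
            raise FormatError(f"samples table header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            sample_id, taxon, ploidy, role = line.rstrip("\n").split("\t")
            samples.append(SampleConfig(sample_id, taxon, int(ploidy), role))
    return SamplesTable(samples)


def write_samples_table(table: SamplesTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttaxon\tploidy\trole\n")
        for s in table.samples:
            fh.write(f"{s.sample_id}\t{s.taxon}\t{s.ploidy}\t{s.role}\n")


def read_gene_map(path: str | Path) -> GeneMap:
    """Read the exon->gene TSV: exon_id, gene_id, ordinal (with header)."""
    mapping: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["exon_id", "gene_id", "ordinal"]
        if header != expected:
            raise FormatError(f"gene map header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            exon, gene, ordinal = line.rstrip("\n").split("\t")
            if exon in mapping:
                raise FormatError(f"exon {exon!r} maps to more than one gene")
            mapping[exon] = (gene, int(ordinal))
    return GeneMap(mapping)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("exon_id\tgene_id\tordinal\n")
        for gene, exons in gene_map.genes().items():
            for exon in exons:
                fh.write(f"{exon}\t{gene}\t{gene_map.exon_to_gene[exon][1]}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a plain ``key: value`` config file (one pair per line, # comments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"config line {lineno} is not key: value")
            key, value = line.split(":", 1)
            out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# Report

REPORT_COLUMNS = (
    "locus_id",
    "level",
    "sample_id",
    "n_alleles",
    "het_class",
    "s_best",
    "s_second",
    "ratio",
    "status",
    "pair_members",
    "label_A_members",
    "mean_dist_A_to_ref",
    "mean_dist_B_to_ref",
    "n_masked_snps",
)


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if math.isinf(value):
            return "inf"
        return format(value, ".6g")
    return str(value)


def write_report(records: Iterable, path: str | Path) -> None:
    """Write summary records as TSV, one row per (locus, sample)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rec in records:
            if dataclasses.is_dataclass(rec):
                get = lambda c: getattr(rec, c)  # noqa: E731
            else:
                get = rec.__getitem__
            fh.write("\t".join(_format_cell(get(c)) for c in REPORT_COLUMNS) + "\n")
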