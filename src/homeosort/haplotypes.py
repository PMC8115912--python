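"""From phased variants to per-sample allele sequences, and allele-set algebra.

Read-backed phasing of a polyploid yields, per locus, ploidy-many haplotype
sequences — but only within phase blocks. When phasing splits a sample's
variants into several blocks, only the longest block (the one carrying the
most phased variant records; ties broken by smallest phase-set id) is
retained, and every heterozygous variant outside it — plus every unphased
heterozygous variant — is masked with N in *all* haplotypes, because its
assignment to a haplotype is unknown. Homozygous-alternate variants carry
no phase information and are substituted everywhere regardless of block.

The module also classifies tetraploid allele sets by their heterozygosity
pattern (the multiset of distinct sequences among the four alleles), and
collapses allele sets to single sequences three ways: masking interallelic
SNPs with N, IUPAC-ambiguity coding, and majority-rule consensus. N is
transparent throughout: it encodes "unknown", not a fifth state.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io import (
    AlleleAlignment,
    PhasedVariantTable,
    SampleConfig,
    SequenceRecord,
    VariantRow,
)

__all__ = [
    "AlleleSet",
    "PhasedVariantTable",
    "extract_allele_sequences",
    "classify_heterozygosity",
    "mask_interallelic_snps",
    "collapse_to_iupac",
    "majority_consensus",
    "trim_alignment",
    "HET_CLASSES",
]

HET_CLASSES = (
    "homozygous",
    "het_1_3",
    "het_2_2",
    "het_3",
    "het_4",
    "diploid_hom",
    "diploid_het",
)

# IUPAC code for each non-empty set of bases
_IUPAC = {
    frozenset(s): code
    for s, code in [
        ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
        ("AG", "R"), ("CT", "Y"), ("CG", "S"), ("AT", "W"),
        ("GT", "K"), ("AC", "M"),
        ("CGT", "B"), ("AGT", "D"), ("ACT", "H"), ("ACG", "V"),
        ("ACGT", "N"),
    ]
}


@dataclass
class AlleleSet:
    """A sample's ploidy-many aligned allele sequences for one locus."""

    sample_id: str
    sequences: list[str]
    het_class: str
    n_masked: int = 0  # positions masked with N during extraction

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("allele sequences must share one length")


def classify_heterozygosity(sequences: list[str]) -> str:
    """Heterozygosity class from the multiset of distinct allele sequences.

    Tetraploid: 4 identical -> homozygous; counts {3,1} -> het_1_3;
    {2,2} -> het_2_2; {2,1,1} -> het_3; all distinct -> het_4.
    Diploid: diploid_hom / diploid_het. Order of alleles is irrelevant.
    """
    counts = sorted(Counter(sequences).values(), reverse=True)
    if len(sequences) == 2:
        return "diploid_hom" if counts == [2] else "diploid_het"
    if len(sequences) != 4:
        raise ValueError(f"expected 2 or 4 alleles, got {len(sequences)}")
    pattern = {
        (4,): "homozygous",
        (3, 1): "het_1_3",
        (2, 2): "het_2_2",
        (2, 1, 1): "het_3",
        (1, 1, 1, 1): "het_4",
    }
    return pattern[tuple(counts)]


def extract_allele_sequences(
    reference: SequenceRecord,
    table: PhasedVariantTable,
    sample: SampleConfig,
    mask_unphased: bool = True,
) -> AlleleSet:
    """Build a sample's allele sequences from its phased variants.

    Returns ploidy-many copies of the reference with, for heterozygous
    variants inside the longest phase block, the per-haplotype alleles
    substituted; heterozygous variants outside that block (and, by default,
    unphased heterozygous variants) are replaced by N in all haplotypes.
    Homozygous-alternate variants are substituted everywhere.
    """
    rows = table.rows.get(sample.sample_id, [])
    ref_len = len(reference.sequence)
    for row in rows:
        if not 1 <= row.position <= ref_len:
            raise ValueError(
                f"variant position {row.position} outside reference "
                f"{reference.label!r} (length {ref_len})"
            )
        for alt in row.alts:
            if len(alt) != len(row.ref):
                raise ValueError(
                    f"non-SNP variant at position {row.position} "
                    f"(ref {row.ref!r}, alt {alt!r})"
                )

    # Longest phase block = most phased heterozygous records; ties broken by
    # the smallest phase-set id. Records without PS share one pseudo-block.
    het_phased = [r for r in rows if r.is_heterozygous and r.phased]
    block_counts: Counter = Counter(
        (r.phase_set if r.phase_set is not None else -1) for r in het_phased
    )
    if block_counts:
        longest_block = min(
            block_counts, key=lambda ps: (-block_counts[ps], ps)
        )
    else:
        longest_block = None

    haplotypes = [list(reference.sequence) for _ in range(sample.ploidy)]
    n_masked = 0
    for row in rows:
        alleles = (row.ref,) + row.alts
        col = row.position - 1
        if not row.is_heterozygous:
            base = alleles[row.haplotypes[0]]
            for hap in haplotypes:
                hap[col] = base
            continue
        if row.phased:
            block = row.phase_set if row.phase_set is not None else -1
            usable = block == longest_block
        else:
            usable = not mask_unphased  # keep-unphased trusts the GT order
        if usable:
            for hap, allele_idx in zip(haplotypes, row.haplotypes):
                hap[col] = alleles[allele_idx]
        else:
            for hap in haplotypes:
                hap[col] = "N"
            n_masked += 1

    sequences = ["".join(h) for h in haplotypes]
    return AlleleSet(
        sample_id=sample.sample_id,
        sequences=sequences,
        het_class=classify_heterozygosity(sequences),
        n_masked=n_masked,
    )


def mask_interallelic_snps(sequences: list[str]) -> tuple[str, int]:
    """Collapse an allele set to one sequence, masking disagreements with N.

    A column keeps the shared residue when all non-N alleles agree, else
    becomes N. Returns (sequence, number of masked columns). Idempotent.
    """
    out = []
    n_masked = 0
    for column in zip(*sequences):
        residues = {c for c in column if c != "N"}
        if len(residues) == 1:
            out.append(next(iter(residues)))
        elif not residues:
            out.append("N")
        else:
            out.append("N")
            n_masked += 1
    return "".join(out), n_masked


def collapse_to_iupac(sequences: list[str]) -> str:
    """Collapse an allele set to one sequence with IUPAC ambiguity codes.

    Per column: the IUPAC code of the distinct non-N bases; a gap present
    alongside bases -> N; all-N -> N; all-gap -> ``-``.
    """
    out = []
    for column in zip(*sequences):
        residues = set(column) - {"N"}
        if not residues:
            out.append("N")
        elif residues == {"-"}:
            out.append("-")
        elif "-" in residues:
            out.append("N")
        else:
            out.append(_IUPAC[frozenset(residues)])
    return "".join(out)


def majority_consensus(sequences: list[str]) -> str:
    """Majority-rule consensus: most frequent base per column, non-N bases
    only; ties collapse to the IUPAC code of the tied bases."""
    out = []
    for column in zip(*sequences):
        counts = Counter(c for c in column if c in "ACGT")
        if not counts:
            out.append("N" if "N" in column else "-")
            continue
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        out.append(_IUPAC[tied] if len(tied) > 1 else next(iter(tied)))
    return "".join(out)


def trim_alignment(
    alignment: AlleleAlignment, max_gap_fraction: float = 0.25
) -> tuple[AlleleAlignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    Returns the trimmed alignment and the removed column indices (1-based).
    An alignment trimmed to length zero is returned empty-sequenced as a
    flagged-empty alignment (``length == 0``) for the caller to drop.
    """
    n = len(alignment.records)
    if n == 0:
        return alignment, []
    length = alignment.length
    columns = list(zip(*(r.sequence for r in alignment.records)))
    removed = [
        i + 1
        for i, col in enumerate(columns)
        if col.count("-") / n > max_gap_fraction
    ]
    removed_set = set(removed)
    kept = [i for i in range(length) if i + 1 not in removed_set]
    if not kept:
        return AlleleAlignment(alignment.locus_id, []), removed
    records = [
        SequenceRecord(r.label, "".join(r.sequence[i] for i in kept))
        for r in alignment.records
    ]
    return AlleleAlignment(alignment.locus_id, records), removed
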