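"""Per-exon sorting workflow, exon→gene concatenation, and the end-to-end run.

The workflow per exon: trim the alignment, compute interallelic distances
(supplied tree or NJ fallback), sort each tetraploid's four alleles into
homeolog pairs, and label accepted pairs A/B against the maternal
reference taxon. Samples whose sorting fails are either collapsed to a
single consensus with interallelic SNPs masked (policy ``mask``, the
default — such exons still contribute to gene concatenation) or removed
from the exon alignment (policy ``drop``, for exon-based analyses).

Exons are then concatenated to genes: per tetraploid, sorted exons
contribute their labelled pairs to the A/B lanes (within a pair, ascending
original haplotype index), masked exons contribute their consensus
duplicated into all four lanes, and missing exons are N-filled. Sorting is
re-verified on the concatenated gene with the same threshold; gene-level
labels override exon-level ones, and samples failing verification are
removed from the gene alignment. Completeness filters then assemble nested
datasets (loci with at least k tetraploids sorted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import io as hio
from .distances import DEFAULT_MIN_OVERLAP, DistanceMatrix, locus_distances
from .haplotypes import classify_heterozygosity, mask_interallelic_snps, trim_alignment
from .io import AlleleAlignment, GeneMap, SamplesTable, SequenceRecord, allele_label
from .sorting import (
    DEFAULT_THRESHOLD,
    DEFAULT_TIE_EPS,
    SortDecision,
    label_homeologs,
    sort_alleles,
)

__all__ = [
    "SummaryRecord",
    "ExonResult",
    "GeneAssembly",
    "PipelineResult",
    "process_exon",
    "build_exon_alignment",
    "concatenate_exons_to_genes",
    "verify_gene_sorting",
    "finalize_gene_alignment",
    "filter_by_completeness",
    "summarize_heterozygosity",
    "summary_record",
    "run_pipeline",
]


@dataclass
class SummaryRecord:
    """One report row per (locus, tetraploid sample); see io.REPORT_COLUMNS."""

    locus_id: str
    level: str  # exon | gene
    sample_id: str
    n_alleles: int
    het_class: str | None
    s_best: float
    s_second: float
    ratio: float
    status: str
    pair_members: str | None
    label_A_members: str | None
    mean_dist_A_to_ref: float
    mean_dist_B_to_ref: float
    n_masked_snps: int


@dataclass
class ExonResult:
    """Everything the gene stage needs from one processed exon."""

    locus_id: str
    length: int
    decisions: dict[str, SortDecision]
    diploid_seqs: dict[str, list[tuple[str, str]]]  # sample -> [(label, seq)]
    sorted_seqs: dict[str, dict[str, tuple[tuple[str, str], ...]]]  # sample -> homeolog -> ((label, seq), (label, seq))
    masked_seqs: dict[str, tuple[str, int]]  # sample -> (consensus, n_masked)
    distances: DistanceMatrix | None = None


@dataclass
class GeneAssembly:
    """Concatenated exon alignments for one gene, with sort provenance."""

    gene_id: str
    exon_ids: list[str]
    exon_lengths: list[int]
    alignment: AlleleAlignment
    provenance: dict[str, list[str]]  # tetraploid sample -> sorted|masked|missing per exon
    n_masked_total: dict[str, int] = field(default_factory=dict)


def _hap_index(label: str) -> int:
    parsed = hio.parse_allele_label(label)
    return parsed[1] if parsed else 0


def _reference_labels(
    alignment: AlleleAlignment, samples: SamplesTable
) -> list[str]:
    groups = alignment.sample_alleles()
    ref_taxon = samples.reference_taxon
    return [
        lab
        for s in samples.taxon_samples(ref_taxon)
        for lab in groups.get(s.sample_id, [])
    ]


def process_exon(
    alignment: AlleleAlignment,
    samples: SamplesTable,
    tree=None,
    distances: DistanceMatrix | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> ExonResult:
    """Sort and label every tetraploid sample's alleles at one exon.

    Distances come from ``distances`` if given, else from ``tree``
    (cophenetic), else from the NJ fallback on p-distances. Homozygous and
    1:3-heterozygous samples are definitionally unsortable and
    short-circuit (no pairing can separate subgenomes when at most one
    distinct sequence per putative pair exists); 2:2 loci sort with ratio
    infinity via the distance criterion.
    """
    D = distances if distances is not None else locus_distances(alignment, tree, min_overlap)
    groups = alignment.sample_alleles()
    ref_labels = _reference_labels(alignment, samples)
    locus = alignment.locus_id

    decisions: dict[str, SortDecision] = {}
    diploid_seqs: dict[str, list[tuple[str, str]]] = {}
    sorted_seqs: dict[str, dict[str, tuple]] = {}
    masked_seqs: dict[str, tuple[str, int]] = {}

    for s in samples.samples:
        if s.ploidy != 2:
            continue
        labs = groups.get(s.sample_id, [])
        if labs:
            diploid_seqs[s.sample_id] = [(l, alignment.get(l)) for l in labs]

    for s in samples.tetraploids:
        sid = s.sample_id
        labs = groups.get(sid, [])
        seqs = [alignment.get(l) for l in labs]
        if len(labs) != 4:
            dec = SortDecision(
                locus, sid, "missing_alleles", reason=f"{len(labs)}_alleles"
            )
        else:
            het = classify_heterozygosity(seqs)
            if het == "homozygous":
                dec = SortDecision(locus, sid, "homozygous_like", het_class=het)
            elif het == "het_1_3":
                dec = SortDecision(
                    locus, sid, "equivocal", het_class=het, reason="het_1_3"
                )
            else:
                dec = sort_alleles(
                    D.submatrix(labs), locus, sid,
                    threshold=threshold, tie_eps=tie_eps,
                )
                dec.het_class = het
                dec = label_homeologs(dec, D, ref_labels, tie_eps=tie_eps)
        if dec.status == "sorted":
            by_homeolog = {}
            for homeolog, pair in (("A", dec.pair_a), ("B", dec.pair_b)):
                ordered = sorted(pair, key=_hap_index)
                by_homeolog[homeolog] = tuple(
                    (lab, alignment.get(lab)) for lab in ordered
                )
            sorted_seqs[sid] = by_homeolog
        elif seqs:
            consensus, n_masked = mask_interallelic_snps(seqs)
            masked_seqs[sid] = (consensus, n_masked)
            dec.n_masked = n_masked
        decisions[sid] = dec

    return ExonResult(
        locus_id=locus,
        length=alignment.length,
        decisions=decisions,
        diploid_seqs=diploid_seqs,
        sorted_seqs=sorted_seqs,
        masked_seqs=masked_seqs,
        distances=D,
    )


def build_exon_alignment(
    result: ExonResult, samples: SamplesTable, policy: str = "mask"
) -> AlleleAlignment:
    """Materialize the exon output alignment under the given policy.

    Sorted tetraploids appear as ``{sample}__{A|B}__{1|2}``; unsorted ones
    as a single masked consensus (policy ``mask``) or not at all (``drop``).
    """
    if policy not in ("mask", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    records: list[SequenceRecord] = []
    for s in samples.samples:
        sid = s.sample_id
        if s.ploidy == 2:
            for lab, seq in result.diploid_seqs.get(sid, []):
                records.append(SequenceRecord(lab, seq))
        elif sid in result.sorted_seqs:
            for homeolog in ("A", "B"):
                for i, (_, seq) in enumerate(result.sorted_seqs[sid][homeolog], 1):
                    records.append(
                        SequenceRecord(f"{sid}__{homeolog}__{i}", seq)
                    )
        elif sid in result.masked_seqs and policy == "mask":
            records.append(SequenceRecord(f"{sid}__masked", result.masked_seqs[sid][0]))
    return AlleleAlignment(result.locus_id, records)


def concatenate_exons_to_genes(
    exon_results: Mapping[str, ExonResult],
    gene_map: GeneMap,
    samples: SamplesTable,
) -> dict[str, GeneAssembly]:
    """Concatenate per-exon outputs to per-gene alignments.

    Exon order follows the gene map ordinals. A sample missing an exon is
    N-filled for that exon's length; genes none of whose exons were
    processed are skipped.
    """
    assemblies: dict[str, GeneAssembly] = {}
    for gene_id, exon_ids in gene_map.genes().items():
        present = [e for e in exon_ids if e in exon_results]
        if not present:
            continue
        lengths = [exon_results[e].length for e in present]
        records: list[SequenceRecord] = []
        provenance: dict[str, list[str]] = {}
        n_masked_total: dict[str, int] = {}

        for s in samples.samples:
            sid = s.sample_id
            if s.ploidy == 2:
                lanes = [[] for _ in range(2)]
                for e, L in zip(present, lengths):
                    seqs = dict(exon_results[e].diploid_seqs.get(sid, []))
                    for i in range(2):
                        lab = allele_label(sid, i + 1)
                        lanes[i].append(seqs.get(lab, "N" * L))
                for i in range(2):
                    records.append(
                        SequenceRecord(allele_label(sid, i + 1), "".join(lanes[i]))
                    )
            else:
                lanes = [[] for _ in range(4)]
                prov: list[str] = []
                masked_sum = 0
                for e, L in zip(present, lengths):
                    res = exon_results[e]
                    if sid in res.sorted_seqs:
                        contributed = (
                            res.sorted_seqs[sid]["A"][0][1],
                            res.sorted_seqs[sid]["A"][1][1],
                            res.sorted_seqs[sid]["B"][0][1],
                            res.sorted_seqs[sid]["B"][1][1],
                        )
                        for i in range(4):
                            lanes[i].append(contributed[i])
                        prov.append("sorted")
                    elif sid in res.masked_seqs:
                        consensus, n_masked = res.masked_seqs[sid]
                        for i in range(4):
                            lanes[i].append(consensus)
                        masked_sum += n_masked
                        prov.append("masked")
                    else:
                        for i in range(4):
                            lanes[i].append("N" * L)
                        prov.append("missing")
                for i in range(4):
                    records.append(
                        SequenceRecord(allele_label(sid, i + 1), "".join(lanes[i]))
                    )
                provenance[sid] = prov
                n_masked_total[sid] = masked_sum

        assemblies[gene_id] = GeneAssembly(
            gene_id=gene_id,
            exon_ids=present,
            exon_lengths=lengths,
            alignment=AlleleAlignment(gene_id, records),
            provenance=provenance,
            n_masked_total=n_masked_total,
        )
    return assemblies


def verify_gene_sorting(
    assembly: GeneAssembly,
    samples: SamplesTable,
    gene_tree=None,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> dict[str, SortDecision]:
    """Re-run sorting and labelling on the concatenated gene alignment.

    Uses the same threshold as the exon stage; gene-level labels override
    exon-level ones. The decision for a sample whose lanes carry no signal
    (all exons masked or missing) degenerates to homozygous_like or
    insufficient_overlap and the sample is later removed from the gene.
    """
    result = process_exon(
        assembly.alignment, samples,
        tree=gene_tree, threshold=threshold,
        min_overlap=min_overlap, tie_eps=tie_eps,
    )
    for sid, dec in result.decisions.items():
        dec.n_masked = assembly.n_masked_total.get(sid, 0)
    return result.decisions


def finalize_gene_alignment(
    assembly: GeneAssembly,
    gene_decisions: Mapping[str, SortDecision],
    samples: SamplesTable,
) -> AlleleAlignment:
    """Apply gene-level decisions: relabel sorted samples, remove the rest."""
    records: list[SequenceRecord] = []
    for s in samples.samples:
        sid = s.sample_id
        if s.ploidy == 2:
            for i in (1, 2):
                lab = allele_label(sid, i)
                if lab in assembly.alignment:
                    records.append(SequenceRecord(lab, assembly.alignment.get(lab)))
            continue
        dec = gene_decisions.get(sid)
        if dec is None or dec.status != "sorted" or dec.pair_a is None:
            continue
        for homeolog, pair in (("A", dec.pair_a), ("B", dec.pair_b)):
            for i, lab in enumerate(sorted(pair, key=_hap_index), 1):
                records.append(
                    SequenceRecord(
                        f"{sid}__{homeolog}__{i}", assembly.alignment.get(lab)
                    )
                )
    return AlleleAlignment(assembly.gene_id, records)


def filter_by_completeness(
    decisions_by_locus: Mapping[str, Iterable[SortDecision]],
    min_sorted_tetraploids: int,
) -> list[str]:
    """Loci whose number of sorted tetraploid samples is >= the minimum."""
    out = []
    for locus in sorted(decisions_by_locus):
        n_sorted = sum(
            1 for d in decisions_by_locus[locus] if d.status == "sorted"
        )
        if n_sorted >= min_sorted_tetraploids:
            out.append(locus)
    return out


def summarize_heterozygosity(decisions: Iterable[SortDecision]):
    """Per-sample fractions of loci in each heterozygosity class."""
    import pandas as pd

    counts: dict[str, dict[str, int]] = {}
    for dec in decisions:
        if dec.het_class is None:
            continue
        counts.setdefault(dec.sample_id, {}).setdefault(dec.het_class, 0)
        counts[dec.sample_id][dec.het_class] += 1
    if not counts:
        return pd.DataFrame()
    frame = pd.DataFrame(counts).T.fillna(0).sort_index()
    return frame.div(frame.sum(axis=1), axis=0)


def summary_record(dec: SortDecision, level: str, n_alleles: int = 4) -> SummaryRecord:
    def fmt_pairing():
        if dec.pairing is None:
            return None
        return "|".join(
            ",".join(sorted(p, key=_hap_index)) for p in dec.pairing.pairs
        )

    return SummaryRecord(
        locus_id=dec.locus_id,
        level=level,
        sample_id=dec.sample_id,
        n_alleles=n_alleles,
        het_class=dec.het_class,
        s_best=dec.s_best,
        s_second=dec.s_second,
        ratio=dec.ratio,
        status=dec.status,
        pair_members=fmt_pairing(),
        label_A_members=(
            ",".join(sorted(dec.pair_a, key=_hap_index)) if dec.pair_a else None
        ),
        mean_dist_A_to_ref=dec.dist_a_ref,
        mean_dist_B_to_ref=dec.dist_b_ref,
        n_masked_snps=dec.n_masked,
    )


@dataclass
class PipelineResult:
    exon_results: dict[str, ExonResult]
    gene_assemblies: dict[str, GeneAssembly]
    gene_decisions: dict[str, dict[str, SortDecision]]
    summary: list[SummaryRecord]
    datasets: dict[str, list[str]]
    counts: dict[str, int]


def run_pipeline(
    exon_dir: str | Path,
    samples: SamplesTable,
    out_dir: str | Path,
    gene_map: GeneMap | None = None,
    trees_dir: str | Path | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    policy: str = "mask",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    trim_gap_fraction: float = 0.25,
    min_sorted_filters: Sequence[int] = (1,),
    tie_eps: float = DEFAULT_TIE_EPS,
) -> PipelineResult:
    """Run trim → sort → label → concat → verify → filter over a directory.

    ``exon_dir`` holds one FASTA per exon (file stem = locus id);
    ``trees_dir``, if given, may hold ``{locus}.nwk`` / ``{gene}.nwk``
    companion trees. Outputs land under ``out_dir``: exons/, genes/,
    datasets/, summary.tsv, taxon_map.tsv, log.txt. Deterministic for
    identical inputs.
    """
    exon_dir = Path(exon_dir)
    out_dir = Path(out_dir)
    if policy not in ("mask", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    (out_dir / "exons").mkdir(parents=True, exist_ok=True)
    (out_dir / "datasets").mkdir(parents=True, exist_ok=True)
    if gene_map is not None:
        (out_dir / "genes").mkdir(parents=True, exist_ok=True)

    def find_tree(stem: str):
        if trees_dir is None:
            return None
        for ext in (".nwk", ".tre", ".newick"):
            p = Path(trees_dir) / f"{stem}{ext}"
            if p.exists():
                return hio.read_newick(p)
        return None

    fasta_paths = sorted(
        p for p in exon_dir.iterdir() if p.suffix in (".fasta", ".fa", ".fna")
    )
    counts = {"exons_in": len(fasta_paths), "exons_dropped_empty": 0}
    exon_results: dict[str, ExonResult] = {}
    summary: list[SummaryRecord] = []
    taxon_rows: set[tuple[str, str]] = set()

    taxon_of = {s.sample_id: s.taxon for s in samples.samples}

    def record_taxa(alignment: AlleleAlignment) -> None:
        for lab in alignment.labels:
            parsed = hio.parse_allele_label(lab)
            if parsed is not None:
                taxon_rows.add((lab, taxon_of.get(parsed[0], parsed[0])))
                continue
            parts = lab.split("__")
            sid = parts[0]
            taxon = taxon_of.get(sid, sid)
            if len(parts) == 3 and parts[1] in ("A", "B"):
                taxon_rows.add((lab, f"{taxon}_{parts[1]}"))
            else:
                taxon_rows.add((lab, taxon))

    for path in fasta_paths:
        alignment = hio.read_alignment(path)
        trimmed, _removed = trim_alignment(alignment, trim_gap_fraction)
        if trimmed.length == 0:
            counts["exons_dropped_empty"] += 1
            continue
        tree = find_tree(trimmed.locus_id)
        result = process_exon(
            trimmed, samples, tree=tree,
            threshold=threshold, min_overlap=min_overlap, tie_eps=tie_eps,
        )
        exon_results[trimmed.locus_id] = result
        out_alignment = build_exon_alignment(result, samples, policy)
        hio.write_alignment(out_alignment, out_dir / "exons" / f"{trimmed.locus_id}.fasta")
        record_taxa(out_alignment)
        for sid in sorted(result.decisions):
            dec = result.decisions[sid]
            n_alleles = 4 if dec.status != "missing_alleles" else 0
            summary.append(summary_record(dec, "exon", n_alleles))

    counts["exons_processed"] = len(exon_results)
    counts["exon_decisions_sorted"] = sum(
        1 for r in exon_results.values()
        for d in r.decisions.values() if d.status == "sorted"
    )

    gene_assemblies: dict[str, GeneAssembly] = {}
    gene_decisions: dict[str, dict[str, SortDecision]] = {}
    if gene_map is not None:
        gene_assemblies = concatenate_exons_to_genes(exon_results, gene_map, samples)
        for gene_id in sorted(gene_assemblies):
            assembly = gene_assemblies[gene_id]
            decisions = verify_gene_sorting(
                assembly, samples,
                gene_tree=find_tree(gene_id),
                threshold=threshold, min_overlap=min_overlap, tie_eps=tie_eps,
            )
            gene_decisions[gene_id] = decisions
            final = finalize_gene_alignment(assembly, decisions, samples)
            hio.write_alignment(final, out_dir / "genes" / f"{gene_id}.fasta")
            record_taxa(final)
            for sid in sorted(decisions):
                summary.append(summary_record(decisions[sid], "gene"))
        counts["genes_out"] = len(gene_assemblies)
        counts["gene_decisions_sorted"] = sum(
            1 for decs in gene_decisions.values()
            for d in decs.values() if d.status == "sorted"
        )

    datasets: dict[str, list[str]] = {}
    exon_dec_by_locus = {
        locus: list(r.decisions.values()) for locus, r in exon_results.items()
    }
    for k in sorted(set(min_sorted_filters)):
        selected = filter_by_completeness(exon_dec_by_locus, k)
        datasets[f"exons_min{k}"] = selected
        with open(out_dir / "datasets" / f"exons_min{k}.txt", "w") as fh:
            fh.write("\n".join(selected) + ("\n" if selected else ""))
        if gene_map is not None:
            gene_dec = {g: list(d.values()) for g, d in gene_decisions.items()}
            g_selected = filter_by_completeness(gene_dec, k)
            datasets[f"genes_min{k}"] = g_selected
            with open(out_dir / "datasets" / f"genes_min{k}.txt", "w") as fh:
                fh.write("\n".join(g_selected) + ("\n" if g_selected else ""))

    hio.write_report(summary, out_dir / "summary.tsv")
    with open(out_dir / "taxon_map.tsv", "w") as fh:
        fh.write("allele_label\ttaxon\n")
        for lab, taxon in sorted(taxon_rows):
            fh.write(f"{lab}\t{taxon}\n")
    with open(out_dir / "log.txt", "w") as fh:
        for key in sorted(counts):
            fh.write(f"{key}: {counts[key]}\n")

    return PipelineResult(
        exon_results=exon_results,
        gene_assemblies=gene_assemblies,
        gene_decisions=gene_decisions,
        summary=summary,
        datasets=datasets,
        counts=counts,
    )
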