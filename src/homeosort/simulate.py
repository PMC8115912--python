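"""Synthetic allotetraploid Hyb-Seq loci with known subgenome structure.

The generator instantiates the scenario the sorter is built for: a fixed
species scaffold with two parental clades — maternal (M1, M2) and paternal
(P1, P2) — an outgroup (OUT), and an allotetraploid (TET) whose subgenome
A is sister to the maternal clade and subgenome B sister to the paternal
clade. Sequences evolve down the scaffold under Jukes–Cantor: the root
sequence is i.i.d. uniform over {A,C,G,T} and each branch of expected
divergence d flips each site independently with probability
p = 3/4 · (1 − e^(−4d/3)) to one of the other three bases uniformly (the
expected *observed* difference form, so closed-form checks on p-distances
are exact in expectation). Each species tip then splits into per-sample
alleles at depth d_allelic/2, giving within-individual allele divergence
d_allelic. The tetraploid's four alleles are shuffled and relabelled
h1..h4 with the permutation recorded as ground truth.

Defaults — locus length 700 bp, parental divergence 0.05 expected
substitutions/site, allelic divergence 0.002 — mirror typical
target-enrichment exons of recently diverged congeners: alignments of a
few hundred bases, parental clades separated by a few percent, and
within-individual variation an order of magnitude smaller.

An optional corruption mode emulates homeologous replacement: at a given
fraction of loci one subgenome-A allele is replaced by an extra allele
drawn from the subgenome-B species sequence, producing a 3:1 mixed-origin
allele set that a working sorter should refuse to sort.

Randomness: a single scenario seed; per-locus streams are derived by
seeding with (seed, locus index), so changing n_loci never reshuffles
earlier loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .io import (
    AlleleAlignment,
    GeneMap,
    SampleConfig,
    SamplesTable,
    SequenceRecord,
    allele_label,
)
from .sorting import SortDecision

__all__ = [
    "SimScenario",
    "SimTruth",
    "SimDataset",
    "simulate_locus",
    "simulate_dataset",
    "write_dataset",
    "score_recovery",
    "RecoveryReport",
    "sweep_threshold",
    "jc_expected_p",
]

_BASES = np.frombuffer(b"ACGTN", dtype="S1")

MATERNAL_TAXA = ("M1", "M2")
PATERNAL_TAXA = ("P1", "P2")
OUTGROUP_TAXON = "OUT"
TETRAPLOID_TAXON = "TET"


def jc_expected_p(d: float) -> float:
    """Expected observed proportion of differing sites after divergence d
    (expected substitutions/site) under Jukes–Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass(frozen=True)
class SimScenario:
    """Generating parameters for one synthetic dataset."""

    n_loci: int = 100
    locus_length: int = 700
    d_parental: float = 0.05
    d_allelic: float = 0.002
    n_tetraploids: int = 1
    exons_per_gene: int = 2
    swap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_allelic < self.d_parental:
            raise ValueError("require 0 <= d_allelic < d_parental")
        if self.locus_length <= 0 or self.n_loci <= 0:
            raise ValueError("n_loci and locus_length must be positive")
        if not 0.0 <= self.swap_fraction <= 1.0:
            raise ValueError("swap_fraction must be in [0, 1]")

    def samples(self) -> SamplesTable:
        rows = [
            SampleConfig("M1", "M1", 2, "reference_taxon_member"),
            SampleConfig("M2", "M2", 2, "diploid"),
            SampleConfig("P1", "P1", 2, "diploid"),
            SampleConfig("P2", "P2", 2, "diploid"),
            SampleConfig("OUT", OUTGROUP_TAXON, 2, "outgroup"),
        ]
        for t in range(1, self.n_tetraploids + 1):
            rows.append(SampleConfig(f"T{t}", TETRAPLOID_TAXON, 4, "tetraploid"))
        return SamplesTable(rows)

    def gene_map(self) -> GeneMap:
        return GeneMap(
            {
                self.locus_id(i): (self.gene_id(i), i % self.exons_per_gene + 1)
                for i in range(self.n_loci)
            }
        )

    def gene_id(self, index: int) -> str:
        return f"g{index // self.exons_per_gene + 1:04d}"

    def locus_id(self, index: int) -> str:
        return f"{self.gene_id(index)}_e{index % self.exons_per_gene + 1}"


@dataclass
class SimTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    pair_a: dict[str, frozenset]  # tetraploid sample -> true A-pair labels
    pair_b: dict[str, frozenset]
    origins: dict[str, dict[str, str]]  # sample -> label -> subgenome origin
    swapped: dict[str, bool]  # sample -> corruption applied
    substitutions: dict[str, int] = field(default_factory=dict)  # branch -> count


@dataclass
class SimDataset:
    scenario: SimScenario
    alignments: dict[str, AlleleAlignment]
    truths: dict[str, SimTruth]

    @property
    def samples(self) -> SamplesTable:
        return self.scenario.samples()

    @property
    def gene_map(self) -> GeneMap:
        return self.scenario.gene_map()


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One branch of expected divergence d under Jukes-Cantor."""
    p = jc_expected_p(d)
    hit = rng.random(seq.size) < p
    out = seq.copy()
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out, n


def simulate_locus(
    scenario: SimScenario, index: int
) -> tuple[AlleleAlignment, SimTruth]:
    """Simulate one locus down the fixed allotetraploid scaffold.

    Scaffold depths (h = d_parental/2): each parental side descends from
    the ingroup root as one stem to depth 3h/4, where the tetraploid
    subgenome lineage splits from the two-diploid clade; the clade splits
    again at 7h/8, and all tips reach depth h, so any maternal-side tip is
    d_parental away from any paternal-side tip. The shallow subgenome
    split reflects that allopolyploid hybridization postdates the
    divergence of the parental clades, leaving each subgenome only
    modestly diverged from its parent lineage. The outgroup leaves the
    root on a branch of length d_parental. Deterministic for a fixed
    (seed, index).
    """
    rng = np.random.default_rng([scenario.seed, index])
    L = scenario.locus_length
    h = scenario.d_parental / 2.0
    subs: dict[str, int] = {}

    def evolve(seq, d, branch):
        out, n = _evolve(seq, d, rng)
        subs[branch] = n
        return out

    root = rng.integers(0, 4, size=L)
    out_tip = evolve(root, scenario.d_parental, "root->OUT")
    species: dict[str, np.ndarray] = {OUTGROUP_TAXON: out_tip}

    for side, taxa, sub_label in (
        ("M", MATERNAL_TAXA, "A"),
        ("P", PATERNAL_TAXA, "B"),
    ):
        stem = evolve(root, 0.75 * h, f"root->{side}stem")
        species[f"TET_{sub_label}"] = evolve(stem, 0.25 * h, f"{side}stem->TET_{sub_label}")
        clade = evolve(stem, 0.125 * h, f"{side}stem->{side}clade")
        for taxon in taxa:
            species[taxon] = evolve(clade, 0.125 * h, f"{side}clade->{taxon}")

    d_half = scenario.d_allelic / 2.0
    records: list[SequenceRecord] = []
    samples = scenario.samples()

    def decode(arr: np.ndarray) -> str:
        return _BASES[arr].tobytes().decode("ascii")

    for s in samples.diploids:
        tip = species[s.taxon]
        for i in (1, 2):
            allele, _ = _evolve(tip, d_half, rng)
            records.append(SequenceRecord(allele_label(s.sample_id, i), decode(allele)))

    swap_locus = rng.random() < scenario.swap_fraction
    locus_id = scenario.locus_id(index)
    pair_a: dict[str, frozenset] = {}
    pair_b: dict[str, frozenset] = {}
    origins: dict[str, dict[str, str]] = {}
    swapped: dict[str, bool] = {}

    for s in samples.tetraploids:
        alleles = []
        for sub_label in ("A", "B"):
            tip = species[f"TET_{sub_label}"]
            for k in (1, 2):
                allele, _ = _evolve(tip, d_half, rng)
                alleles.append((f"{sub_label}{k}", allele))
        if swap_locus:
            # homeologous replacement: the second A allele is overwritten by
            # an extra allele derived from the B subgenome
            extra, _ = _evolve(species["TET_B"], d_half, rng)
            alleles[1] = ("B3", extra)
        perm = rng.permutation(4)
        sample_origin: dict[str, str] = {}
        for hap, src in enumerate(perm, start=1):
            origin, seq = alleles[src]
            label = allele_label(s.sample_id, hap)
            records.append(SequenceRecord(label, decode(seq)))
            sample_origin[label] = origin
        origins[s.sample_id] = sample_origin
        pair_a[s.sample_id] = frozenset(
            lab for lab, o in sample_origin.items() if o.startswith("A")
        )
        pair_b[s.sample_id] = frozenset(
            lab for lab, o in sample_origin.items() if o.startswith("B")
        )
        swapped[s.sample_id] = swap_locus

    truth = SimTruth(
        locus_id=locus_id,
        pair_a=pair_a,
        pair_b=pair_b,
        origins=origins,
        swapped=swapped,
        substitutions=subs,
    )
    return AlleleAlignment(locus_id, records), truth


def simulate_dataset(scenario: SimScenario) -> SimDataset:
    alignments: dict[str, AlleleAlignment] = {}
    truths: dict[str, SimTruth] = {}
    for i in range(scenario.n_loci):
        aln, truth = simulate_locus(scenario, i)
        alignments[aln.locus_id] = aln
        truths[truth.locus_id] = truth
    return SimDataset(scenario, alignments, truths)


def write_dataset(dataset: SimDataset, out_dir: str | Path) -> None:
    """Write exon FASTAs, samples table, gene map, truth TSV and a run config."""
    out_dir = Path(out_dir)
    (out_dir / "exons").mkdir(parents=True, exist_ok=True)
    for locus_id in sorted(dataset.alignments):
        hio.write_alignment(
            dataset.alignments[locus_id], out_dir / "exons" / f"{locus_id}.fasta"
        )
    hio.write_samples_table(dataset.samples, out_dir / "samples.tsv")
    hio.write_gene_map(dataset.gene_map, out_dir / "gene_map.tsv")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("locus_id\tsample_id\tswapped\tpair_a\tpair_b\n")
        for locus_id in sorted(dataset.truths):
            t = dataset.truths[locus_id]
            for sid in sorted(t.pair_a):
                fh.write(
                    f"{locus_id}\t{sid}\t{int(t.swapped[sid])}\t"
                    f"{','.join(sorted(t.pair_a[sid]))}\t"
                    f"{','.join(sorted(t.pair_b[sid]))}\n"
                )
    with open(out_dir / "config.txt", "w") as fh:
        fh.write("exon_dir: exons\n")
        fh.write("samples: samples.tsv\n")
        fh.write("gene_map: gene_map.tsv\n")
        fh.write("threshold: 4.0\n")
        fh.write("policy: mask\n")


@dataclass
class RecoveryReport:
    """How well sorting decisions recover the simulated truth."""

    n_decisions: int
    n_sorted: int
    frac_sorted: float
    frac_correct_pairing: float | None  # of sorted clean decisions
    frac_correct_labels: float | None
    frac_equivocal: float
    equivocal_rate_clean: float | None
    equivocal_rate_swapped: float | None
    by_het_class: dict[str, dict[str, float]] = field(default_factory=dict)


def score_recovery(
    decisions: Iterable[SortDecision], truths: Mapping[str, SimTruth]
) -> RecoveryReport:
    """Compare decisions with ground truth.

    Pairing/label accuracy is computed over sorted decisions at clean
    (non-corrupted) loci; corrupted loci are reported via their equivocal
    rate. Correctness fractions are None when no such decision exists.
    """
    n = n_sorted = n_equiv = 0
    n_clean_sorted = n_pairing_ok = n_labels_ok = 0
    clean_total = clean_equiv = swapped_total = swapped_equiv = 0
    by_class: dict[str, dict[str, int]] = {}
    for dec in decisions:
        if dec.locus_id not in truths:
            raise KeyError(f"no truth for locus {dec.locus_id!r}")
        truth = truths[dec.locus_id]
        n += 1
        cls = dec.het_class or "unknown"
        slot = by_class.setdefault(cls, {"n": 0, "sorted": 0})
        slot["n"] += 1
        is_swapped = truth.swapped.get(dec.sample_id, False)
        if is_swapped:
            swapped_total += 1
            swapped_equiv += dec.status != "sorted"
        else:
            clean_total += 1
            clean_equiv += dec.status != "sorted"
        if dec.status == "equivocal":
            n_equiv += 1
        if dec.status != "sorted":
            continue
        n_sorted += 1
        slot["sorted"] += 1
        if is_swapped:
            continue
        n_clean_sorted += 1
        found = {frozenset(p) for p in dec.pairing.pairs}
        expected = {truth.pair_a[dec.sample_id], truth.pair_b[dec.sample_id]}
        if found == expected:
            n_pairing_ok += 1
            if (
                dec.pair_a is not None
                and frozenset(dec.pair_a) == truth.pair_a[dec.sample_id]
            ):
                n_labels_ok += 1

    def frac(num, den):
        return num / den if den else None

    return RecoveryReport(
        n_decisions=n,
        n_sorted=n_sorted,
        frac_sorted=n_sorted / n if n else 0.0,
        frac_correct_pairing=frac(n_pairing_ok, n_clean_sorted),
        frac_correct_labels=frac(n_labels_ok, n_clean_sorted),
        frac_equivocal=n_equiv / n if n else 0.0,
        equivocal_rate_clean=frac(clean_equiv, clean_total),
        equivocal_rate_swapped=frac(swapped_equiv, swapped_total),
        by_het_class={
            cls: {
                "n": float(v["n"]),
                "frac_sorted": v["sorted"] / v["n"],
            }
            for cls, v in sorted(by_class.items())
        },
    )


def sweep_threshold(
    dataset: SimDataset,
    thresholds: Sequence[float],
    min_overlap: int = 50,
) -> pd.DataFrame:
    """Sort every locus at each threshold; report sorted fraction and accuracy.

    Distances are computed once per locus and reused across thresholds, so
    the sorted-locus sets are nested and the sorted fraction is
    non-increasing in the threshold.
    """
    from .distances import locus_distances
    from .pipeline import process_exon  # local import: avoids cycle at module load

    samples = dataset.samples
    matrices = {
        locus_id: locus_distances(aln, min_overlap=min_overlap)
        for locus_id, aln in sorted(dataset.alignments.items())
    }
    rows = []
    for threshold in thresholds:
        decs: list[SortDecision] = []
        for locus_id in sorted(dataset.alignments):
            result = process_exon(
                dataset.alignments[locus_id], samples,
                distances=matrices[locus_id],
                threshold=threshold, min_overlap=min_overlap,
            )
            decs.extend(result.decisions.values())
        report = score_recovery(decs, dataset.truths)
        rows.append(
            {
                "threshold": threshold,
                "frac_sorted": report.frac_sorted,
                "frac_correct_pairing": report.frac_correct_pairing,
                "frac_correct_labels": report.frac_correct_labels,
            }
        )
    return pd.DataFrame(rows)
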