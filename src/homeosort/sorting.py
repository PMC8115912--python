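"""The core algorithm: partition four alleles into two homeolog pairs.

An allotetraploid carries four alleles per locus, two from each parental
subgenome. Among the three perfect matchings of four alleles into two
pairs, the true homeolog pairing minimizes within-pair distance while the
between-pair distances reflect parental divergence. A pairing is accepted
as unequivocal only when its mean within-pair distance is more than
``threshold`` times shorter than that of *any* alternative arrangement
(default threshold 4): with scores s(pi) = mean of the two within-pair
distances, the decision is sorted iff min alternative score / best score
> threshold (strict). A best score of exactly zero with positive
alternatives (e.g. a 2:2 heterozygous locus) sorts with ratio infinity;
all three scores zero is degenerate (homozygous-like); a tie between the
best two scores is equivocal.

Accepted pairs are then labelled: the pair whose alleles lie closer (mean
pairwise distance) to the maternal reference taxon's alleles becomes
homeolog A, the other B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SamplesTable, parse_allele_label
from .distances import DistanceMatrix

__all__ = [
    "Pairing",
    "SortDecision",
    "enumerate_pairings",
    "sort_alleles",
    "label_homeologs",
    "homeolog_reference_distances",
    "STATUSES",
    "DEFAULT_THRESHOLD",
    "DEFAULT_TIE_EPS",
]

DEFAULT_THRESHOLD = 4.0
DEFAULT_TIE_EPS = 1e-12

STATUSES = (
    "sorted",
    "equivocal",
    "homozygous_like",
    "missing_alleles",
    "insufficient_overlap",
)

# the (4-1)!! = 3 perfect matchings of indices 0..3, deterministic order
_PAIRING_INDICES = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


@dataclass(frozen=True)
class Pairing:
    """Two disjoint unordered pairs covering a sample's four allele labels."""

    pairs: tuple[tuple[str, str], tuple[str, str]]
    score: float = math.nan  # mean of the two within-pair distances

    def as_sets(self) -> tuple[frozenset, frozenset]:
        return frozenset(self.pairs[0]), frozenset(self.pairs[1])


@dataclass
class SortDecision:
    """Outcome of allele sorting for one (locus, tetraploid sample)."""

    locus_id: str
    sample_id: str
    status: str
    het_class: str | None = None
    pairing: Pairing | None = None
    s_best: float = math.nan
    s_second: float = math.nan
    ratio: float = math.nan
    pair_a: tuple[str, str] | None = None  # homeolog A members
    pair_b: tuple[str, str] | None = None
    dist_a_ref: float = math.nan
    dist_b_ref: float = math.nan
    reason: str | None = None
    n_masked: int = 0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def enumerate_pairings(labels: Sequence[str]) -> list[Pairing]:
    """The three ways to split four allele labels into two pairs.

    Order is deterministic: partner of the first label is the 2nd, 3rd,
    4th label in turn. Each of the six unordered pairs appears in exactly
    one pairing.
    """
    if len(labels) != 4 or len(set(labels)) != 4:
        raise ValueError(f"need exactly 4 distinct labels, got {list(labels)}")
    out = []
    for (i, j), (k, l) in _PAIRING_INDICES:
        out.append(Pairing(((labels[i], labels[j]), (labels[k], labels[l]))))
    return out


def sort_alleles(
    D: DistanceMatrix,
    locus_id: str = "",
    sample_id: str = "",
    threshold: float = DEFAULT_THRESHOLD,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> SortDecision:
    """Score the three pairings of a tetraploid's four alleles and decide.

    ``D`` must be the distance matrix restricted to the sample's four
    allele labels. Any needed pair distance missing -> insufficient_overlap.
    """
    if len(D) != 4:
        raise ValueError("sort_alleles needs a 4x4 distance matrix")
    labels = list(D.labels)
    if np.isnan(D.values[np.triu_indices(4, k=1)]).any():
        return SortDecision(
            locus_id, sample_id, "insufficient_overlap", reason="missing_distance"
        )

    pairings = enumerate_pairings(labels)
    scored = [
        replace(
            p,
            score=0.5 * (D.get(*p.pairs[0]) + D.get(*p.pairs[1])),
        )
        for p in pairings
    ]
    order = sorted(range(3), key=lambda k: scored[k].score)
    best, second = scored[order[0]], scored[order[1]]
    s_best, s_second = best.score, second.score

    if all(p.score <= tie_eps for p in scored):
        return SortDecision(
            locus_id, sample_id, "homozygous_like",
            s_best=s_best, s_second=s_second,
        )
    if s_second - s_best <= tie_eps:
        # covers a tied pair of zero scores too: the best pairing is
        # ambiguous, so an infinite ratio is not claimable
        return SortDecision(
            locus_id, sample_id, "equivocal", pairing=best,
            s_best=s_best, s_second=s_second,
            ratio=s_second / s_best if s_best > 0 else math.nan,
            reason="score_tie",
        )
    if s_best <= tie_eps:
        return SortDecision(
            locus_id, sample_id, "sorted", pairing=best,
            s_best=s_best, s_second=s_second, ratio=math.inf,
        )
    ratio = s_second / s_best
    if ratio > threshold:
        return SortDecision(
            locus_id, sample_id, "sorted", pairing=best,
            s_best=s_best, s_second=s_second, ratio=ratio,
        )
    return SortDecision(
        locus_id, sample_id, "equivocal", pairing=best,
        s_best=s_best, s_second=s_second, ratio=ratio,
        reason="below_threshold",
    )


def _mean_pair_to_reference(
    pair: Iterable[str], reference_labels: Sequence[str], D: DistanceMatrix
) -> float:
    dists = [
        D.get(a, r)
        for a in pair
        for r in reference_labels
        if not math.isnan(D.get(a, r))
    ]
    return float(np.mean(dists)) if dists else math.nan


def label_homeologs(
    decision: SortDecision,
    D_full: DistanceMatrix,
    reference_labels: Sequence[str],
    tie_eps: float = DEFAULT_TIE_EPS,
) -> SortDecision:
    """Attach A/B labels: the pair closer to the maternal reference is A.

    The reference labels are the maternal taxon's allele labels present at
    this locus. No reference present, or a tie in the two mean distances,
    downgrades the decision to equivocal (reasons no_reference / label_tie).
    """
    if decision.status != "sorted":
        return decision
    assert decision.pairing is not None
    present = [r for r in reference_labels if r in D_full.labels]
    if not present:
        return replace(decision, status="equivocal", reason="no_reference")
    pair1, pair2 = decision.pairing.pairs
    m1 = _mean_pair_to_reference(pair1, present, D_full)
    m2 = _mean_pair_to_reference(pair2, present, D_full)
    if math.isnan(m1) or math.isnan(m2):
        return replace(decision, status="equivocal", reason="no_reference")
    if abs(m1 - m2) <= tie_eps:
        return replace(decision, status="equivocal", reason="label_tie")
    if m1 < m2:
        pair_a, pair_b, da, db = pair1, pair2, m1, m2
    else:
        pair_a, pair_b, da, db = pair2, pair1, m2, m1
    return replace(
        decision, pair_a=pair_a, pair_b=pair_b, dist_a_ref=da, dist_b_ref=db
    )


def homeolog_reference_distances(
    decisions: Iterable[SortDecision],
    distances_by_locus: Mapping[str, DistanceMatrix],
    samples: SamplesTable,
) -> pd.DataFrame:
    """Mean distance from each homeolog to each diploid taxon, over loci.

    Only sorted loci contribute; each locus's mean weighs equally. Rows are
    (sample_id, homeolog in {A, B}); columns are diploid taxa; values are
    averages of the per-locus mean pairwise distances between the
    homeolog's two alleles and the taxon's alleles present at that locus.
    Empty (no sorted loci) -> empty frame.
    """
    diploid_taxa = sorted({s.taxon for s in samples.diploids})
    taxon_to_samples = {
        t: [s.sample_id for s in samples.taxon_samples(t)] for t in diploid_taxa
    }
    acc: dict[tuple[str, str, str], list[float]] = {}
    for dec in decisions:
        if dec.status != "sorted" or dec.pair_a is None:
            continue
        D = distances_by_locus.get(dec.locus_id)
        if D is None:
            continue
        locus_samples = _labels_by_sample(D.labels)
        for homeolog, pair in (("A", dec.pair_a), ("B", dec.pair_b)):
            for taxon in diploid_taxa:
                ref_labels = [
                    lab
                    for sid in taxon_to_samples[taxon]
                    for lab in locus_samples.get(sid, [])
                ]
                if not ref_labels:
                    continue
                m = _mean_pair_to_reference(pair, ref_labels, D)
                if not math.isnan(m):
                    acc.setdefault((dec.sample_id, homeolog, taxon), []).append(m)
    if not acc:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["sample_id", "homeolog"])
        )
    rows = sorted({(s, h) for s, h, _ in acc})
    data = {
        taxon: [
            float(np.mean(acc[(s, h, taxon)])) if (s, h, taxon) in acc else math.nan
            for s, h in rows
        ]
        for taxon in diploid_taxa
    }
    index = pd.MultiIndex.from_tuples(rows, names=["sample_id", "homeolog"])
    return pd.DataFrame(data, index=index)


def _labels_by_sample(labels: Sequence[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for lab in labels:
        parsed = parse_allele_label(lab)
        if parsed is not None:
            out.setdefault(parsed[0], []).append(lab)
    return out
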