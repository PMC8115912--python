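"""Independent brute-force re-derivation of the allele-sorting decision.

Kept deliberately naive and separate from the package: matchings are
enumerated from raw permutations, scores from plain arithmetic, and the
decision rules re-stated from scratch, so agreement with
``homeosort.sorting.sort_alleles`` is a genuine cross-check.
"""

import itertools
import math


def all_matchings(labels):
    """Every way to split 4 labels into 2 unordered pairs, via permutations."""
    out = set()
    for perm in itertools.permutations(labels):
        out.add(frozenset({frozenset(perm[:2]), frozenset(perm[2:])}))
    return out


def brute_force_sort(labels, dist, threshold=4.0, tie_eps=1e-12):
    """Return (status, best_matching_or_None, ratio).

    ``dist`` maps frozenset({a, b}) -> distance. Decision rules: mean of
    the two within-pair distances per matching; all three scores ~0 ->
    homozygous_like; zero best with positive alternative -> sorted with
    infinite ratio; best/second tie -> equivocal; else sorted iff
    second/best > threshold strictly.
    """
    if any(math.isnan(d) for d in dist.values()):
        return "insufficient_overlap", None, math.nan
    scores = {}
    for matching in all_matchings(labels):
        pair1, pair2 = tuple(matching)
        scores[matching] = (dist[pair1] + dist[pair2]) / 2
    assert len(scores) == 3
    ranked = sorted(scores.items(), key=lambda kv: kv[1])
    (best_m, s_best), (_, s_second) = ranked[0], ranked[1]
    if all(s <= tie_eps for s in scores.values()):
        return "homozygous_like", None, math.nan
    if s_second - s_best <= tie_eps:
        # a tie for best pairing — including two zero scores — is ambiguous
        return "equivocal", None, s_second / s_best if s_best > 0 else math.nan
    if s_best <= tie_eps:
        return "sorted", best_m, math.inf
    ratio = s_second / s_best
    if ratio > threshold:
        return "sorted", best_m, ratio
    return "equivocal", None, ratio


def random_matrix_cases(rng, n):
    """Random symmetric 4x4 cases with deliberate zero/tie injections.

    Yields dicts frozenset({i,j}) -> distance over labels 0..3. One in
    five matrices is drawn from a coarse grid (frequent exact ties), one
    in ten has one within-pair distance zeroed, one in twenty is all-zero.
    """
    labels = list(range(4))
    pairs = [frozenset(p) for p in itertools.combinations(labels, 2)]
    for k in range(n):
        mode = k % 20
        if mode == 0:
            yield {p: 0.0 for p in pairs}
            continue
        if mode % 5 == 1:
            values = rng.integers(0, 4, size=6) / 4.0
        else:
            values = rng.random(6)
        dist = dict(zip(pairs, (float(v) for v in values)))
        if mode % 10 == 2:
            dist[frozenset({0, 1})] = 0.0
            dist[frozenset({2, 3})] = 0.0
        yield dist
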