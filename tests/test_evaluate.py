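"""Partition comparison, OG-size binning, DC refinement and bootstrap."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from sjinet.evaluate import (
    Partition,
    adjusted_mutual_information,
    adjusted_rand_index,
    bin_by_og_size,
    dc_refinement_curve,
    pairwise_consistency,
    refinement_sizes,
)
from sjinet.ogdetect import OrthologGroup
from sjinet.records import InvalidInputError


# ---------------------------------------------------------------- oracles --
def set_partitions(items):
    """All set partitions of a sequence (textbook recursion)."""
    if len(items) == 1:
        yield [list(items)]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def _labels(partition_blocks, items):
    lab = {}
    for i, block in enumerate(partition_blocks):
        for x in block:
            lab[x] = i
    return [lab[x] for x in items]


def oracle_ari(a, b):
    """Hubert–Arabie ARI from explicit pair counting over all item pairs."""
    n = len(a)
    sum_ij = sum(
        math.comb(c, 2)
        for c in Counter(zip(a, b)).values()
    )
    sum_a = sum(math.comb(c, 2) for c in Counter(a).values())
    sum_b = sum(math.comb(c, 2) for c in Counter(b).values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0  # both partitions degenerate (all-singletons or one block)
    return (sum_ij - expected) / (maximum - expected)


def oracle_ami(a, b):
    """AMI with the expected mutual information computed exhaustively by
    averaging MI over every permutation of one labelling (the permutation
    model itself); max-entropy normalization."""
    n = len(a)

    def mi(x, y):
        total = 0.0
        cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
        for (i, j), nij in cxy.items():
            total += (nij / n) * math.log(n * nij / (cx[i] * cy[j]))
        return total

    def entropy(x):
        return -sum((c / n) * math.log(c / n) for c in Counter(x).values())

    emi = np.mean([mi(a, perm) for perm in itertools.permutations(b)])
    h_max = max(entropy(a), entropy(b))
    mi_ab = mi(a, b)
    if h_max == 0:
        return 1.0  # two single-block partitions
    denom = h_max - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi_ab - emi) < 1e-15 else 0.0
    return (mi_ab - emi) / denom


# ---------------------------------------------------------------- tests --
def _part(mapping):
    return Partition(dict(mapping))


class TestAriAmi:
    def test_identical_partitions(self):
        p = _part({"a": 1, "b": 1, "c": 2})
        assert adjusted_rand_index(p, p) == 1.0
        assert adjusted_mutual_information(p, p) == 1.0

    def test_crossed_two_blocks(self):
        p = _part({"a": 0, "b": 0, "c": 1, "d": 1})
        q = _part({"a": 0, "b": 1, "c": 0, "d": 1})
        assert adjusted_rand_index(p, q) == pytest.approx(-0.5)

    def test_single_block_vs_single_block_is_one(self):
        p = _part({"a": 0, "b": 0, "c": 0})
        q = _part({"a": 9, "b": 9, "c": 9})
        assert adjusted_mutual_information(p, q) == 1.0
        assert adjusted_rand_index(p, q) == 1.0

    def test_comparison_restricted_to_common_universe(self):
        p = _part({"a": 0, "b": 0, "c": 1, "z": 5})
        q = _part({"a": 0, "b": 0, "c": 1, "y": 7})
        assert adjusted_rand_index(p, q) == 1.0

    def test_too_few_common_proteins(self):
        with pytest.raises(InvalidInputError):
            adjusted_rand_index(_part({"a": 0}), _part({"a": 0, "b": 1}))

    def test_label_permutation_invariance(self):
        p = _part({x: l for x, l in zip("abcdef", [0, 0, 1, 1, 2, 2])})
        q = _part({x: l for x, l in zip("abcdef", ["x", "x", "y", "y", "z", "z"])})
        assert adjusted_rand_index(p, q) == 1.0
        assert adjusted_mutual_information(p, q) == 1.0

    def test_exhaustive_partitions_of_five_match_oracles(self):
        """ARI/AMI equal brute-force contingency/permutation oracles on every
        pair of set partitions of 5 items."""
        items = list("abcde")
        parts = [_labels(bl, items) for bl in set_partitions(items)]
        for a, b in itertools.combinations_with_replacement(parts, 2):
            p = _part(dict(zip(items, a)))
            q = _part(dict(zip(items, b)))
            assert adjusted_rand_index(p, q) == pytest.approx(oracle_ari(a, b), abs=1e-9)
            assert adjusted_mutual_information(p, q) == pytest.approx(
                oracle_ami(a, b), abs=1e-9
            )

    def test_random_partitions_near_zero(self):
        rng = np.random.default_rng(17)
        ids = [f"p{i}" for i in range(2000)]
        hits_ari = hits_ami = 0
        for _ in range(100):
            p = _part(dict(zip(ids, rng.integers(0, 2, len(ids)))))
            q = _part(dict(zip(ids, rng.integers(0, 2, len(ids)))))
            if abs(adjusted_rand_index(p, q)) < 0.05:
                hits_ari += 1
            if abs(adjusted_mutual_information(p, q)) < 0.05:
                hits_ami += 1
        assert hits_ari >= 95 and hits_ami >= 95


class TestPairwiseConsistency:
    def test_copies_give_unit_ari(self):
        p = _part({x: l for x, l in zip("abcd", [0, 0, 1, 1])})
        res = pairwise_consistency([p, p, p])
        assert all(r.ari == 1.0 for r in res.values())

    def test_relabelling_detected_as_identical(self):
        p = _part({x: l for x, l in zip("abcd", [0, 0, 1, 1])})
        q = _part({x: l for x, l in zip("abcd", "xxyy")})
        r = _part({x: l for x, l in zip("abcd", [0, 1, 0, 1])})
        res = pairwise_consistency([p, q, r])
        assert res[(0, 1)].ari == 1.0 and res[(0, 1)].ami == 1.0
        assert res[(0, 2)].ari < 1.0

    def test_empty_subset_marked_missing(self):
        p = _part({"a": 0, "b": 1})
        q = _part({"a": 0, "b": 1})
        res = pairwise_consistency([p, q], subset={"zzz"})
        assert res[(0, 1)] is None

    def test_ari_decreases_with_disagreement_rate(self):
        rng = np.random.default_rng(23)
        ids = [f"p{i}" for i in range(1000)]
        base = dict(zip(ids, rng.integers(0, 10, len(ids))))
        p = _part(base)
        aris = []
        for r in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            noisy = dict(base)
            flip = rng.choice(ids, size=int(r * len(ids)), replace=False)
            for x in flip:
                noisy[x] = 10 + int(rng.integers(0, 10))
            aris.append(adjusted_rand_index(p, _part(noisy)))
        assert all(a > b for a, b in zip(aris, aris[1:]))

    def test_restriction_equals_physical_deletion(self):
        rng = np.random.default_rng(29)
        ids = [f"p{i}" for i in range(200)]
        p = dict(zip(ids, rng.integers(0, 5, 200)))
        q = dict(zip(ids, rng.integers(0, 5, 200)))
        subset = set(rng.choice(ids, size=80, replace=False))
        full = adjusted_rand_index(_part(p), _part(q), subset=subset)
        cut = adjusted_rand_index(
            _part({k: v for k, v in p.items() if k in subset}),
            _part({k: v for k, v in q.items() if k in subset}),
        )
        assert full == pytest.approx(cut, abs=1e-12)


def _ogs_from_sizes(sizes):
    ogs, n = [], 0
    for i, s in enumerate(sizes):
        members = frozenset(f"g{i:03d}m{j:03d}" for j in range(s))
        ogs.append(OrthologGroup(f"OG{i:04d}", members, 1.0, False, {m: 0.5 for m in members}))
        n += s
    return ogs


class TestBinByOgSize:
    def test_two_obvious_bins(self):
        ogs = _ogs_from_sizes([1, 1, 10, 10])
        bins = bin_by_og_size(ogs, 2)
        assert [(b.min_size, b.max_size) for b in bins] == [(1, 1), (10, 10)]
        assert [len(b.proteins) for b in bins] == [2, 20]

    def test_og_never_split_and_mass_balanced(self):
        """Against an exhaustive search over all boundary placements."""
        sizes = [1, 1, 1, 2, 2, 3, 5, 5, 8, 13]
        ogs = _ogs_from_sizes(sizes)
        bins = bin_by_og_size(ogs, 3)
        total = sum(sizes)
        # every OG intact in exactly one bin
        seen = [p for b in bins for p in b.proteins]
        assert len(seen) == len(set(seen)) == total
        # exhaustive oracle: best achievable max deviation from equal mass
        distinct = sorted({s for s in sizes})
        mass = {s: sum(x for x in sizes if x == s) for s in distinct}
        best = None
        for cut in itertools.combinations(range(1, len(distinct)), 2):
            groups = np.split(np.array(distinct), cut)
            dev = max(abs(sum(mass[s] for s in g) - total / 3) for g in groups)
            best = dev if best is None else min(best, dev)
        mine = max(abs(len(b.proteins) - total / 3) for b in bins)
        assert mine <= best + max(sizes)  # within one OG of the optimum

    def test_seven_bins_monotone_ranges(self):
        rng = np.random.default_rng(41)
        sizes = [int(s) for s in rng.integers(1, 60, 300)]
        bins = bin_by_og_size(_ogs_from_sizes(sizes), 7)
        assert len(bins) == 7
        ranges = [(b.min_size, b.max_size) for b in bins]
        assert all(a[1] < b[0] for a, b in zip(ranges, ranges[1:]))

    def test_fewer_sizes_than_bins(self):
        bins = bin_by_og_size(_ogs_from_sizes([3, 3, 7]), 5)
        assert len(bins) == 2


class TestRefinement:
    def test_fixed_schedule_from_656(self):
        sizes = refinement_sizes(656, steps=10)
        assert sizes[0] == 656
        assert abs(sizes[1] - 590) <= 1
        assert abs(sizes[-1] - 66) <= 1
        diffs = [a - b for a, b in zip(sizes, sizes[1:])]
        assert max(diffs) - min(diffs) <= 1  # equal decile removals

    def test_compounding_schedule(self):
        sizes = refinement_sizes(1000, steps=10, schedule="compounding")
        assert sizes[:3] == [1000, 900, 810]

    def test_ties_broken_by_protein_id(self):
        ogs = _ogs_from_sizes([12, 12])
        dc = {m: 0.5 for og in ogs for m in og.members}
        ids = sorted(dc)
        p = Partition({m: i // 12 for i, m in enumerate(ids)})
        curve = dc_refinement_curve([p, p], dc, ogs, min_og_size=10, steps=4)
        assert [st.n_retained for st in curve] == [24, 18, 12, 6]
        assert all(r.ari == 1.0 for st in curve for r in st.consistency.values())

    def test_noise_in_low_dc_gives_nondecreasing_ari(self):
        """Label noise concentrated below the DC median makes the curve rise."""
        rng = np.random.default_rng(53)
        ogs = _ogs_from_sizes([20] * 20)
        members = sorted(m for og in ogs for m in og.members)
        dc = {m: float(rng.uniform(0, 1)) for m in members}
        truth = {}
        for og in ogs:
            for m in og.members:
                truth[m] = og.og_id
        noisy = dict(truth)
        median = np.median(list(dc.values()))
        for m in members:
            if dc[m] < median and rng.random() < 0.5:
                noisy[m] = f"wrong{rng.integers(0, 20)}"
        curve = dc_refinement_curve(
            [Partition(truth), Partition(noisy)], dc, ogs, min_og_size=10, steps=10
        )
        aris = [st.consistency[(0, 1)].ari for st in curve]
        assert all(b >= a - 0.02 for a, b in zip(aris, aris[1:]))
        assert aris[-1] > aris[0]
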