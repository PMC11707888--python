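"""Partition comparison (ARI/AMI), OG-size binning, DC refinement, bootstrap.

Different orthology methods cover different protein sets, so every comparison
here is computed on the intersection of the two universes.  ARI is the
chance-corrected pair-counting agreement; AMI is mutual information corrected
for its permutation-model expectation and normalized by the larger marginal
entropy, so both equal 1 on identical partitions and hover near 0 for
independent ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .ogdetect import OrthologGroup
from .pipeline import PipelineConfig, PipelineResult, drop_proteins, run_from_hits
from .records import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    assignment: dict[str, object]

    @property
    def universe(self) -> set[str]:
        return set(self.assignment)

    @classmethod
    def from_tsv(cls, path) -> "Partition":
        assignment: dict[str, object] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pid, label = line.split("\t")
                assignment[pid] = label
        return cls(assignment)


@dataclass(frozen=True)
class ConsistencyResult:
    ari: float
    ami: float
    n_common: int


@dataclass
class BootstrapResult:
    replicate_aris: list[float | None]
    replicate_dc_correlations: list[float | None]

    @property
    def mean_ari(self) -> float:
        vals = [a for a in self.replicate_aris if a is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_dc_corr(self) -> float:
        vals = [c for c in self.replicate_dc_correlations if c is not None]
        return float(np.mean(vals)) if vals else float("nan")


def _same_partition(a: Sequence, b: Sequence) -> bool:
    """True when two label vectors induce the same grouping."""
    fwd: dict = {}
    rev: dict = {}
    for x, y in zip(a, b):
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True


def _common_labels(p: Partition, q: Partition, subset: set[str] | None = None):
    common = p.universe & q.universe
    if subset is not None:
        common &= subset
    ids = sorted(common)
    a = [p.assignment[i] for i in ids]
    b = [q.assignment[i] for i in ids]
    return ids, a, b


def adjusted_rand_index(p: Partition, q: Partition, subset: set[str] | None = None) -> float:
    """Permutation-model ARI over the common universe; identical -> 1."""
    ids, a, b = _common_labels(p, q, subset)
    if len(ids) < 2:
        raise InvalidInputError("ARI needs at least 2 common proteins")
    return float(adjusted_rand_score(a, b))


def adjusted_mutual_information(
    p: Partition, q: Partition, subset: set[str] | None = None
) -> float:
    """AMI with permutation-model expected MI and max-entropy normalization.

    Identical partitions score 1.0 even in the degenerate all-singleton case
    (where the general formula is 0/0); two single-block partitions likewise.
    """
    ids, a, b = _common_labels(p, q, subset)
    if len(ids) < 2:
        raise InvalidInputError("AMI needs at least 2 common proteins")
    if _same_partition(a, b):
        return 1.0
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def pairwise_consistency(
    partitions: Sequence[Partition], subset: set[str] | None = None
) -> dict[tuple[int, int], ConsistencyResult | None]:
    """ARI and AMI for every unordered pair, restricted to the given subset.

    A pair whose effective common universe has fewer than 2 proteins is
    recorded as None (missing).
    """
    if len(partitions) < 2:
        raise InvalidInputError("need at least 2 partitions")
    out: dict[tuple[int, int], ConsistencyResult | None] = {}
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            ids, a, b = _common_labels(partitions[i], partitions[j], subset)
            if len(ids) < 2:
                out[(i, j)] = None
            else:
                same = _same_partition(a, b)
                out[(i, j)] = ConsistencyResult(
                    ari=float(adjusted_rand_score(a, b)),
                    ami=1.0 if same else float(
                        adjusted_mutual_info_score(a, b, average_method="max")
                    ),
                    n_common=len(ids),
                )
    return out


@dataclass(frozen=True)
class SizeBin:
    min_size: int
    max_size: int
    proteins: frozenset[str]


def bin_by_og_size(ogs: Sequence[OrthologGroup], n_bins: int) -> list[SizeBin]:
    """Group proteins into bins of approximately equal protein mass by OG size.

    Bin boundaries fall on OG-size values, so an OG (indeed, all OGs of one
    size) is never split across bins.  With fewer distinct sizes than bins,
    fewer bins are returned and a warning logged.
    """
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    mass: dict[int, list[str]] = {}
    for og in ogs:
        mass.setdefault(og.size, []).extend(og.members)
    sizes = sorted(mass)
    if len(sizes) < n_bins:
        logger.warning(
            "only %d distinct OG sizes for %d bins; returning %d bins",
            len(sizes), n_bins, len(sizes),
        )
        n_bins = len(sizes)
    total = sum(len(v) for v in mass.values())
    bins: list[SizeBin] = []
    idx = 0
    remaining = total
    for b in range(n_bins):
        bins_left = n_bins - b
        target = remaining / bins_left
        acc: list[str] = []
        lo = sizes[idx]
        # every remaining bin must still get at least one size group
        while idx < len(sizes):
            if acc and bins_left > 1:
                if len(sizes) - idx - 1 < bins_left - 1:
                    break
                nxt = len(mass[sizes[idx]])
                if abs(len(acc) + nxt - target) > abs(len(acc) - target):
                    break
            acc.extend(mass[sizes[idx]])
            idx += 1
        hi = sizes[idx - 1]
        remaining -= len(acc)
        bins.append(SizeBin(lo, hi, frozenset(acc)))
    return bins


def refinement_sizes(n0: int, steps: int = 10, schedule: str = "fixed") -> list[int]:
    """Retained-set sizes along the DC refinement curve.

    "fixed" removes an equal 1/steps share of the *starting* set each step
    (n0, n0*(1-1/steps), ..., n0/steps); "compounding" removes 1/steps of the
    *previous* step's set each time.
    """
    if schedule == "fixed":
        return [int(round(n0 * (1 - s / steps))) for s in range(steps)]
    if schedule == "compounding":
        sizes = [n0]
        for _ in range(steps - 1):
            sizes.append(sizes[-1] - int(round(sizes[-1] / steps)))
        return sizes
    raise InvalidInputError(f"unknown schedule {schedule!r}")


@dataclass(frozen=True)
class RefinementStep:
    step: int
    n_retained: int
    consistency: dict[tuple[int, int], ConsistencyResult | None]


def dc_refinement_curve(
    partitions: Sequence[Partition],
    dc: Mapping[str, float],
    ogs: Sequence[OrthologGroup],
    min_og_size: int = 10,
    steps: int = 10,
    schedule: str = "fixed",
) -> list[RefinementStep]:
    """Pairwise consistency as low-DC proteins are progressively excluded.

    The starting set is every protein from an OG of size >= min_og_size,
    ordered by DC descending (ties by protein_id); step s keeps the top
    (1 - s/steps) fraction under the default schedule.  The curve truncates
    with a warning once the retained set can no longer support a comparison.
    """
    pool = [v for og in ogs if og.size >= min_og_size for v in og.members]
    missing = [v for v in pool if v not in dc]
    if missing:
        raise InvalidInputError(f"DC undefined for {len(missing)} proteins, e.g. {missing[0]!r}")
    pool.sort(key=lambda v: (-dc[v], v))
    curve: list[RefinementStep] = []
    for s, m in enumerate(refinement_sizes(len(pool), steps, schedule)):
        retained = set(pool[:m])
        if len(retained) < 2:
            logger.warning("refinement curve truncated at step %d (retained %d)", s, m)
            break
        curve.append(RefinementStep(s, m, pairwise_consistency(partitions, retained)))
    return curve


def bootstrap_stability(
    result: PipelineResult,
    config: PipelineConfig,
    frac: float = 0.1,
    reps: int = 20,
    seed: int = 0,
) -> BootstrapResult:
    """Stability of OGs and DC under random protein removal.

    Each replicate removes round(frac*n) proteins without replacement (from
    the hit table, as both seeds and targets), reruns signal detection, the
    SJI network and OG detection, and records (a) the ARI between replicate
    and original OGs on the surviving proteins and (b) the Pearson
    correlation between replicate and original DC.  A failed replicate (or an
    undefined correlation on constant DC) is recorded as missing.
    """
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    all_ids = sorted(result.partition)
    n_remove = int(round(frac * len(all_ids)))
    original = Partition(dict(result.partition))
    original_dc = result.dc
    aris: list[float | None] = []
    corrs: list[float | None] = []
    for _ in range(reps):
        removed = set(rng.choice(all_ids, size=n_remove, replace=False)) if n_remove else set()
        try:
            hits, kept = drop_proteins(result.hits, all_ids, removed)
            rep = run_from_hits(hits, kept, config)
            aris.append(adjusted_rand_index(original, Partition(dict(rep.partition))))
            rep_dc = rep.dc
            x = np.array([original_dc[v] for v in kept])
            y = np.array([rep_dc[v] for v in kept])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corrs.append(None)
            else:
                corrs.append(float(np.corrcoef(x, y)[0, 1]))
        except Exception:  # noqa: BLE001 - a replicate failure must not abort the run
            logger.exception("bootstrap replicate failed; recorded as missing")
            aris.append(None)
            corrs.append(None)
    return BootstrapResult(aris, corrs)
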