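"""Full-length global protein alignment and per-species top-K hit selection.

Similarity between two proteins is the percent identity (or percent positive
substitutions) of an optimal Needleman–Wunsch global alignment, with the
alignment length — gap columns included — as denominator.  Candidates whose
length ratio (longer/shorter) reaches 1.5 are excluded before ranking, so a
multi-domain protein can never occupy a top-K slot of a single-domain seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import InvalidInputError, ProteinRecord, Proteomes

#: Default length-ratio candidacy cutoff: hits must satisfy ratio < 1.5.
DEFAULT_MAX_RATIO = 1.5
#: Per-species top-K defaults for prokaryote and eukaryote collections.
K_PROKARYOTE = 10
K_EUKARYOTE = 50


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring parameters.

    gap_open is the score of the first residue of a gap and gap_extend of each
    further residue, so a gap of length g scores gap_open + (g-1)*gap_extend.
    similarity_mode selects percent identity (default) or percent similarity
    (fraction of columns with a positive substitution score).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    similarity_mode: str = "percent_identity"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise InvalidInputError("require gap_open <= gap_extend <= 0")
        if self.similarity_mode not in ("percent_identity", "percent_similarity"):
            raise InvalidInputError(f"unknown similarity_mode {self.similarity_mode!r}")


@dataclass(frozen=True)
class SimilarityHit:
    seed_id: str
    target_id: str
    target_species: str
    similarity: float
    length_ratio: float


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    """Substitution matrix with the X row/column zeroed (X scores 0 vs all)."""
    mat = substitution_matrices.load(name).copy()
    if "X" in mat.alphabet:
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


def _new_aligner(cfg: ScoringConfig, matrix) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


@lru_cache(maxsize=8)
def _make_aligner(cfg: ScoringConfig) -> Align.PairwiseAligner:
    return _new_aligner(cfg, _load_matrix(cfg.substitution_matrix))


# Dyadic perturbations for the traceback-free identity computation: with
# integral base scores, an epsilon bonus on the counted substitution pairs
# cannot reorder distinct base scores (eps * count < 1/2), so the perturbed
# optimum is s1 + eps * max-count over co-optimal alignments, and the count
# is recovered exactly from the score difference.  delta (<< eps) counts
# aligned columns the same way, giving the alignment length la + lb - aligned.
_EPS = 2.0**-12
_DELTA = 2.0**-24
_MAX_FAST_LEN = 2047  # eps * count stays below 1/2 up to this length


@lru_cache(maxsize=8)
def _make_scorers(cfg: ScoringConfig):
    """(base, +eps on counted pairs, +eps counted +delta all) aligners, or
    None when the scoring system is not integral (the trick needs exact
    dyadic arithmetic)."""
    base = _load_matrix(cfg.substitution_matrix)
    entries = np.asarray(base)
    if not (
        float(cfg.gap_open).is_integer()
        and float(cfg.gap_extend).is_integer()
        and np.all(entries == np.round(entries))
    ):
        return None
    counted = base.copy()
    if cfg.similarity_mode == "percent_identity":
        for aa in counted.alphabet:
            if aa != "X":
                counted[aa, aa] += _EPS
    else:  # percent_similarity: columns with a positive substitution score
        for a in counted.alphabet:
            for b in counted.alphabet:
                if base[a, b] > 0:
                    counted[a, b] += _EPS
    every = counted.copy()
    for a in every.alphabet:
        for b in every.alphabet:
            every[a, b] += _DELTA
    return (
        _new_aligner(cfg, base),
        _new_aligner(cfg, counted),
        _new_aligner(cfg, every),
    )


def global_similarity(a: ProteinRecord, b: ProteinRecord, cfg: ScoringConfig | None = None) -> float:
    """Percent similarity of the optimal global alignment of two proteins.

    Symmetric; in [0, 100].  In percent_identity mode a column counts when
    both residues are equal and neither is X; the denominator is the full
    alignment length including gap columns.  Among co-optimal alignments the
    one maximizing the counted columns (then the aligned columns) defines
    the value, which makes it independent of traceback order.
    """
    cfg = cfg or ScoringConfig()
    scorers = _make_scorers(cfg)
    s, t = sorted((a.sequence, b.sequence))
    if scorers is not None and min(len(s), len(t)) <= _MAX_FAST_LEN:
        base, counted, every = scorers
        s1 = base.score(s, t)
        s2 = counted.score(s, t)
        s3 = every.score(s, t)
        matched = round((s2 - s1) / _EPS)
        aligned = round((s3 - s2) / _DELTA)
        ncols = len(s) + len(t) - aligned
        return 100.0 * matched / ncols
    return _similarity_traceback(s, t, cfg)


def _similarity_traceback(s: str, t: str, cfg: ScoringConfig) -> float:
    """Fallback path: one optimal alignment via explicit traceback."""
    aligner = _make_aligner(cfg)
    aln = aligner.align(s, t)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ncols = len(s1)
    if cfg.similarity_mode == "percent_identity":
        matched = sum(1 for x, y in zip(s1, s2) if x == y and x != "-" and x != "X")
    else:
        mat = aligner.substitution_matrix
        matched = sum(
            1 for x, y in zip(s1, s2) if x != "-" and y != "-" and mat[x, y] > 0
        )
    return 100.0 * matched / ncols


def length_ratio(len_a: int, len_b: int) -> float:
    """Longer-to-shorter length ratio; always >= 1."""
    if len_a <= 0 or len_b <= 0:
        raise InvalidInputError("sequence lengths must be positive")
    return max(len_a, len_b) / min(len_a, len_b)


def top_hits(
    seed: ProteinRecord,
    proteomes: Proteomes,
    k_per_species: int = K_PROKARYOTE,
    max_ratio: float = DEFAULT_MAX_RATIO,
    cfg: ScoringConfig | None = None,
) -> list[SimilarityHit]:
    """The seed's top-K most similar proteins from each species.

    The length-ratio filter is a candidacy condition: proteins at ratio >=
    max_ratio never occupy a slot.  Within a species hits are ranked by
    similarity descending, ties broken by lexicographic target_id; a species
    with fewer than k qualifying proteins contributes all of them.  The seed
    never appears among its own hits.
    """
    if not proteomes or all(len(v) == 0 for v in proteomes.values()):
        raise InvalidInputError("empty proteome collection")
    if k_per_species < 1:
        raise InvalidInputError("k_per_species must be >= 1")
    cfg = cfg or ScoringConfig()
    hits: list[SimilarityHit] = []
    for species_id in sorted(proteomes):
        scored: list[SimilarityHit] = []
        for rec in proteomes[species_id]:
            if rec.protein_id == seed.protein_id:
                continue
            ratio = length_ratio(seed.length, rec.length)
            if ratio >= max_ratio:
                continue
            scored.append(
                SimilarityHit(
                    seed_id=seed.protein_id,
                    target_id=rec.protein_id,
                    target_species=species_id,
                    similarity=global_similarity(seed, rec, cfg),
                    length_ratio=ratio,
                )
            )
        scored.sort(key=lambda h: (-h.similarity, h.target_id))
        hits.extend(scored[:k_per_species])
    return hits


def all_hits(
    proteomes: Proteomes,
    k_per_species: int = K_PROKARYOTE,
    max_ratio: float = DEFAULT_MAX_RATIO,
    cfg: ScoringConfig | None = None,
) -> dict[str, list[SimilarityHit]]:
    """Top-K hit lists for every protein used as a seed.

    Equivalent to calling :func:`top_hits` per protein, but each unordered
    pair is aligned once (global_similarity is symmetric), roughly halving
    the work of an all-vs-all run.
    """
    cfg = cfg or ScoringConfig()
    records = [r for sp in sorted(proteomes) for r in proteomes[sp]]
    if not records:
        raise InvalidInputError("empty proteome collection")
    n = len(records)
    sim: dict[tuple[int, int], float] = {}
    ratios: dict[tuple[int, int], float] = {}
    lengths = [r.length for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = lengths[i], lengths[j]
            ratio = (la if la > lb else lb) / (la if la < lb else lb)
            if ratio >= max_ratio:
                continue
            ratios[(i, j)] = ratio
            sim[(i, j)] = global_similarity(records[i], records[j], cfg)

    by_species: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_species.setdefault(rec.species_id, []).append(idx)

    result: dict[str, list[SimilarityHit]] = {}
    for i, seed in enumerate(records):
        hits: list[SimilarityHit] = []
        for species_id in sorted(by_species):
            scored = []
            for j in by_species[species_id]:
                if j == i:
                    continue
                key = (i, j) if i < j else (j, i)
                if key not in sim:
                    continue
                scored.append(
                    SimilarityHit(
                        seed_id=seed.protein_id,
                        target_id=records[j].protein_id,
                        target_species=species_id,
                        similarity=sim[key],
                        length_ratio=ratios[key],
                    )
                )
            scored.sort(key=lambda h: (-h.similarity, h.target_id))
            hits.extend(scored[:k_per_species])
        result[seed.protein_id] = hits
    return result


HITS_HEADER = ["seed_id", "target_id", "target_species", "similarity", "length_ratio"]


def write_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_HEADER) + "\n")
        for h in hits:
            fh.write(
                f"{h.seed_id}\t{h.target_id}\t{h.target_species}\t"
                f"{h.similarity:.4f}\t{h.length_ratio:.6g}\n"
            )


def read_hits(path) -> dict[str, list[SimilarityHit]]:
    """Read a hits TSV back into per-seed hit lists (insertion order kept)."""
    result: dict[str, list[SimilarityHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HITS_HEADER:
            raise InvalidInputError(f"unexpected hits header {header}")
        for line in fh:
            seed_id, target_id, species, similarity, ratio = line.rstrip("\n").split("\t")
            result.setdefault(seed_id, []).append(
                SimilarityHit(seed_id, target_id, species, float(similarity), float(ratio))
            )
    return result
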