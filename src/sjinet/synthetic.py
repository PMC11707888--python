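"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's test surface:

* :func:`simulate_proteomes` — proteomes with planted ortholog families under
  a two-regime model of discontinuous sequence evolution: within a family,
  substitutions accumulate site-by-site at a low rate (continuous regime);
  a new family is founded by a jump that rewrites a large fraction of sites
  at once, so inter-family identity drops to the 20–35% "noise" band and a
  valley separates the two identity modes.  Inparalogs arise by per-species
  duplications with a little extra divergence; rare single-residue indels
  and rare terminal extensions create length variation straddling the 1.5
  length-ratio filter.
* :func:`planted_plot` — labelled Gaussian point clouds mimicking the 2D
  plot geometry (a big low-similarity noise blob plus signal clusters).
* :func:`planted_graph` — planted-partition weighted graphs for the OG
  detector (dense unit-jitter blocks, sparse weak between-block edges).

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .align import SimilarityHit
from .records import AMINO_ACIDS, InvalidInputError, ProteinRecord

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Planted-proteome generator settings (defaults = the study conditions).

    within_family_divergence is the expected per-lineage fraction of
    substituted sites; each family draws its own rate uniformly within
    ±within_family_divergence_spread of it (different families evolve under
    different selection pressures), so pairwise intra-family identity lands
    in the (1-d)^2 ≈ 60–95% range.  between_family_divergence is the mean
    fraction of sites rewritten when a family is founded from the master
    sequence, again with a per-family uniform spread; inter-family identity
    (1-d_f)(1-d_g) + small then fills a band around 10–35% rather than one
    degenerate value, which is what observed 2D plots show for the noise.
    """

    n_species: int = 10
    n_families: int = 30
    root_length_range: tuple[int, int] = (150, 450)
    within_family_divergence: float = 0.15
    within_family_divergence_spread: float = 0.05
    between_family_divergence: float = 0.6
    between_family_divergence_spread: float = 0.15
    duplication_prob: float = 0.15
    inparalog_extra_divergence: float = 0.05
    #: each species' copy of a family scales the family rate by a uniform
    #: draw from this range (lineage-to-lineage rate variation smears
    #: identities into a continuum instead of one level per family pair)
    lineage_rate_range: tuple[float, float] = (0.5, 1.5)
    indel_rate: float = 0.005
    terminal_extension_prob: float = 0.02
    terminal_extension_frac: tuple[float, float] = (0.3, 0.7)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.within_family_divergence,
            self.between_family_divergence,
            self.duplication_prob,
            self.inparalog_extra_divergence,
            self.indel_rate,
            self.terminal_extension_prob,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidInputError("all probabilities must lie in [0, 1]")
        between_lo = self.between_family_divergence - self.between_family_divergence_spread
        within_hi = self.within_family_divergence + self.within_family_divergence_spread
        if not between_lo > within_hi:
            raise InvalidInputError(
                "between_family_divergence (minus spread) must exceed "
                "within_family_divergence (plus spread): the valley premise"
            )
        lo, hi = self.root_length_range
        if not (0 < lo <= hi):
            raise InvalidInputError("invalid root_length_range")


@dataclass
class GroundTruth:
    family_of: dict[str, str] = field(default_factory=dict)
    inparalog_flags: dict[str, bool] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_AA, size=length)


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-site substitution; replacements drawn uniformly, never the
    original residue (a 'mutated' site always changes)."""
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def _jump(seq: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Rewrite an exact fraction of sites (family-founding jump mutation)."""
    out = seq.copy()
    k = int(round(frac * len(seq)))
    idx = rng.choice(len(seq), size=k, replace=False)
    for i in idx:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def _indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Single-residue insertions/deletions at a low per-site rate."""
    if rate <= 0:
        return seq
    out: list[int] = []
    for residue in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append(int(rng.choice(_AA)))  # insertion before the site
        out.append(int(residue))
    if not out:
        out = [int(rng.choice(_AA))]
    return np.array(out, dtype=np.uint8)


def simulate_proteomes(cfg: SimulationConfig) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Planted-family proteomes plus their ground truth.

    Each family's root is founded from one master sequence by a jump
    mutation and trimmed to its own root length; each species' copy then
    diverges independently (star phylogeny).  Duplications fire per species
    per family with ``duplication_prob`` and add a little extra divergence.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.root_length_range
    master = _random_seq(rng, hi)
    species_ids = [f"sp{j:02d}" for j in range(cfg.n_species)]
    proteomes: dict[str, list[ProteinRecord]] = {s: [] for s in species_ids}
    truth = GroundTruth()

    def emit(species: str, fam: str, seq: np.ndarray, pid: str, inparalog: bool) -> None:
        if rng.random() < cfg.terminal_extension_prob:
            frac = rng.uniform(*cfg.terminal_extension_frac)
            seq = np.concatenate([seq, _random_seq(rng, int(round(frac * len(seq))))])
        rec = ProteinRecord(pid, species, seq.tobytes().decode())
        proteomes[species].append(rec)
        truth.family_of[pid] = fam
        truth.inparalog_flags[pid] = inparalog

    for f in range(cfg.n_families):
        fam = f"F{f:03d}"
        length = int(rng.integers(lo, hi + 1))
        jump_frac = rng.uniform(
            cfg.between_family_divergence - cfg.between_family_divergence_spread,
            cfg.between_family_divergence + cfg.between_family_divergence_spread,
        )
        sub_rate = rng.uniform(
            max(0.0, cfg.within_family_divergence - cfg.within_family_divergence_spread),
            cfg.within_family_divergence + cfg.within_family_divergence_spread,
        )
        root = _jump(master, jump_frac, rng)[:length]
        for species in species_ids:
            rate = sub_rate * rng.uniform(*cfg.lineage_rate_range)
            seq = _indels(_substitute(root, min(rate, 1.0), rng), cfg.indel_rate, rng)
            emit(species, fam, seq, f"{fam}_{species}", inparalog=False)
            if rng.random() < cfg.duplication_prob:
                dup = _indels(
                    _substitute(seq, cfg.inparalog_extra_divergence, rng),
                    cfg.indel_rate,
                    rng,
                )
                emit(species, fam, dup, f"{fam}_{species}_dup", inparalog=True)
    return proteomes, truth


def write_simulation(
    proteomes: dict[str, list[ProteinRecord]], truth: GroundTruth, out_dir: str | os.PathLike
) -> None:
    """One FASTA per species plus truth.tsv (protein_id, family_id, inparalog)."""
    from .records import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for species, records in sorted(proteomes.items()):
        write_fasta(records, out / f"{species}.fasta")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("protein_id\tfamily_id\tinparalog\n")
        for pid in sorted(truth.family_of):
            fh.write(
                f"{pid}\t{truth.family_of[pid]}\t{int(truth.inparalog_flags[pid])}\n"
            )


@dataclass
class PlantedPlot:
    """Labelled raw-coordinate point cloud; cluster of index noise_cluster is
    the planted noise (the largest one)."""

    points: np.ndarray  # (n, 2) raw coords: x in [1, 1.5), y in [0, 100]
    labels: np.ndarray  # planted cluster index per point
    noise_cluster: int

    @property
    def planted_signal(self) -> np.ndarray:
        return self.labels != self.noise_cluster

    def as_hits(self, seed_id: str = "seed") -> list[SimilarityHit]:
        return [
            SimilarityHit(seed_id, f"t{i:05d}", "spX", float(y), float(x))
            for i, (x, y) in enumerate(self.points)
        ]


def planted_plot(
    sizes: list[int],
    centers: list[tuple[float, float]],
    spreads: list[tuple[float, float]],
    seed: int = 0,
) -> PlantedPlot:
    """Gaussian clusters on the (length ratio, similarity) plane.

    The largest cluster (ties: lowest center y) is the planted noise.
    Sampled coordinates are clipped to the valid plot ranges; overlapping
    clusters are allowed — hard cases are legitimate inputs.
    """
    if not (len(sizes) == len(centers) == len(spreads)):
        raise InvalidInputError("sizes, centers, spreads must have equal length")
    for cx, cy in centers:
        if not (1.0 <= cx < 1.5 and 0.0 <= cy <= 100.0):
            raise InvalidInputError(f"center ({cx}, {cy}) outside the plot domain")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for c, (n, (cx, cy), (sx, sy)) in enumerate(zip(sizes, centers, spreads)):
        xy = rng.normal(loc=(cx, cy), scale=(sx, sy), size=(n, 2))
        xy[:, 0] = np.clip(xy[:, 0], 1.0, np.nextafter(1.5, 1.0))
        xy[:, 1] = np.clip(xy[:, 1], 0.0, 100.0)
        pts.append(xy)
        labels.append(np.full(n, c))
    points = np.concatenate(pts)
    labels = np.concatenate(labels)
    noise = min(range(len(sizes)), key=lambda c: (-sizes[c], centers[c][1], c))
    return PlantedPlot(points, labels, noise)


def planted_graph(
    block_sizes: list[int],
    p_in_weight: float,
    p_out_weight: float,
    seed: int = 0,
    between_prob: float = 0.05,
    jitter: float = 0.02,
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition weighted graph.

    Within-block pairs are fully connected at weight ``p_in_weight`` (uniform
    jitter ± ``jitter``, clipped to (0, 1]); between-block pairs get an edge
    with probability ``between_prob`` at weight ``p_out_weight`` (same
    jitter).  Returns the graph and the node -> planted block map.
    """
    if not (0 <= p_in_weight <= 1 and 0 <= p_out_weight <= 1):
        raise InvalidInputError("weights must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    membership: dict[str, int] = {}
    nodes: list[str] = []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            name = f"b{b:02d}n{i:03d}"
            nodes.append(name)
            membership[name] = b
            graph.add_node(name)

    def w(base: float) -> float:
        return float(np.clip(base + rng.uniform(-jitter, jitter), 1e-9, 1.0))

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            if membership[u] == membership[v]:
                if p_in_weight > 0:
                    graph.add_edge(u, v, weight=w(p_in_weight))
            elif p_out_weight > 0 and rng.random() < between_prob:
                graph.add_edge(u, v, weight=w(p_out_weight))
    return graph, membership
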