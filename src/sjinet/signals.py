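"""Per-seed 2D similarity plots and unsupervised signal detection.

For each seed protein the retained hits form a point cloud with x = length
ratio (in [1, 1.5)) and y = global similarity percent.  Ortholog candidates
("signals") sit as one or more dense clusters high on the plot, while distant
homologs pile up in a large low-similarity cluster ("noise").  Spectral
clustering on the z-scored cloud separates the two without any similarity
threshold: the affinity graph uses a Gaussian kernel on Euclidean distances,
the number of clusters is chosen by the eigengap of the random-walk
normalized Laplacian, and k-means on the leading eigenvectors assigns points
to clusters.  The largest cluster is noise; small clusters shifted to the
right of it (excessive length difference) and not above it join the noise.

Signal quality is audited with the noise convex hull: signal points inside or
on the hull are counted as false positives and PPV = TP / (TP + FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .align import SimilarityHit
from .records import InvalidInputError


@dataclass
class SpectralConfig:
    """Knobs of the per-plot spectral clustering step.

    min_points: below this the plot is degenerate and everything is noise.
    k_min/k_max: eigengap search range for the cluster count.
    n_init: k-means restarts (best inertia kept).
    random_state: k-means RNG seed (the rest of the step is deterministic).
    """

    min_points: int = 10
    k_min: int = 1
    k_max: int = 8
    n_init: int = 10
    random_state: int = 17
    #: clusters closer than this to the noise set (min point-pair distance in
    #: per-dimension bandwidth units) are absorbed into the noise: only
    #: clusters noticeably separated from the noise count as signal.
    separation: float = 3.0
    #: absolute floor on that separation, in normalized-coordinate units
    #: (the per-axis sd is 1 after z-scoring): the valley must be visible at
    #: the scale of the whole plot, even when degenerate point clouds drive
    #: the kernel bandwidths toward zero.
    min_gap: float = 0.5


@dataclass
class PlotPoint:
    target_id: str
    x: float
    y: float
    x_norm: float = float("nan")
    y_norm: float = float("nan")
    cluster_label: int = -1
    is_signal: bool | None = None


@dataclass
class SpectralState:
    n: int
    eigenvalues: np.ndarray
    k: int
    labels: np.ndarray

    @property
    def clusters(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == c) for c in range(self.k)]


@dataclass
class SeedPlot:
    seed_id: str
    points: list[PlotPoint] = field(default_factory=list)
    spectral: SpectralState | None = None

    @property
    def signal_ids(self) -> set[str]:
        return {p.target_id for p in self.points if p.is_signal}

    @property
    def noise_ids(self) -> set[str]:
        return {p.target_id for p in self.points if p.is_signal is False}

    def coords(self, normalized: bool = True) -> np.ndarray:
        if normalized:
            return np.array([[p.x_norm, p.y_norm] for p in self.points], dtype=float)
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass
class NoiseHull:
    vertices: np.ndarray  # (m, 2) ordered hull vertices; m may be 1 or 2 when degenerate

    @property
    def degenerate(self) -> bool:
        return len(self.vertices) < 3


@dataclass
class PPVReport:
    tp: int
    fp: int

    @property
    def ppv(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None


def build_plot(seed_id: str, hits: list[SimilarityHit]) -> SeedPlot:
    """One PlotPoint per hit: x = length ratio, y = similarity percent."""
    if any(h.seed_id != seed_id for h in hits):
        raise InvalidInputError("hits do not all share the given seed_id")
    return SeedPlot(seed_id, [PlotPoint(h.target_id, h.length_ratio, h.similarity) for h in hits])


def normalize_plot(plot: SeedPlot) -> SeedPlot:
    """Z-score each dimension in place (population sd); zero-variance axes map to 0."""
    if not plot.points:
        raise InvalidInputError("cannot normalize an empty plot")
    xy = plot.coords(normalized=False)
    mean = xy.mean(axis=0)
    sd = xy.std(axis=0)
    sd[sd == 0] = 1.0  # centred zero-variance axis stays 0
    norm = (xy - mean) / sd
    for p, (xn, yn) in zip(plot.points, norm):
        p.x_norm, p.y_norm = float(xn), float(yn)
    return plot


def _affinity(coords: np.ndarray) -> np.ndarray:
    """Dense Gaussian product kernel with one bandwidth per dimension.

    sigma_d is the median absolute pairwise difference along dimension d, so
    the scale of each axis is set by the dense majority of points (the noise
    band), not by how far the signal cluster sits from it; a single isotropic
    sigma would let the elongated noise cloud drown the signal/noise valley.
    A zero-variance dimension is ignored.  A tiny affinity floor keeps the
    graph connected so degrees never vanish.
    """
    expo = np.zeros((len(coords), len(coords)))
    for d, sigma in enumerate(_bandwidths(coords)):
        if sigma > 0:
            diff = coords[:, None, d] - coords[None, :, d]
            expo += diff**2 / (2.0 * sigma**2)
    A = np.exp(-expo) + 1e-12
    np.fill_diagonal(A, 0.0)
    return A


def _bandwidths(coords: np.ndarray) -> np.ndarray:
    """Per-dimension kernel bandwidth: min(median, 2 * lower quartile) of the
    absolute pairwise differences along that dimension (0 for a flat one).

    For a unimodal cloud 2*q25 ~ 0.94*median, so this is just the median
    scale; but when two clusters of comparable mass make the difference
    distribution bimodal, the median jumps to the between-cluster scale
    while the lower quartile stays within-cluster — taking the min keeps the
    bandwidth on the within-cluster scale in both regimes.  Quantiles are
    taken over positive differences only: exactly-coincident points carry
    no scale information and would otherwise zero the bandwidth of an
    informative axis."""
    iu = np.triu_indices(len(coords), k=1)
    out = []
    for d in range(coords.shape[1]):
        a = np.abs((coords[:, None, d] - coords[None, :, d])[iu])
        a = a[a > 0]
        if a.size == 0:
            out.append(0.0)
            continue
        out.append(float(min(np.quantile(a, 0.5), 2.0 * np.quantile(a, 0.25))))
    return np.array(out)


def spectral_cluster(plot: SeedPlot, cfg: SpectralConfig | None = None) -> SpectralState:
    """Cluster the normalized plot; the eigengap picks the cluster count.

    Solves the generalized problem L u = lambda Deg u with L = Deg - A, whose
    eigenpairs are those of the random-walk Laplacian I - Deg^-1 A.  k is the
    j in [k_min, k_max] maximizing lambda_{j+1} - lambda_j (ascending
    eigenvalues, 1-based); k-means then runs on the rows of the n x k
    eigenvector matrix U.
    """
    cfg = cfg or SpectralConfig()
    n = len(plot.points)
    if n < cfg.min_points:
        raise InvalidInputError(
            f"plot has {n} < min_points={cfg.min_points} points; treat as all noise"
        )
    coords = plot.coords(normalized=True)
    if not np.all(np.isfinite(coords)):
        raise InvalidInputError("plot must be normalized before clustering")
    A = _affinity(coords)
    deg = A.sum(axis=1)
    L = np.diag(deg) - A
    kmax = min(cfg.k_max, n - 1)
    eigenvalues, vecs = eigh(L, np.diag(deg))
    gaps = np.diff(eigenvalues[: kmax + 1])
    k = int(np.argmax(gaps[cfg.k_min - 1 :])) + cfg.k_min
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        U = vecs[:, :k]
        km = KMeans(n_clusters=k, n_init=cfg.n_init, random_state=cfg.random_state)
        labels = km.fit_predict(U)
    state = SpectralState(n=n, eigenvalues=eigenvalues, k=k, labels=labels)
    for p, lab in zip(plot.points, labels):
        p.cluster_label = int(lab)
    plot.spectral = state
    return state


def label_noise_signal(
    state: SpectralState, plot: SeedPlot, separation: float = 3.0, min_gap: float = 0.5
) -> SeedPlot:
    """Assign signal/noise per cluster.

    Noise starts as the largest cluster (ties: lower centroid y, then lower
    index).  A remaining cluster joins the noise when it is not noticeably
    separated from the current noise region: its centroid fails to rise at
    least ``min_gap`` normalized units above the noise set's top (satellites
    split off by length difference — on either side — share the noise's low
    similarity), or its minimum point-pair distance to the noise set falls
    below ``separation`` in per-dimension bandwidth units or ``min_gap`` in
    plain normalized units (degenerate point clouds drive the bandwidths
    toward zero).  Absorption iterates to a fixpoint; what remains is
    signal.
    """
    coords = plot.coords(normalized=True)
    clusters = state.clusters
    sizes = np.array([len(c) for c in clusters])
    cys = np.array([coords[c, 1].mean() for c in clusters])
    order = sorted(range(state.k), key=lambda c: (-sizes[c], cys[c], c))
    noise_clusters = {order[0]}

    sigmas = _bandwidths(coords)
    scale = np.where(sigmas > 0, sigmas, 1.0)
    scaled = coords / scale
    changed = True
    while changed:
        changed = False
        noise_idx = np.concatenate([clusters[c] for c in sorted(noise_clusters)])
        noise_top_y = coords[noise_idx, 1].max()
        for c in range(state.k):
            if c in noise_clusters:
                continue
            diff = scaled[clusters[c]][:, None, :] - scaled[noise_idx][None, :, :]
            d_bw = float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).min()))
            raw = coords[clusters[c]][:, None, :] - coords[noise_idx][None, :, :]
            d_norm = float(np.sqrt(np.einsum("ijk,ijk->ij", raw, raw).min()))
            if (
                cys[c] <= noise_top_y + min_gap
                or d_bw < separation
                or d_norm < min_gap
            ):
                noise_clusters.add(c)
                changed = True
    for p in plot.points:
        p.is_signal = p.cluster_label not in noise_clusters
    return plot


def detect_signals(
    seed_id: str, hits: list[SimilarityHit], cfg: SpectralConfig | None = None
) -> SeedPlot:
    """Full per-seed pass: plot, normalize, cluster, label.

    Degenerate plots (< min_points, including empty) come back with every
    point labelled noise and an empty signal set.
    """
    cfg = cfg or SpectralConfig()
    plot = build_plot(seed_id, hits)
    if len(plot.points) < cfg.min_points:
        for p in plot.points:
            p.is_signal = False
        return plot
    normalize_plot(plot)
    state = spectral_cluster(plot, cfg)
    return label_noise_signal(
        state, plot, separation=cfg.separation, min_gap=cfg.min_gap
    )


def noise_hull(plot: SeedPlot) -> NoiseHull:
    """Convex hull of the noise points in normalized coordinates (qhull).

    Fewer than 3 distinct or non-collinear points give a degenerate
    segment/point hull.
    """
    pts = np.array(
        [[p.x_norm, p.y_norm] for p in plot.points if p.is_signal is False], dtype=float
    )
    if len(pts) == 0:
        raise InvalidInputError("no noise points; cannot build a noise hull")
    uniq = np.unique(pts, axis=0)
    if len(uniq) >= 3:
        try:
            hull = ConvexHull(uniq)
            return NoiseHull(uniq[hull.vertices])
        except QhullError:
            pass  # collinear: fall through to the degenerate segment
    if len(uniq) == 1:
        return NoiseHull(uniq)
    # collinear (or exactly two) points: keep the two extremes
    d = uniq - uniq[0]
    t = d @ d.sum(axis=0)
    return NoiseHull(np.array([uniq[np.argmin(t)], uniq[np.argmax(t)]]))


def _inside_hull(points: np.ndarray, hull: NoiseHull, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask: inside or on the hull (boundary counts as inside)."""
    v = hull.vertices
    if len(v) == 1:
        return np.linalg.norm(points - v[0], axis=1) <= tol
    if len(v) == 2:
        a, b = v
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        return np.linalg.norm(points - proj, axis=1) <= tol
    qh = ConvexHull(v)
    # qhull half-space form: A x + b <= 0 inside
    ineq = qh.equations  # (m, 3)
    vals = points @ ineq[:, :2].T + ineq[:, 2]
    return np.all(vals <= tol, axis=1)


def signal_ppv(plot: SeedPlot, hull: NoiseHull) -> PPVReport:
    """PPV of the signal set against the noise hull.

    FP = signal points inside or on the hull; TP = the rest.  An empty signal
    set has no defined PPV and raises.
    """
    sig = np.array(
        [[p.x_norm, p.y_norm] for p in plot.points if p.is_signal], dtype=float
    )
    if len(sig) == 0:
        raise InvalidInputError("empty signal set: PPV undefined")
    inside = _inside_hull(sig, hull)
    fp = int(inside.sum())
    return PPVReport(tp=len(sig) - fp, fp=fp)
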