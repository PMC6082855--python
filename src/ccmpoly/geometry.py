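"""Distance-space analyses: R_ij maps, R(s), Ward linkage matrices, shapes, droplets.

The mean spatial distance matrix R_ij = <|r_i - r_j|> (time and/or ensemble
averaged) is the bridge between contact statistics and real-space structure:
Ward agglomeration of R yields a cophenetic ("Ward linkage") matrix whose
entries are ultrametric merge heights; comparing such matrices between
single trajectories quantifies cell-to-cell structural heterogeneity, and
the power-law link 1/C_ij ~ R_ij^lambda connects contact frequency to mean
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .contacts import fit_power_law
from .core import LoopSet
from .trajectory import Trajectory

__all__ = [
    "mean_distance_map",
    "r_of_s",
    "ward_linkage_matrix",
    "hic_to_distance",
    "contact_distance_exponent",
    "wlm_similarity",
    "wlm_similarity_population",
    "gyration_shape",
    "tad_shape_stats",
    "detect_droplets",
    "droplet_growth",
    "coalescence_window",
    "radius_of_gyration",
]


def mean_distance_map(
    trajectories: Sequence[Trajectory] | Trajectory,
    mode: str = "single_cell",
) -> np.ndarray:
    """Mean pairwise distance matrix R_ij.

    mode 'single_cell' averages over the frames of one trajectory (a single
    cell followed in time); 'ensemble' additionally averages over
    trajectories (cells).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if mode == "single_cell" and len(trajectories) != 1:
        raise ValueError("single_cell mode takes exactly one trajectory")
    if mode not in ("single_cell", "ensemble"):
        raise ValueError("mode must be 'single_cell' or 'ensemble'")
    n = trajectories[0].n_beads
    acc = np.zeros((n, n))
    total = 0
    for traj in trajectories:
        for frame in traj.frames:
            acc += squareform(pdist(frame))
            total += 1
    return acc / total


def r_of_s(
    trajectories: Sequence[Trajectory] | Trajectory,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R(s) and its coefficient of variation deltaR(s).

    R(s) is the root of the mean squared distance over all pairs at genomic
    separation s, frames, and trajectories.  deltaR(s) is the coefficient of
    variation of the scalar distance population at each s:
    sqrt(<R_s^2> - <R_s>^2) / <R_s>.  Returns (s, R, deltaR).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    n = trajectories[0].n_beads
    sum_r = np.zeros(n - 1)
    sum_r2 = np.zeros(n - 1)
    count = np.zeros(n - 1)
    for traj in trajectories:
        for frame in traj.frames:
            d = squareform(pdist(frame))
            for s in range(1, n):
                diag = np.diagonal(d, offset=s)
                sum_r[s - 1] += diag.sum()
                sum_r2[s - 1] += (diag**2).sum()
                count[s - 1] += diag.size
    mean_r = sum_r / count
    mean_r2 = sum_r2 / count
    r_curve = np.sqrt(mean_r2)
    var = np.maximum(mean_r2 - mean_r**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(mean_r > 0, np.sqrt(var) / mean_r, 0.0)
    return np.arange(1, n), r_curve, delta


def ward_linkage_matrix(distance_matrix: np.ndarray) -> np.ndarray:
    """Cophenetic matrix from Ward agglomeration of a distance matrix.

    Entry (i, j) is the merge height of the lowest cluster containing both i
    and j; the result is ultrametric by construction.  Ward's variance
    interpretation assumes Euclidean input — applying it directly to a mean
    spatial-distance matrix is a deliberate modelling choice here, and the
    cophenetic output remains a well-defined ultrametric summary.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, 0.0):
        return np.zeros((n, n))
    z = linkage(condensed, method="ward")
    return squareform(cophenet(z))


def hic_to_distance(
    p_matrix: np.ndarray,
    exponent: float = 4.1,
    floor: Optional[float] = None,
) -> np.ndarray:
    """Convert a contact-probability matrix to relative distances: R ~ P^(-1/exponent).

    The prefactor is unit (downstream Ward + Pearson comparisons are
    invariant under monotone rescaling).  Zero entries are floored at
    ``floor`` (default: smallest positive entry) with a warning.
    """
    p = np.asarray(p_matrix, dtype=float).copy()
    if np.any(p < 0):
        raise ValueError("contact probabilities must be non-negative")
    zero = p <= 0
    if zero.any():
        if floor is None:
            pos = p[p > 0]
            if pos.size == 0:
                raise ValueError("matrix has no positive entries")
            floor = float(pos.min())
        warnings.warn(f"{int(zero.sum())} zero entries floored at {floor:g}")
        p[zero] = floor
    r = p ** (-1.0 / exponent)
    np.fill_diagonal(r, 0.0)
    return r


def contact_distance_exponent(
    counts: np.ndarray,
    r_matrix: np.ndarray,
    fit_range: Optional[tuple[float, float]] = None,
    n_bins: int = 30,
    min_sep: int = 2,
) -> tuple[float, float]:
    """Exponent lambda in 1/C_ij ~ R_ij^lambda from the 2-D histogram ridge.

    Pairs are binned by log R; within each bin the ridge is the mean of
    log(1/C) (limits the heteroscedasticity of the raw pair scatter).  A
    straight-line fit of the ridge returns (lambda, stderr).  Pairs closer
    than ``min_sep`` along the chain and pairs with zero contacts are
    excluded.
    """
    c = np.asarray(counts, dtype=float)
    r = np.asarray(r_matrix, dtype=float)
    n = c.shape[0]
    iu = np.triu_indices(n, k=min_sep)
    cv, rv = c[iu], r[iu]
    m = (cv > 0) & (rv > 0)
    cv, rv = cv[m], rv[m]
    if fit_range is not None:
        m2 = (rv >= fit_range[0]) & (rv <= fit_range[1])
        cv, rv = cv[m2], rv[m2]
    if len(rv) < n_bins:
        raise ValueError("too few positive pairs for a ridge fit")
    lr = np.log(rv)
    linv = np.log(1.0 / cv)
    edges = np.linspace(lr.min(), lr.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(lr, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 5:
            xs.append(np.mean(lr[sel]))  # bin-mean abscissa: exact on planted laws
            ys.append(np.mean(linv[sel]))
    xs, ys = np.exp(xs), np.exp(ys)
    return fit_power_law(xs, ys)


def wlm_similarity(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """Pearson correlation between two Ward linkage matrices (upper triangles)."""
    a = np.asarray(w_a, dtype=float)
    b = np.asarray(w_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(a.shape[0], k=1)
    av, bv = a[iu], b[iu]
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("degenerate (constant) linkage matrix")
    return float(np.corrcoef(av, bv)[0, 1])


def wlm_similarity_population(
    wlms: Sequence[np.ndarray],
) -> tuple[np.ndarray, float]:
    """All unordered pairwise Pearson correlations of single-cell WLMs.

    Returns (rho values, mean rho-bar).  A small mean signals strong
    cell-to-cell structural heterogeneity.
    """
    rhos = []
    for i in range(len(wlms)):
        for j in range(i + 1, len(wlms)):
            rhos.append(wlm_similarity(wlms[i], wlms[j]))
    rhos = np.array(rhos)
    return rhos, float(rhos.mean())


def gyration_shape(points: np.ndarray) -> tuple[float, float, float]:
    """Gyration-tensor descriptors: (Rg, kappa^2, S).

    With ordered eigenvalues l1 >= l2 >= l3 of the gyration tensor:
    Rg^2 = l1+l2+l3; relative shape anisotropy
    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1+l2+l3)^2 (0 isotropic, 1
    rod); shape parameter S = 27 (l1-m)(l2-m)(l3-m) / (l1+l2+l3)^3 with m
    the eigenvalue mean (prolate S > 0, oblate S < 0, S in [-1/4, 2]).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    c = pts - pts.mean(axis=0)
    gyr = c.T @ c / len(pts)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    tr = lam.sum()
    rg = float(np.sqrt(tr))
    if tr <= 0:
        return 0.0, 0.0, 0.0
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
    mbar = tr / 3.0
    s_par = 27.0 * np.prod(lam - mbar) / tr**3
    return rg, float(kappa2), float(s_par)


@dataclass
class TadShapeStats:
    """Per-TAD normalized distributions of time-averaged shape descriptors."""

    spans: list[tuple[int, int]]
    rg2_norm: np.ndarray     # (n_tads, n_traj): <Rg^2> / mean over trajectories
    kappa_norm: np.ndarray
    s_norm: np.ndarray


def tad_shape_stats(
    trajectories: Sequence[Trajectory], loops: LoopSet
) -> TadShapeStats:
    """Shape heterogeneity of TADs (bead spans between loop anchors).

    For each TAD and trajectory, the time-averaged Rg^2, kappa and S are
    normalized by their cross-trajectory means, giving per-TAD
    distributions whose width measures cell-to-cell variability.
    """
    spans = [(int(i), int(j)) for i, j in loops.anchors]
    if not spans:
        raise ValueError("empty loop set: no TADs to analyze")
    nt = len(trajectories)
    rg2 = np.zeros((len(spans), nt))
    kap = np.zeros((len(spans), nt))
    spar = np.zeros((len(spans), nt))
    for t, traj in enumerate(trajectories):
        for m, (i, j) in enumerate(spans):
            vals = [gyration_shape(frame[i : j + 1]) for frame in traj.frames]
            rgs, ks, ss = zip(*vals)
            rg2[m, t] = np.mean(np.square(rgs))
            kap[m, t] = np.mean(np.sqrt(np.maximum(ks, 0.0)))
            spar[m, t] = np.mean(ss)

    def norm(x):
        mean = x.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean != 0, x / mean, 0.0)

    return TadShapeStats(
        spans=spans, rg2_norm=norm(rg2), kappa_norm=norm(kap), s_norm=norm(spar)
    )


def detect_droplets(
    conformation: np.ndarray,
    linkage_radius: float = 2.0,
    min_size: int = 10,
) -> list[np.ndarray]:
    """Chromosome droplets: connected components of the spatial proximity graph.

    Edges join bead pairs with |r_i - r_j| < linkage_radius and |i - j| > 1
    (chain neighbors alone do not define a droplet).  Components smaller
    than ``min_size`` beads are discarded.  Returns bead-index arrays.
    """
    pos = np.asarray(conformation, dtype=float)
    n = pos.shape[0]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(linkage_radius, output_type="ndarray")
    if len(pairs):
        keep = np.abs(pairs[:, 0] - pairs[:, 1]) > 1
        pairs = pairs[keep]
    if len(pairs) == 0:
        return []
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        if len(members) >= min_size:
            clusters.append(members)
    return clusters


@dataclass
class DropletTrace:
    """Mean droplet size n(t) (base pairs) through a collapse trajectory."""

    times: np.ndarray
    n_bp: np.ndarray          # NaN where no droplet exceeded min_size
    n_droplets: np.ndarray = None
    exponent: Optional[float] = None
    exponent_stderr: Optional[float] = None


def coalescence_window(
    trace: "DropletTrace", total_bp: float
) -> tuple[float, float]:
    """Intermediate coalescence window of a collapse.

    Starts at the earliest frame where the droplet count reaches its
    maximum (formation complete, merging takes over) and ends when the mean
    droplet holds 80% of the chain (single-globule saturation) or the run
    ends.  Standard coarsening-analysis choice.
    """
    valid = np.isfinite(trace.n_bp)
    if valid.sum() < 4:
        raise ValueError("too few frames with droplets")
    tv = trace.times[valid]
    nv = trace.n_bp[valid]
    counts = trace.n_droplets[valid]
    t_lo = float(tv[int(np.argmax(counts))])  # argmax: earliest maximum
    cross = tv[nv >= 0.8 * total_bp]
    t_hi = float(cross[0]) if len(cross) else float(tv[-1])
    if t_hi <= t_lo:
        t_hi = float(tv[-1])
    return t_lo, t_hi


def droplet_growth(
    trajectory: Trajectory,
    bead_bp: int = 1200,
    linkage_radius: float = 2.0,
    min_size: int = 10,
    fit_window: Optional[tuple[float, float]] = None,
) -> DropletTrace:
    """Droplet coarsening curve n(t) and, optionally, its growth exponent.

    n(t) is the mean bead count per droplet times ``bead_bp``.  If
    ``fit_window`` (t_lo, t_hi) is given, the log-log slope over that window
    is fitted (coalescence-stage growth is ~ t^1, the Lifshitz-Slyozov
    signature).
    """
    nbp = np.full(trajectory.n_frames, np.nan)
    ndrop = np.zeros(trajectory.n_frames)
    for f, frame in enumerate(trajectory.frames):
        clusters = detect_droplets(frame, linkage_radius, min_size)
        ndrop[f] = len(clusters)
        if clusters:
            nbp[f] = np.mean([len(c) for c in clusters]) * bead_bp
    trace = DropletTrace(times=trajectory.times.copy(), n_bp=nbp,
                         n_droplets=ndrop)
    if fit_window is not None:
        m = (
            (trace.times >= fit_window[0])
            & (trace.times <= fit_window[1])
            & np.isfinite(nbp)
        )
        if m.sum() >= 3:
            expo, err = fit_power_law(trace.times[m], nbp[m])
            trace.exponent, trace.exponent_stderr = expo, err
    return trace


def radius_of_gyration(trajectory: Trajectory) -> np.ndarray:
    """Whole-chain Rg per frame."""
    c = trajectory.frames - trajectory.frames.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum(c**2, axis=2), axis=1))
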