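"""Contact-map construction and contact-space analyses.

Covers: contact maps from trajectories (r_c = 2 sigma), the contact
probability curve P(s) and its two-regime crossover s*, subchain contact
counts A(s), Spearman correlation maps, spectral co-clustering compartments
scored by adjusted mutual information, directionality-index TAD calling,
radial distribution functions g_AA/g_BB/g_AB and normalized radial density
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import CCMParameters, EpigenomeAnnotation
from .trajectory import Trajectory

__all__ = [
    "ContactStats",
    "CompartmentResult",
    "contact_map",
    "contact_probability",
    "log_binned_ps",
    "fit_power_law",
    "crossover_scale",
    "subchain_contacts",
    "spearman_map",
    "compartments_cocluster",
    "ami",
    "directionality_index",
    "call_tads",
    "radial_distribution",
    "radial_density_profile",
]


@dataclass
class ContactStats:
    """Contact counts C_ij, probabilities P_ij = C_ij / n_frames, and metadata."""

    counts: np.ndarray
    n_frames: int
    params: Optional[CCMParameters] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def probability(self) -> np.ndarray:
        return self.counts / self.n_frames

    @property
    def n_beads(self) -> int:
        return self.counts.shape[0]


@dataclass
class CompartmentResult:
    """Two-way compartment call plus the Spearman map it came from."""

    labels: np.ndarray
    spearman: np.ndarray
    degenerate: bool = False
    ami_vs_reference: Optional[float] = None


def contact_map(trajectory: Trajectory, params: CCMParameters) -> ContactStats:
    """Count (frame, pair) contact events: |r_i - r_j| < r_c, i < j, |i-j| >= 1.

    Matches an O(N^2 * frames) brute force exactly; the diagonal is zero.
    """
    if trajectory.n_frames < 1:
        raise ValueError("empty trajectory")
    n = trajectory.n_beads
    rc = params.r_contact
    counts = np.zeros((n, n))
    for frame in trajectory.frames:
        d = squareform(pdist(frame))
        counts += (d < rc)
    np.fill_diagonal(counts, 0.0)
    return ContactStats(counts=counts, n_frames=trajectory.n_frames, params=params)


def contact_probability(stats: ContactStats) -> tuple[np.ndarray, np.ndarray]:
    """P(s): mean contact probability over all pairs at genomic separation s (beads).

    Returns (s, P(s)) for s = 1 .. N-1.
    """
    p = stats.probability
    n = stats.n_beads
    s = np.arange(1, n)
    ps = np.array([np.mean(np.diagonal(p, offset=k)) for k in s])
    return s, ps


def log_binned_ps(
    s: np.ndarray, ps: np.ndarray, bins_per_decade: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean binning of a P(s) curve, 20 bins per decade by default."""
    s = np.asarray(s, dtype=float)
    ps = np.asarray(ps, dtype=float)
    lo, hi = np.log10(s.min()), np.log10(s.max())
    edges = np.logspace(lo, hi, max(2, int((hi - lo) * bins_per_decade) + 1))
    idx = np.clip(np.digitize(s, edges) - 1, 0, len(edges) - 2)
    sb, pb = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            sb.append(np.exp(np.mean(np.log(s[m]))))
            pb.append(np.mean(ps[m]))
    return np.array(sb), np.array(pb)


def fit_power_law(
    x: np.ndarray,
    y: np.ndarray,
    fit_range: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Least-squares slope in log-log space: y ~ x^exponent.

    Returns (exponent, stderr); exact on noiseless planted power laws.
    Zero or negative y values inside the range are excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x > 0) & (y > 0)
    if fit_range is not None:
        mask &= (x >= fit_range[0]) & (x <= fit_range[1])
    if mask.sum() < 2:
        raise ValueError("need at least 2 positive points in the fit range")
    lx, ly = np.log(x[mask]), np.log(y[mask])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    slope = coef[0]
    dof = len(lx) - 2
    if dof > 0 and len(res):
        sxx = np.sum((lx - lx.mean()) ** 2)
        stderr = float(np.sqrt(res[0] / dof / sxx))
    else:
        stderr = 0.0
    return float(slope), stderr


@dataclass
class CrossoverFit:
    """Two-segment log-log fit of P(s): slopes and the breakpoint s*."""

    s_star: float          # beads
    s_star_bp: Optional[float]
    slope_small: float
    slope_large: float
    no_crossover: bool


def crossover_scale(
    s: np.ndarray,
    ps: np.ndarray,
    params: Optional[CCMParameters] = None,
    min_points: int = 4,
) -> CrossoverFit:
    """Breakpoint of a two-segment log-log fit minimizing total squared error.

    Each candidate breakpoint splits the curve into two independently fitted
    segments of at least ``min_points`` points.  If the best break lands on
    a range boundary or the slopes agree closely, the fit is flagged
    ``no_crossover``.
    """
    x = np.asarray(s, dtype=float)
    y = np.asarray(ps, dtype=float)
    m = (x > 0) & (y > 0)
    x, y = x[m], y[m]
    if len(x) < 2 * min_points:
        raise ValueError("curve too short for a two-segment fit")
    lx, ly = np.log(x), np.log(y)

    def sse(i0, i1):
        xs, ys = lx[i0:i1], ly[i0:i1]
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, res, *_ = np.linalg.lstsq(A, ys, rcond=None)
        return (res[0] if len(res) else 0.0), coef[0]

    best = None
    for k in range(min_points, len(x) - min_points + 1):
        e1, s1 = sse(0, k)
        e2, s2 = sse(k, len(x))
        tot = e1 + e2
        if best is None or tot < best[0]:
            best = (tot, k, s1, s2)
    _, k, s1, s2 = best
    s_star = float(np.exp(0.5 * (lx[k - 1] + lx[k])))
    boundary = k == min_points or k == len(x) - min_points
    no_cross = boundary or abs(s1 - s2) < 0.05
    bp = s_star * params.bead_bp if params is not None else None
    return CrossoverFit(
        s_star=s_star, s_star_bp=bp, slope_small=float(s1),
        slope_large=float(s2), no_crossover=bool(no_cross),
    )


def subchain_contacts(stats: ContactStats, s_values: Sequence[int]) -> np.ndarray:
    """A(s): mean contacts between an s-sized window and the rest of the chain.

    For every window [k, k+s) the contacts to the complement are summed; the
    average over windows is returned for each s.  A compact structure gives
    A(s) ~ s^(2/3); an ideal chain gives A(s) ~ s.
    """
    c = stats.counts
    n = stats.n_beads
    out = np.empty(len(s_values))
    row_tot = c.sum(axis=1)
    # prefix sums for O(1) window-block sums
    csum2 = np.zeros((n + 1, n + 1))
    csum2[1:, 1:] = np.cumsum(np.cumsum(c, axis=0), axis=1)

    def block(a, b, c0, d0):  # sum of c[a:b, c0:d0]
        return csum2[b, d0] - csum2[a, d0] - csum2[b, c0] + csum2[a, c0]

    for m, s in enumerate(s_values):
        if not 1 <= s < n:
            raise ValueError("need 1 <= s < n_beads")
        vals = []
        for k in range(n - s + 1):
            tot = row_tot[k : k + s].sum()
            internal = block(k, k + s, k, k + s)
            vals.append(tot - internal)
        out[m] = np.mean(vals)
    return out


def spearman_map(
    matrix: np.ndarray, exclude_band: int = 1
) -> np.ndarray:
    """Row-wise Spearman correlation map of a contact matrix.

    Entries within ``exclude_band`` of the diagonal are masked before
    ranking (near-diagonal contacts are close to deterministic and swamp
    the rank correlation); correlations use pairwise-complete columns.
    The result is symmetric with unit diagonal.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("matrix must be square")
    work = m.copy()
    for k in range(-exclude_band, exclude_band + 1):
        idx = np.arange(max(0, -k), min(n, n - k))
        work[idx, idx + k] = np.nan

    # rank each row over its valid entries
    ranks = np.full_like(work, np.nan)
    valid = ~np.isnan(work)
    for i in range(n):
        v = work[i, valid[i]]
        r = np.empty_like(v)
        order = np.argsort(v, kind="mergesort")
        r[order] = np.arange(len(v), dtype=float)
        # average ties
        sv = v[order]
        ties = np.concatenate([[True], sv[1:] != sv[:-1]])
        grp = np.cumsum(ties) - 1
        sums = np.bincount(grp, weights=np.arange(len(v), dtype=float))
        cnts = np.bincount(grp)
        r[order] = (sums / cnts)[grp]
        ranks[i, valid[i]] = r

    # pairwise-complete Pearson of rank rows via masked matrix products
    Z = np.nan_to_num(ranks)
    W = valid.astype(float)
    nij = W @ W.T
    sx = Z @ W.T
    sy = W @ Z.T
    sxy = Z @ Z.T
    sxx = (Z * Z) @ W.T
    syy = W @ (Z * Z).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / nij
        vx = sxx - sx**2 / nij
        vy = syy - sy**2 / nij
        rho = cov / np.sqrt(vx * vy)
    rho[~np.isfinite(rho)] = 0.0
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def compartments_cocluster(
    spearman: np.ndarray,
    n_clusters: int = 2,
    seed: int = 0,
    reference: Optional[np.ndarray] = None,
) -> CompartmentResult:
    """Two-way compartment assignment by spectral co-clustering.

    The correlation map is shifted to be non-negative before co-clustering.
    A constant (informationless) map is flagged degenerate.  If
    ``reference`` labels are given, the AMI against them is attached.
    """
    from sklearn.cluster import SpectralCoclustering

    s = np.asarray(spearman, dtype=float)
    shifted = s - s.min() + 1e-9
    if np.ptp(s) < 1e-12:
        labels = np.zeros(s.shape[0], dtype=int)
        return CompartmentResult(labels=labels, spearman=s, degenerate=True)
    model = SpectralCoclustering(n_clusters=n_clusters, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(shifted)
    labels = np.asarray(model.row_labels_, dtype=int)
    res = CompartmentResult(labels=labels, spearman=s)
    if reference is not None:
        res.ami_vs_reference = ami(labels, np.asarray(reference))
    return res


def ami(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted mutual information between two partitions (1 iff identical up to relabeling)."""
    from sklearn.metrics import adjusted_mutual_info_score

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    return float(adjusted_mutual_info_score(a, b))


def directionality_index(matrix: np.ndarray, window: int) -> np.ndarray:
    """Directionality index per bead.

    DI_i = sign(B - A) * [(A - E)^2 / E + (B - E)^2 / E] with A the upstream
    and B the downstream contact sums within ``window`` beads and
    E = (A + B) / 2.  DI = 0 where A = B = 0.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if window >= n / 2:
        raise ValueError("window must be < n/2")
    di = np.zeros(n)
    # beads whose window is truncated by the chain end carry a spurious
    # one-sided bias and are left at zero
    for i in range(window, n - window):
        a = m[i, i - window : i].sum()
        b = m[i, i + 1 : i + 1 + window].sum()
        e = 0.5 * (a + b)
        if e <= 0:
            continue
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def call_tads(
    di: np.ndarray,
    params: Optional[CCMParameters] = None,
    min_run: Optional[int] = None,
    window: Optional[int] = None,
) -> list[tuple[int, int]]:
    """Call TAD intervals from a DI profile by persistent sign changes.

    A domain starts at a persistent positive run (downstream bias) and ends
    where a persistent negative run (upstream bias) finishes.  ``min_run``
    defaults to window/4 (minimum 2).  Returns half-open bead intervals.
    """
    di = np.asarray(di, dtype=float)
    if min_run is None:
        min_run = max(2, (window or 8) // 4)
    sign = np.sign(di)
    # runs of identical nonzero sign with length >= min_run
    runs = []  # (start, end, sign)
    i = 0
    n = len(di)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j, int(sign[i])))
        i = j
    tads = []
    start = None
    for s0, e0, sg in runs:
        if sg > 0 and start is None:
            start = s0
        elif sg < 0 and start is not None:
            tads.append((start, e0))
            start = None
    return tads


def _globule_volume(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center points on their COM and return (centered, bounding-sphere volume)."""
    com = points.mean(axis=0)
    centered = points - com
    rmax = np.linalg.norm(centered, axis=1).max()
    return centered, 4.0 / 3.0 * np.pi * rmax**3


def radial_distribution(
    trajectory: Trajectory,
    annotation: EpigenomeAnnotation,
    pair: str = "AA",
    r_max: Optional[float] = None,
    dr: float = 0.1,
    min_sep: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pair correlation g(r) between bead types and its first-peak position r_s.

    Normalized by the ideal-gas pair count at the globule's mean density
    (volume of the bounding sphere around the COM), so uniform random points
    give g ~ 1 away from the boundary.  ``min_sep`` excludes pairs closer
    than that along the chain (|i-j| <= min_sep): with blocky annotations
    the like-type first peak is otherwise dominated by trivially adjacent
    chain neighbors rather than spatial segregation.  Returns (r, g, r_s).
    """
    if pair not in ("AA", "BB", "AB"):
        raise ValueError("pair must be one of 'AA', 'BB', 'AB'")
    types = annotation.labels
    sel_a = np.where(types == pair[0])[0]
    sel_b = np.where(types == pair[1])[0]
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError(f"no beads of required types for pair {pair}")
    if r_max is None:
        centered, _ = _globule_volume(trajectory.frames[-1])
        r_max = float(np.linalg.norm(centered, axis=1).max())
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    vol_acc = 0.0
    n_pairs_acc = 0.0
    from scipy.spatial.distance import cdist

    if pair[0] == pair[1]:
        ii, jj = np.triu_indices(len(sel_a), k=1)
        gi, gj = sel_a[ii], sel_a[jj]
    else:
        gi = np.repeat(sel_a, len(sel_b))
        gj = np.tile(sel_b, len(sel_a))
    keep = np.abs(gi - gj) > min_sep
    gi, gj = gi[keep], gj[keep]
    for frame in trajectory.frames:
        _, vol = _globule_volume(frame)
        vol_acc += vol
        d = np.linalg.norm(frame[gi] - frame[gj], axis=1)
        hist += np.histogram(d, bins=edges)[0]
        n_pairs_acc += len(gi)
    vol = vol_acc / trajectory.n_frames
    r_sphere = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * dr
    # finite-sphere edge correction: the ideal-gas pair density at distance r
    # inside a sphere of radius R is reduced by the shell-overlap factor
    x = centers / r_sphere
    overlap = np.clip(1.0 - 0.75 * x + x**3 / 16.0, 0.05, None)
    ideal = n_pairs_acc * shell * overlap / vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    # first peak: maximum of g over r < half the range (avoid boundary artifacts)
    half = max(2, len(centers) // 2)
    r_s = float(centers[:half][np.argmax(g[:half])])
    return centers, g, r_s


def radial_density_profile(
    trajectory: Trajectory,
    annotation: EpigenomeAnnotation,
    r_max: Optional[float] = None,
    dr: float = 0.25,
) -> dict[str, np.ndarray]:
    """Normalized radial density rho_alpha(r) of each bead type about the COM.

    rho_alpha(r) = <N_alpha(r)> V / (4 pi r^2 dr N_alpha) with
    V = (4/3) pi r_max^3; a uniform sphere of one type gives ~1 inside and 0
    outside.  ``r_max`` defaults to the largest COM distance observed (17
    sigma is the full-scale convention).  Returns {'r', 'A', 'B'}.
    """
    types = annotation.labels
    if r_max is None:
        r_max = 0.0
        for frame in trajectory.frames:
            c = frame - frame.mean(axis=0)
            r_max = max(r_max, float(np.linalg.norm(c, axis=1).max()))
        r_max *= 1.0 + 1e-9
    edges = np.arange(0.0, r_max + dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vol = 4.0 / 3.0 * np.pi * r_max**3
    out = {"r": centers}
    for lab in ("A", "B"):
        sel = types == lab
        n_alpha = int(sel.sum())
        if n_alpha == 0:
            out[lab] = np.zeros(len(centers))
            continue
        hist = np.zeros(len(centers))
        for frame in trajectory.frames:
            c = frame - frame.mean(axis=0)
            r = np.linalg.norm(c[sel], axis=1)
            hist += np.histogram(r, bins=edges)[0]
        mean_counts = hist / trajectory.n_frames
        shell = 4.0 * np.pi * centers**2 * dr
        with np.errstate(divide="ignore", invalid="ignore"):
            out[lab] = np.where(shell > 0, mean_counts * vol / (shell * n_alpha), 0.0)
    return out
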