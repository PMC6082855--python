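"""Synthetic inputs: block-copolymer annotations, loop sets and analytic trajectories.

These generators stand in for genomic inputs (ChromHMM tracks, CTCF loop
calls) and provide closed-form test signals for the dynamics estimators.
Everything is seeded and reproducible.
"""

from __future__ import annotations

import numpy as np

from .core import EpigenomeAnnotation, LoopSet
from .trajectory import Trajectory

__all__ = ["synth_annotation", "synth_loops", "synth_trajectory"]


def synth_annotation(
    n_beads: int,
    mean_block_len: float = 20.0,
    fraction_a: float = 0.24,
    seed: int = 0,
) -> EpigenomeAnnotation:
    """Alternating A/B blocks with geometric block lengths.

    Block lengths are geometric with means chosen so the expected A fraction
    equals ``fraction_a``: mean A-block length = 2*mean_block_len*fraction_a,
    mean B-block length = 2*mean_block_len*(1-fraction_a).  The default A
    fraction 0.24 mirrors the active/repressive balance of a typical
    gene-dense human region (about one active locus in four).
    """
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError("fraction_a must be in [0, 1]")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if fraction_a == 0.0:
        return EpigenomeAnnotation(labels=np.full(n_beads, "B"))
    if fraction_a == 1.0:
        return EpigenomeAnnotation(labels=np.full(n_beads, "A"))

    rng = np.random.default_rng(seed)
    mean_a = max(1.0, 2.0 * mean_block_len * fraction_a)
    mean_b = max(1.0, 2.0 * mean_block_len * (1.0 - fraction_a))
    labels = np.empty(n_beads, dtype="U1")
    pos = 0
    # start with a random phase so bead 0 is not always the same type
    current = "A" if rng.random() < fraction_a else "B"
    while pos < n_beads:
        mean = mean_a if current == "A" else mean_b
        length = rng.geometric(1.0 / mean)
        labels[pos : pos + length] = current
        pos += length
        current = "B" if current == "A" else "A"
    return EpigenomeAnnotation(labels=labels)


def synth_loops(
    n_beads: int,
    n_loops: int,
    mean_span: float = 40.0,
    seed: int = 0,
    allow_nested: bool = True,
    min_span: int = 2,
) -> LoopSet:
    """Random loop-anchor pairs with exponentially distributed spans.

    With ``allow_nested=False`` the anchors are laid out left to right so no
    loop contains another.  Duplicate pairs are rejected and redrawn.
    """
    if n_loops < 0:
        raise ValueError("n_loops must be >= 0")
    if n_loops == 0:
        return LoopSet.empty(n_beads)
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    if allow_nested:
        tries = 0
        while len(pairs) < n_loops:
            tries += 1
            if tries > 1000 * n_loops:
                raise RuntimeError("could not place requested loops")
            span = max(min_span, int(round(rng.exponential(mean_span))))
            if span >= n_beads:
                continue
            i = int(rng.integers(0, n_beads - span))
            pairs.add((i, i + span))
    else:
        pos = 0
        for _ in range(n_loops):
            span = max(min_span, int(round(rng.exponential(mean_span))))
            if pos + span >= n_beads:
                break
            pairs.add((pos, pos + span))
            pos += span + 1
    anchors = np.array(sorted(pairs), dtype=np.int64)
    return LoopSet(anchors, n_beads=n_beads)


def synth_trajectory(
    kind: str,
    n_beads: int,
    n_frames: int,
    seed: int = 0,
    dt: float = 1.0,
    speed: float = 1.0,
    diffusion: float = 1.0,
    spring: float = 1.0,
    box: float = 10.0,
) -> Trajectory:
    """Analytic trajectory fixtures for estimator tests.

    kind:
      - 'static':    frozen random conformation (zero displacement).
      - 'ballistic': each bead moves with a constant random-direction
                     velocity of magnitude ``speed``; MSD = speed^2 t^2.
      - 'brownian':  independent Gaussian increments of variance
                     2*diffusion*dt per coordinate; MSD = 6 D t.
      - 'caged':     Ornstein-Uhlenbeck walk about fixed centers with
                     stiffness ``spring`` (bounded, plateauing MSD).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, box, size=(n_beads, 3))
    times = dt * np.arange(n_frames)
    if kind == "static":
        frames = np.repeat(x0[None], n_frames, axis=0)
    elif kind == "ballistic":
        v = rng.normal(size=(n_beads, 3))
        v *= speed / np.linalg.norm(v, axis=1, keepdims=True)
        frames = x0[None] + v[None] * times[:, None, None]
    elif kind == "brownian":
        steps = rng.normal(
            scale=np.sqrt(2.0 * diffusion * dt), size=(n_frames - 1, n_beads, 3)
        )
        frames = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
    elif kind == "caged":
        # Euler-discretised OU: x_{k+1} = x_k - spring*(x_k - x0)*dt + noise
        frames = np.empty((n_frames, n_beads, 3))
        frames[0] = x0
        a = spring * dt
        if a >= 1.0:
            raise ValueError("spring*dt must be < 1 for a stable caged walk")
        sd = np.sqrt(2.0 * diffusion * dt)
        for k in range(1, n_frames):
            noise = rng.normal(scale=sd, size=(n_beads, 3))
            frames[k] = frames[k - 1] - a * (frames[k - 1] - x0) + noise
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    return Trajectory(frames=frames, times=times, seed=seed, meta={"kind": kind})
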