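"""Genomic-format I/O: ChromHMM BED tracks, BEDPE loop calls, contact matrices.

Coordinates are 0-based half-open throughout (BED convention).  Bead k of a
model anchored at ``start`` covers [start + k*bead_bp, start + (k+1)*bead_bp).
Strand is ignored: the model is strand-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import CCMParameters, EpigenomeAnnotation, LoopSet

__all__ = [
    "GenomicInterval",
    "ContactMatrix",
    "read_chromhmm_bed",
    "read_loops_bedpe",
    "read_contact_matrix",
    "write_contact_matrix",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ContactMatrix:
    """Square locus-by-locus contact matrix (raw counts or probabilities)."""

    matrix: np.ndarray
    bin_bp: int = 1200
    origin: Optional[GenomicInterval] = None
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact matrix must be non-negative")
        if self.is_probability and np.any(m > 1.0 + 1e-12):
            raise ValueError("probability matrix has entries > 1")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def _parse_chromhmm_state(name: str) -> int:
    """Extract the numeric ChromHMM state from a BED name like '5_Strong_Enhancer'."""
    token = name.split("_")[0]
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"cannot parse ChromHMM state from name {name!r}") from exc


def read_chromhmm_bed(
    path,
    region: GenomicInterval,
    params: CCMParameters,
    fill_policy: str = "error",
) -> EpigenomeAnnotation:
    """Read a ChromHMM segmentation BED and bin it into per-bead A/B labels.

    Each bead bin of ``params.bead_bp`` bp takes the state with the largest
    overlap (ties broken toward the lower-numbered state), then states 1-11
    collapse to A and 12-15 to B.  ``fill_policy``: 'error' raises on a bin
    with no covering record; an integer-like string (e.g. '13') fills with
    that state.
    """
    bead_bp = params.bead_bp
    n_beads = len(region) // bead_bp
    if n_beads < 1:
        raise ValueError("region shorter than one bead")

    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs >= 4 columns")
            chrom, s, e, name = parts[0], parts[1], parts[2], parts[3]
            if chrom != region.chromosome:
                continue
            try:
                s, e = int(s), int(e)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates")
            if s >= e:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            records.append((s, e, _parse_chromhmm_state(name)))

    states = np.zeros(n_beads, dtype=int)
    for k in range(n_beads):
        bin_s = region.start + k * bead_bp
        bin_e = bin_s + bead_bp
        overlap: dict[int, int] = {}
        for s, e, st in records:
            ov = min(e, bin_e) - max(s, bin_s)
            if ov > 0:
                overlap[st] = overlap.get(st, 0) + ov
        if not overlap:
            if fill_policy == "error":
                raise ValueError(f"bead bin {k} has no covering ChromHMM record")
            states[k] = int(fill_policy)
            continue
        best = max(overlap.values())
        states[k] = min(st for st, ov in overlap.items() if ov == best)

    labels = np.array([EpigenomeAnnotation.state_to_label(s) for s in states])
    return EpigenomeAnnotation(
        labels=labels,
        states=states,
        chromosome=region.chromosome,
        start_bp=region.start,
        bead_bp=bead_bp,
    )


def read_loops_bedpe(path, region: GenomicInterval, params: CCMParameters) -> LoopSet:
    """Read BEDPE loop calls and map anchor midpoints to bead indices.

    Pairs with either anchor midpoint outside ``region`` are dropped;
    duplicates are collapsed; pairs whose anchors land on the same bead or on
    adjacent beads are dropped with a warning (they carry no loop information
    at bead resolution).
    """
    bead_bp = params.bead_bp
    n_beads = len(region) // bead_bp
    pairs = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BEDPE line needs >= 6 columns")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            if c1 != region.chromosome or c2 != region.chromosome:
                continue
            try:
                mid1 = (int(s1) + int(e1)) // 2
                mid2 = (int(s2) + int(e2)) // 2
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates")
            if not (region.start <= mid1 < region.end and region.start <= mid2 < region.end):
                continue
            b1 = (mid1 - region.start) // bead_bp
            b2 = (mid2 - region.start) // bead_bp
            if b1 >= n_beads or b2 >= n_beads:
                continue
            i, j = sorted((int(b1), int(b2)))
            if j - i < 2:
                warnings.warn(
                    f"{path}:{ln}: anchors map to beads {i},{j} (< 2 apart); dropped"
                )
                continue
            pairs.add((i, j))
    anchors = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return LoopSet(anchors, n_beads=n_beads)


def read_contact_matrix(path, is_probability: bool = False) -> ContactMatrix:
    """Read a dense square contact matrix from TSV (symmetry is enforced)."""
    m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return ContactMatrix(m, is_probability=is_probability)


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    """Write a contact matrix as plain TSV; round-trips bit-exactly."""
    pd.DataFrame(cm.matrix).to_csv(path, sep="\t", header=False, index=False,
                                   float_format="%.17g")
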