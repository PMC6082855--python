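"""Chromosome copolymer model (CCM): parameters, epigenetic annotation and energy function.

The CCM represents a chromatin fiber as a self-avoiding bead-spring copolymer
with two epigenetic bead types: A (active / euchromatin, ChromHMM states 1-11)
and B (repressive / heterochromatin, states 12-15).  Each bead covers 1200 bp
(about six nucleosomes) with diameter ``sigma`` = 70 nm.  Loci of the same
type attract with well depth ``epsilon`` (= eps_AA = eps_BB); unlike pairs
attract with eps_AB = epsilon / eps_ratio (default ratio 11/9).  CTCF loop
anchors are modelled as permanent bonds between the anchor beads.

The total energy is ``E = U_S + U_L + U_LJ``: chain bonds (FENE +
short-range repulsion, Kremer-Grest constants), loop bonds (permanent
harmonic tethers whose restoring force is capped so a collapse can start
from an extended conformation with distant anchors) and a
truncated-and-shifted Lennard-Jones pair interaction whose attractive branch
scales with the type-dependent well depth while the repulsive core is kept at
unit amplitude, so that ``epsilon = 0`` reduces to an athermal self-avoiding
chain.

Internally the model uses reduced units: sigma = 1, k_B T = 1.  Physical
units (nm, seconds) enter only through :class:`CCMParameters` at I/O time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CCMParameters",
    "EpigenomeAnnotation",
    "LoopSet",
    "BondSpec",
    "LoopBondSpec",
    "EnergyModel",
    "EnergyBreakdown",
    "OverstretchedBondError",
    "default_parameters",
    "estimate_monomer_size",
    "pair_energy",
    "total_energy",
]

#: ChromHMM states collapsed to the active class.
ACTIVE_STATES = frozenset(range(1, 12))
#: ChromHMM states collapsed to the repressive class.
REPRESSIVE_STATES = frozenset(range(12, 16))

LJ_MIN = 2.0 ** (1.0 / 6.0)  # location of the LJ minimum, in sigma


class OverstretchedBondError(ValueError):
    """A bond length left the FENE domain (r >= r_max)."""

    def __init__(self, bond_index: int, i: int, j: int, r: float, r_max: float):
        self.bond_index = bond_index
        self.pair = (i, j)
        self.r = r
        super().__init__(
            f"bond {bond_index} ({i}-{j}) overstretched: r={r:.4f} >= r_max={r_max:.4f}"
        )


@dataclass
class CCMParameters:
    """Physical and model parameters of the CCM.

    Attributes
    ----------
    n_beads : int
        Chain length N.
    bead_bp : int
        Base pairs per bead (1200: six nucleosomes plus linkers).
    sigma : float
        Monomer diameter in nm (70 nm, the mean of the 20-130 nm bracket).
    epsilon : float
        Same-type well depth eps_AA = eps_BB in k_B T (2.4 reproduces
        experiment-like contact maps; 1.0 gives a fluid-like control).
    eps_ratio : float
        Ratio epsilon / eps_AB (11/9).
    r_contact : float
        Contact threshold in multiples of sigma (2).
    temperature : float
        k_B T in reduced units.
    time_calibration : float or None
        Seconds per reduced time unit; None means reduced units only.
    """

    n_beads: int = 1000
    bead_bp: int = 1200
    sigma: float = 70.0
    epsilon: float = 2.4
    eps_ratio: float = 11.0 / 9.0
    r_contact: float = 2.0
    temperature: float = 1.0
    time_calibration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eps_ratio <= 0:
            raise ValueError("eps_ratio must be positive")
        if self.r_contact <= 0:
            raise ValueError("r_contact must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @property
    def eps_ab(self) -> float:
        """Cross-type well depth eps_AB = epsilon / eps_ratio, in k_B T."""
        return self.epsilon / self.eps_ratio

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CCMParameters":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown parameter keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class EpigenomeAnnotation:
    """Per-bead epigenetic labels A/B, optionally with source ChromHMM states.

    ``labels`` is a length-N array of 'A'/'B'.  Bead k covers the genomic bin
    [start_bp + k*bead_bp, start_bp + (k+1)*bead_bp), 0-based half-open.
    """

    labels: np.ndarray
    states: Optional[np.ndarray] = None  # ChromHMM state 1-15 per bead
    chromosome: str = "chrS"
    start_bp: int = 0
    bead_bp: int = 1200

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        bad = set(np.unique(self.labels)) - {"A", "B"}
        if bad:
            raise ValueError(f"labels must be 'A' or 'B', got {sorted(bad)}")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=int)
            if self.states.shape != self.labels.shape:
                raise ValueError("states must match labels in length")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def types(self) -> np.ndarray:
        """Integer type codes: 0 for A, 1 for B (used by the kernels)."""
        return (self.labels == "B").astype(np.int64)

    @property
    def fraction_a(self) -> float:
        return float(np.mean(self.labels == "A"))

    @staticmethod
    def state_to_label(state: int) -> str:
        """Collapse a ChromHMM state (1-15) to the two-letter alphabet."""
        if state in ACTIVE_STATES:
            return "A"
        if state in REPRESSIVE_STATES:
            return "B"
        raise ValueError(f"ChromHMM state out of range 1-15: {state}")


@dataclass
class LoopSet:
    """Permanent loop bonds between anchor bead pairs (i, j), i < j."""

    anchors: np.ndarray  # (n_loops, 2) int
    n_beads: Optional[int] = None

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int64).reshape(-1, 2)
        if self.anchors.size:
            i, j = self.anchors[:, 0], self.anchors[:, 1]
            if np.any(i < 0):
                raise ValueError("anchor indices must be non-negative")
            if np.any(j - i < 2):
                raise ValueError("anchors must satisfy j - i >= 2")
            if self.n_beads is not None and np.any(j >= self.n_beads):
                raise ValueError("anchor index beyond n_beads")
            seen = set(map(tuple, self.anchors))
            if len(seen) != len(self.anchors):
                raise ValueError("duplicate anchor pairs")

    def __len__(self) -> int:
        return len(self.anchors)

    @classmethod
    def empty(cls, n_beads: Optional[int] = None) -> "LoopSet":
        return cls(np.empty((0, 2), dtype=np.int64), n_beads=n_beads)


@dataclass
class BondSpec:
    """FENE bond constants (Kremer-Grest defaults: k=30 eps0/sigma^2, r_max=1.5 sigma).

    The bond also carries a unit-amplitude short-range repulsion (WCA with
    well depth ``eps_repulsive``) so bonded beads cannot collapse onto each
    other; bonded pairs are excluded from the type-dependent pair term.
    """

    k: float = 30.0
    r_max: float = 1.5
    eps_repulsive: float = 1.0


@dataclass
class LoopBondSpec:
    """Permanent loop-anchor tether: harmonic about ``r0`` with a force cap.

    The restoring force is k * clip(r - r0, -cap, cap): near rest it is an
    ordinary stiff spring; for anchors far apart (extended starts) it pulls
    at constant force k*cap, which stays below the excluded-volume scale so
    the chain cannot be dragged through itself.
    """

    k: float = 30.0
    r0: float = 0.9609  # FENE+WCA chain-bond rest length, sigma
    cap: float = 1.0


@dataclass
class EnergyModel:
    """Full CCM energy specification: E = U_S (chain) + U_L (loops) + U_LJ (pairs)."""

    parameters: CCMParameters
    annotation: EpigenomeAnnotation
    loops: LoopSet
    bond: BondSpec = field(default_factory=BondSpec)
    loop_bond: LoopBondSpec = field(default_factory=LoopBondSpec)
    cutoff: float = 2.5  # LJ truncation radius, sigma

    def __post_init__(self) -> None:
        n = self.parameters.n_beads
        if len(self.annotation) != n:
            raise ValueError(
                f"annotation length {len(self.annotation)} != n_beads {n}"
            )
        if len(self.loops) and np.any(self.loops.anchors[:, 1] >= n):
            raise ValueError("loop anchor beyond chain")

    @property
    def eps_matrix(self) -> np.ndarray:
        """2x2 well-depth matrix indexed by type codes (0=A, 1=B)."""
        e = self.parameters.epsilon
        eab = self.parameters.eps_ab
        return np.array([[e, eab], [eab, e]])


@dataclass
class EnergyBreakdown:
    """Energy terms in k_B T: E = u_bond + u_loop + u_pair."""

    u_bond: float
    u_loop: float
    u_pair: float

    @property
    def total(self) -> float:
        return self.u_bond + self.u_loop + self.u_pair


def default_parameters() -> CCMParameters:
    """Parameters matching the standard model defaults.

    1200 bp per bead, sigma = 70 nm, epsilon = 2.4 k_B T, epsilon/eps_AB =
    11/9, contact threshold r_c = 2 sigma.
    """
    return CCMParameters()


def estimate_monomer_size(
    nucleosome_radius: float,
    linker_length: float,
    nucleosomes_per_bead: float,
) -> tuple[float, float]:
    """Bracket the monomer diameter sigma (nm) by two limiting estimates.

    Lower bound: compact packing — the bead volume equals
    ``nucleosomes_per_bead`` nucleosome volumes, sigma = n^(1/3) * R_N.
    Upper bound: the nucleosome array as a worm-like chain with persistence
    length comparable to its contour length L = n * (linker + R_N), for which
    the mean end-to-end distance is R = L * sqrt(2/e).

    Returns the unrounded (lower, upper) pair; with R_N = 10 nm, 16.5 nm
    linkers and six nucleosomes these bracket ~18-136 nm, quoted in the
    field as the 20-130 nm range whose midpoint motivates sigma = 70 nm.
    """
    if nucleosome_radius <= 0 or linker_length < 0 or nucleosomes_per_bead <= 0:
        raise ValueError("inputs must be positive (linker_length may be zero)")
    lower = nucleosomes_per_bead ** (1.0 / 3.0) * nucleosome_radius
    contour = nucleosomes_per_bead * (linker_length + nucleosome_radius)
    upper = contour * math.sqrt(2.0 / math.e)
    return lower, upper


def _lj_split(r: float, eps_attr: float, cutoff: float, shifted: bool) -> float:
    """Pair potential: unit-amplitude WCA core + eps-scaled attractive branch.

    For eps_attr = 1 this is the standard 12-6 LJ; for eps_attr = 0 it is the
    purely repulsive (athermal) reference.  The attractive branch is
    truncated at ``cutoff`` and, if ``shifted``, shifted to zero there.
    """
    if r >= cutoff:
        return 0.0
    inv6 = 1.0 / r**6
    lj = 4.0 * (inv6 * inv6 - inv6)
    if r < LJ_MIN:
        core = lj + 1.0  # WCA, zero at the minimum
        attr = -1.0
    else:
        core = 0.0
        attr = lj
    shift = 0.0
    if shifted:
        inv6c = 1.0 / cutoff**6
        shift = 4.0 * (inv6c * inv6c - inv6c)
    return core + eps_attr * (attr - shift)


def pair_energy(
    label_a: str,
    label_b: str,
    r: float,
    model: EnergyModel,
    shifted: bool = True,
) -> float:
    """Non-bonded pair energy (k_B T) between beads of the given labels at distance r (sigma).

    Well depth eps_AA = eps_BB = epsilon, eps_AB = epsilon/eps_ratio.  Beyond
    the cutoff the energy is exactly zero.  ``shifted=False`` returns the
    unshifted potential (the analytic minimum is then exactly -eps at
    r = 2^(1/6) sigma).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    ta = 0 if label_a == "A" else 1
    tb = 0 if label_b == "A" else 1
    eps = model.eps_matrix[ta, tb]
    return _lj_split(float(r), float(eps), model.cutoff, shifted)


def _fene_energy(r: float, spec: BondSpec) -> float:
    """FENE + unit-WCA bond energy; raises for r outside the FENE domain."""
    if r >= spec.r_max:
        raise FloatingPointError  # caller converts with bond context
    u = -0.5 * spec.k * spec.r_max**2 * math.log(1.0 - (r / spec.r_max) ** 2)
    if r < LJ_MIN:
        inv6 = 1.0 / r**6
        u += spec.eps_repulsive * (4.0 * (inv6 * inv6 - inv6) + 1.0)
    return u


def total_energy(positions: np.ndarray, model: EnergyModel) -> EnergyBreakdown:
    """Full energy breakdown of a conformation (positions in sigma, shape (N, 3)).

    Chain-bonded and loop-bonded pairs are excluded from the pair term (their
    excluded volume lives in the bond's own repulsion).  Raises
    :class:`OverstretchedBondError` if any bond leaves the FENE domain.
    """
    pos = np.asarray(positions, dtype=float)
    n = model.parameters.n_beads
    if pos.shape != (n, 3):
        raise ValueError(f"positions must have shape ({n}, 3), got {pos.shape}")

    # chain bonds
    u_bond = 0.0
    dr = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    for b, r in enumerate(dr):
        try:
            u_bond += _fene_energy(float(r), model.bond)
        except FloatingPointError:
            raise OverstretchedBondError(b, b, b + 1, float(r), model.bond.r_max)

    # loop bonds (capped harmonic: finite energy at any separation)
    u_loop = 0.0
    bonded = {(i, i + 1) for i in range(n - 1)}
    lb = model.loop_bond
    for i, j in model.loops.anchors:
        r = float(np.linalg.norm(pos[i] - pos[j]))
        ext = abs(r - lb.r0)
        if ext <= lb.cap:
            u_loop += 0.5 * lb.k * ext**2
        else:
            u_loop += lb.k * lb.cap * ext - 0.5 * lb.k * lb.cap**2
        bonded.add((int(i), int(j)))

    # non-bonded pairs within cutoff, via a KD-tree
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    pairs = tree.query_pairs(model.cutoff, output_type="ndarray")
    labels = model.annotation.labels
    u_pair = 0.0
    for i, j in pairs:
        if (int(i), int(j)) in bonded:
            continue
        r = float(np.linalg.norm(pos[i] - pos[j]))
        u_pair += pair_energy(labels[i], labels[j], r, model)
    return EnergyBreakdown(u_bond=u_bond, u_loop=u_loop, u_pair=u_pair)
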