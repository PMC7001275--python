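"""Heterogeneously flexible bead-spring DNA substrate and its energy function.

The host DNA is a linear chain of ``n_beads`` beads, each representing
``bp_per_bead`` base pairs (defaults: 200 beads of 8 bp, i.e. a 1.6 kbp
substrate). Bending rigidity is set per joint through the Kratky-Porod
penalty ``k_i (1 - cos theta_i)``; a baseline persistence length ``lp_bp``
applies everywhere except at designated *soft sites*, short segments whose
reduced rigidity ``lf_bp`` mimics locally denatured or stressed DNA
(denaturation bubbles, R-loops, replication stress).

Units: thermal energy kT = 1, bead diameter sigma = 1 (8 bp of B-DNA,
about 2.7 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels


class EnergyDivergenceError(ValueError):
    """Raised when a conformation contains coincident beads, for which the
    excluded-volume energy diverges."""


def stiffness_from_lp(lp_bp: float, bp_per_bead: int) -> float:
    """Dimensionless joint stiffness k (in kT) for a persistence length.

    Uses the discretised worm-like-chain mapping ``k = lp_bp / bp_per_bead``
    (persistence length in bonds equals the stiffness in kT), the large-k
    limit of the Kratky-Porod relation
    ``l_p = -1 / ln(coth k - 1/k)`` bonds.
    """
    if lp_bp <= 0:
        raise ValueError(f"lp_bp must be positive, got {lp_bp}")
    if bp_per_bead <= 0:
        raise ValueError(f"bp_per_bead must be positive, got {bp_per_bead}")
    return lp_bp / bp_per_bead


def lp_from_stiffness(k: float, bp_per_bead: int) -> float:
    """Inverse of :func:`stiffness_from_lp`."""
    if k <= 0:
        raise ValueError(f"stiffness k must be positive, got {k}")
    if bp_per_bead <= 0:
        raise ValueError(f"bp_per_bead must be positive, got {bp_per_bead}")
    return k * bp_per_bead


def kratky_porod_mean_cos(k: float) -> float:
    """Exact equilibrium <cos theta> of one Kratky-Porod joint: the Langevin
    function coth(k) - 1/k (freely jointed limit 0 at k = 0)."""
    if k < 1e-8:
        return 0.0
    if k > 20.0:
        # coth(k) - 1 underflows; use the asymptotic form
        return 1.0 - 1.0 / k
    return 1.0 / np.tanh(k) - 1.0 / k


@dataclass(frozen=True)
class SubstrateSpec:
    """Full description of the host polymer.

    ``soft_indices`` are the starting joints of the soft sites; each site
    spans ``soft_len_beads`` consecutive joints. Joints are indexed by the
    interior bead they are centred on (1 .. n_beads - 2).
    """

    n_beads: int
    bp_per_bead: int = 8
    lp_bp: float = 150.0
    soft_indices: tuple = ()
    lf_bp: Optional[float] = None
    soft_len_beads: int = 1
    attraction_eps: float = 0.0

    def __post_init__(self):
        if self.n_beads < 3:
            raise ValueError(f"n_beads must be >= 3, got {self.n_beads}")
        if self.bp_per_bead < 1:
            raise ValueError(f"bp_per_bead must be >= 1, got {self.bp_per_bead}")
        if self.lp_bp <= 0:
            raise ValueError(f"lp_bp must be positive, got {self.lp_bp}")
        lf = self.lf_bp if self.lf_bp is not None else self.lp_bp
        if not (0 < lf <= self.lp_bp):
            raise ValueError(
                f"lf_bp must lie in (0, lp_bp]; got lf_bp={lf}, lp_bp={self.lp_bp}")
        if self.soft_len_beads < 1:
            raise ValueError(
                f"soft_len_beads must be >= 1, got {self.soft_len_beads}")
        if self.attraction_eps < 0:
            raise ValueError(
                f"attraction_eps must be >= 0, got {self.attraction_eps}")
        idx = tuple(sorted(int(i) for i in self.soft_indices))
        object.__setattr__(self, "soft_indices", idx)
        covered = set()
        for s in idx:
            joints = range(s, s + self.soft_len_beads)
            for j in joints:
                if not (1 <= j <= self.n_beads - 2):
                    raise ValueError(
                        f"soft site starting at joint {s} leaves the interior "
                        f"joint range [1, {self.n_beads - 2}] (joint {j})")
                if j in covered:
                    raise ValueError(
                        f"soft sites overlap at joint {j}")
                covered.add(j)

    @property
    def lf_bp_effective(self) -> float:
        return self.lf_bp if self.lf_bp is not None else self.lp_bp

    @property
    def n_loci(self) -> int:
        """Number of host bonds (candidate integration loci)."""
        return self.n_beads - 1

    def soft_joints(self) -> np.ndarray:
        """All joint (interior-bead) indices carrying the soft rigidity."""
        out = []
        for s in self.soft_indices:
            out.extend(range(s, s + self.soft_len_beads))
        return np.asarray(sorted(out), dtype=np.int64)

    def soft_loci(self) -> np.ndarray:
        """Bond loci biased by the soft sites.

        An insertion at bond l deforms both flanking joints l and l+1, so a
        soft joint at bead b biases bonds b-1 and b; a site spanning joints
        s..s+m-1 therefore covers bonds s-1..s+m-1.
        """
        loci = set()
        for j in self.soft_joints():
            for l in (j - 1, j):
                if 0 <= l <= self.n_beads - 2:
                    loci.add(int(l))
        return np.asarray(sorted(loci), dtype=np.int64)


def default_soft_indices(n_beads: int, spacing: int = 20,
                         soft_len_beads: int = 1) -> tuple:
    """Regularly spaced soft sites: one every ``spacing`` beads starting at
    joint ``spacing - 1`` (9 one-bead sites for the 200-bead default)."""
    if spacing < 2:
        raise ValueError(f"spacing must be >= 2, got {spacing}")
    last = n_beads - 1 - soft_len_beads
    return tuple(range(spacing - 1, last + 1, spacing))


@dataclass
class ForceFieldParams:
    """Numerical parameters of the substrate energy function.

    * harmonic bonds about ``bond_rest_length`` with ``bond_strength`` stiff
      enough that length fluctuations stay below 10% of a bead diameter;
    * Kratky-Porod bending with per-joint constants ``bend_constants``
      (n_beads - 2 entries, one per interior joint);
    * WCA excluded volume of diameter ``ev_diameter`` (0 disables all
      non-bonded terms, the ideal-chain regime);
    * optional short-range attraction of depth ``attraction_eps`` and range
      ``attraction_range``, used for the collapsed-polymer regime.
    """

    bend_constants: np.ndarray
    bond_rest_length: float = 1.0
    bond_strength: float = 200.0
    ev_diameter: float = 1.0
    attraction_eps: float = 0.0
    attraction_range: float = 1.8

    def __post_init__(self):
        self.bend_constants = np.asarray(self.bend_constants, dtype=np.float64)
        if self.bend_constants.ndim != 1:
            raise ValueError("bend_constants must be a 1-D array")
        if np.any(self.bend_constants < 0):
            raise ValueError("bend_constants must be non-negative")
        for name in ("bond_rest_length", "bond_strength", "ev_diameter",
                     "attraction_eps", "attraction_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_beads(self) -> int:
        return self.bend_constants.size + 2

    def padded_bend(self) -> np.ndarray:
        """Length-N stiffness array indexed by the central bead of each
        joint (zeros at the two chain ends), the layout the kernels use."""
        out = np.zeros(self.n_beads, dtype=np.float64)
        out[1:-1] = self.bend_constants
        return out


def build_forcefield(spec: SubstrateSpec) -> ForceFieldParams:
    """Force field for a substrate: baseline stiffness everywhere, soft-site
    stiffness on the joints covered by the soft sites."""
    k_stiff = stiffness_from_lp(spec.lp_bp, spec.bp_per_bead)
    k_soft = stiffness_from_lp(spec.lf_bp_effective, spec.bp_per_bead)
    bend = np.full(spec.n_beads - 2, k_stiff, dtype=np.float64)
    for j in spec.soft_joints():
        bend[j - 1] = k_soft
    return ForceFieldParams(bend_constants=bend,
                            attraction_eps=spec.attraction_eps)


@dataclass
class PolymerConformation:
    """Ordered 3D bead positions of one chain (bead-diameter units)."""

    coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a chain needs at least 2 beads")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def bonds(self):
        """Connectivity of the linear chain as (i, i+1) pairs."""
        return [(i, i + 1) for i in range(self.n_beads - 1)]

    def copy(self) -> "PolymerConformation":
        return PolymerConformation(self.coords.copy(), dict(self.metadata))


def _check_dimensions(conf: PolymerConformation, ff: ForceFieldParams):
    if conf.n_beads != ff.n_beads:
        raise ValueError(
            f"conformation has {conf.n_beads} beads but the force field "
            f"expects {ff.n_beads}")


def _check_coincident(conf: PolymerConformation):
    c = conf.coords
    n = c.shape[0]
    d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
    iu, ju = np.triu_indices(n, k=2)
    if iu.size and np.min(d2[iu, ju]) < 1e-16:
        raise EnergyDivergenceError(
            "conformation contains coincident non-bonded beads; "
            "excluded-volume energy diverges")


def energy_components(conf: PolymerConformation, ff: ForceFieldParams) -> dict:
    """Separate energy terms in kT: bond, bend, excluded volume, attraction."""
    _check_dimensions(conf, ff)
    _check_coincident(conf)
    eb, ea, eev, eat = _kernels.total_components(
        conf.coords, ff.padded_bend(), ff.bond_strength, ff.bond_rest_length,
        ff.ev_diameter, ff.attraction_eps, ff.attraction_range)
    return {"bond": eb, "bend": ea, "excluded_volume": eev, "attraction": eat}


def total_energy(conf: PolymerConformation, ff: ForceFieldParams) -> float:
    """Total energy E = E_bond + E_bend + E_ev + E_attr in kT."""
    return float(sum(energy_components(conf, ff).values()))


def _sample_kp_cos(k: float, rng: np.random.Generator) -> float:
    """Draw cos(theta) from the Kratky-Porod joint Boltzmann density
    p(c) propto exp(k c) on [-1, 1] by inverse CDF."""
    if k < 1e-9:
        return rng.uniform(-1.0, 1.0)
    u = rng.random()
    # c = 1 + ln(u + (1-u) e^{-2k}) / k, numerically safe for large k
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * k)) / k


def _grow_chain(n_beads: int, bend_padded: np.ndarray, ev_sigma: float,
                rng: np.random.Generator,
                confine_radius: Optional[float] = None,
                min_sep: float = 0.9, max_retry: int = 80,
                max_restart: int = 60) -> np.ndarray:
    """Random non-reversal growth with joint angles drawn from the local
    Boltzmann bending density, rejecting sterically clashing placements."""

    def random_unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    thresh = min_sep * ev_sigma if ev_sigma > 0 else 0.0
    for _ in range(max_restart):
        coords = np.zeros((n_beads, 3))
        if confine_radius is not None:
            coords[0] = random_unit() * confine_radius * 0.3
        t_prev = random_unit()
        coords[1] = coords[0] + t_prev
        ok_chain = True
        for b in range(2, n_beads):
            k = bend_padded[b - 1]
            placed = False
            for _ in range(max_retry):
                c = _sample_kp_cos(k, rng)
                s = np.sqrt(max(0.0, 1.0 - c * c))
                phi = rng.uniform(0.0, 2.0 * np.pi)
                # frame perpendicular to t_prev
                ref = np.array([0.0, 0.0, 1.0]) if abs(t_prev[2]) < 0.9 \
                    else np.array([1.0, 0.0, 0.0])
                n1 = np.cross(t_prev, ref)
                n1 /= np.linalg.norm(n1)
                n2 = np.cross(t_prev, n1)
                t_new = c * t_prev + s * (np.cos(phi) * n1 + np.sin(phi) * n2)
                pos = coords[b - 1] + t_new
                if confine_radius is not None and \
                        np.linalg.norm(pos - coords[0]) > confine_radius:
                    continue
                if thresh > 0 and b >= 2:
                    d = np.linalg.norm(coords[:b - 1] - pos, axis=1)
                    if np.min(d) < thresh:
                        continue
                coords[b] = pos
                t_prev = t_new
                placed = True
                break
            if not placed:
                ok_chain = False
                break
        if ok_chain:
            return coords
    raise RuntimeError(
        "chain growth failed: could not place a non-overlapping conformation "
        f"of {n_beads} beads after {max_restart} restarts")


def init_conformation(spec: SubstrateSpec, seed: int,
                      ff: Optional[ForceFieldParams] = None,
                      confine_radius: Optional[float] = None
                      ) -> PolymerConformation:
    """Non-overlapping starting conformation, deterministic given ``seed``.

    Growth draws each joint angle from its own Boltzmann bending density, so
    the chain starts close to conformational equilibrium up to
    excluded-volume corrections.
    """
    if ff is None:
        ff = build_forcefield(spec)
    rng = np.random.default_rng(seed)
    coords = _grow_chain(spec.n_beads, ff.padded_bend(), ff.ev_diameter, rng,
                         confine_radius=confine_radius)
    return PolymerConformation(coords, {"seed": int(seed), "sweep": 0})
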