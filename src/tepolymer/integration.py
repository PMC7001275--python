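"""Stochastic quasi-equilibrium integration of an invading DNA element.

Integration is modelled as a Metropolis reconnection: a host bond is opened
and rewired through the invading element, and the move is accepted with
probability min(1, exp(-dE/kT)) where dE is the energy difference between
the post- and pre-insertion configurations. The process is quasi-equilibrium
(no ATP drive) and irreversible by fiat: once a replicate accepts an
insertion the element is stuck and the replicate ends.

Geometry of the rewiring: only the element's two junction beads are placed
explicitly. They sit at rest bond length from the two host beads flanking
the opened bond, splayed by a kink angle (default 60 deg, the opening at
which unit-length junction bonds clear the host beads sterically) with an
azimuthal spread that keeps the two element ends apart. The element interior
is implicit; its internal energy is unchanged by reconnection and cancels
from dE. The energetic bias that remains is exactly the mechanism under
study: bending the host at the two flanking joints, which is cheaper where
the substrate is soft.

Attempts are proposed at uniformly random interior host bonds on an
equilibrated host, which isolates the flexibility bias from any transport
effect; an optional proximity-gated mode restricts attempts to bonds near a
randomly diffusing element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _kernels
from .substrate import (ForceFieldParams, PolymerConformation, SubstrateSpec,
                        build_forcefield, init_conformation)
from .sampler import DEFAULT_CRANK_MAX, DEFAULT_MAX_DISP

DEFAULT_KINK_DEG = 60.0
DEFAULT_PSI_DEG = 70.0


def derive_seed(master_seed: int, *key: int) -> int:
    """Per-replicate seed from a master seed and an integer counter path
    (numpy SeedSequence spawn keys), kept below 2^31."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class TESpec:
    """Invading transposable element: length in beads, single insertion per
    replicate. Within the junction-bead approximation the energy change is
    independent of the element length, which is retained for interface
    completeness and serialisation."""

    te_len_beads: int = 10
    mode: str = "generic"

    def __post_init__(self):
        if self.te_len_beads < 1:
            raise ValueError(
                f"te_len_beads must be >= 1, got {self.te_len_beads}")
        if self.mode != "generic":
            raise ValueError(f"unknown TE mode {self.mode!r}")


@dataclass(frozen=True)
class AttemptSchedule:
    """How a replicate alternates relaxation sweeps and insertion attempts."""

    equil_sweeps: int = 150
    attempts_per_sweep: int = 20
    max_attempts: int = 1_000_000
    n_trials: int = 8
    kink_deg: float = DEFAULT_KINK_DEG
    psi_deg: float = DEFAULT_PSI_DEG
    proposal_mode: str = "uniform"

    def __post_init__(self):
        if self.equil_sweeps < 1 or self.attempts_per_sweep < 1:
            raise ValueError("equil_sweeps and attempts_per_sweep must be >= 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.kink_deg < 90):
            raise ValueError("kink_deg must lie in (0, 90)")
        if self.proposal_mode not in ("uniform", "proximity"):
            raise ValueError(
                f"proposal_mode must be 'uniform' or 'proximity', "
                f"got {self.proposal_mode!r}")


@dataclass
class IntegrationEvent:
    """One integration outcome. ``flagged`` replicates hit the attempt cap
    without an acceptance (locus = -1) and are excluded from profiles."""

    replicate_id: int
    locus: int
    delta_E: float
    sweep: int
    seed: int
    flagged: bool = False


@dataclass
class ExperimentResult:
    events: List[IntegrationEvent]
    spec: SubstrateSpec
    te: TESpec
    n_replicates: int

    def __post_init__(self):
        if len(self.events) != self.n_replicates:
            raise ValueError("one event record per replicate is required")

    @property
    def ok_events(self) -> List[IntegrationEvent]:
        return [e for e in self.events if not e.flagged]

    @property
    def n_flagged(self) -> int:
        return sum(e.flagged for e in self.events)


def _locus_valid(conf: PolymerConformation, locus: int):
    if not (0 <= locus <= conf.n_beads - 2):
        raise ValueError(
            f"locus {locus} out of range [0, {conf.n_beads - 2}]")


def place_junction(conf: PolymerConformation, locus: int, phi: float,
                   kink_deg: float = DEFAULT_KINK_DEG,
                   psi_deg: float = DEFAULT_PSI_DEG,
                   ff: Optional[ForceFieldParams] = None):
    """(delta_E, junction coordinates (2, 3)) for one explicit azimuth."""
    if ff is None:
        raise ValueError("a force field is required")
    _locus_valid(conf, locus)
    junc = np.empty((2, 3))
    d_e = _kernels.insertion_delta(
        conf.coords, ff.padded_bend(), ff.bond_strength, ff.bond_rest_length,
        ff.ev_diameter, ff.attraction_eps, ff.attraction_range,
        locus, np.deg2rad(kink_deg), np.deg2rad(psi_deg), float(phi), junc)
    return float(d_e), junc


def proposal_delta_energy(conf: PolymerConformation, ff: ForceFieldParams,
                          locus: int, te: TESpec, rng,
                          n_trials: int = 8,
                          kink_deg: float = DEFAULT_KINK_DEG,
                          psi_deg: float = DEFAULT_PSI_DEG) -> float:
    """dE of inserting the element at ``locus``, minimised over a small
    trial set of junction azimuths (the relaxed trial placement)."""
    if not isinstance(te, TESpec):
        te = TESpec(te_len_beads=int(te))
    _locus_valid(conf, locus)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    phis = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    junc = np.empty((2, 3))
    d_e = _kernels.best_insertion(
        conf.coords, ff.padded_bend(), ff.bond_strength, ff.bond_rest_length,
        ff.ev_diameter, ff.attraction_eps, ff.attraction_range,
        locus, np.deg2rad(kink_deg), np.deg2rad(psi_deg), phis, junc)
    return float(d_e)


def metropolis_accept(delta_E: float, rng) -> bool:
    """Accept with probability min(1, exp(-delta_E))."""
    if not np.isfinite(delta_E):
        raise ValueError("delta_E must be finite")
    if delta_E <= 0:
        return True
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if delta_E > 700:
        return False
    return bool(rng.random() < np.exp(-delta_E))


def run_replicate(spec: SubstrateSpec, te: TESpec, seed: int,
                  attempt_schedule: Optional[AttemptSchedule] = None,
                  replicate_id: int = 0,
                  ff: Optional[ForceFieldParams] = None) -> IntegrationEvent:
    """One independent simulation: equilibrate a fresh host, then alternate
    MC relaxation sweeps with insertion attempts until the first Metropolis
    acceptance. Attempts target interior bonds so every candidate locus has
    both flanking joints; the element is never excised afterwards."""
    sched = attempt_schedule or AttemptSchedule()
    if ff is None:
        ff = build_forcefield(spec)
    conf = init_conformation(spec, derive_seed(seed, 0), ff=ff)
    if sched.proposal_mode == "proximity":
        return _run_replicate_proximity(spec, te, seed, sched, replicate_id,
                                        ff, conf)
    locus, d_e, sweep, _ = _kernels.run_replicate(
        conf.coords, ff.padded_bend(), ff.bond_strength, ff.bond_rest_length,
        ff.ev_diameter, ff.attraction_eps, ff.attraction_range,
        DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX,
        sched.equil_sweeps, sched.attempts_per_sweep, sched.max_attempts,
        np.deg2rad(sched.kink_deg), np.deg2rad(sched.psi_deg),
        sched.n_trials, derive_seed(seed, 1))
    flagged = locus < 0
    return IntegrationEvent(replicate_id=replicate_id, locus=int(locus),
                            delta_E=float(d_e), sweep=int(sweep),
                            seed=int(seed), flagged=flagged)


def _run_replicate_proximity(spec, te, seed, sched, replicate_id, ff, conf):
    """Proximity-gated proposal: the element diffuses near the substrate and
    only bonds whose midpoint lies within the capture radius (2 sigma) of
    the element can be attempted. Slower, python-level reference mode."""
    from .sampler import mc_sweep

    capture = 2.0
    rng = np.random.default_rng(derive_seed(seed, 1))
    bend = ff.padded_bend()
    for _ in range(sched.equil_sweeps):
        _kernels.run_sweeps(conf.coords, bend, ff.bond_strength,
                            ff.bond_rest_length, ff.ev_diameter,
                            ff.attraction_eps, ff.attraction_range,
                            DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX, 0, np.pi,
                            1, int(rng.integers(2 ** 31)), False)
    attempts = 0
    sweep = 0
    n = spec.n_beads
    while attempts < sched.max_attempts:
        _kernels.run_sweeps(conf.coords, bend, ff.bond_strength,
                            ff.bond_rest_length, ff.ev_diameter,
                            ff.attraction_eps, ff.attraction_range,
                            DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX, 0, np.pi,
                            1, int(rng.integers(2 ** 31)), False)
        sweep += 1
        for _ in range(sched.attempts_per_sweep):
            attempts += 1
            # element position: near a random bead, uniform in the capture ball
            t = int(rng.integers(0, n))
            v = rng.normal(size=3)
            v *= capture * rng.random() ** (1 / 3) / np.linalg.norm(v)
            p = conf.coords[t] + v
            mid = 0.5 * (conf.coords[1:n - 2] + conf.coords[2:n - 1])
            near = np.where(np.linalg.norm(mid - p, axis=1) < capture)[0]
            if near.size == 0:
                continue
            locus = int(near[rng.integers(0, near.size)]) + 1
            d_e = proposal_delta_energy(conf, ff, locus, te, rng,
                                        n_trials=sched.n_trials,
                                        kink_deg=sched.kink_deg,
                                        psi_deg=sched.psi_deg)
            if metropolis_accept(d_e, rng):
                return IntegrationEvent(replicate_id=replicate_id,
                                        locus=locus, delta_E=float(d_e),
                                        sweep=sweep, seed=int(seed))
            if attempts >= sched.max_attempts:
                break
    return IntegrationEvent(replicate_id=replicate_id, locus=-1,
                            delta_E=float("nan"), sweep=sweep,
                            seed=int(seed), flagged=True)


def run_experiment(spec: SubstrateSpec, te: TESpec, n_replicates: int,
                   master_seed: int,
                   attempt_schedule: Optional[AttemptSchedule] = None,
                   start_index: int = 0) -> ExperimentResult:
    """Independent replicates with seeds derived from ``master_seed`` by the
    replicate counter, so runs can be split, merged and reproduced."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ff = build_forcefield(spec)
    events = []
    for i in range(n_replicates):
        rid = start_index + i
        ev = run_replicate(spec, te, derive_seed(master_seed, rid),
                           attempt_schedule=attempt_schedule,
                           replicate_id=rid, ff=ff)
        events.append(ev)
    return ExperimentResult(events=events, spec=spec, te=te,
                            n_replicates=n_replicates)


def merge_results(*results: ExperimentResult) -> ExperimentResult:
    """Concatenate replicate sets from the same substrate/element specs."""
    first = results[0]
    events = []
    for r in results:
        if r.spec != first.spec or r.te != first.te:
            raise ValueError("cannot merge experiments with different specs")
        events.extend(r.events)
    return ExperimentResult(events=events, spec=first.spec, te=first.te,
                            n_replicates=sum(r.n_replicates for r in results))
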