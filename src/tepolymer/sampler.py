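"""Metropolis Monte Carlo sampling of substrate conformations.

The move set is N single-bead displacements plus N/2 crankshaft rotations
per sweep (optionally augmented with pivot moves for fast equilibration of
long or flexible chains); every move is accepted with probability
min(1, exp(-dE/kT)), so the stationary distribution is the Boltzmann
distribution of the substrate energy. Equilibrium observables therefore
coincide with those of any properly thermostatted dynamics; no kinetic
quantities are inferred from sweep counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _kernels
from .substrate import (ForceFieldParams, PolymerConformation, SubstrateSpec,
                        build_forcefield, init_conformation)

# displacement half-width tuned for ~40% single-bead acceptance at k ~ 19
DEFAULT_MAX_DISP = 0.3
DEFAULT_CRANK_MAX = 1.0
DEFAULT_PIVOT_MAX = np.pi


def _derive_seed(rng_or_seed) -> int:
    if isinstance(rng_or_seed, np.random.Generator):
        return int(rng_or_seed.integers(2 ** 31))
    return int(rng_or_seed) % (2 ** 31)


def mc_sweep(conf: PolymerConformation, ff: ForceFieldParams, rng,
             max_disp: float = DEFAULT_MAX_DISP,
             crank_max: float = DEFAULT_CRANK_MAX,
             n_pivot: int = 0, pivot_max: float = DEFAULT_PIVOT_MAX,
             zero_temperature: bool = False) -> PolymerConformation:
    """One Monte Carlo sweep; returns a new conformation.

    ``rng`` is a numpy Generator (or an integer seed); ``zero_temperature``
    switches to the greedy limit in which only downhill moves are accepted.
    """
    if conf.n_beads != ff.n_beads:
        raise ValueError("conformation and force field sizes differ")
    out = conf.copy()
    seed = _derive_seed(rng)
    _kernels.run_sweeps(out.coords, ff.padded_bend(), ff.bond_strength,
                        ff.bond_rest_length, ff.ev_diameter,
                        ff.attraction_eps, ff.attraction_range,
                        max_disp, crank_max, n_pivot, pivot_max, 1, seed,
                        zero_temperature)
    out.metadata["sweep"] = conf.metadata.get("sweep", 0) + 1
    return out


def radius_of_gyration(conf) -> float:
    """Root-mean-square distance of beads from their centroid."""
    coords = conf.coords if hasattr(conf, "coords") else np.asarray(conf)
    if coords.shape[0] < 2:
        raise ValueError("radius of gyration needs at least 2 beads")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c * c, axis=1))))


def equilibrate(spec: SubstrateSpec, n_sweeps: int, seed: int,
                ff: Optional[ForceFieldParams] = None,
                record_every: int = 20,
                n_pivot: int = 0) -> PolymerConformation:
    """Grow a chain and run ``n_sweeps`` sweeps; deterministic given seed.

    The returned conformation carries ``energy_history`` and ``rg_history``
    arrays (one entry per ``record_every`` sweeps) in its metadata so that
    convergence to a plateau is auditable.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if ff is None:
        ff = build_forcefield(spec)
    rng = np.random.default_rng(seed)
    conf = init_conformation(spec, _derive_seed(rng), ff=ff)
    bend = ff.padded_bend()
    e_hist, rg_hist = [], []
    done = 0
    while done < n_sweeps:
        chunk = min(record_every, n_sweeps - done)
        _kernels.run_sweeps(conf.coords, bend, ff.bond_strength,
                            ff.bond_rest_length, ff.ev_diameter,
                            ff.attraction_eps, ff.attraction_range,
                            DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX,
                            n_pivot, DEFAULT_PIVOT_MAX,
                            chunk, _derive_seed(rng), False)
        done += chunk
        comps = _kernels.total_components(
            conf.coords, bend, ff.bond_strength, ff.bond_rest_length,
            ff.ev_diameter, ff.attraction_eps, ff.attraction_range)
        e_hist.append(float(sum(comps)))
        rg_hist.append(radius_of_gyration(conf))
    conf.metadata.update({
        "seed": int(seed), "sweep": int(n_sweeps),
        "energy_history": np.asarray(e_hist),
        "rg_history": np.asarray(rg_hist),
    })
    return conf


@dataclass
class EnsembleSample:
    """Conformations sampled at a fixed sweep stride from one trajectory."""

    frames: List[PolymerConformation]
    spec: Optional[SubstrateSpec]
    sweeps_per_frame: int
    master_seed: int

    def __post_init__(self):
        if not self.frames:
            raise ValueError("an ensemble needs at least one frame")
        if self.sweeps_per_frame < 1:
            raise ValueError("sweeps_per_frame (stride) must be >= 1")
        n = self.frames[0].n_beads
        if any(f.n_beads != n for f in self.frames):
            raise ValueError("all frames must share the same bead count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames[0].n_beads

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


def sample_ensemble(spec: SubstrateSpec, n_frames: int, stride: int,
                    equil_sweeps: int, seed: int,
                    ff: Optional[ForceFieldParams] = None,
                    n_pivot: int = 0,
                    pivot_max: float = DEFAULT_PIVOT_MAX,
                    n_chains: int = 1) -> EnsembleSample:
    """Equilibrate then collect ``n_frames`` frames every ``stride`` sweeps.

    With ``n_chains > 1`` the frames are split across that many independent
    trajectories (chain seeds derived from ``seed``), which decorrelates the
    slow large-scale modes far more cheaply than a longer single run.
    """
    if n_frames < 1 or stride < 1 or n_chains < 1:
        raise ValueError("n_frames, stride and n_chains must be >= 1")
    if ff is None:
        ff = build_forcefield(spec)
    frames = []
    per_chain = -(-n_frames // n_chains)  # ceil
    for chain in range(n_chains):
        take = min(per_chain, n_frames - len(frames))
        if take <= 0:
            break
        rng = np.random.default_rng(
            np.random.SeedSequence(int(seed), spawn_key=(chain,)))
        conf = init_conformation(spec, _derive_seed(rng), ff=ff)
        out = np.empty((take, spec.n_beads, 3))
        _kernels.sample_frames(conf.coords, ff.padded_bend(),
                               ff.bond_strength, ff.bond_rest_length,
                               ff.ev_diameter, ff.attraction_eps,
                               ff.attraction_range,
                               DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX,
                               n_pivot, pivot_max,
                               equil_sweeps, stride, out, _derive_seed(rng))
        frames.extend(PolymerConformation(
            out[f], {"seed": int(seed), "chain": chain,
                     "sweep": equil_sweeps + (f + 1) * stride})
            for f in range(take))
    return EnsembleSample(frames=frames, spec=spec, sweeps_per_frame=stride,
                          master_seed=int(seed))


def tangent_correlation(ensemble: EnsembleSample,
                        max_lag: Optional[int] = None) -> np.ndarray:
    """<t_i . t_{i+s}> averaged over joints i and frames, for s = 1..max_lag.

    Entry ``s - 1`` of the returned array is the correlation at lag s bonds.
    """
    coords = ensemble.coords_array()
    t = np.diff(coords, axis=1)
    t /= np.linalg.norm(t, axis=2, keepdims=True)
    n_bonds = t.shape[1]
    if max_lag is None:
        max_lag = n_bonds - 1
    max_lag = min(max_lag, n_bonds - 1)
    out = np.empty(max_lag)
    for s in range(1, max_lag + 1):
        out[s - 1] = np.mean(np.sum(t[:, :-s, :] * t[:, s:, :], axis=2))
    return out


@dataclass
class PersistenceLengthEstimate:
    lp_bp: float
    se_bp: float
    lp_bonds: float
    n_lags: int


def estimate_persistence_length(ensemble: EnsembleSample,
                                n_boot: int = 200,
                                boot_seed: int = 0,
                                corr_floor: float = 0.37
                                ) -> PersistenceLengthEstimate:
    """Persistence length from the exponential decay of tangent correlations.

    Fits log <t_i . t_{i+s}> against s over the lags where the correlation
    is above ``corr_floor`` (default 1/e, i.e. lags up to about one decay
    length, where the signal-to-noise of a finite ensemble is solid),
    converts the decay length from bonds to base pairs, and attaches a
    bootstrap-over-frames uncertainty. Requires a uniformly stiff,
    non-attracting substrate so the decay is a single exponential.
    """
    spec = ensemble.spec
    if spec is not None:
        if spec.soft_joints().size and spec.lf_bp_effective != spec.lp_bp:
            raise ValueError(
                "persistence-length estimation requires uniform stiffness")
        if spec.attraction_eps > 0:
            raise ValueError(
                "persistence-length estimation requires attraction_eps = 0")
    bp = spec.bp_per_bead if spec is not None else 1

    coords = ensemble.coords_array()
    t = np.diff(coords, axis=1)
    t /= np.linalg.norm(t, axis=2, keepdims=True)
    n_bonds = t.shape[1]

    def corr_curve(tang):
        n_lag = n_bonds // 2
        out = np.empty(n_lag)
        for s in range(1, n_lag + 1):
            out[s - 1] = np.mean(np.sum(tang[:, :-s, :] * tang[:, s:, :],
                                        axis=2))
        return out

    def fit_lp_bonds(c):
        n_use = 0
        while n_use < c.size and c[n_use] > corr_floor:
            n_use += 1
        if n_use < 3:
            if c[0] > 0:
                return -1.0 / np.log(c[0])  # freely-jointed limit
            raise RuntimeError(
                "tangent correlation does not decay resolvably; "
                "use a longer chain or more frames")
        s = np.arange(1, n_use + 1, dtype=float)
        slope, _ = np.polyfit(s, np.log(c[:n_use]), 1)
        if slope >= 0:
            raise RuntimeError(
                "tangent correlation does not decay (non-negative slope); "
                "use a longer chain")
        return -1.0 / slope

    lp_bonds = fit_lp_bonds(corr_curve(t))

    rng = np.random.default_rng(boot_seed)
    n_frames = t.shape[0]
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_frames, size=n_frames)
        try:
            boots.append(fit_lp_bonds(corr_curve(t[idx])))
        except RuntimeError:
            continue
    se_bonds = float(np.std(boots)) if len(boots) > 10 else float("nan")
    return PersistenceLengthEstimate(
        lp_bp=float(lp_bonds * bp), se_bp=float(se_bonds * bp),
        lp_bonds=float(lp_bonds), n_lags=n_bonds // 2)
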