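"""Reference polymer regimes for scaling analyses.

Three canonical states bracket the folding of chromatin at the TAD scale:

* ``ideal``     — no non-bonded interactions (theta-like / euchromatin-like),
                  R ~ L^(1/2), P_c(s) ~ s^(-3/2);
* ``saw``       — excluded volume only (swollen coil), R ~ L^nu with
                  nu ~ 3/5;
* ``collapsed`` — excluded volume plus short-range attraction well above the
                  collapse point (heterochromatin-like globule), R ~ L^(1/3).

Scaling runs use fully flexible chains (no bending stiffness) so that the
asymptotic regime is reached at accessible chain lengths; stiffness only
shifts the onset of scaling, not the exponent. Ideal and self-avoiding
ensembles are decorrelated with pivot moves; collapsed globules are grown
directly at liquid-like density and relaxed with local moves, since pivots
are always rejected inside a dense globule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .sampler import (DEFAULT_CRANK_MAX, DEFAULT_MAX_DISP, EnsembleSample,
                      radius_of_gyration)
from .substrate import ForceFieldParams, PolymerConformation, _grow_chain
from .integration import derive_seed
from .observables import ScalingCurve

REGIMES = ("ideal", "saw", "collapsed")

COLLAPSED_EPS = 1.5        # attraction depth, comfortably above collapse
_GROWTH_DENSITY = 0.55     # beads / sigma^3 for confined globule growth


def regime_forcefield(regime: str, n_beads: int) -> ForceFieldParams:
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    bend = np.zeros(n_beads - 2)
    if regime == "ideal":
        return ForceFieldParams(bend_constants=bend, ev_diameter=0.0)
    if regime == "saw":
        return ForceFieldParams(bend_constants=bend)
    return ForceFieldParams(bend_constants=bend,
                            attraction_eps=COLLAPSED_EPS)


def regime_ensemble(regime: str, n_beads: int, n_frames: int, seed: int,
                    ) -> EnsembleSample:
    """Equilibrated conformations of one chain length in a given regime."""
    ff = regime_forcefield(regime, n_beads)
    rng = np.random.default_rng(seed)
    bend = ff.padded_bend()

    if regime == "collapsed":
        radius = 1.05 * (3.0 * n_beads / (4.0 * np.pi * _GROWTH_DENSITY)) ** (1.0 / 3.0)
        coords = _grow_chain(n_beads, bend, ff.ev_diameter, rng,
                             confine_radius=radius)
        equil, stride, n_pivot = 600, 15, 0
    else:
        coords = _grow_chain(n_beads, bend, ff.ev_diameter, rng)
        equil, stride, n_pivot = 10, 2, max(n_beads // 4, 10)

    out = np.empty((n_frames, n_beads, 3))
    _kernels.sample_frames(coords, bend, ff.bond_strength,
                           ff.bond_rest_length, ff.ev_diameter,
                           ff.attraction_eps, ff.attraction_range,
                           DEFAULT_MAX_DISP, DEFAULT_CRANK_MAX,
                           n_pivot, np.pi, equil, stride, out,
                           int(rng.integers(2 ** 31)))
    frames = [PolymerConformation(out[f], {"seed": int(seed), "sweep": f})
              for f in range(n_frames)]
    return EnsembleSample(frames=frames, spec=None, sweeps_per_frame=stride,
                          master_seed=int(seed))


def size_scaling_curve(regime: str, lengths: Sequence[int], n_frames: int,
                       seed: int) -> ScalingCurve:
    """R(L) = sqrt(<R_g^2>) across chain lengths, with frame-to-frame SEs."""
    lengths = sorted(int(x) for x in lengths)
    if len(lengths) < 2:
        raise ValueError("at least two chain lengths are required")
    r_mean, r_se = [], []
    for i, length in enumerate(lengths):
        ens = regime_ensemble(regime, length, n_frames,
                              derive_seed(seed, i))
        rg2 = np.array([radius_of_gyration(f) ** 2 for f in ens.frames])
        r = np.sqrt(rg2.mean())
        se = 0.5 * rg2.std(ddof=1) / np.sqrt(rg2.size) / r
        r_mean.append(r)
        r_se.append(se)
    return ScalingCurve(abscissa=np.asarray(lengths, dtype=float),
                        ordinate=np.asarray(r_mean),
                        ordinate_se=np.asarray(r_se))
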