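# Methods

This note defines the model implemented by `tepolymer`, the default
parameters and why they were chosen, what the generator does and does not
capture, and the numerical methods behind the statistics.

## 1. Model

### 1.1 Substrate

The host DNA is a linear bead-spring chain of `N` beads (default 200), each
bead representing `bp_per_bead` base pairs (default 8 bp, so one bead
diameter σ ≈ 2.7 nm of B-DNA and the default substrate is 1.6 kbp). Energies
are in units of kT, lengths in units of σ. The energy has four terms:

- **Bonds** — harmonic, `E_bond = k_b (r - r_0)^2` with `r_0 = 1` and
  `k_b = 200`, stiff enough that bond-length fluctuations stay below ~5% of
  a bead diameter and never contribute to conformational statistics.
- **Bending** — discretised Kratky–Porod (worm-like chain) penalty per
  interior joint, `E_bend = Σ_i k_i (1 - cos θ_i)`. The stiffness mapping is
  `k = l_p / (bp·per·bead)` in kT: for a discrete WLC the exact persistence
  length is `-1/ln(coth k - 1/k)` bonds, which approaches `k` bonds at
  large `k`; at the default `k = 18.75` the two differ by ~2.5%, well inside
  the estimator's own uncertainty, so the transparent linear mapping is used
  as the constructor and the exact relation (`kratky_porod_mean_cos`) as the
  test oracle.
- **Excluded volume** — WCA (purely repulsive, truncated-shifted
  Lennard-Jones) of diameter σ, cut at `2^(1/6) σ`. Setting the diameter to
  0 disables all non-bonded terms (the ideal-chain regime).
- **Attraction** (off by default) — a depth-ε square-ish well: `-ε` inside
  the WCA minimum, tapered to zero at 1.8 σ by a `cos²` ramp (continuous,
  no force discontinuity at the cutoff). Used only for the collapsed regime.

*Soft sites* are short runs of joints (default 1 joint) whose stiffness is
set from a reduced rigidity `l_f ≤ l_p`, modelling locally denatured or
mechanically stressed DNA. The default layout places one soft joint every 20
beads (nine sites on the 200-bead substrate), far enough apart that their
biased footprints never touch.

### 1.2 Sampling

Metropolis Monte Carlo with a sweep of `N` single-bead displacement attempts
(uniform cube of half-width 0.3 σ, ≈ 40% acceptance at the default
stiffness) plus `N/2` crankshaft rotations (random interior arc of 2–4
beads rotated about its anchor axis). Both moves are local, so energy
differences are evaluated locally; kernels are `numba`-compiled and seeded
explicitly. For flexible or long chains (the scaling regimes) pivot moves
(tail rotation about a random bead) are added during sampling; they
decorrelate global modes orders of magnitude faster but are always rejected
inside dense globules, so the collapsed regime relies on local moves from a
near-equilibrium start instead.

Initial conformations are grown bead by bead with each joint angle drawn
from its own Boltzmann bending density (exact inverse-CDF sampling of
`p(cos θ) ∝ exp(k cos θ)`), rejecting sterically clashing placements, so
chains start at conformational equilibrium up to excluded-volume
corrections. Equilibration sweeps on top of that are short and auditable
(`equilibrate` records energy and gyration-radius histories).

### 1.3 Integration

Integration is modelled as a quasi-equilibrium Metropolis reconnection with
no energy source: a host bond `(ℓ, ℓ+1)` is opened and rewired through the
invading element, and the attempt is accepted with probability
`min(1, exp(-ΔE))`. An accepted insertion is final (the element is never
excised); a replicate ends at its first acceptance.

Only the element's two *junction beads* are represented explicitly. They
are placed at rest bond length from the two host anchor beads, splayed by a
kink angle of 60° off the old bond axis with an azimuthal opening of 70°
between the two junction directions. These numbers are geometric, not
fitted: 60° is the opening at which unit-length junction bonds clear the
host beads' excluded volume, and the 70° azimuthal spread keeps the two
junction beads ≈ 1 σ apart. ΔE is minimised over 8 random azimuths of this
construction (a relaxed trial placement). The element interior is implicit:
its internal energy is identical before and after reconnection and cancels
from ΔE, which also makes ΔE independent of the element length. What
remains in ΔE is exactly the mechanism under study — bending the host at
the two joints flanking the insertion, plus sterics — so the flexibility
bias is isolated by construction.

A replicate alternates one relaxation sweep with 20 insertion attempts at
uniformly random *interior* bonds (loci `1 … N-3`). Terminal bonds are
excluded because they lack one flanking joint, making them structurally
cheaper; including them would add a boundary artifact unrelated to soft
sites. A replicate that reaches the attempt cap (default 10⁶) without an
acceptance is flagged, excluded from profiles and counted. An alternative
proximity-gated proposal mode (attempts only at bonds within 2 σ of a
diffusing element) is implemented for comparison; the uniform mode is the
default because it isolates energetics from transport.

### 1.4 Observables

- **Frequency profile** — per-locus fraction of accepted events pooled over
  unflagged replicates, with binomial standard errors.
- **Enhancement** — summed soft-locus frequency over the uniform-random
  expectation `n/N`, where the soft footprint counts *both* bonds adjacent
  to each soft joint (an insertion at a bond deforms both flanking joints)
  and `N` is the number of insertable loci (197 for the default substrate).
  With these conventions the uniform null is exactly 1.
- **Enhancement vs softening** — least squares on `log(enhancement)`
  against the rigidity drop `l_p - l_f`; the fit reports the rate per bp
  and flags the most-softened point when it sits clearly above the line
  (faster-than-exponential onset).
- **Scaling** — `R(L) = sqrt(⟨R_g²⟩)` across chain lengths and contact
  probability `P_c(s)` within one length; log–log fits give the Flory
  exponent `ν` (contact mode: slope/(-3)). The contact route is used for
  the ideal regime, where `P_c ~ s^(-3ν)` is exact; for self-avoiding and
  collapsed chains the size route is used, since the interior contact
  exponent of a SAW is a different universal number than `3ν`.
- **Re-integration distance** — the analytic law `p(s) ∝ s^(-3ν)` over a
  genomic window, normalised; medians order as collapsed > ideal >
  self-avoiding (condensed chromatin favours long-range re-entry).

## 2. Default parameters

| parameter | default | rationale |
|---|---|---|
| `n_beads` | 200 | 1.6 kbp substrate at 8 bp/bead; bending-dominated scale |
| `bp_per_bead` | 8 | resolves bending at sub-persistence-length scales |
| `lp_bp` | 150 | B-DNA persistence length |
| `lf_bp` grid | 150, 120, 90, 60 | spans no-softening to strong softening |
| soft spacing | 20 beads | 9 isolated 1-bead sites; footprints never merge |
| `k_b` | 200 kT/σ² | near-inextensible bonds |
| kink / azimuth | 60° / 70° | geometric steric clearance (see §1.3) |
| trials per attempt | 8 | relaxed placement; ΔE within ~0.1 kT of dense-scan minimum |
| attempts/sweep | 20 | attempt rate slow vs relaxation of local modes |
| attempt cap | 10⁶ | flags pathologies without censoring the stiff null |
| replicates | 1000 | enhancement SE ≈ 0.1 at the null |
| collapsed ε | 1.5 kT | well above the collapse point; dense, local-move-equilibrable globules |
| scaling lengths | 50–400 (40–320 collapsed) | asymptotic regime at tractable cost |

Scaling runs use fully flexible chains (`k = 0`): stiffness shifts the onset
of scaling but not the exponent, and flexible chains reach the asymptotic
regime at these lengths. Collapsed globules are grown directly inside a
sphere at density 0.55 beads/σ³ and relaxed for 600 sweeps; equilibration
was verified by gyration-radius plateau blocks.

## 3. What the generator does and does not capture

The model isolates one mechanism: the bending-energy cost of insertion on a
heterogeneously flexible substrate in thermal equilibrium. It does not
include protein targeting (integrase/transposase chromodomains, tethering),
ATP-driven steps, sequence-specific recognition, torsional stress or
supercoiling, nucleosomes, or the genome-scale chromatin organisation a
Hi-C-informed model would carry. The element interior is not simulated;
consequently element-length effects (loop entropy of large inserts) are out
of scope. The quasi-equilibrium Metropolis rule means *relative* frequencies
across loci are meaningful; absolute integration rates and sweep counts are
not kinetic quantities.

## 4. Numerical and statistical methods

- **Energy difference correctness** — the local ΔE used by the insertion
  kernel is tested against an independently hand-coded global
  `E(post) - E(pre)` at every locus to 10⁻⁸ kT.
- **Persistence length** — tangent correlations `C(s) = ⟨t_i·t_{i+s}⟩`
  averaged over joints, frames and 25 independent chains; log-linear fit
  restricted to lags with `C(s) > 1/e` (within one decay length, where a
  finite ensemble has solid signal-to-noise — unrestricted fits are biased
  low by slow-mode noise at large lags); uncertainty by bootstrap over
  frames. Independent chains matter: a single trajectory's large-scale
  modes decorrelate too slowly for unbiased large-lag statistics.
- **Uniformity test** — chi-squared goodness of fit of event counts over
  the insertable loci (scipy).
- **Exponent fits** — `numpy.polyfit` on log–log data with covariance;
  fit windows exclude the monomer scale (`s < 4`) and chain-end effects
  (`s > L/4`) for contact curves.
- **Seeding** — all randomness derives from explicit master seeds through
  `numpy.random.SeedSequence` spawn-key counters (`derive_seed`); seeds stay
  below 2³¹ for portability into the compiled kernels. Replicate streams
  are independent and position-addressable, so experiments can be split,
  merged (`merge_results`) and reproduced byte-identically.
- **Statistical test design** — distributional tests in the suite compare
  simulation output against closed-form oracles (Langevin `⟨cos θ⟩`,
  discrete-WLC end-to-end distance, Boltzmann bond/angle marginals,
  Bernoulli acceptance) using sample sizes and strides chosen so that the
  Monte Carlo error, including autocorrelation, is small against the
  asserted tolerance. On very small chains the crankshaft move preserves
  the joint angle, so those tests use long strides across many independent
  chains.

## 5. Decisions on under-determined points

Where the underlying physical picture leaves freedom, this package chose:

- junction-bead insertion geometry (kink 60°, azimuth 70°) from steric
  geometry alone (§1.3);
- interior-loci-only attempts, to remove the chain-end boundary artifact;
- a 2-bonds-per-soft-joint enhancement footprint, matching what the energy
  actually biases, with the insertable-locus count as the null denominator;
- soft sites every 20 beads — isolated sites, clean single-site statistics;
- collapsed-regime depth ε = 1.5 kT with confined growth at 0.55 beads/σ³ —
  deep enough to collapse decisively, dilute enough to equilibrate with
  local moves (verified by R_g plateaus);
- uniform-random attempt placement as the default proposal, with the
  proximity-gated variant available but not used for headline numbers.
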