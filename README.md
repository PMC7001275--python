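# tepolymer

Coarse-grained polymer Monte Carlo model of transposable-element (TE) and
retroviral DNA integration into heterogeneously flexible DNA substrates.

## The scientific problem

Where a mobile genetic element lands is not uniform along the genome. One
physical contribution, separate from protein targeting, is the mechanics of
the host DNA itself: integration requires bending the host duplex at the
insertion point, so locally flexible stretches (denaturation bubbles,
R-loops, nucleosome-depleted or stressed DNA) are energetically cheaper
targets than stiff B-DNA. `tepolymer` quantifies this bias with a
bead-spring polymer model:

- the host is a chain of beads (default 200 beads, 8 bp/bead, a 1.6 kbp
  substrate) with worm-like-chain bending rigidity set by a persistence
  length `l_p` (default 150 bp), interrupted by *soft sites* of reduced
  rigidity `l_f ≤ l_p`;
- the substrate is equilibrated by Metropolis Monte Carlo (single-bead +
  crankshaft moves, optional pivots);
- integration is a quasi-equilibrium Metropolis reconnection: a host bond is
  opened and rewired through the element's two junction beads, accepted with
  probability `min(1, exp(-ΔE/kT))`; the element is stuck once inserted;
- over many independent replicates, per-locus integration frequencies and
  the *enhancement* of the soft sites (their summed frequency over the
  uniform-random share `n/N`) measure the flexibility bias.

A second set of observables connects polymer state to re-integration range
for cut-and-paste elements: size scaling `R ~ L^ν` and contact probability
`P_c(s) ~ s^(-3ν)` with `ν = 1/3` (collapsed), `1/2` (ideal), `3/5`
(self-avoiding), and the resulting analytic re-integration distance law
`p(s) ∝ s^(-3ν)`.

See `docs/methods.md` for the model definition, parameter choices and
numerical methods.

## Worked example

```python
import tepolymer as tp

# 200-bead substrate, l_p = 150 bp, nine 1-bead soft sites with l_f = 60 bp
spec = tp.SubstrateSpec(n_beads=200,
                        soft_indices=tp.default_soft_indices(200),
                        lf_bp=60.0)

# 200 independent integration replicates
result = tp.run_experiment(spec, tp.TESpec(), n_replicates=200, master_seed=7)
profile = tp.frequency_profile(result)
enh = tp.soft_site_enhancement(profile, spec.soft_loci(), n_insertable=197)
print(f"soft-site enhancement {enh.value:.2f} +/- {enh.se:.2f}")
# soft-site enhancement 3.61 +/- 0.36
```

The same spec with `lf_bp=150.0` (no softening) gives an enhancement
statistically indistinguishable from 1 — soft sites then capture exactly
their random share.

Persistence-length recovery from tangent correlations:

```python
spec = tp.SubstrateSpec(n_beads=200)  # uniform l_p = 150 bp
ens = tp.sample_ensemble(spec, n_frames=500, stride=10, equil_sweeps=150,
                         seed=42, n_chains=25)
est = tp.estimate_persistence_length(ens)
print(f"l_p = {est.lp_bp:.1f} +/- {est.se_bp:.1f} bp")
# l_p = 150.5 +/- 2.2 bp
```

## Command line

```bash
# integration experiment over a grid of soft-site rigidities
tepolymer simulate --n-replicates 1000 --lf-grid 150,120,90,60 \
    --seed 1 --out runs/softsites

# polymer scaling in one regime (ideal | saw | collapsed)
tepolymer scaling --regime saw --lengths 50,100,200,400 --out runs/saw
```

`simulate` writes, per rigidity value, the event table (TSV), the accepted
events as BED intervals on the contig `substrate`, the per-locus frequency
profile, plus an enhancement summary, an exponential enhancement-vs-softening
fit in the log, and a `manifest.txt` that fully reproduces the run. All
options can also come from a flat key-value YAML file via `--config`;
explicit flags win.

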