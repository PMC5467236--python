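# holoflex

Quantitative single-particle geometry analysis for flexible ring-shaped
holoenzymes such as CaMKIIα, built around a calibrated synthetic
conformational-ensemble generator.

CaMKIIα holoenzymes consist of a rigid central hub complex (radius
≈ 55 Å) carrying twelve — rarely fourteen — kinase domains, each tethered
by an intrinsically disordered linker.  In projection images each
subunit is characterised by two lengths: the **kinase radius of
extension** r (hub centre to kinase outer edge, i.e. centre-to-centre
distance + 22.5 Å for the mean kinase radius) and the **clockwise
neighbour separation** d (centre-to-centre).  The basal-state population
forms a continuum: radii are approximately Gaussian, r̄ ≈ 127 ± 16 Å over
77–175 Å; separations centre near 58 ± 15 Å, with ≈20 % below the 45 Å
steric-contact threshold (transient kinase dimers) and < 3 % of radii
below 100 Å (compact, hub-docked kinases).

holoflex is for structural biologists and method developers who want a
tested, reproducible implementation of this analysis: the measurement
rules, the distribution statistics and pair classification, the
closed-form physical models that interpret them —

* random-coil tether extension  b·√N  (3.5 Å · √45 ≈ 23.5 Å),
* linker decomposition  r̄ − 55 Å (hub) − 45 Å (kinase diameter) ≈ 27 Å,
* torus local concentration  c = n / (N_A · 2π²Rr²)  with R = 126 Å,
  r = 49 Å → 3.3 mM for 12 kinases,

— plus a 2D particle renderer/detector for image-level round trips, the
three-filter sensitized-emission FRET correction
(FRETc = raw − 0.02093·donor − 0.09484·acceptor, with donor
normalisation and 4–11× acceptor/donor gating) and variable-slope Hill
dose-response fitting.  Because no experimental data ships with the
package, a seeded generator produces ensembles with exactly the
statistical structure above, and every pipeline stage is validated as
parameter recovery against that known ground truth.

## Worked example

```python
import holoflex as hf

cfg = hf.EnsembleConfig(n_particles=1000, seed=42)   # calibrated defaults
particles = hf.generate_ensemble(cfg)
ms = hf.measure_ensemble(particles)

r = hf.pooled_radii(ms)
s = hf.pooled_separations(ms)
pcd = hf.pair_count_distribution(ms)
rho, _, _ = hf.radius_separation_correlation(ms)

print(f"kinase radius     : {r.mean():.1f} +/- {r.std(ddof=1):.1f} A")
print(f"separation        : {s.mean():.1f} +/- {s.std(ddof=1):.1f} A")
print(f"separations <45 A : {100*hf.fraction_below(s, 45):.1f} %")
print(f"radii <100 A      : {100*hf.fraction_below(r, 100):.2f} %")
print(f"zero-pair particles: {100*pcd.frequencies[0]:.1f} %")
print(f"linker extension  : {hf.mean_linker_extension(r.mean()):.1f} A "
      f"(random-coil prediction {hf.random_coil_extension():.1f} A)")
print(f"local concentration: {hf.local_concentration():.2f} mM")
```

prints

```
kinase radius     : 127.4 +/- 15.1 A
separation        : 58.0 +/- 14.6 A
separations <45 A : 20.8 %
radii <100 A      : 2.59 %
zero-pair particles: 9.2 %
linker extension  : 27.4 A (random-coil prediction 23.5 A)
local concentration: 3.34 mM
```

The measured population reproduces the calibration targets: a ~127 Å
mean extension whose decomposition leaves a ~27 Å linker (close to the
ideal-chain prediction for a 45-residue tether), a fifth of neighbour
separations within steric-contact distance, a compact fraction below
3 %, about 10 % of particles with no kinase pairs, and a millimolar
local kinase concentration in the occupancy torus — high enough for a
weak (sub-mM) dimerization affinity to populate the paired state.

The same pipeline runs from the shell:

```sh
holoflex synth --n-particles 1000 --seed 42 --out particles.csv
holoflex stats --in particles.csv --out summary.json
holoflex physics coil --n 45
holoflex physics concentration -R 126 -r 49 --n 12
holoflex synth --n-particles 50 --seed 1 --mode angular --out ang.csv
holoflex render --in ang.csv --out imgs/ && holoflex detect --in imgs/ --out coords.csv
```

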