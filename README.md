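# helix3c

Polymer-physics modelling of chromatin contact-frequency decay inside
topologically associating domains (TADs), for people analysing
quantitative-3C profiles or binned Hi-C maps: fit simple polymer models to
contact frequency versus genomic separation, test for the supranucleosomal
modulation that signals constrained higher-order dynamics, and batch-fit
"virtual 3C" slices of a Hi-C matrix stratified by epigenetic domain.

## The models

The cross-linking (contact) frequency between two chromatin sites
separated by *s* kb is modelled with a combined Freely-Jointed-Chain /
worm-like-chain form

```
X(s) = K · 0.53 · β^(−3/2) · exp(−2/β²) · (L·S)^(−3)
```

where *K* is the cross-linking efficiency (arbitrary relative scale), *L*
the linear mass density (nm of fiber per kb; compaction) and *S* the Kuhn
statistical segment (kb; flexibility).  The reduced separation β encodes
the higher-order organisation:

* **unconstrained chain** — `β = s/S`: no supranucleosomal constraint;
* **statistical helix** — constraints fold the fiber, on average, into a
  helix of mean diameter *D* and mean pitch *P* (nm):

  ```
  β = sqrt( D²·sin²[πLs / sqrt(π²D² + P²)] + P²L²s² / (π²D² + P²) ) / (L·S)
  ```

  One helix turn contains `Sh = sqrt((πD)² + P²)/L` kb of DNA, which is
  also the genomic period of the contact-frequency modulation.

Globule power laws `X = k·s^α` (equilibrium globule α = −3/2, crumpled
globule α = −1, free α when fitted) are provided for model discrimination,
and `L` can be derived from a nucleosome repeat length via the packing
ratio of 6 nucleosomes per 11 nm (NRL 194 bp → 9.45 nm/kb; 189 bp →
9.70 nm/kb).

Fitting is weighted nonlinear least squares (weights 1/SEM² when SEMs are
available) with a deterministic multi-start grid for the oscillatory helix
objective; supranucleosomal separation domains are compared with
Mann–Whitney U tests; virtual-3C profiles are extracted from 5-kb binned
contact maps (25-kb anchors, one-sided 400-kb span), filtered for TAD
containment, classified by epigenetic domain (D1 active/red, D2
unmarked/black, D3 Polycomb/blue, D4 HP1/green) and batch-fitted with the
unconstrained model.  A synthetic-data module generates every input with
known ground truth.

## Worked example

```python
import numpy as np
import helix3c as h3c

truth = h3c.LocalChromatinParams(K=1.07, L=9.70, S=2.7)
helix = h3c.HelixParams(D=255.0, P=201.0)

s = np.arange(5.0, 251.0, 5.0)
profile = h3c.simulate_3c_profile(
    truth, s, h3c.NoiseSpec(sigma_log=0.1, seed=4),
    helix=helix, fixed_L=truth.L)

fit = h3c.fit_helix(profile)
print(f"S = {fit.params['S']:.2f} kb  D = {fit.params['D']:.0f} nm  "
      f"P = {fit.params['P']:.0f} nm  Sh = {fit.sh_kb:.1f} kb  "
      f"R2 = {fit.r_squared:.3f}")
```

prints

```
S = 2.95 kb  D = 259 nm  P = 226 nm  Sh = 87.2 kb  R2 = 0.996
```

i.e. from one noisy simulated gene-rich profile the helix fit lands close
to the generating flexibility (S = 2.7 kb), helix diameter (255 nm) and
pitch (201 nm), with one helix turn holding ~85 kb of DNA; averaging over
replicates tightens the estimates (see the Monte-Carlo recovery test).  The same API drives
the CLI: `helix3c simulate`, `helix3c fit3c`, `helix3c powerlaw`,
`helix3c domstats`, `helix3c virtual3c`.

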