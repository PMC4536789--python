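# Methods

## Model

Contact (cross-linking) frequency between chromatin sites *s* kb apart is
modelled as

    X(s) = K · 0.53 · β^(−3/2) · exp(−2/β²) · (L·S)^(−3)

a combined Freely-Jointed-Chain / Kratky–Porod worm-like-chain form.  The
constants 0.53, −3/2 and −2 are part of the model, not fitting parameters.
The reduced separation β is either `s/S` (unconstrained chain) or the
statistical-helix form

    β = sqrt( D² sin²[πLs/√(π²D²+P²)] + P²L²s²/(π²D²+P²) ) / (L·S)

which describes the *average* effect of supranucleosomal constraints as if
the fiber were statistically folded into a helix of mean diameter D and
mean pitch P (both nm).  The helix is an effective, population-averaged
description — no claim is made about individual conformations.  Setting
D = 0 recovers the unconstrained chain exactly, so the two models are
nested.  One helix turn contains `Sh = √((πD)² + P²)/L` kb; Sh is also the
exact genomic period of the sin² modulation.

Parameters and units:

| parameter | meaning | units | typical values |
|---|---|---|---|
| K | cross-linking efficiency (assay scale) | relative | ~1 (reported ×10³ for 3C-qPCR, ×10⁹ for Hi-C) |
| L | linear mass density (compaction) | nm/kb | 9.4–10.8 |
| S | Kuhn segment (flexibility) | kb | 2.5–5.5 |
| D | mean helix diameter | nm | 200–300 |
| P | mean helix pitch | nm | 150–400 |

`L` can be fixed from a nucleosome repeat length: `L = (1000/NRL)·(11/6)`
nm/kb, using the packing ratio of 6 nucleosomes per 11 nm of fiber.  For a
TKO-like NRL of 174 bp this evaluates to 10.536 (≈10.54 at two decimals);
the package always reports the exact value.  `Sh` is likewise reported at
full precision and rounded only for display, so values recomputed from
*rounded* fitted parameters can differ by ±1 kb from a printed table.

Globule power laws `X = k·s^α` (equilibrium α = −3/2, crumpled/fractal
α = −1) are implemented only as power-law signatures for model
discrimination; no globule ensemble is simulated.

Numerical guard: for β < 10⁻³ the exponential underflows and the analytic
limit X → 0 is returned directly.

## Estimation

Weighted nonlinear least squares, minimising `Σ wᵢ(Xᵢ − model(sᵢ))²`.

* **Weights.**  `wᵢ = 1/SEMᵢ²` when every observation carries a positive
  SEM, uniform otherwise (configurable).  Inverse-variance weighting is
  the conventional reading of a "(weighted)" least-squares fit; note that
  with few replicates SEM estimates are noisy, so occasional points draw
  very large weights — the uniform mode is the robust alternative.
* **Optimizer.**  Bounded trust-region least squares (K ≥ 0, S > 0,
  D ≥ 0, P > 0) with Jacobian-based variable scaling.  Residuals are
  normalised by the largest weighted frequency so that gradient-based
  stopping rules behave identically whatever the (arbitrary) frequency
  scale.  Each multi-start run has a 1 000-evaluation exploration budget;
  the best solution is then polished with unbounded Levenberg–Marquardt
  (10 000 evaluations), which converges much tighter on narrow parameter
  ridges.  Tolerances 10⁻¹² (ftol/xtol/gtol).  Everything is
  deterministic: same profile + options ⇒ bit-identical result.
* **Multi-start for the helix fit.**  The objective is oscillatory in
  (D, P).  Starts: D ∈ {100, 200, 300, 400} × P ∈ {50, 150, 250, 400} ×
  S ∈ {2, 4}, K at its closed-form optimum for each start, plus a
  degenerate-helix start (D = 0) seeded from the nested unconstrained
  fit — this guarantees the helix optimum is never worse than the
  unconstrained one.
* **Standard errors.**  Asymptotic, `(JᵀWJ)⁻¹` scaled by residual
  variance at the optimum (pseudo-inverse, so rank-deficient directions
  yield large, not spurious, errors).  R² is `1 − SSres/SStot` on the
  unweighted frequencies and may be negative.
* **Identifiability.**  In the unconstrained model K and L enter only
  through the amplitude `K·(L·S)^(−3)`.  With L free (the virtual-3C
  fits) only that amplitude and S are identifiable; the reported (K, L)
  split depends on the optimizer start (default L start 10.5 nm/kb).
  Recovery tests and cross-class comparisons therefore rest on S and the
  amplitude; per-class K/L medians should be read as start-anchored
  conventions, exactly as in any 3-parameter `nls` fit of this model.
* **Power law.**  Fitted on the linear scale (NLS), not by log-log
  regression; a log-log regression only provides the starting point.
  With multiplicative noise and known SEMs the default weighting makes
  this equivalent in precision to a log-scale fit.

Pooling: 3C-style fits are performed on observations pooled across
anchors within a TAD class, matching how compiled per-class profiles are
assembled.

## Supranucleosomal domain statistics

Separation axes are partitioned into consecutive left-closed right-open
domains ([a, b); a boundary value belongs to the upper domain — the
convention is fixed here because "35–70 kb" leaves 35 ambiguous).  Two
built-in schemes: 35-kb steps to 250 kb (gene-rich/gene-poor) and 25-kb
steps to 150 kb (gene-desert); custom boundaries are config data.
Adjacent domains are compared with two-sided Mann–Whitney U tests (a
one-sided flag exists): exact null distribution when n₁+n₂ ≤ 12 with no
ties, otherwise normal approximation with tie and continuity correction.
No multiple-testing correction is applied across the five adjacent pairs
(raw p-values are reported).  Star annotations follow two conventions:
"fig2" (** p<0.05, *** p<0.01) and "fig4" (* p<0.05, ** p<0.01,
*** p<0.001).

A note on the modulation signature: the sin² modulation has period
exactly Sh, but the *raw decay curve's* local maxima are dragged to
smaller separations by the decaying envelope (for mESC-like parameters
the two curve maxima are ~79 kb apart against Sh = 85 kb), and domain
grids misaligned with Sh/2 need not alternate strictly.  Period checks
therefore use the isolated modulation component
(`helix_modulation_component`).

## Virtual 3C

From a normalized 5-kb binned contact map (one chromosome per map,
upper-triangular storage):

* **Extraction.**  One profile per 25-kb anchor window (5 bins), stepped
  every 5 kb, over a one-sided 400-kb downstream span; anchors whose span
  exceeds the chromosome are dropped (no partial windows), giving exactly
  `n_bins − 80 + 1` profiles on a gap-free chromosome.  The profile value
  at separation d is the **mean of the five bin pairs at constant genomic
  offset d** (one per anchor bin).  This keeps the nominal separation
  equal to the true pair separation, so fits are unbiased; the
  alternative fixed-target-bin rule (mean of the five anchor-bin →
  single-target values) mixes true separations d−20…d under one label —
  a ~2× distortion on an s^(−3/2) decay — and is provided only as
  `aggregation="target_bin"`.  A centred (two-sided) window is a noted
  alternative reading; one-sided downstream is implemented.
* **TAD filter.**  A profile is kept when its anchor window plus a
  minimum downstream span lies inside a single TAD.  The generic filter
  defaults to 65 kb; the pipeline default equals the fit span (70 kb) so
  that *no fitted bin pair can cross a TAD border* (window 25 kb + fit
  span 70 kb bounds the genomic reach of every fitted pair).
* **Classification.**  Majority base-pair overlap of the anchor window
  with the epigenetic track (D1 red/active, D2 black/unmarked, D3
  blue/Polycomb, D4 green/HP1); exact ties or zero overlap ⇒ unassigned
  and excluded from domain statistics.
* **Fitting.**  Unconstrained model, K, L, S free, uniform weights, on
  all points with separation ≤ 70 kb (14 five-kb bins — the
  small-separation points carry most of the information on S).
  Non-convergent fits are recorded, not raised; records with R² outside
  (0, 1) are filtered out and the fraction of retained fits with
  R² > 0.5 is reported.
* **Summaries.**  Per chromosome × domain medians of K, L, S with
  pairwise two-sided Wilcoxon rank-sum p-values (skipped below 2 records
  per group); chromosomes can be excluded from summaries (e.g. a
  dosage-compensated X).

## Synthetic data

The generator produces every input with known truth, seed-deterministic
via `numpy.random.default_rng`:

* **3C profiles** — `X_model(s)·exp(ε)`, ε ~ N(0, σ²), mirroring a
  scale-proportional qPCR error; three independent assays × three
  technical replicates by default, reported as the mean of assay means
  with the SEM across assay means.  (Multiplicative noise has mean
  `exp(σ²/2)`; at the default σ = 0.1 this is a 0.5 % scale bias absorbed
  by K.)
* **Genomes** — chromosomes tiled by consecutive TADs with log-normal
  sizes (fly-like median 70 kb or mouse-like 840 kb presets), rounded to
  whole 5-kb bins (min 2), each TAD carrying one epigenetic class drawn
  from configurable proportions (default D1 25 %, D2 45 %, D3 15 %,
  D4 15 %) or assigned cyclically for deterministic class counts.
* **Contact maps** — expected in-TAD value = the class's unconstrained
  decay at the pair separation (cross-class pairs: geometric mean of the
  two ends); pairs crossing a TAD border are multiplied by a hard
  attenuation factor (default 0.1, emulating strongly insulated
  borders).  Noise: log-normal (default σ = 0.1), Poisson counts at a
  given depth, or none.  Default per-class truths follow fly-like
  chromatin (active least compact/most flexible, HP1 stiffest).

What the generator does **not** emulate: locus-specific loops or
boundary elements (borders are plain attenuation multipliers), mappability
or coverage gaps, matrix-balancing artefacts, distance-dependent noise
structure, polymer dynamics (no bead-spring or binder simulation), or
replicate-to-replicate assay drift.  Passing recovery tests therefore
show the estimation machinery is correct and calibrated under the stated
noise model — not that real Hi-C data meet these assumptions.

## Problem sizes used in the test-suite experiments

Recovery experiments run at desk scale, chosen to give stable medians
while keeping the suite quick: 50-separation profiles spanning ~3 helix
turns; 100 Monte-Carlo replicates at 10 % noise for helix-parameter
recovery; 200 replicates (n = 50 points, 5 % noise) per globule slope;
1 000 null draws for rank-test calibration; and a 4-Mb two-class genome
(~20 TADs of ~200 kb, ≥ 190 fitted profiles per class, 10 % map noise)
for the end-to-end virtual-3C check.

## Known limitations

* K–L non-identifiability in free-L fits (above) makes per-class K and L
  medians start-anchored; only S and the amplitude are fully identified.
* Inverse-SEM² weighting with very few replicates can let a few
  low-SEM points dominate; prefer uniform weights for 3-replicate data
  unless SEMs are well estimated.
* The helix model describes population-average constraints; fitted D and
  P are effective quantities with no single-cell interpretation.
* Virtual-3C profiles are one-sided downstream; upstream or centred
  windows are not produced.
* No Bayesian inference, bootstrap intervals, hierarchical multi-profile
  fits, TAD calling or matrix normalization — TADs and normalized maps
  are inputs.
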