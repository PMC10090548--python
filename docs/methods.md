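# Methods

## Model

The package predicts the fate of a population of nanoparticles coated with
extruded glioblastoma cell membrane. Each particle displays `n` receptor
species; every binding event engages `k ≤ n` of them (the *degree of
interaction*), of which `k_F` are captured by secreted soluble factors and
the remaining `k − k_F` by one cell surface. The model's assumptions:

1. a combination interacts with GCC only, GCC+F, NHC only, NHC+F, or F only;
2. the cell branch is exclusive — a combination never touches GCC and NHC
   simultaneously;
3. at least one surface protein interacts (an all-inert input is an error,
   `DegenerateModelError`);
4. `k_F = k` means no cell contact (the F-only branch, emitted once, not per
   cell branch);
5. factor–factor interactions are ignored;
6. every other contact contributes no directional mass (represented by
   contributing nothing, not by an extra channel).

**Inputs.** One conditional binding efficiency (CBE) per receptor and
channel: `CBE = BS · min(NEX_ccmen, NEX_target) · min(FC_ccmen, FC_target)`.
`BS` is an intrinsic docking score (consumed as given — no docking is
performed here), `NEX` native expression in arbitrary units, `FC` the
glioblastoma-vs-normal fold change (dimensionless). The NHC-side fold change
is fixed at 1 because fold change is defined against the normal cell. The
factor channel pairs each receptor with its cognate factor by default; a
`max_over_factors` mode takes the best cross-pairing instead, since the full
receptor-by-factor score matrix exists in principle. Precomputed CBE channel
files (`cmcc.csv`/`cmnc.csv`/`cmf.csv`, one row per receptor in code order)
take precedence over BS+expression inputs when both are supplied.

**Binding strengths.** Within a `(combination, k_F)` subclass, which members
bind factors is unobserved; all `C(k, k_F)` assignments are treated as
exchangeable and averaged. The average has the closed form
`BST_cell = (k−k_F)/k · Σ CBE_cell`, `BST_F = k_F/k · Σ CBE_F`; the test
suite keeps the explicit per-assignment enumeration as an independent oracle.
The full `(BST_GCC, BST_NHC, BST_F)` triple is retained for the geometry
regardless of branch.

**Probability.** Mass is taken proportional to binding strength — the
minimal faithful map from efficiencies to probabilities. Each cell-branch
configuration contributes its branch BST to its channel, every configuration
with `k_F > 0` additionally contributes `BST_F` to the factor channel, and
the grand total is normalized to 1. Conditional per-degree distributions
`CP_k` renormalize within each `k`. All probabilities and angles are
invariant to a global rescaling of the CBE inputs; only channel ratios
matter.

**Propensity and classification.** `S_p,T = 90° − arccos(BST_T/‖BST‖)` per
channel, in degrees. The squared direction cosines sum to one, so at most
one channel can exceed 45°; classification uses a strict `> 45°` test
(exact-45° ties, e.g. two equal channels with the third zero, fall to NNDP).
A zero BST vector has undefined angles and classifies NNDP rather than
erroring, so inert configurations never abort a run. The threshold is
configurable in (0°, 90°); below 45° uniqueness is no longer guaranteed and
the largest propensity wins deterministically.

**Population summary.** Each `(combination, k_F)` subclass pools the mass of
all its configurations onto its classified direction. The headline report
redistributes the NNDP share equally over GCC/NHC/F (an undirected particle
still lands somewhere); intermediate CSVs keep the raw NNDP mass so the
bookkeeping stays auditable. Odds ratios per channel are
`[f/(1−f)] / [g/(1−g)]` with `f` the channel's fraction and `g` the mean of
the two competitors' fractions — the published analysis reports odds ratios
without stating a formula, so this definition is deliberately isolated in
one function (`ccmen.population.odds_ratio`) and can be swapped. Degenerate
fractions yield `inf`/`nan` signals, not exceptions. The break-even point is
the smallest `k` with `CP_{k,GCC} < max(CP_{k,NHC}, CP_{k,F})`; when the GCC channel never falls
behind, the library reports `None` and the CLI prints "none" (the
acceptance script alone maps "never crossed" to `n + 1` so its report stays
numeric).
Expectations `E(BST)` and `E(S_p)` are probability-weighted means with
weights renormalized within each `(k, k_F, channel)` cell, plus class-wide
values per `(k, channel)`.

Culture mode I (tumor cells and factors, no normal cells) zeroes the NHC
channel before enumeration; mode II uses all three channels. The two are
exactly equivalent when mode II is fed an all-zero NHC file, and this is
tested.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `threshold` | 45 | degrees | propensity classification boundary; 45° is the geometric point where one channel's squared strength exceeds the other two combined |
| `pairing` | `cognate` | – | receptor→factor pairing for the F channel |
| `baseline_gene` | min-expression factor | – | denominator of relative expression |
| `mode` | `culture_II` | – | whether normal cells are present |

## Synthetic generator

The real binding-score matrices behind the published analysis are not
public, so the pipeline's study conditions are emulated: each channel's
per-receptor CBE is `level × lognormal(mean 1, cv)`. Defaults
(`n_receptors=11`, `gcc_bias=1.63`, `nhc_level=0.1`, `factor_level=1.0`,
`noise_cv=0.25`) encode the regime the model describes for glioblastoma
membrane coats: homotypic tumor binding clearly stronger per receptor than
factor sequestration, normal-cell binding an order of magnitude weaker
(fold-change conditioning suppresses it), and tumor preference persisting
through mid-range degrees. Under the model the per-degree channel masses are
`CP_GCC ∝ g·(k+1)/2` and `CP_F ∝ f·k`, so a break-even at `k = 5` pins the
channel ratio to `g/f ∈ [1.60, 1.667)`; 1.63 is the midpoint. Lognormal
noise keeps CBEs nonnegative and mirrors the multiplicative
affinity-times-expression structure; cv = 0.25 is a typical spread for
expression-conditioned affinities. Individual seeds shift the realized
ratio, so the realized break-even point varies by a degree or two around the
noiseless value — that spread is part of the modelled conditions.

What the generator does **not** emulate: correlated channels (a receptor
with a strong homotypic score often also has a strong cognate-factor score),
heavy-tailed docking-score distributions, and receptor-specific expression
conditioning (levels are exchangeable across receptors). Passing tests
therefore demonstrate the engine's correctness and the model's structural
behavior, not agreement with any particular wet-lab panel.

## Numerical choices

- Exhaustive enumeration throughout — `Σ_k C(11,k)(2k+1) = 24 575`
  configurations evaluate in well under a second, so no sampling mode
  exists. Iteration order (degree ascending, combinations lexicographic,
  `k_F` ascending, GCC branch before NHC) is fixed; re-running on identical
  inputs reproduces byte-identical CSVs (floats at six significant digits;
  `summary.json` keeps full precision).
- Propensity vectors are rescaled by their largest component before taking
  the norm; angles are scale invariant and this avoids under/overflow on
  extreme inputs. Direction cosines are clipped to [−1, 1] before `arccos`.
- Global normalization is asserted to 1e−9; fraction bookkeeping to 1e−12
  in the oracle-equivalence tests.
- The ELISA fit is ordinary least squares on ln-transformed concentration
  (`scipy.stats.linregress`); replicate absorbances at the same
  concentration are averaged before fitting; R² is reported on the
  absorbance scale. At least three points and two distinct positive
  concentrations are required.
- Supplied `rnx` columns are recomputed from `nex` and only warn (1%
  relative tolerance) on disagreement — printed tables are rounded at the
  last digit and internally inconsistent at that level.

## Design choices where the design was open

- **Probability = BST-proportional mass.** The source analysis states that
  probabilities derive from binding efficiencies without giving the map;
  proportional weighting is the minimal choice consistent with scale
  invariance, and it is confined to `class_probabilities`.
- **Factor mass attribution.** Factor-engaged members of a cell-branch
  configuration contribute their `BST_F` to the factor channel (per
  configuration, i.e. once per cell branch), which reproduces the documented
  dominance of the factor channel at high degree.
- **Angles from the averaged vector.** Propensities are computed from the
  assignment-averaged BST triple, not averaged over per-assignment angles;
  the alternative is a one-line change and the oracle enumerates assignments
  explicitly if it is ever wanted.
- **`ESP_*` headers.** The expected-propensity files use `SP_Overall` /
  `SP@kf=N` column names; the corresponding published file description
  reuses the binding-strength header names, which is read here as a typo.
- **CCMEN expression = GCC expression.** The particle coat is extruded
  tumor membrane, so both sides of the homotypic term share the tumor
  expression table; both sides are nonetheless separate arguments in
  `build_cbe_tables` for sensitivity work.

## Known limitations

- Three channels only; the geometry is genuinely three-dimensional and does
  not generalize to more fates as written.
- The odds-ratio definition is a documented choice, not a published formula;
  comparisons of absolute OR values across implementations are not
  meaningful.
- No uncertainty quantification: expectations are point values, and the
  model is deterministic given its CBE inputs.
- Binding scores are consumed as given; nothing here validates docking
  quality, and the synthetic generator's independence assumptions (above)
  are optimistic.
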