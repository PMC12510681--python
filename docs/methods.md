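# Methods

## Model

Both partitioning models start from the replacement-design null expectation:
with expected relative yield RY_Ei and full-density monoculture yield M_if,
species i is expected to yield Y_NEi = RY_Ei · M_if in mixture, and the net
biodiversity effect is ΣY_Oi − ΣY_NEi = Σ ΔRY_i · M_if with
ΔRY_i = Y_Oi/M_if − RY_Ei.

**Additive partitioning** decomposes that sum by the covariance identity into
CE = N · mean(ΔRY) · mean(M_if) and SE = N · cov(ΔRY, M_if) with the
*population* covariance (divisor N); SE is computed as net − CE so that
CE + SE = net is exact in floating point. With the sample covariance the
identity would fail by a factor (N−1)/N.

**Competitive partitioning** replaces the assumption of competitive
equivalence with a competitive hypothesis: species share a niche but differ
in growth and competitive ability. Each species' null expectation is shifted
by a competitive growth response MG_i · RC_i:

- MG_i is the maximum proportional change in per-capita size under
  competitive exclusion. A species more competitive than the mean of its
  companions would, in the limit, dominate the mixture and grow like its
  partial-density monoculture: MG_i = w_ip/w_if − 1, where w = yield/density
  is per-capita size and the partial-density monoculture is planted at the
  species' density within the mixture (RY_Ei · total density). A less
  competitive species is excluded in the limit: MG_i = −1.
- RC_i = |H_i − mean(H_j, j≠i)| / max(H) scales that maximum by how far the
  species' competitive ability deviates from its companions' average,
  relative to the community maximum; RC ∈ [0, 1], and for two species both
  share the same RC.
- Y_CEi = Y_NEi (1 + MG_i RC_i) ≥ 0 since MG ≥ −1 and RC ≤ 1.

Community components: competitive = ΣY_CE − ΣY_NE; the residual
ΣY_O − ΣY_CE is attributed to dominance of positive interactions when
positive and of negative interactions when negative. The three components sum
to the net effect exactly. In the two-species replacement case the
competitive effect telescopes to RC · BPM, where
BPM = M_ip(most competitive) − ΣY_NE; this closed form is used as an
independent oracle in the tests.

The general per-capita form of MG is canonical: the shortcut
MG = M_ip/(M_if · RY_E) − 1 holds only when the full-monoculture density
equals the mixture's total density, so densities are stored explicitly and
never inferred.

## Parameters and defaults

- **Ability proxy H** (`ability_source`): defaults to the full-density
  monoculture yield (`monoculture_full`) — more productive species are
  assumed more competitive, as in both packaged case studies. An explicit
  per-species column (`column`) supports proxies such as reference-age stand
  volumes; `monoculture_partial` uses the partial-density monoculture yield
  instead, preferable where full-density monocultures stagnate (e.g.
  pot-bound rooting volumes). Changing the proxy changes the competitive /
  positive split but never the net effect.
- **Neutrality band** (`neutrality_band`, default 0.05): a species is
  classed *neutral* when |Y_O − Y_CE| ≤ 0.05 · max(Y_CE, Y_NE). Purely a
  reporting convention for the species-level labels; community components
  never use it. The *facilitative* class (Y_O strictly above the species' own
  partial-density monoculture yield) takes precedence over the sign classes.
- **Replacement check** (`ry_sum_tolerance`, default 1e-6): ΣRY_E ≠ 1 is a
  warning, not an error, so additive-design and low-density experiments
  remain analysable.
- **Tie-breaks**: a species whose ability exactly equals its companions' mean
  has RC = 0, making MG mathematically inert; MG is reported as 0 rather than
  −1 to avoid a spurious exclusion label. A tie for most competitive makes
  BPM the maximum over the tied species (all candidates are retained in
  `bpm_by_species`).
- **Dominant shrinking at partial density** (w_ip < w_if for a
  more-competitive species) is allowed and produces MG < 0 with a warning:
  the framework expects growth release at lower density, but data may
  disagree.
- **Response linearity**: the competitive growth response is linear in RC by
  default. `RunConfig.response_curve` accepts a user-supplied monotone
  function f(RC) as an extension hook; nothing nonlinear is fitted.
- **MG overrides** (`mg_overrides`): per-(mixture, species) values replace
  the partial-density estimate, e.g. when derived from published
  density–yield relationships for experiments without partial-density
  monocultures. BPM is then unavailable (reported as NaN with a warning).
- **Mixtures of three or more species** are experimental. RC generalises
  verbatim. For a mid-ranked species (stronger than some companions, weaker
  than others) the available resource gain is (1 − ΣRY_Ej)/RY_Ei − 1 (j over
  strictly stronger species) rather than 1/RY_Ei − 1, so with
  `multispecies_adjustment` the partial-density MG is scaled by the ratio of
  the two and clamped at −1; the top-ranked species is unchanged. This
  proportional scaling is one admissible reading of how the maximum response
  should shrink; it is off by default.

## Synthetic data generator

`SyntheticSpec`/`generate` build replacement-design communities with a known
interaction structure. Per-capita size follows a power law in planting
density, w(d) = w_f (d_f/d)^θ: θ = 0 means no release at lower density, θ = 1
the constant-final-yield law (a monoculture yields the same total at any
density), so M_ip = M_if · RY^(1−θ). Observed yields are the pipeline's own
competitive expectations distorted by per-species multipliers,
Y_Oi = Y_CEi (1 + δ_i), making the recovered positive + negative deviation
equal Σ Y_CEi δ_i exactly — any discrepancy flags a pipeline defect, not
noise. Defaults emulate the grassland pot study: two species, six plants per
pot, M_if uniform on (2, 15) g/pot (covering the fixture's 4.4–13.3 range),
θ = 1, δ = 0. All randomness flows from the single seed.

What the generator does **not** emulate: replicate-level measurement error,
density-dependent pests/pathogens or microclimate (which real partial-density
monocultures absorb into MG), nonlinear responses to RC, and competition
dynamics over time. Passing recovery tests therefore demonstrate the
partition's internal consistency, not that real communities obey the linear
response.

## Packaged fixtures

`grassland`: 15 two-species pot mixtures of six grassland species
(13 weeks, aboveground biomass g/pot, 6 plants per pot at full density,
half-density monocultures at 3 per pot). `trees`: 20 simulated trembling
aspen × white spruce stands (four ages × five compositions, stand volume
m³/ha); the simulated yields come from an external forest growth model and
are treated as data. Fixture values are printed to one decimal, so recomputed
per-mixture components are expected to match published per-mixture values
only within ±0.2 yield units (dataset means within ±0.1); the identities
above are still exact on the fixtures as given. Species references are
resolved per community so the same species can carry different monoculture
yields at different stand ages.

For the tree analysis the published component breakdown used a reference-age
ability proxy whose values are not part of the fixture; with the default
H = M_if the community components differ at the margin, and the fixture-based
checks therefore cover the mean net effect, the BPM column, and the
facilitation flag rather than the exact tree component breakdown.

## Numerical choices and edge cases

- Identities (net = CE + SE; net = positive + negative + competitive) are
  asserted at 1e-9 relative tolerance, scaled to input magnitude.
- Exactly one of positive/negative is nonzero (or both zero) by
  construction via max/min on the same residual.
- Zero full-density monoculture yield is an error for relative-yield-based
  operations (it is a denominator) and for RC when all abilities are zero.
- Degenerate inputs — a single species, non-positive densities, RY_E outside
  (0, 1] — are rejected at construction with the species or mixture named.
- Report tables serialise at full precision; `round_digits` affects display
  output only.

## Known limitations

- MG from a single partial density assumes that one density contrast
  captures the full release potential; species stagnating at full density
  bias MG upward and the positive/competitive split with it (mitigated by
  `ability_source="monoculture_partial"`).
- The −1 exclusion limit overstates losses in very low-density or
  short-duration experiments where subordinates are suppressed but not
  eliminated; proportional reduction alternatives can be expressed via
  `mg_overrides`.
- No uncertainty quantification: the model is deterministic given its
  inputs, and no bootstrap or replicate machinery is provided.
- No unit inference or conversion; yield and density units are opaque
  labels.
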