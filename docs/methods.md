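# Methods

This note documents the models and numerical choices behind `fjordconn`:
what each stage computes, what the synthetic scenario generator does and
does not emulate, and where genuinely open design questions were settled.

## 1. Velocity fields and drifter advection

A `VelocityField` is a 2-D, single-layer gridded flow (u, v in km day⁻¹ on
(time, y, x), daily means, with a boolean land mask). A single layer stands
in for the near-surface band that picoplankton occupy; connectivity logic at
this scale is depth-independent. Velocities at land cells are treated as
zero during interpolation, which decelerates drifters approaching the coast.

Advection uses classical RK4 with default `dt = 0.25` day (configurable;
`dt` must divide the 1-day storage interval), bilinear interpolation in
space and piecewise-constant (daily) interpolation in time. Intermediate RK4
stage positions are clipped to the domain box; boundary crossing is decided
on the full step. For a constant field RK4 is exact to machine precision;
for solid-body rotation the orbit radius is conserved to < 10⁻⁶ relative
error over one period at `dt = 0.1` day (both are regression-tested).

Drifters that enter a land cell are flagged **beached and frozen** there —
coastal retention — and still count in concentration fields at their
beaching cell. Drifters crossing the domain boundary are flagged
out-of-domain and frozen at their last inside position; they are excluded
from concentration numerators but kept in denominators, so a release site's
domain-wide concentration sums to exactly 1 only while no drifter has been
lost. Drifter conservation (seeded = active + beached + out) holds at every
stored step. Randomness enters only through seeding positions (uniform over
the ocean part of an odd square of cells centred on the site); advection
itself is deterministic.

Cohort seeding follows the standard protocol for statistical dispersal
estimates: cohorts at a fixed interval (default every 10 days), uniformly
over a 3 × 3-cell window, each tracked for a fixed lifetime. The desk-scale
defaults (6 cohorts of 50 floats, 365-day lifetime) are deliberately far
smaller than a basin-scale study (which would use ~1000 floats over years);
they suffice because the toy domain is small and the statistics pool over
cohorts and daily snapshots.

## 2. Connectivity and hydrodynamic distance

Concentration fields pool **all snapshots** whose drifter age falls in a
bin (cumulative bins (0, 30], (0, 90], (0, 180], (0, 365] days by default);
pooling over snapshots rather than using bin-end snapshots only was chosen
because it uses far more of the simulated information at small cohort
counts — a bin-end variant is available by computing single-day bins.

Connectivity entries average the release site's concentration over an odd
square window (default 15 cells, matching typical ocean-model practice at
~4 km resolution) centred on the receiving site; land cells count in the
mean's denominator and edge-clipped windows average over fewer cells. On toy
grids the window is automatically capped at the grid dimension.

The hydrodynamic distance inverts connectivity on a log scale:
`−log₁₀` of the symmetrized concentration, min–max normalized to [0, 1]
**within each age bin** over the connected pairs. Negation (rather than the
reciprocal `1/log₁₀ C`) is the only reading that is bounded and monotone on
concentrations in (0, 1]; the reciprocal variant is kept behind a flag.
Symmetrization uses the maximum of the two directed entries — transport in
either direction can homogenize two communities — with the mean available
by option. Pairs with zero concentration both ways are marked *unconnected*
and excluded from normalization and from the correlation analyses; they are
never assigned distance 1. Because beached drifters are frozen, the set of
connected pairs can only grow as the age-bin upper bound increases.

## 3. Compositional stack

Filtering removes ASVs with total count ≤ 1 across all samples, plus ASVs
flagged as mitochondria/chloroplast (16S) or metazoan (18S) in the
annotation table. Samples left empty are dropped and logged by id; silent
drops are forbidden.

Zero replacement is geometric Bayesian-multiplicative (GBM): a zero in
sample *i*, part *j* receives its Dirichlet posterior expectation
`t_j · s_i / (n_i + s_i)` with prior proportions `t` from the across-sample
geometric mean of observed proportions and square-root prior strength
`s_i = √n_i`; imputed values are capped at 65 % of the sample's smallest
observed proportion (the conventional safeguard), and nonzero parts shrink
multiplicatively so rows sum to 1. Samples with fewer than two nonzero ASVs
are rejected. A closed-form simple multiplicative replacement is provided as
an independently testable fallback.

CLR uses the natural log (the convention of the compositional literature;
distances under log₁₀ differ only by a constant factor), and the Aitchison
distance is plain Euclidean distance between CLR rows. Both are verified
against a brute-force pairwise-log-ratio oracle to 10⁻¹⁰ and against
scikit-bio's `clr`.

## 4. Diversity statistics

*Alpha.* Hill numbers of order 0 (richness) and 1 (exp Shannon entropy,
nats), with standard errors from multinomial bootstrap resampling at the
observed depth (default 100 resamples). Coverage-based rarefaction/
extrapolation is deliberately not implemented — observed Hill numbers plus
bootstrap are sufficient at planted, equal sequencing depths. Evenness is
reported in two variants because the field uses both: `shannon/richness`
(default) and classical Pielou `shannon/ln(richness)` (undefined and
flagged for single-ASV samples).

*PERMANOVA.* One-factor, via the sums-of-squares identity
`SS = Σ_{i<j} d²_ij / n` applied to the whole sample and within groups;
R² = SS_between/SS_total; pseudo-F with (k−1, n−k) degrees of freedom;
p-values by free (unstratified) permutation with the add-one convention
`(1 + #{F* ≥ F}) / (1 + n_perm)`, so p is never exactly 0. R² and pseudo-F
match a brute-force oracle to 10⁻¹⁰ and vegan's `adonis2` to 10⁻⁹; the null
rejection rate at α = 0.05 calibrates to 0.056 over 500 simulations.

*RDA.* The CLR matrix is column-centred and projected (least squares,
pseudo-inverse with a warning under rank deficiency) onto the z-scored
predictor span; the SVD of the fitted values gives constrained axes and
scores; `constrained_fraction = SS_fit / SS_total` (matches vegan's `rda`
to 10⁻⁹). The model p-value permutes predictor rows against the response
using the overall pseudo-F.

*Forward selection.* Greedy on adjusted R², with a marginal permutation
test per candidate (add-one convention, 199 permutations under the
`perm_max = 200` cap) and the scope rule that the running adjusted R² may
not exceed the full-model adjusted R². This matches `ordiR2step` semantics,
including its conservative corner case: when a lone strong predictor's
adjusted R² exceeds the noise-diluted full model's, selection legitimately
stops empty (verified against vegan on the same data).

*Group tests.* One-way ANOVA followed by pairwise Welch t-tests (unequal
variances), or Kruskal–Wallis; Bonferroni adjustment
`p_adj = min(1, m·p)` across the pairwise family. Groups with fewer than
two samples are flagged and skipped.

## 5. Coupling and trophic profiles

One representative site per fjord — minimum distance-to-mouth, determinism
under ties by lexicographic site id (logged), with a configurable exclusion
list for stations a coarse model coastline cannot resolve. The pair table
keeps all C(k, 2) unordered pairs; unconnected pairs remain as rows and are
excluded only inside the per-bin correlations (which require ≥ 3 connected
pairs and nonconstant hydrodynamic distance). Aitchison-vs-ΔT regressions
are ordinary least squares with 95 % t-based slope CIs, fit for all pairs,
within-subzone pairs, and crossing classes separately.

Trophic profiles resolve a genuine ambiguity in how concatenated CLR
tables can be "normalized to 1": CLR values are signed, so the only reading
that yields non-negative parts summing to one is **min-shift then
sum-normalize per sample**, which is what is implemented (and recorded in
the output metadata). Unknown-trophy ASVs form explicit `unknown × domain`
cells rather than being dropped, preserving the normalization. Subzone
tests merge high and low Arctic into one class by default (small polar
sample sizes); the eukaryote share of a trophic group is the eukaryotic
cell over the sum of both domain cells of that group.

## 6. The synthetic scenario generator

The generator emulates, at desk scale, the structure of a fjord-chain
survey:

- **Geometry/flow:** a land strip along one grid edge with 2-cell-wide,
  3-cell-deep fjord notches; a boundary current (default 10 km day⁻¹,
  ~0.12 m s⁻¹) flowing warm→cold along the coast with a smooth cross-shore
  jet profile; cross-shore meanders and a weak fjord outflow, both scaled
  by `meander_amplitude` (so `meander_amplitude = 0` gives a purely
  along-channel flow); all speeds bounded by twice the nominal current.
- **Environment:** three sites per fjord (head/middle/mouth; mouth flagged
  representative); temperature decreasing monotonically along the path,
  with one `barrier_step` °C drop at `barrier_position` separating the
  subarctic from the low-Arctic subzone; nutrients enriched toward fjord
  heads and cold sites; salinity, fluorescence, depth and sun-elevation
  covariates with plausible magnitudes.
- **Communities:** per domain, a latent CLR-space vector per fjord-mouth
  site following a Gaussian random walk along the chain with per-coordinate
  step variance `decay_rate · d_hydro + temp_sensitivity · |ΔT|`, so the
  expected squared Aitchison distance accumulates linearly in the planted
  divergence (the logistic-normal construction makes recovery analytically
  predictable); head/middle sites jitter around their mouth vector
  (variance 0.05). Counts are multinomial at `seq_depth` (row sums exact).
- **Cold-site prokaryote suppression:** a nested, coldness-proportional
  fraction of prokaryotic ASVs (up to `richness_cold_penalty_pro` at the
  coldest site) is excluded before sampling. Observed richness ratios run
  slightly below `1 − penalty` because rare surviving ASVs also fall under
  the detection limit at finite depth.
- **Trophic structure:** each ASV carries a thermal niche in [0, 1] that
  (a) tilts its latent abundance along the coldness gradient, scaled by
  `NICHE_TILT_SCALE × temp_sensitivity` of its domain, and (b) biases its
  annotation: cold-niche prokaryotes are mostly `unknown`, cold-niche
  eukaryotes mostly annotated. Together these make cold sites
  eukaryote-heavy within each labeled trophic group. A direct domain-level
  CLR shift cannot plant this signal (each domain's CLR sums to zero per
  sample), which is why the mechanism works through niche–label coupling.
  The tilt scale (25) was set so that per-group label signal stands above
  the community-level random walk when averaged over a few hundred ASVs per
  domain; the tilt vanishes when a domain's temperature sensitivity is
  zero, keeping the transport-only scenarios clean.

Default parameters are the package's study conditions: 21 fjords
(→ 210 representative-site pairs), 300 ASVs per marker at 20 000 reads,
decay 2.5 CLR-variance units per unit hydrodynamic distance, temperature
sensitivities 0.4 (16S) vs 0.2 (18S) — prokaryotes twice as
temperature-sensitive — and a 50 % cold-site prokaryote richness penalty.
The decay value was chosen once so that planted divergence clearly exceeds
multinomial sampling noise at this scaled-down depth. The presets in
`fjordconn.presets` freeze the recovery-analysis conditions (transport-only
decay; asymmetric temperature barrier; trophic structure at 600 ASVs per
domain).

**What the generator does not emulate:** sequencing-read error models,
chimeras or primer bias; inter-annual revisits (available in principle as
extra samples, not planted by default); 3-D or ice-covered flow; tidal
forcing; taxonomic structure beyond coarse placeholder lineages. Passing
recovery tests therefore demonstrate that the inference chain recovers
structure of the planted kind at realistic noise levels — not that any
field data set contains such structure.

## 7. Determinism, sizes, and degenerate inputs

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawns (scenario seed → field/sites/communities/drifters); identical
configurations reproduce identical outputs bit for bit, including the full
pipeline summary. Problem sizes throughout (toy grids of 48–128 × 16–24
cells, tens of sites, hundreds of ASVs, hundreds of permutations) were
chosen so a complete pipeline runs in seconds on one CPU while every
statistic stays comfortably out of its small-sample degenerate regime.
Degenerate inputs are first-class: empty age bins, all-land seeding
windows, unconnected pair sets, zero-variance predictors, single-ASV
samples and single-group designs all raise specific errors or flagged NaN
results rather than propagating silently.
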