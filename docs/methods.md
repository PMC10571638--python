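# Methods

## The behavioral model

`audpipe` analyzes home-cage operant drinking experiments of the IntelliCage
type: group-housed, transponder-tagged mice visit instrumented corners where
nosepokes open doors to drinking bottles and individual licks are logged.
Over a ~60-day protocol — adaptation, alcohol initiation at 4/8/12%, a long
free-access period (10%), a progressive-ratio motivation test, a 3-day
persistence test, 7 days of extinction, a 24-h cue relapse and an alcohol
relapse — five per-animal indices are computed, each oriented so that larger
is more AUD-like:

| index | phase | definition |
|---|---|---|
| M | motivation | fixed-ratio (FR) requirement reached on the progressive-ratio ladder 2, 4, 8, 12, 16, 20, 24, 28, 32, 36 |
| E | extinction | mean daily reward-corner nosepokes over the 7 extinction days |
| CR | cue relapse | reward-corner nosepokes during the 24-h cue test |
| AR | alcohol relapse | first-day alcohol intake, g/kg/day |
| P | persistence | reward-corner nosepokes during the non-active 6-h periods |

For E, CR and P the battery also defines difference variants (E minus the
last pre-extinction day; CR minus the last extinction day; nA minus A
nosepokes). The 5-column matrix uses the count/average variants by default;
all variants are emitted in `behavior_matrix.csv` and `IndexConfig` can swap
them.

### Progressive-ratio replay

A *set* at requirement r is a burst of r nosepokes at the reward corner with
consecutive gaps under 1 s, inside one visit. A gap of >= 1 s or a visit
boundary resets a partial burst (the protocol defines what completes a set,
not what happens to an interrupted one; resetting matches the literal
"spaced by less than 1 s" reading). After 10 sets the requirement advances to
the next ladder value. The reported breakpoint is the requirement in effect
at the end of the slice — the level advanced *to*; an animal that never
completes a set scores the first ladder value (2). A
`mode="last_completed"` switch returns the last level at which a set was
completed instead. The replay is checked against an independently written
burst-first simulator on 500 randomized streams.

### Consumption

Daily alcohol intake is
`licks x lick_volume(ml) x alcohol_fraction x 1 g/ml / body_weight(kg)`,
with the conventional 1 g/ml density applied as-is (not ethanol's physical
density, following field practice for this assay). The lick volume is a
single cohort-wide calibration constant, defaulting to 1.94 µl per lick;
`calibrate_lick_volume` recomputes it from measured volume and lick counts.
The relapse-day alcohol fraction is taken from the schedule window (0.10 by
default), substituting for the 12% the formula is usually quoted with.

## Scoring and classification

An animal is positive for a criterion when its index lies in the uppermost
q = 35% of the cohort. The threshold is the nearest-rank (1-q)-quantile —
the ceil((1-q)·n)-th smallest value — and positivity requires being
*strictly above* it: with all-distinct values and integral q·n this flags
exactly q·n animals, and animals tied with the threshold are never flagged
(a deterministic, conservative tie rule; the protocol defines none). A
zero-variance column flags nobody and emits a warning. A small epsilon
(1e-9) guards the ceil against floating error when (1-q)·n is integral.

The AUD index is the criterion count (0–5); animals with >= 2 criteria are
classified AUD-prone, the rest AUD-resistant. The continuous AUD score is
the z-sum AS_i = Σ_b (V_ib − mean_b)/SD_b with the sample SD (n−1; a
`sd_ddof` switch gives the population SD). AS is invariant to affine
rescaling of any column and sums to zero over the cohort by construction.

## Group structure

Spearman correlation matrices (average ranks on ties; two-sided p from the
large-sample t approximation, permutation p-values behind `exact=True` for
small groups) and a PCA are computed within the prone group, the resistant
group, and the pooled cohort. The PCA eigendecomposes the group's
*correlation* matrix — behaviors have incommensurable units, matching the
z-scoring used in AS — with components ordered by eigenvalue and each
component's sign oriented so its largest-magnitude loading is positive.
Loadings are reported on the correlation scale (eigenvector × sqrt
eigenvalue); explained-variance fractions are eigenvalues / 5. No
multiple-testing correction is applied to the correlation p-values by
default, matching how such matrices are conventionally reported.

`independence_null(q, m, k)` gives the binomial tail Σ_{j≥k} C(m,j) q^j
(1−q)^{m−j}: the fraction of animals expected to meet >= k of m criteria if
criteria were independent (57.2% for q=0.35, m=5, k=2). An observed prone
fraction well below it indicates that criteria co-occur in a minority
subgroup rather than scattering independently.

## The synthetic cohort generator

Raw logs from experiments of this kind are rarely shared (cage exports are
proprietary), so the pipeline ships a generative stand-in with known ground
truth. Each animal draws a
latent class (prone with probability 0.38) and a 5-vector of latent traits
(motivation, extinction responding, cue reactivity, relapse drinking,
persistence) from a class-specific multivariate normal with equicorrelated
covariance: rho = 0.6 among prone traits, 0 among resistant traits, unit
SDs, class means 2.0 vs 0.0 on the latent scale. Traits map to non-negative
rates through a softplus link, so prone rates are roughly three times
resistant ones — a well-separated regime.

Trait-to-behavior couplings:

* **M** — the animal completes 10 sets at every ladder level up to a target
  level `floor(3·softplus(t_M))` (capped at the ladder top), plus a partial
  set count at the target; 30% of sets are preceded by a failed shorter
  burst in its own visit, exercising the reset rule.
* **E** — daily extinction nosepokes are Poisson(level·exp(−decay·day)) with
  level = 30·softplus(t_E)/day and decay = 0.5·exp(−0.35·t_E)/day, clipped
  to [0.02, 3]: higher traits mean both more responding and slower decay
  (impaired extinction).
* **CR** — cue-day nosepokes Poisson(40·softplus(t_CR)).
* **AR** — first-relapse-day licks Poisson(500·softplus(t_AR)), giving
  roughly 8–10 g/kg/day for typical prone animals at 25 g body weight.
* **P** — non-active-period nosepokes Poisson(60·softplus(t_P)); active
  periods carry a trait-free rewarded baseline (Poisson(80) total).

Background visitation is homogeneous Poisson within 12-h dark/light blocks
at a 3:1 dark:light rate ratio (1 visit/h on average, split evenly between
water and reward corners); rewarded nosepokes trigger Poisson-distributed
lick trains. One root seed spawns per-animal substreams via
`SeedSequence(seed, spawn_key=(1, i))`, so cohorts are byte-reproducible
and animals are statistically independent.

The default schedule compresses the published ~90-day timeline to 63 days
(3 d adaptation, 3+3+3 d initiation, 35 d free access, 3 d motivation, 3 d
persistence, 7 d extinction, 1 d cue relapse, 2 d alcohol relapse) and event
rates are deliberately thinner than real cages record (free-access intake
~1–2 g/kg/day rather than ~10), keeping a 200-animal cohort at a
few-million-row table. What the generator reproduces is the *relative*,
trait-driven contrast between subpopulations — which is what the indices,
the classifier and the structure analyses measure. It does not emulate
social competition for corners, realistic circadian shape beyond the
dark/light ratio, licking microstructure, alcohol pharmacokinetics, or
missing-transponder artifacts; passing tests therefore demonstrate the
pipeline's correctness and discriminative behavior under the stated
generative model, not performance on any specific laboratory's raw data.

## Numerical conventions and degenerate inputs

* Timestamps are seconds since experiment start, anchored at the day-0
  dark-phase onset; daily bins are 24-h bins from that anchor. Phase windows
  are half-open `[start, end)`: boundary events belong to the later window.
* Orphan nosepokes/licks (no enclosing visit of the same animal and corner)
  are hard validation errors, never silently dropped — the indices are
  counts and silent drops would bias them.
* Extinction slices must span exactly 7 daily bins, cue slices 1, persistence
  slices 3 (tolerance 1 s); violations raise schedule errors.
* Animals with no events at all in a scored phase window are excluded from
  the behavior matrix, listed in a completeness report, and warned about;
  animals present but inactive score legitimate zeros.
* Quantile criteria need >= 3 animals; group correlation/PCA needs >= 4. In
  the orchestrated report, a too-small or degenerate group degrades to an
  n-only entry with a warning instead of failing the run.
* PCA eigenvalues are clipped at zero against round-off; the persistence
  period index is clipped to [0, 11] so an event exactly at the window end
  cannot index a 13th block.

## Problem sizes used by the test suite

Parameter recovery runs 10 seeds × 3 trait-gap levels of 200-animal
cohorts; the structure contrast runs 20 seeds of 58-animal cohorts; the
validation property runs 100 seeds of 2-animal cohorts; the breakpoint
oracle comparison runs 500 randomized streams. These sizes give the
relevant Monte-Carlo error a comfortable margin against the tested
thresholds while keeping the full suite under two minutes.

## Known limitations

* The criterion rule's tie handling and the sample-SD choice in AS are
  documented conventions; protocols in the literature underdetermine both.
* The persistence test's active-first period parity is a convention (the
  test starts at dark-phase onset with a signalled active period).
* Side (left/right nozzle) is retained in the event model but unused by the
  indices.
* With very small cohorts (n < ~15) the 35% quantile thresholds are coarse
  and classification is noisy; the simulator's defaults target study-sized
  cohorts.
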