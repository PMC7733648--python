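# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices that affect results.

## 1. Relatedness estimation

### Dyadic maximum likelihood (`dyadml`, default)

For a non-inbred pair of diploids, each biallelic locus is in one of three
IBD modes — the pair shares 0, 1 or 2 alleles identical by descent — with
probabilities `k = (k0, k1, k2)` on the 2-simplex and relatedness
`r = k2 + k1/2`.  Given the scored-allele frequency `p` at a locus, the
joint genotype probabilities per mode are

| mode | P(g1, g2) |
|---|---|
| 0 | HWE(g1) · HWE(g2) |
| 1 | shared allele drawn at frequency, remaining alleles independent (e.g. P(AA,AA)=p³, P(AB,AB)=pq, P(AA,BB)=0) |
| 2 | HWE(g1) · 1{g1 = g2} |

Genotyping error is modelled as a symmetric per-allele flip with rate `e`
(default 0.01; the platform's true error model is unknown, and a symmetric
flip is the weakest structural assumption).  The 3×3 genotype confusion
matrix is applied on both sides of each mode's joint table, so opposing
homozygotes no longer have zero likelihood under modes 1–2 when `e > 0`.

The per-dyad log-likelihood `Σ_loci log Σ_m k_m A_m` is concave in `k`, so
EM from an interior start reaches the global maximum.  We run SQUAREM-
accelerated EM (two EM steps, squared extrapolation, fall back to the plain
EM iterate if the likelihood would decrease), batched across dyads with an
active set that freezes converged dyads.  Because a boundary optimum on a
simplex corner is only approached asymptotically by EM, the returned
estimate is the argmax over the EM solution and the three corners; this
also guarantees the invariant that the reported likelihood is at least that
of the unrelated, parent–offspring and identical hypotheses.  Convergence
tolerance is 1e-8 on `k` per cycle, max 100 cycles, with near-corner
restarts for stragglers.  The estimator is cross-checked in the test suite
against an exhaustive simplex grid search (step 0.001) on small inputs and
against Monte-Carlo pedigree truths at 10⁴ loci.

The triadic likelihood (a third reference individual) used by some field
studies is deliberately not implemented: it is not specifiable from first
principles without additional modelling choices, and the dyadic ML targets
the same quantity `r`.  `dyadml` r is bounded to [0, 1] by construction.

### Queller–Goodnight moment estimator (`qg`)

The classic unbiased moment estimator, symmetrized by summing numerators
and denominators across loci for each direction and averaging the two
directional ratios.  It is unbounded (negative values are informative —
see the outbred screen) and an order of magnitude faster than ML; the two
estimators agree within ±0.05 in mean on simulated full-sib dyads.

Missing data: per-dyad complete-case loci; dyads with fewer than 100 joint
loci (configurable) are flagged unusable rather than dropped silently.

## 2. Inbreeding screen

Per larva, `F = 1 − H_obs / Σ 2f(1−f)` over its non-missing retained loci,
clamped to [−1, 1].  Hatchery-stocked fish in a wild sample are typically
*outbred* relative to the river gene pool: their heterozygosity exceeds the
HWE expectation computed from sample frequencies, driving `F` strongly
negative.  Larvae with `F < −0.4` are excluded before sibship analysis
(exclude-then-analyse, with the exclusion list logged).  The screen is
exposed on both `F` and pairwise `r`; `F` is the default because it is a
per-individual quantity and partitions the sample cleanly.

## 3. Sibship cutoff calibration

Relationship-category distributions (full-sib, half-sib, parent–offspring,
unrelated) are simulated by explicit gamete dropping from the observed
allele-frequency vector (1,000 dyads per category by default) and the
chosen estimator is applied to each simulated dyad.  The full-sib cutoff is

* `fixed` (default): `r > 0.4`, strict inequality — between the FS mean
  (0.5) and the HS mean (0.25), keeping most full sibs while excluding
  half-sib leakage; the empirical FS false-negative and HS false-positive
  rates at the cutoff are always reported, plus a count of dyads within
  ±0.05 of the cutoff as a sensitivity band;
* `auto`: the value minimizing (FS false-negative rate + HS false-positive
  rate), returned as the midpoint of the optimal gap between simulated
  values so degenerate, fully separated distributions yield an interior
  cutoff.

Parent–offspring dyads cannot occur among the larvae themselves (a ≤3-year
collection window vs 4–5 years to maturity), so an above-cutoff dyad is
interpreted as full-sib without a PO tie-break.

Families are connected components of the full-sib graph.  Non-clique
components (a member missing an edge to another member) are logged as a
data-quality warning but never split — with a correct cutoff they arise
from borderline dyads, and splitting would require an arbitrary rule.
Family labels ("M01", …) are arbitrary putative-mother names.

## 4. Spatio-temporal back-calculation

Larval age comes from a per-cohort-year least-squares line of
daily-increment age on mean sagittal otolith length (≈30 aged larvae per
year).  A linear form was chosen for identifiability at that calibration
size; the residual sd is reported per year.  Then, per larva:

```
hatch DoY  = capture DoY − age
incubation = 20.67 − 0.667 · T(°C)        (valid below ~31 °C)
spawn DoY  = hatch DoY − incubation
dispersal  = max(age − brood care, 0)     brood care default 7 d (median of 4–10 d)
nest km    = capture km − v · dispersal   v default 700 m/day
```

Temperature is looked up once at the estimated hatch day (no fixed-point
iteration: incubation is ≤ ~14 d, so within-incubation temperature drift is
second order).  Chainage increases downstream, drift is downstream-only,
and an age below the brood-care duration clamps dispersal to zero with a
warning rather than placing the nest downstream of the capture site.

Putative nests are single-linkage clusters within a cohort year: two larvae
join when |Δhatch| ≤ 3 d and |Δnest| ≤ 1 km.  The rule and defaults are a
formalization of cluster-by-eye scatterplot reading; both tolerances are
configurable, and shrinking them only ever refines the partition.
Agreement with the genetic families is summarized by the adjusted Rand
index, plus a per-full-sib-pair report of shared/adjacent capture sites.

## 5. Chance-pairing model

With `n` pairs including singletons and a 50/50 sex ratio, a female
re-choosing at random has `n − 1` alternative males each season, so

```
p = (1/(n−1))^(y−1)
```

for `y` seasons with the same mate.  This algebraic form is the one
consistent with both of its published anchor values (p < 0.008 at n = 138,
y = 2, and a critical pool of five pairs at α = 0.05, y = 3); the printed
rendering of the formula in the source literature is typographically
ambiguous, which is why the anchors matter.  `critical_pool_size(y, α)`
returns the exact integer boundary (largest `n` with `p ≥ α`), verified by
integer scan.  Joint probabilities across independent females multiply;
independence is an assumption, stated, not tested.  No philopatry or
assortative-mating structure is modelled in the null.

## 6. Isotope validation

Cohesion statistic `S`: after per-axis z-scoring of (δ13C, δ15N) across all
larvae in the table, `S` is the mean over families (size ≥ 2) of the mean
within-family pairwise Euclidean distance.  `S` deliberately ignores
between-family separation — the claim under test is that siblings share a
maternal signature, not that mothers differ maximally.  Significance comes
from permuting family labels (within cohort year by default, since baseline
isotopes drift between years), one-sided toward cohesion, with
`p = (1 + #{S_perm ≤ S_obs})/(n_perm + 1)`, so the minimal attainable p is
`1/(n_perm+1)` and p is exactly uniform under the null.  The statistic and
test are this package's quantitative formalization of what is usually shown
as a colour-coded scatterplot.

## 7. Synthetic-data generator

The generator emulates the study design end to end, with every larva
carrying pedigree and space-time truth:

* **Genetics** — allele frequencies uniform on a configurable MAF range
  (default 0.1–0.5, mirrored to either allele); adults drawn under HWE;
  larvae by Mendelian gamete dropping; symmetric per-allele genotyping
  error (default 1%) and missing calls (default 2%).
* **Mating** — a per-year count of nests (default 7); planted repeat pairs
  re-mate across configured year sets (default pattern: first pair spans
  all years, later pairs two years, consecutive then gap-year); remaining
  matings drawn monogamous by default with configurable polygyny/polyandry
  proportions; each non-planted pair breeds at most once across the study.
  Sex ratio is fixed 50/50.
* **Geometry** — scalar chainage on a one-reach river (increasing
  downstream, 65 km with six capture sites by default).  A drawn drift-day
  value (uniform 0–6 d) places a provisional position `nest + v·d` which is
  snapped to the nearest capture site at or downstream; the *realized*
  drift duration is the travel time `(site − nest)/v`, so capture day
  equals `hatch + brood care + travel` exactly and the back-calculation
  chain is invertible in the noise-free limit.  This treats drift nets as
  catching larvae in transit, which is how they operate.
* **Contaminants** — stocked outbreds are F1 crosses between the river pool
  and a hatchery pool whose allele frequencies are shifted toward the
  opposite allele (default shift 0.7, i.e. a strongly diverged, near-fixed
  strain).  Pure draws from a shifted pool would have F ≈ 0 and could never
  reproduce the strongly negative inbreeding signal that motivates the
  screen; F1 admixture gives the observed excess heterozygosity.
* **Isotopes** — mothers draw a (δ13C, δ15N) signature around a population
  mean (default −28‰, 10‰) with between-family sd 1.0‰; offspring add
  within-family noise at the assay-precision floor (0.15‰).
* **Ageing** — otolith length grows linearly with age (0.045 mm/day from
  0.15 mm at hatch) plus reading noise; an aged subset of ~30 larvae per
  year forms the calibration table.

Not emulated: sequence-level artefacts (reads, tags), linkage (loci are
independent), mortality or gear selectivity, within-season temperature
structure (scalar per year by default), barriers to drift, and any spatial
or preference structure in mate choice.  Passing tests on this generator
therefore demonstrate correctness of the inference chain under its own
assumptions, not robustness to linked markers, family-correlated dropout or
non-random mating — the known limitations of the real study system.

## 8. Problem sizes and determinism

Default test and acceptance runs use 10⁴ loci × 500 dyads/category for
estimator calibration, and a 20-nest / 3-cohort / 1,000-locus scenario
(~110 larvae, 4 planted repeat pairs, 10% contaminants) for end-to-end
recovery — sizes chosen to match the study's scale while keeping a full
run in minutes on one core.  One integer seed drives everything; the
pipeline forks an independent child stream per stage (frequency draws,
pedigree, isotopes, calibration subset, cutoff simulation, permutations),
so stages are individually reproducible and a rerun with the same
configuration is byte-identical.
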