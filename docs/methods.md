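# Methods

## Editability

A site-count row gives, for one genomic adenosine on the expressed strand,
the number of reads supporting A and supporting G (inosine reads as G).
Per-element editability is the pooled ratio

    E = 100 · ΣG / (ΣA + ΣG)   [percent]

over all covered adenosine positions inside the element, with reads
attributed to the annotated gene strand (no per-read strand inference).
Elements are retained when at least `min_sites = 30` distinct adenosine
positions are covered and at least `min_depth = 1000` adenosine/inosine
bases were sequenced in total; both thresholds are inclusive. The
strong-site variant recomputes E after zeroing the G count of every site
whose own editing level is at or below a threshold (25% by default) while
keeping its depth in the denominator, so the two statistics share a read
pool and are directly comparable.

Sites are matched to elements by half-open interval containment; a site
inside an element whose strand disagrees with the gene strand raises an
error rather than being dropped, because it indicates inconsistent strand
handling upstream. With nested elements a site counts toward every
containing element.

## Architecture covariates

All coordinates are 0-based half-open. The distance `d` between two
elements is the gap between their nearest edges; touching, overlapping and
nested elements are at `d = 0`. The nearest reversely oriented neighbor is
searched over **all** annotated Alu/FLAM elements on the chromosome, genic
or not; ties are broken by smaller start, then identifier. Window counts
`Nss`/`Nrs` tally elements whose gap is at most the window half-width
(10 000 and 2000 bp by default), inclusive at the boundary and excluding
the focal element. Exon/intron co-residence is assigned by the midpoint of
each element; an element can straddle a boundary, and the midpoint rule is
the documented convention. Pair identity is the percent of matched columns
in the best local alignment of the element against the reverse complement
of its neighbor, under match +2, mismatch −3, gap of length k costing
5 + 2k; the Gotoh dynamic program is implemented in-package so the
statistic is reproducible bit for bit (traceback prefers diagonal, then
vertical, then horizontal, and ends at the best-scoring cell with the
smallest row/column).

## Model fits

The distance law `E(d) = A·exp(−d/L) + B` is fitted by trust-region
nonlinear least squares with multi-start initialization (L₀ ∈ {200, 1000,
3000} bp), bounds A ≥ 0, L ∈ [10, 10⁶] bp, B ≥ 0 and tolerances 10⁻¹² on
the objective; the decay is parameterized on a log scale. The default
mode fits the mean editability of 100-bp distance bins up to 4000 bp,
weighting each bin by √n so sparsely populated far bins do not dominate —
bin means have variance ∝ 1/n, making this the inverse-variance weighting.
Records beyond 4000 bp are excluded from the curve fit but always included
in the per-element variance-explained statistic
`1 − SS_res/SS_tot`, which is computed on raw per-element data whatever
the fit mode; that is the only reading under which a fraction of *total*
variance is meaningful. A `per_element` mode fitting raw pairs is provided
for sensitivity analysis.

The neighbor-count model is deliberately sequential, mirroring how such
analyses control for the dominant distance effect first: residuals from
the fitted curve are regressed by ordinary least squares on (1, Nss, Nrs).
The combined intercept is the exponential baseline plus the OLS intercept.
A rank check rejects degenerate designs (e.g. Nss ≡ Nrs). No joint
refitting is attempted. Note a structural property of this two-stage
procedure: the curve absorbs the component of the count effects that is
predictable from d, so the OLS coefficients estimate the count effects
*orthogonal to distance*. E[Nrs|d] necessarily falls as d grows (no
reverse element can sit closer than d), so a small attenuation of the
reverse-count coefficient is intrinsic to the procedure; on the default
synthetic cohort it is held to a few percent by the layout design below,
with a residual spread of roughly ±6% across seeds at n = 50 000.

Group summaries (family, subfamily match, segment relation, length and
identity bins) report per-group counts and mean editability, optionally
with the mean residual from the global curve as a distance-corrected
comparison.

## Synthetic cohorts

The generator is the package's test bed: it produces a repeat layout,
gene models, true per-element editability and site-level read counts with
the statistical structure the analysis expects, so every stage can be
validated end to end without genome-scale data.

**Layout.** Exactly `n_alus` genic elements are placed in genes of ~15
elements. Consecutive within-gene gaps follow a two-exponential mixture;
the `p_close` component's scale is multiplied by a bounded log-uniform
per-gene density factor raised to power 1.935, so dense regions have both
tighter inverted pairing and more elements per window, as real Alu-rich
isochores do. Gene-level strand composition follows a Beta prior (nearly
balanced at the default concentration), lengths are truncated normal
(300 ± 60 bp in [50, 600]), and subfamily names are drawn per family.
Intergenic spacers host "islands": bursts of ~14 tightly spaced
same-orientation insertions that emulate clustered retrotransposition.
Islands are returned as ordinary repeats — they belong to the neighbor
pool and to window counts — but lie outside every gene span, so they are
not part of the editability cohort. Their role is to give the neighbor
counts variance that is independent of the focal element's own pairing
distance, which is what makes the count coefficients identifiable at the
stated precision. A heavy-tailed density factor was rejected because it
made cohort-level variance statistics unstable across seeds.

**True editability.** μᵢ = A·exp(−dᵢ/L) + B + βss·Ñssᵢ + βrs·Ñrsᵢ, with
the published defaults (2.9, 800 bp, 0.25, −0.022, +0.015). The counts
enter orthogonalized against distance (empirical d-bin means subtracted,
fine bins where the curve is steep, wider bins over the far range): the
sequential estimator can only ever recover the distance-orthogonal
component of the count effects, so generating that component keeps the
generator's declared truth and the estimator's estimand aligned, leaves
the cohort mean and the curve untouched, and changes the OLS slopes on
raw counts only marginally. Means that fall below the 0.02% floor are
raised to it, and the lift is redistributed within the same distance bin
so no bin mean — hence no point on the fitted curve — is biased.

**Noise.** Editability is non-negative with an SD (1.4595% at the default
28% variance fraction) far above the mean of weakly edited elements, so
any valid noise law is strongly skewed. The realized value is a
zero-inflated Gamma: a floor-level spike plus, with probability p, a
shape-5 Gamma "edited" component whose mean is capped at 12%. p and the
component mean are chosen per element so that the mean is exact and the
variance equals σ²; variance lost to the cap is redistributed across
elements in proportion to μ², keeping the cohort-average noise variance
exactly σ² while protecting the far-distance bins the curve fit depends
on. This construction keeps fourth moments near their feasible minimum —
with plain moment-matched Gamma noise (shape ≈ 0.03 at the baseline) the
cohort variance-explained statistic itself fluctuated by several
percentage points between seeds.

**Read counts.** Per element, Poisson(60) distinct adenosine positions
(minimum 1, capped by length) placed uniformly without replacement;
per-site depth Poisson(50) (minimum 1); per-site editing probability Beta
with mean E/100 and concentration 20 (large site-to-site variability is a
documented feature of real elements); G reads Binomial. Site strand is
the gene strand. Under these defaults the expected per-element depth
(~3000) makes >99% of elements pass the default coverage filters.

**Calibration.** `calibrate_generator` solves the closed-form moment
equations of the pure mixture — E[exp(−kd/L)] = 1/(1 + k·m/L) for an
exponential component — for a requested mean, SD and distance-explained
fraction, returning the mixture and the noise SD
(target_sd·√(1−fraction)). In an actual layout the induced
nearest-reverse distances are shaped by strand runs, islands and density,
so `fit_layout_mixture` refines the mixture against probe layouts under
common random numbers; with `tune_design` it additionally tunes island
size, the strand-bias concentration and the density coupling to null the
sequential estimator's projection bias on the count coefficients. The
shipped `GeneratorConfig` defaults are the refined values (averaged over
four probe layouts). One deliberate trade-off: the default cohort's
marginal SD comes out near 1.8 rather than 1.72, because the mean, the
variance fraction, the curve recovery and the count-coefficient recovery
take priority; the closed-form calibrator still hits all three requested
moments exactly for the pure mixture.

**Determinism.** All randomness flows from the single config seed through
fixed-stage child seeds; identical configs give bit-identical outputs.

## What the synthetic tests do and do not show

Passing the cohort-scale tests demonstrates that the pipeline is
numerically faithful: given data generated under the declared model at
realistic scale, it recovers the generating parameters within the stated
tolerances. It does not validate the biological model itself, the
upstream read alignment and site calling (out of scope), hyper-edited
read rescue, RNA secondary structure, or tissue effects. The generator
reproduces moments of the distance distribution, not the shape of any
empirical distance histogram, and its sequences are not simulated at all
— identity features are exercised on constructed strings.

## Degenerate inputs and edge rules

Thresholds are inclusive; sites with zero total depth are rejected at
parse time; elements without any opposite-strand repeat on their
chromosome carry an absent distance and are excluded from distance-based
fits (but not from coverage statistics); flat editability data fit as
amplitude ≈ 0 with the variance-explained reported as 0; collinear count
designs and sub-3-point distance sets raise errors rather than returning
garbage. Multi-gene containment is resolved to the smallest transcript
span, then lexicographic gene id — the underlying data do not determine
this choice, so it is fixed and documented.
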