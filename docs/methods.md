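# Methods

## The screening model

An operon configuration is a point in a mixed factor space: the promoter
and the RBS at each gene position are *discrete numeric* factors whose
levels are part-strength ranks (1 = weakest within the class), and gene
order is a *categorical* factor with g! levels for g genes. The response
(product titre, mg per g dry cell weight) is modelled as linear in coded
units:

- a rank r in a class spanning [r_min, r_max] is coded
  x = 2(r − r_min)/(r_max − r_min) − 1, so every numeric column lies in
  [−1, +1];
- a categorical factor with k levels contributes k − 1 sum-to-zero
  (effects-coded) columns: level i < k is the i-th unit vector, the last
  level is all −1. Under this coding the per-level effect of level i is
  the i-th coefficient (the last level's effect is minus their sum), and
  the partial F test for a factor block matches the effect-summary
  semantics of standard DoE software.

The default model is main effects only — intercept + 4 numeric columns +
5 gene-order columns = 10 parameters for the canonical 5×3×3×3×6 space.
Two-factor interactions can be added per term; they are not part of the
default because a 41-observation screen leaves little room for them.

Rank, not raw strength, is used as the numeric level. This is a deliberate
coarsening: ranks are robust to the (often large) uncertainty of RPU-style
measurements and keep the coded levels evenly spaced; the cost is that the
fitted "per coded unit" slope cannot be read as "per RPU".

## D-optimal selection by coordinate exchange

The n-run design maximising det(XᵀX) over the N enumerated candidates is
searched by coordinate exchange: starting from a random nonsingular n-row
subset, each design row in turn is tested against every candidate row and
the best determinant-increasing replacement is accepted; sweeps repeat
until a full pass changes nothing (or 50 passes). The determinant ratio of
a single swap (drop u, add v) is computed in O(p²) per candidate with the
rank-two update

    det(M − uuᵀ + vvᵀ)/det(M) = (1 − uᵀM⁻¹u)(1 + vᵀM⁻¹v) + (uᵀM⁻¹v)²,

so one sweep over the 810-candidate, 88-run, p = 10 problem is a few small
matrix products; the full 10-start search runs in well under a second.

Numerical choices:

- swaps are accepted only when the ratio exceeds 1 + 1e−9, making the
  accepted-swap sequence strictly determinant-increasing (no cycling);
- starting designs are validated by matrix rank, not by the determinant
  alone — a determinant of 1e−14 passes a naive nonsingularity test but is
  numerical noise; up to 100 redraws are attempted before a singularity
  error;
- the determinant is tracked as a log-determinant via `slogdet`;
- runs are distinct by default (sampling without replacement); replicated
  runs can be allowed explicitly;
- the search is greedy and multistarted (default 10 seeded starts), not
  globally optimal in general. On every candidate set small enough to
  check exhaustively (≤ 12 candidates, n ≤ 6) the search attains the
  brute-force optimum (tested), and on the 810-candidate space it
  dominates 1000 random designs (tested); global optimality at 88 runs is
  not claimed.

D-efficiency is reported as 100·det(XᵀX)^(1/p)/n, which is 100 for an
orthogonal ±1 design and is bounded above by 100 for any coded matrix with
entries in [−1, 1] (Hadamard bound).

## Build planning

Constructs are realised from the template promoter, (linker+RBS, CDS) per
position, terminator, plus backbone; stitch IDs are zero-padded and
assigned in design order (S001…S088). One destination well per construct
is filled row-major; each construct receives one transfer per DNA element
plus one per shared reagent (a single pooled master mix by default —
enzyme/buffer granularity is configurable but not prescribed). Volumes are
quantised *upward* to the 2.5 nL droplet of Echo-class acoustic
dispensers so molar targets are met or exceeded. Default transfer volumes
(25 nL per DNA part/linker at 76 nM and 1 µM stocks respectively, 500 nL
master mix) are configuration placeholders, not protocol recommendations.
The plan is a pure function of constructs × layout × config; rewriting the
picklist is byte-identical.

## Quantification

Units are fixed package-wide: standard and sample concentrations mg/mL,
volumes mL, DCW g, titres mg/g DCW. Biomass: DCW = 0.36·OD600·V/1000 g —
linear and homogeneous in OD. The standard curve is an ordinary
least-squares line (area = slope·conc + intercept) fitted with an
intercept by default (a zero-intercept variant is available); the default
detection floor is the smallest nonzero standard, since instrument LODs
vary. The 471 nm channel is the default of the two recorded wavelengths
(lycopene's absorbance maximum); 450 nm is selectable. Negative implied
concentrations are clamped to zero (warned when there was genuine signal);
a nonzero signal with zero biomass is an error rather than an infinite
titre.

## Effect screening and prediction

Constructs with no growth or no detected product are excluded from the
titre fit; replicates of a construct are averaged by default (the
screening design carries its information in the between-construct
contrasts; a per-replicate mode exists). The fit is OLS on the coded
matrix; each factor's significance is a partial F test (full model vs the
model without that factor's block), summarised as LogWorth = −log₁₀(p),
capped at 320 against underflow, significant above 2. An interpolating
fit (residual sum of squares at rounding-noise level, below 1e−12·‖y‖²)
reports p at the cap with a warning instead of dividing by zero.
Rank-deficiency of the observed matrix raises an aliasing error naming
single-level factors rather than returning a silently pseudo-inverted
fit. The failure trend (failure vs promoter rank) can additionally be
quantified by a logistic fit.

Prediction evaluates the fitted linear model over all enumerated
configurations; ranks are dense with ties (at 1e−9 relative tolerance)
sharing a rank, so order-symmetric optima are reported together.

## The screening simulator

The simulator generates what the analysis assumes, so that end-to-end
tests measure the statistics, not data quirks. Per selected construct:

- **failure**: Bernoulli with probability logit⁻¹(α₀ + α₁·x_prom), rising
  with coded promoter strength — the metabolic-burden failure trend. A
  failed construct is emitted with empty titres; a fraction p_ng of
  failures shows no growth at all, the rest grow without product.
- **titre**: per replicate, max(0, β₀ + β_prom·x_prom + Σᵢ β_rbsᵢ·x_rbsᵢ +
  γ_order + N(0, σ)); values below the detection floor are flagged
  undetected.

Default ground truth (a calibration, not an estimate — chosen once to
match the study conditions the analysis is meant for):

| parameter | default | rationale |
|---|---|---|
| β₀ | 1.7 mg/g | sets detected titres in ≈ 0.05–4.6 mg/g (≥ 99% of detected replicates inside; per-screen maxima ≈ 4.6) |
| β_prom | −0.8 | strong negative promoter effect (weak promoters win) |
| β_rbs | (0, 0, −0.45) | only the position-3 RBS matters, negatively; positions 1–2 are true nulls for calibration tests |
| γ_order | (−0.6, 1.2, −0.9, 1.2, −0.3, −0.6) | gene order dominates; B-I-E and E-I-B are tied optima (desaturase mid-operon) |
| σ | 0.25 mg/g | replicate-scale noise |
| α₁ | 1.0 | failure odds rise ≈ e-fold per half-range of promoter strength |
| α₀ | solved per design | design-average P(fail to produce) = 0.53 exactly, counting both Bernoulli failures and grown-but-sub-LOD constructs |
| LOD | 0.05 mg/g | detection floor |
| p_ng | 45/47 | share of failures with no growth |

All draws flow through one `numpy` generator: a seed fixes the output
table bitwise. With σ = 0 and failures disabled, titres equal the linear
predictor exactly and refitting recovers the truth to machine precision
(tested).

What the simulator does **not** emulate: growth kinetics, between-batch
effects, part-part interactions (epistasis), chromatogram peak-shape
artefacts, plate position effects, or misassembly genotypes. Passing
tests therefore demonstrate that the statistical machinery is calibrated
and unbiased *under the assumed linear structure*; they say nothing about
whether a real pathway obeys that structure.

## Calibration results the tests enforce

- Coordinate exchange equals exhaustive subset search on all small
  candidate sets tried (≤ 12 candidates, n ≤ 6, 20 starts).
- Over 200 simulated 88-run screens at defaults, the signs of both true
  nonzero numeric effects are recovered in ≥ 95% of screens and each
  true-null factor exceeds LogWorth 2 in ≤ 3%.
- Over 2000 pure-noise screens, each factor is flagged significant at a
  rate within [0, 2]% of the nominal 1% (LogWorth > 2 ⇔ p < 0.01).
- Over 500 screens, the mean failure fraction lies inside the binomial
  95% interval around 0.53.

Problem sizes used throughout (810 candidates, 88 runs, 3 replicates,
200/500/2000 simulated screens) are the package's canonical demonstration
scale; the library itself is size-agnostic.

## Known limitations

- Coordinate exchange offers no global-optimality certificate at
  production sizes (standard for this algorithm class).
- The effects model treats ranks as equally spaced; strongly nonlinear
  strength scales are better served by entering log-strength as a
  continuous factor, which the factor types support but the shipped
  configuration does not use.
- The per-construct mean collapses replicate variance; a mixed model
  would weight unbalanced replication better than the optional
  per-replicate OLS.
- The assembly planner covers transfer logistics only — no linker
  chemistry, thermocycling or transformation modelling.
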