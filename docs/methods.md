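# Methods

## Model and assumptions

`gfabric` treats a condition's transcriptome as a statistical object with
three independent coordinates per gene, estimated across biological
replicates (independent animals or samples of one experimental group;
4 per group in the motivating designs):

* **AVE.** After optional spot collapsing (mean over the valid probing
  spots of a gene, per replicate), every value is divided by the median
  over genes of the per-gene replicate mean. AVE is then the per-gene mean
  of the normalized values, so the median gene has AVE = 1 exactly and all
  levels are expressed in "multiples of the median gene". No other
  normalization is performed: input tables are assumed background-corrected
  and array-normalized upstream, with strictly positive values (flooring of
  values below detection is the caller's responsibility and is validated,
  not applied).
* **REV.** The sample coefficient of variation `s/μ̂` across replicates,
  widened by the mid-interval factor of its chi-square confidence band:
  `REV = 100·CV·½(√(ν/χ²₁₋α/₂;ν) + √(ν/χ²α/₂;ν))` with `ν = n−1` degrees
  of freedom and α = 0.05 by default (configurable). At n = 4 the factor is
  ≈ 2.15. When a gene has several spots, per-spot CVs are pooled as their
  root mean square and ν adds over spots (`ν = #spots·(n−1)`), so technical
  replication tightens the interval. REV is scale-invariant and reported in
  percent; `s = 0` gives REV = 0.
* **COR.** Pearson correlation of log₂ values between every gene pair,
  within one condition. The diagonal is exactly 1. A gene with zero
  log-variance carries no co-variation information; its off-diagonal
  entries are set undefined (NaN) and excluded from every downstream
  average rather than imputed as 0, which would silently deflate hubs.

Control scores derive from REV: `REC = median(REV)/REV − 1` per gene and
`PREC = median(REV)/median(REV over Γ) − 1` per gene set Γ. A gene at the
transcriptome median scores 0; REV = 0 would be infinite control and is
reported capped (default 100, configurable) to keep rankings finite.

## Hierarchy

`GCH = (REC + 1)·exp(4·⟨COR²⟩ − 1)`, where ⟨COR²⟩ is the gene's mean
squared correlation with every other gene (undefined entries excluded).
The exponent is read as `4·⟨COR²⟩ − 1`: this gives a neutral baseline of
exactly 1 (median control, ⟨COR²⟩ = 0.25) and top scores of the observed
order of magnitude (tens) when REC + 1 is large and ⟨COR²⟩ approaches
0.5–0.7. Ranking is by descending GCH with lexicographic tie-break; the
top gene is the condition's gene master regulator (GMR). GCH is a ranking
heuristic, not a causal claim — correlation cannot orient an edge.

## Two-condition comparison

For B (e.g. disease) against reference A, on the intersection of the two
quantified-gene universes (reference order; genes present on one side only
go to a separate presence/absence report, never into the numeric
pipeline):

* signed ratio `x = AVE_B/AVE_A` if ≥ 1 else `−AVE_A/AVE_B` (|x| ≥ 1);
* two-tailed Welch (heteroscedastic) t-test on log₂ normalized values,
  consistent with COR's log₂ convention; two flat identical groups give
  p = 1;
* per-gene cut-off `CUT = 1 + 2·√((REV_A/100)² + (REV_B/100)²)`: the two
  conditions' CVs root-sum-squared above 1. At typical REV ≈ 23% this is
  ≈ 1.65, recovering the classical 1.5×/2× bands as special cases of
  noise; a perfectly reproducible gene has CUT = 1 and any significant
  ratio counts;
* call: UP iff `x ≥ CUT` and `p < 0.05`; DOWN iff `x ≤ −CUT` and
  `p < 0.05`; otherwise NEUTRAL. **No multiple-testing correction is
  applied anywhere**: the composite per-gene criterion (p < 0.05 *and* the
  gene-specific CUT) is the method's definition. The coordination module
  logs the expected false-positive count so users see the consequence of
  the uncorrected 0.05.
* `WIR = AVE_A·sign(x)·(|x|−1)·(1−p)` — zero at x = 1, sign follows the
  regulation direction, damped by statistical uncertainty;
* `ITD = √(d_AVE² + d_REV² + d_COR²)` with `d_AVE = sign(x)(|x|−1)`,
  `d_REV = (REV_B−REV_A)/REV_A` (0 when both are 0; if REV_A alone is 0
  the component is infinite — practically unreachable with noisy data),
  and `d_COR = ½·mean over other genes of |COR_B − COR_A|`. ITD is the
  all-inclusive per-gene distance: a NEUTRAL gene with rewired
  correlations or exploded variability can out-score an UP gene.

Pathway aggregates use `(100/{Γ})·√Σ(·)²` over the quantified members of
Γ (WPR over WIR, PTD over ITD). With this form, a ~40–80-gene pathway
dominated by a single WIR of ≈ −28 yields WPR in the tens, the printed
order of magnitude; the alternative reading `100·RMS` does not. Because
the prefactor is shared, all score *ratios* over a fixed Γ are immune to
this choice. Adding a member with zero alteration strictly lowers both
scores (they are per-member densities), which is intended and tested.

## Coordination classification

The exact small-sample critical value
`r* : |r|√((n−2)/(1−r²)) = t(1−p/2; n−2)` gives r* ≈ 0.950 at n = 4,
p < 0.05. Pairs are SYNERGISTIC (≥ r*), ANTAGONISTIC (≤ −r*), INDEPENDENT
(|r| within a near-zero band, default 0.05 — independence is treated as a
positive finding, not mere non-significance; the band is configurable and
non-significance is recoverable from the edge list), or UNCLASSIFIED
(explicitly kept, never dropped). Partner summaries report a hub's
percentage of each class over a scope excluding the hub (1-decimal
half-up in reports); remodeling diffs report per-partner label sequences
across conditions and the gained/lost sets per transition.

## Recovery metrics

Each gene's category is two letters: its call in disease-vs-reference and
treated-vs-reference (D/U/X with X = NEUTRAL). Then

`GER = 100·(DX + UX − XD − XU − 2·(DU + UD)) / (DX + DD + DU + UX + UU + UD + XD + XU)`

— recovered genes count for, newly dysregulated against, and
regulation-type switches doubly against; genes never regulated (XX) stay
out of the denominator. `PRE = (1 − WPR_treated/WPR_disease)·100` and
`CPR = (1 − PTD_treated/PTD_disease)·100`, with CPR classified ideal
(= 100, treated distance exactly 0), positive, null (= 0), or negative
(treatment moved the pathway farther from reference). All three are ≤ 100
and reach 100 exactly when the treated condition is byte-identical to the
reference. Reports round to two decimals, half-up.

## Synthetic data

The generator draws log₂ expression from a multivariate normal whose
correlation matrix is assembled from within-block constants, then
exponentiates — a correlated log-normal, chosen because coordination is
defined on log₂ values and expression intensities are positive and
right-skewed. Per-gene linear means and CVs are matched exactly via
`σ_ln = √ln(1+CV²)`, `μ_ln = ln(mean) − σ_ln²/2`. Non-PSD assemblies from
overlapping blocks are projected to the nearest correlation matrix
(eigenvalue clipping, logged); a non-PSD single block is an error. Spots
add independent multiplicative log-normal technical noise. Draws are
deterministic given the seed, with one spawned stream per condition.

The canonical fixture is a 200-gene, 4-replicate reference/disease/treated
study whose 40-gene pathway carries designed categories
(DX = 7, UX = 5, XD = 2, DD = 1, rest XX), a designed co-expression block
that moves between conditions, and a low replicate CV (2%) so the designed
calls are the deterministic pipeline outcome; `restored="full"` copies the
reference draws into the treated condition (ideal recovery), `"worse"`
amplifies the dysregulation (negative recovery). What the generator does
**not** emulate: array spatial artifacts, dye effects, count noise,
heavy-tailed outliers, or realistic pathway overlap — so green tests
demonstrate correctness of the estimators and metrics under the stated
model, not robustness to every failure mode of real data.

## Numerical choices and limitations

* Problem sizes in the test suite (200–2,000 genes, up to ~500k pairs)
  are chosen to make Monte-Carlo checks sharp while keeping the whole
  suite fast; all statistics are O(n²) in genes via vectorized NumPy.
* The sample CV at n = 4 is biased low (E[s]/σ ≈ 0.921), so the mean REV
  over many genes recovers the chi-square mid-interval factor times that
  finite-sample expectation, not the factor itself; the parameter-recovery
  test asserts the correct finite-sample expectation against an
  independent Monte-Carlo oracle.
* Ties in GCH ranking break lexicographically; classification boundaries
  are closed (`x ≥ CUT` counts as UP at equality).
* Correlation estimation is raw Pearson — no shrinkage or regularization —
  and at n = 4 individual correlations are extremely noisy; only the
  r* ≈ 0.95 significance band makes calls defensible at that depth.
* Rounding in all printed reports is half-up (two decimals; one for
  partner percentages), matching report conventions rather than Python's
  banker's rounding.
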