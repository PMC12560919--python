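# Methods

## Scope and data model

The package starts where wet-lab quantification ends: a fatty-acid
profile expressed as percent of total identified FAME, an amino-acid
profile in g/100 g fresh meat, and a proximate composition in percent.
Chromatogram parsing, peak integration and FAME identification are out
of scope. Records are sex-stratified (`male`/`female`) because the
downstream contrasts are; group-mean rows are admitted as
pseudo-records so published summary tables flow through the same
pipeline as per-animal data.

Analyte keys are geometry-resolved lipid shorthand (`C18:1 cis`,
`C18:1 trans`, `C18:2 cis`, `C18:2 trans`, `C18:3 cis n3`, …) because
the health indices treat oleic and trans-vaccenic acid differently; a
synonym map resolves trivial names ("Oleic", "Trans-vaccenic") and
punctuation dialects ("C18:3:cis:ω3") onto the 16-acid canonical panel.

## Lipid indices and the two dialects

The atherogenic index, thrombogenic index and h/H ratio are computed
exactly as defined in the README. The class sums follow the standard
convention with one deliberate resolution: the ambiguous "C18:1" in
∑MUFA is oleic (*cis*) only — the reference table's printed MUFA
(37.21 = 0.62 + 2.39 + 34.02 + 0.17 + rounding) is reproducible only
under that reading, and trans isomers are conventionally excluded from
MUFA in the health-index literature.

Two index dialects are exposed because the packaged reference table's
arithmetic deviates from the literature convention in two places, and
both deviations are exactly identifiable from the printed cells:

* **n−6 sum**: the printed male n−6 (6.51) equals C18:2 *cis* + C18:2
  *trans* (3.99 + 2.52) exactly; the conventional n−6 excludes trans
  isomers.
* **h/H numerator**: the printed hypocholesterolemic sums (6.38, 4.52,
  5.89) equal trans-vaccenic + PUFA in all three columns, not
  oleic + PUFA.

`as_published` reproduces the table; `conventional` is the literature
reading. The default is `as_published` because the packaged fixtures
exist for reproduction; the docstrings flag it as a reproduction
dialect, not a recommendation. The "S(n−6)" in the thrombogenic-index
denominator is read as ∑(n−6), validated by exact reproduction of the
male (2.03) and overall (1.54) TI.

A structural note: TI is *not* scale-invariant, although the other
indices are. Its denominator mixes degree-1 class sums with the
dimensionless n−3/n−6 term, so multiplying a profile by k changes TI
(the exact law is TI(k·p) = k·num/(k·(0.5·MUFA + 0.5·n6 + 3·n3) +
n3/n6)). On percent-normalized profiles this never matters; the
property suite asserts exact invariance for AI, h/H, UFA/SFA and
n6/n3, and the algebraic scaling law for TI.

Degenerate inputs: a profile with no unsaturates makes AI undefined
(domain error); n−6 = 0 makes TI undefined (its last term divides by
n−6); no C12:0/C14:0/C16:0 makes h/H undefined; SFA = 0 reports
UFA/SFA as +inf with a warning. Missing panel acids contribute zero
with a warning so partial panels remain scoreable.

Cohort aggregation defaults to computing indices per record and
averaging (the aggregation consistent with per-sample summary columns:
the reference table's overall n6/n3 of 12.07 is a mean of per-sample
ratios, not the ratio 5.39/0.47 = 11.47 of the overall class means);
scoring the mean profile instead is available by flag.

## Protein quality

Profiles convert to protein basis as 100·(g/100 g meat)/protein%. For
the packaged sex-pooled evaluation the protein denominator is the
unweighted mean of the male and female protein percentages
((21.85 + 21.38)/2 = 21.615%) — the only value under which the
packaged basis column reproduces (1.28 → 5.92, 3.00 → 13.88, …); a
group-size-weighted mean is available by flag. The Met+Cys group sums
methionine with the combined cystine+cysteine determination, and
tryptophan uses the total-tryptophan determination; these pairings
reproduce the packaged 4.58 and 13.88 basis values.

Chemical scores are reported in percent. The EAAI is the geometric
mean of the eight scores, computed in log space: tryptophan scores can
exceed 2300%, and while a direct 8-fold product stays inside float64
range, the log form is exact under permutation and immune to
overflow for custom patterns with more groups or larger scores. BV is
affine in EAAI (1.09·EAAI − 11.7, returned as-is with a warning when
negative, i.e. EAAI < 10.73). Reported rounding (two decimals) is
applied only at the reporting layer; all chaining is done unrounded.

The three packaged FAO/WHO age-group patterns (children 43.4, youth
36.0, adults 22.0 g EAA/100 g protein) are fixture data; a custom
pattern (e.g. whole egg, the classical reference) loads from CSV.

## Cohort statistics

Descriptives use the n−1 SD. The sex contrast is the two-group one-way
ANOVA (identical to the equal-variance t-test, F = t²; Welch by flag),
coded `***` p ≤ 0.001, `**` p ≤ 0.01, `*` p ≤ 0.05, `ns` otherwise.

The amino-acid category scheme (essential; flavour = Asp, Glu; sweet =
Gly, Ala, Ser, Thr, Pro; fragrant = Phe, Tyr, Trp; categories may
overlap) is a documented convention from the sensory-amino-acid
literature, fully overridable — the underlying membership lists are
cited inconsistently across studies, so none is ground truth.

PCA is the eigendecomposition of the correlation matrix
(covariance when standardization is off), with the sign convention
that each component's largest-magnitude loading is positive. It
refuses inputs with fewer than three records: a two-row group-mean
table has at most one non-trivial component and its "loadings" would
be noise — which is also why published biplot loadings computed from
unpublished per-replicate data cannot be verified from summary tables.

## Synthetic cohort generator

The generator emulates exactly what a compositional study reports:
independent per-analyte truncated normals (lower bound 0) with the
published group means ± SD, at the published group sizes (27 males,
22 females by default). No inter-analyte covariance is imposed because
none is published; an explicit correlation hook would be the natural
extension but defaults to independence. Consequences: synthetic data
reproduce marginal means, SDs and sex contrasts, but *not* realistic
correlation structure — PCA on synthetic cohorts exercises the
machinery, it does not emulate published biplots, and closure effects
(compositional negative correlation) are absent unless closure is
switched on.

Structural constraints honoured:

* water and dry matter are complementary (dry matter = 100 − water,
  never drawn independently);
* fatty-acid vectors breaching the 101% FAME-sum validity bound are
  redrawn in full (< 1% of draws under the packaged scenarios; the
  induced truncation bias on any single analyte mean is an order of
  magnitude below its 3·SE at n = 1000);
* with `closure_total` set, vectors are rescaled to that exact total
  (off by default — the packaged columns do not sum to exactly 100).

Parameter recovery z-scores compare sample means against the mean and
SD of the *truncated* distribution actually sampled, not the nominal
(untruncated) parameters. For analytes far from the bound these
coincide; near it they do not — arachidic acid in the male scenario
(0.08 ± 0.14) has a truncated mean of ≈ 0.146, and scoring against the
nominal 0.08 would flag a perfectly healthy generator at |z| ≈ 15 for
n = 1000. Scoring against the generating distribution's own moments is
the statistically coherent check.

The proximate invariant protein + fat + minerals ≤ dry matter + 0.5 is
enforced as a warning rather than a hard error: the male scenario's
slack (0.72) is comparable to the combined draw SD (≈ 0.48), so ~7% of
honest independent draws violate it, and rejection sampling would bias
recovered means. Hard validation errors are reserved for the strict
contract: missing sex, negative analytes, FAME sum > 101.

## Fixture tables and known discrepancies

The packaged fixtures transcribe a sex-stratified compositional study
of Aubrac cattle Longissimus dorsi (27 males, 22 females; proximate,
fatty-acid and amino-acid tables plus the FAO/WHO evaluation).
Tolerances for reproduction are ±0.05 absolute for lipid quantities
and ±0.5% relative for protein-quality quantities, both derived from
two-decimal input rounding propagated through the formulas (the
fatty-acid columns themselves sum to 99.9–100.1).

Three printed quantities are irreconcilable with the tables' own
arithmetic and are flagged as known discrepancies by the reproduction
report rather than silently passed or patched:

* **∑TFA** (printed 2.67 / 2.06 / 2.51): the definitional
  trans-vaccenic + C18:2-trans sum gives 4.47 / 2.00 / 3.82. The
  package computes the definitional sum.
* **Female TI** (printed 1.74): recomputes to 1.78 from the printed
  female column; treated as input-rounding noise upstream of print.
* **Overall stearic** (printed 9.86 against sex means 22.15 / 13.45):
  lies outside the convex hull of the group means, which no
  male/female weighting can produce. The overall column is otherwise
  treated as given data, so the overall ∑SFA and UFA/SFA — direct
  arithmetic descendants of stearic — are flagged alongside it. The
  overall TI, which *uses* the printed 9.86, reproduces exactly,
  consistent with a transcription error in the stearic row itself.

## Problem sizes

The test suite's statistical checks use n = 1000 per sex for parameter
recovery (3·SE criterion, ≥ 99% of analytes) and 200 replicates at the
study size (27/22) for contrast power (p ≤ 0.001 in ≥ 90% of
replicates for oleic acid and total amino acids); both are sized so
the binomial acceptance margins are comfortably wide at standard
sampling-theory rates. The full suite runs in well under a minute.
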