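# Methods

## The problem

Case-control studies of oral malignant disorders collect, per subject, a
group label — healthy control, OPMD (oral potentially malignant disorders:
leukoplakia, oral submucous fibrosis, verrucous hyperplasia, erythroplakia)
or oral/pharyngeal cancer — together with coded SNP genotypes and
environmental exposures (age band, ethnicity, education, alcohol, betel
quid, cigarette use).  Single-factor association tests miss joint effects:
a particular *combination* of genotype levels and exposure levels (a
"SNP-environment barcode", e.g. age>50 ∧ Minnan ∧ betel-quid chewer ∧
rs887844 A/G ∧ rs12256889 A/C, written `2-1-1-1-1`) can carry far more risk
than any of its parts.  The number of candidate combinations grows as
∑ₖ ∑_{|S|=k} ∏_{m∈S} Lₘ for level counts Lₘ, so the package pairs a
stochastic search (binary particle swarm optimisation, BPSO) with an
exhaustive enumeration oracle that is still feasible at study scale
(14 factors, order ≤ 6 ⇒ ~10⁴–10⁵ candidates).

## Risk statistics

A barcode partitions each comparison group into **exposed** (matches every
selected level), **unexposed** (differs on a fully observed selected
factor) and **excluded** (missing a selected factor; listwise per barcode).
Two 2×2 tables result — cancer vs control and OPMD vs control, sharing the
control arm — each summarised by:

* crude odds ratio OR = D_E·H_N / (H_E·D_N);
* Woolf (logit) 95% CI, exp(ln OR ± z₀.₉₇₅·√(1/D_E + 1/H_E + 1/D_N + 1/H_N));
* plain Pearson chi-square on the raw counts (1 df, no continuity
  correction), computed with the algebraically identical 2×2 shortcut
  N(ad−bc)²/(row·column margins).

Zero cells: the Haldane–Anscombe correction (+0.5 on all four cells) is
applied *only when a zero is present* and *only* for the OR and CI; the
chi-square always uses raw counts, and a zero margin leaves it undefined
(NaN), which the fitness treats as non-significant.  Reports round OR/CI to
2 decimals; full precision is retained internally.

## Search objective

Candidate barcodes are scored by

  f = S(OR_CvN) + S(OR_PvN) + S(OR_CvN − OR_PvN) + p,

with S the logistic sigmoid and p = 1 iff both comparisons have chi-square
p < α (default 0.05), else 0.  Defined fitness lies in (0, 4).  The
objective prefers combinations that are high-risk in both case groups,
*separate* the cancer and OPMD groups (the Δ = OR_CvN − OR_PvN term), and
are jointly significant.  Note S saturates quickly: for OR ≳ 5 the first
two terms are within 0.01 of 1, so discrimination among strong barcodes
comes mostly from the Δ term and the significance indicator.  The sigmoid
is applied to the OR values literally, without rescaling.

## Binary particle swarm

Each particle encodes a barcode with two bits per factor: (0,0) unselected,
otherwise status s = 2b₁+b₂ ∈ {1,2,3} selecting level code s−1 (so status 1
reaches code 0, e.g. alcohol non-drinkers — barcode `2-0`).  A status whose
level is not valid for that factor leaves it unselected, so every bit
pattern is decodable.  Per iteration and per dimension, with fresh uniform
r₁, r₂, r₃:

  v ← clip(v + c₁r₁(pBest − x) + c₂r₂(gBest − x), v_min, v_max)
  x ← 1 if S(v) > r₃ else 0

Positions and velocities initialise uniformly; particles decoding to the
empty barcode are re-sampled a bounded number of times at initialisation.
pBest/gBest update on *strict* improvement, so the gBest fitness trace is
monotone non-decreasing and ties keep the earliest incumbent.  A single
seeded generator drives everything; identical seeds give identical runs.

Defaults: N = 50 particles, 100 iterations (the only stopping rule),
c₁ = c₂ = 2.0, velocity clamp ±2, α = 0.05, no order cap.  The clamp was
calibrated against the exhaustive oracle on planted synthetic cohorts: at
the textbook ±6 a converged swarm flips bits with probability
S(−6) ≈ 0.0025 and stalls on local optima (it found the true optimum in
~85% of 100 seeded runs), while ±2 keeps a 0.12 per-bit exploration rate
after convergence and found the optimum in 99–100% of the same runs.
No inertia weight or constriction variants are used.

`max_order` caps barcode order at decode time.  Over-cap decodes score
−(order − max_order): strictly below every defined fitness, so they can
never be a final answer, but graded so that a randomly initialised swarm
(whose uniform bit patterns decode to order ≈ 3M/4, far above a small cap)
is steered toward the feasible region instead of wandering a flat −∞
plateau.  A flat sentinel was measurably less reliable.  The empty barcode
and undefined evaluations keep the −∞ sentinel.

Fitness values are cached per barcode (the evaluation is a pure function
of the cohort), with per-(factor, level) match masks precomputed once.

## Exhaustive oracle and ranking

`ExhaustiveBarcodeSearch` enumerates every barcode in an order window in a
deterministic order, refuses enumerations above a configurable safety bound
(default 10⁶), and ranks by fitness (ties: Δ descending, then lower order,
then label) or by Δ with `rank_by="delta"`.  It is the ground truth against
which the swarm is validated, and regenerates top-k ranking tables exactly
at study scale.

## Risk classification

A priority-ordered family of barcode models (typically the nested family
from the search, highest order first) scores each subject with the
pooled-case odds ratio (OPMD+cancer vs control, Haldane-corrected) of the
first model it matches as exposed; unmatched subjects — including those
excluded from every model by missingness, which are flagged — carry the
reference score 1.0.  The ROC pools OPMD and cancer as "case", the AUC is
trapezoidal (equal to the tie-corrected pairwise rank statistic), and the
operating cutoff maximises Youden's J = sensitivity + specificity − 1,
with ties resolved to the higher-specificity threshold; score ≥ cutoff is
called high risk.  The per-subject scoring construction is a
reconstruction of the published analysis style — the exact construction
behind the study's reported AUC and cutoff is not documented — so those
published operating numbers are treated as qualitative context, not as
reproduction targets.

## Synthetic cohorts

The generator emulates the study's structure: groups of 264 controls, 70
OPMD and 242 cancer subjects; a panel of 7 environmental factors and 7
SNPs whose level frequencies are the study control group's marginals (SNPs
with an unobserved homozygote class are coded {1,2}; two panel levels are
degenerate in controls — male sex at 100% and one SNP fixed at its
heterozygote class — exactly as the source marginals have them).  All
groups draw from the control marginals, so without planting every barcode
has expected OR 1 in both comparisons.

A planted effect fixes a barcode and per-case-group target ORs.  Controls
are drawn first; the case exposure probability is solved from
p/(1−p) = OR_target · o_ctrl against the *realised* control exposure odds
o_ctrl, and realised as an exact count (⌊np⌋ exposed subjects plus one more
with probability np−⌊np⌋, at uniformly chosen positions).  Exposed subjects
receive the member levels jointly; non-exposed subjects redraw member
factors from the background until they do not match the full barcode;
non-member factors stay independent.  Exact-count planting keeps the
realised OR on target so that recovery experiments measure search
behaviour rather than binomial noise.  Missingness (default 0) is applied
last, completely at random.  What the generator does **not** model:
linkage between SNPs, population stratification, group-specific background
frequencies, covariate confounding, or informative missingness — so
passing recovery tests demonstrates search correctness under clean joint
effects, not robustness to real-data pathologies.

## Validation experiments

Two standing seeded experiments (`snpbarcode.experiments`):

* **Oracle equivalence** — 20 planted cohorts over an 8-factor sub-panel
  (the environmental factors minus sex, plus rs4411227 and rs887844); one
  swarm run each (N=50, 100 iterations, max_order=3) must attain the
  enumerated maximum fitness.

* **Planted recovery** — the standing planted effect is education>6y ∧
  betel-quid chewer ∧ rs887844 A/G at cancer OR 8 and OPMD OR 4.  The 2:1
  gradient mirrors the study's own best models (10.30 vs 5.42) and
  maximises S(OR_PvN) + S(Δ) at OR_CvN = 8; the member levels have
  moderate background frequencies (0.78, 0.83, 0.375) so that every
  sub-barcode is strongly diluted while the OPMD cells stay large enough
  for certain significance.  A study-panel cohort is generated and
  screened with the oracle until the planted barcode is its verified
  fitness optimum, then 20 independently seeded swarm runs are scored for
  returning it as gBest.

The screening step matters: at n = 576 (and only 70 OPMD subjects) the
saturating objective gives small-cell barcodes heavy-tailed fitness draws,
and across the full ~4.4×10³-candidate order-≤3 space a sampling fluke or
a near-clone displaces the planted barcode as the *true* optimum in a
measurable fraction of cohorts.  That generator-level property is reported
separately as the planted-optimum rate (~80–90% across seeds under these
conditions) rather than being conflated with search failure; asking the
swarm to return a barcode that is not the objective's optimum would test
the wrong thing.

## Numerical and interface choices

* Missing-value tokens on input: `NA`, empty, `-`; values are never imputed.
* Hardy-Weinberg equilibrium is tested per group by the 1-df goodness-of-fit
  chi-square from estimated allele frequencies, only for SNPs with all
  three genotype classes codable; two-class SNPs are reported
  not-applicable.
* Group-difference p-values in cohort summaries use the Pearson chi-square
  on the level×group table without continuity correction; a single
  observed level yields an undefined p-value, not an error.
* The swarm's top-k ranking breaks fitness ties toward lower order
  (parsimony) then lexicographic label.
* Estimators follow scikit-learn conventions (`fit(X, y)`, fitted
  attributes with trailing underscores, `get_params`/`set_params`); `X`
  may be a DataFrame/array of integer codes (NaN = missing) with `y` the
  group labels, or a `Cohort` directly.
* The CLI writes TSV reports (2-dp rounding at the presentation layer
  only) plus a JSON run manifest with resolved parameters, seed, input
  digests and package version.

## Known limitations

* The fitness's sigmoid saturation makes rankings among strong barcodes
  (OR ≳ 5 in both arms) depend almost entirely on the Δ term, which has
  the highest sampling variance of the three — exact model selection at
  these group sizes is intrinsically noisy.
* Crude ORs only: no covariate adjustment, stratification or exact tests.
* The risk classifier's subject scoring is a reconstruction (see above);
  AUC confidence intervals are not computed.
* The generator's independence assumptions (no LD, shared background
  marginals) are simplifications; recovery rates measured on it do not
  transfer directly to real cohorts.
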