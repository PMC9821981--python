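# Methods

## Problem setting

A retrospective virtual-screening benchmark consists of N molecules — n
confirmed actives and N − n presumed-inactive decoys — each scored by J
docking programs.  The package evaluates how well each program, and each
consensus combination of programs, concentrates the actives at the top of
the ranked library.

## Score tables, orientation, ranks

Docking programs disagree on sign conventions, so orientation
(`lower_better` / `higher_better`) is explicit per-program metadata, supplied
by the user and never inferred from the data.  All internal work happens
after re-orientation to a single higher-is-better convention (lower-better
scores are negated).  Ranks use the average ("fractional") tie convention:
tied scores receive the mean of the positions they span.  This keeps rank
sums exactly N(N+1)/2 and makes every rank-based consensus deterministic
without arbitrary ordering.  Molecule IDs are compared case-sensitively
after whitespace trimming; scores are stored and round-tripped at full
(`repr`) precision.

## Benchmark assembly

Actives are molecules with IC50 strictly below the threshold (default
200 nM); the boundary value is excluded.  Decoys are attached at a fixed
ratio per active (default 50), and an oversupply of decoy IDs is resolved by
deterministic ID-sort truncation so assembly needs no seed.  The default
212-active preset therefore yields 10,600 decoys and a 10,812-molecule
library.

Alignment produces one molecule × program matrix.  Molecules a program
failed to score are handled by policy:

- `penalize` (default): the molecule receives that program's worst oriented
  score minus one resolution step (the smallest positive gap between
  distinct scores, or 1 if all scores coincide), hence rank N_j + 1.
  Dropping failures silently would bias enrichment upward, so penalization
  is the default.
- `intersect`: molecules missing from any program are dropped and the label
  bookkeeping updated.

## Consensus strategies

All strategies emit higher-is-better combined values with regenerated
average-tie ranks.  With r_ij the rank and s_ij the oriented score of
molecule i in program j:

| method | combined value |
|---|---|
| RBR | −(1/J) Σ_j r_ij |
| RBN | (1/J) Σ_j s_ij |
| RBV | Σ_j 1{r_ij ≤ ⌈xN⌉}, ties broken by the RBR value |
| AASS | (1/J) Σ_j (s_ij − min_j)/(max_j − min_j) |
| Z | (1/J) Σ_j (s_ij − mean_j)/sd_j |
| ECR | Σ_j (1/σ) exp(−r_ij/σ) |
| NSR | (1/J) Σ_j s'_ij / max_i s'_ij, s' shifted non-negative |

Design choices in the genuinely open spots:

- **RBV cutoff**: rank percentile (not score percentile), cutoff ⌈xN⌉ with
  x = 0.10 by default; an average-tie rank straddling the cutoff votes iff
  its value is ≤ the cutoff.  The vote count alone produces massive ties, so
  the stored combined value embeds the RBR ordering as a deterministic
  secondary key scaled into (0, 1) — votes always dominate.  With x = 1 the
  ordering therefore reduces exactly to RBR.
- **ECR σ**: defaults to 0.05·N, tying the exponential window to the
  early-recognition region (the top few percent of the library) that the
  method is designed to emphasize; fully configurable.
- **Z-score SD**: population (divide-by-N) by default, since the scored
  library is the entire population of interest; `zscore_ddof=1` switches to
  the sample SD.
- **NSR**: the name circulates in the consensus-docking literature without a
  published formula.  The definition here — shift each program's oriented
  scores non-negative when any are negative, divide by the shifted maximum,
  average — is this package's own documented choice.  When scores are
  already non-negative with minimum zero it coincides with AASS.
- **Degenerate programs**: a program with all-equal scores contributes 0 to
  AASS/Z/NSR with a logged warning rather than erroring — it carries no
  ordering information but should not abort a multi-program run.

Top-k intersection (default k = 1000) reports each program's top-k set and
the intersection of every program subset, with active counts when labels are
supplied — the numbers a Venn diagram of program agreement shows.

## Metrics

All metrics consume a hit list: benchmark molecules ordered best-first, ties
resolved deterministically by molecule ID, with the average-tie rank values
retained.

- **Confusion/rates** at cutoff k = ⌈χN⌉: TPR, PRE, FPR, TNR from the four
  counts.
- **EF(χ)** = (a_k/k)/(n/N); bounded by min(1/χ, N/n) and exactly 1 at
  χ = 1.
- **ROC-AUC**: the rank-sum (Mann–Whitney) estimator with half credit for
  active/decoy ties — AUC = [n(N+1) − Σ r_act − n(n+1)/2]/(n·m).  It equals
  the trapezoidal area of the tie-aware step curve and is oracle-checkable
  by brute-force pair counting.
- **PR-AUC**: average precision without interpolation (precision at each
  active's position, averaged over actives).
- **RIE(α)**: Σ_actives e^(−α·r_i/N) divided by its closed-form expectation
  under uniformly random ranks, (n/N)(1 − e^(−α))/(e^(α/N) − 1); a random
  ranking scores ≈ 1.  α defaults to 20, the conventional early-recognition
  emphasis (weight concentrated in roughly the top 1/α of the list).
- **BEDROC(α)** = (RIE − RIE_min)/(RIE_max − RIE_min), with the endpoint
  RIEs evaluated in closed form for the perfect and inverted rankings.
  RIE/BEDROC use the deterministically resolved integer positions (not
  average-tie values) so the normalization endpoints are exact and the
  [0, 1] bound holds for every input.
- **Enrichment plot**: % actives recovered vs % library screened on a
  30-point log-spaced grid from 0.1% to 100%, matching the semi-log axis
  such plots are conventionally drawn on.

### Bootstrap

Errors are estimated by resampling the (rank, label) hit list with
replacement B = 1000 times (the conventional sample count), recomputing each
metric per resample with ties re-ranked by original rank, and reporting the
resample mean, SD and 2.5/97.5 percentile CI.  A resample that loses an
entire class is redrawn (logged, capped at 100 consecutive redraws before a
hard error) so all B samples are effective.  Within `evaluate_all`, the same
B resamples serve every metric of a given method, and per-method bootstrap
streams are derived from the master seed by hashing the method name — results
are independent of mapping order and fully reproducible.

## Synthetic score generator

The simulator draws, for molecule i and program j,

    score_ij = δ_j·1{i active} + τ_j(√ρ·t_i + √(1−ρ)·e_ij)

with t_i and e_ij independent standard normals.  δ_j is program j's
active/decoy mean gap, τ_j its label-conditional SD, and ρ the
label-conditional between-program correlation.  The implied per-program
ROC-AUC has the binormal closed form Φ(δ_j/(τ_j√2)), which the tests use as
an analytic parameter-recovery oracle.  Emitted tables are affinely mapped
to program-native-looking units, with mixed lower-better / higher-better
orientations so the alignment path is exercised.  Per-program random
streams are derived from the master seed by hashing the program ID, so
adding a program never perturbs the others' draws.

The `trpv1_preset` (212 actives, 50 decoys each, seven programs named after
a typical docking/rescoring line-up, ρ = 0.3, δ spanning 0.30–1.10) is a
qualitative stand-in for a real antagonist screen: the separations are
illustrative, chosen so the programs span weak to moderate discrimination
(AUC ≈ 0.58–0.78), and are not calibrated to any measured campaign.

What the generator does **not** emulate: chemical structure, property-matched
decoy biases (analogue, artificial-enrichment, false-negative), heavy-tailed
or multimodal score distributions, and systematic docking failures.  Passing
tests therefore demonstrate correctness of the consensus/metric machinery
and qualitative transfer of the consensus-gain effect under a Gaussian
model — not performance claims about any particular real target.

## Numerical and scale choices

- Calibration tests at the full preset scale (10,812 molecules) use a
  handful of replicates and 3-standard-error bands; a single replicate's AUC
  has SD ≈ 0.02 at 212 actives, so one-draw point checks would be noise-
  dominated.  The consensus-gain replication uses 20 replicates of five
  equal-power programs (individual AUC ≈ 0.70, δ = √2·Φ⁻¹(0.70), ρ = 0.3).
- Unit and pipeline tests run on scaled-down libraries (tens to hundreds of
  molecules, B = 20–400 bootstrap resamples), chosen as the smallest sizes
  at which the checked statistics are stable.
- ECR values at the default σ = 0.05·N stay far from floating-point
  underflow (exp arguments ≥ −20 at rank N).

## Known limitations

- Score-level only: no poses, no RMSD-based consensus, no rescoring engines.
- NSR is a package-defined statistic (see above) and is flagged as such.
- Analytic variance formulas for AUC/EF are not implemented; the bootstrap
  is the only error estimator.
- The bootstrap resamples molecules of a single campaign; replicate-docking
  variability is out of scope.
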