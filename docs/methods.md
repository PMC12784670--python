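# Methods

## Setting and data model

Spontaneous reporting systems collect individual case safety reports
(ICSRs): one report per suspected adverse event episode, carrying drug
mentions with reporter-assigned roles (primary suspect PS, secondary
suspect SS, concomitant C), reactions coded as MedDRA preferred terms
(PTs), free-text indications, and demographics with heavy missingness.
A case may be resubmitted; analysis keeps only the latest version per
(database, report id), breaking exact version ties by keeping the
last-read record with a logged warning. Text is uppercased and trimmed
for matching while verbatim values are preserved for output.

Two file dialects are read and written: a normalized four-table TSV
schema (reports / drugs / reactions / indications) and a minimal
FAERS-quarterly-style `$`-delimited DEMO/DRUG/REAC/INDI layout. Ages
and weights are binned at ingest into the reporting bands 12–17 /
18–64 / 65–85 years and <50 / 50–100 / >100 kg; ages outside 12–85 have
no band and become unknown. Occupation codes MD/PH/OT/HP count as
health-care professionals. Role codes other than PS/SS/C (e.g.
interacting) are treated as concomitant.

## Cohort, exposure, endpoints

The glioma cohort is built by case-insensitive contiguous-substring
matching of configured tumor terms over the indication and
history/diagnosis fields. Substring (not word-boundary) semantics are
deliberate — `ASTROCYTOMA` matches `ANAPLASTIC ASTROCYTOMA` — and the
shipped broad term list is closed under substring containment, so no
over-capture occurs within it. The strict definition (malignant glioma,
glioblastoma, glioblastoma multiforme, anaplastic astrocytoma) is a
subset of the broad one, so the strict cohort is provably a subset of
the broad cohort. Abbreviations such as "GBM" are not in the default
lists (configurable).

Drug names are normalized to uppercase generics through an editable
brand map (Avastin→bevacizumab, Temodar/Temodal→temozolomide,
Gleostine/CeeNU→lomustine, BiCNU/Gliadel→carmustine, plus biosimilars).
A report is exposed to a drug when any entry carries its generic name,
under either role filter: any role (main analyses) or primary suspect
only (sensitivity).

Endpoints are composite PT sets (VTE, CNS bleeding, GI bleeding),
compared by exact string equality after case normalization — no MedDRA
hierarchy expansion. A report counts once per endpoint regardless of
how many matching PTs it lists, and may count toward several endpoints.
The shipped PT lists are a clinically reasonable approximation (the
exact lists behind the source tables are not published); they are
config, not code, and the three defaults are pairwise disjoint by
construction (validated at load).

## Disproportionality statistics

For each pair the 2×2 table holds deduplicated report counts a, b, c, d
(see README for the formulas). Numerical choices:

- z = 1.959964 for all 95% intervals.
- Zero cells: Haldane–Anscombe +0.5 on all four cells for the ratio
  estimates, with the result flagged; the chi-square is computed on the
  raw cells unless a margin is zero.
- A drug absent from the cohort yields a degenerate (0, 0, c, d) table;
  pipeline assembly computes its statistics on the corrected cells and
  flags the pair not analyzable rather than erroring, while the
  operation-level PRR keeps its "undefined proportion" error.
- Pearson chi-square without continuity correction; the recovery oracle
  (below) accepts the Yates-corrected variant as well, since published
  tables rarely state which was used.
- Signal rule: a ≥ 3 and ROR CI lower bound > 1 (strict inequality).
  Pairs with a < 3 are never evaluated for signal; their counts are
  still reported.
- Reported tables round to 2 decimals; computation is full precision.

### Empirical-Bayes shrinkage

The gamma–Poisson shrinker places a two-component gamma mixture prior
on the relative reporting rate λ = observed/expected. Hyperparameters
(α₁, β₁, α₂, β₂, w) are fitted by maximizing the marginal likelihood —
a mixture of negative binomials — over all (a, E) pairs of one analysis
call, via L-BFGS-B on log/logit-transformed parameters from the
conventional start (0.2, 0.1, 2, 4, 1/3), bounded to e^±7. The fit is
deterministic given inputs. Calls with fewer than 10 pairs (or fewer
than 2 distinct counts) fall back to the starting prior, flagged
`low_information`; non-convergence raises an error carrying the
best-found parameters, and the pipeline degrades to that best fit with
the same flag.

Posterior summaries are closed-form: component posterior weights from
the negative-binomial likelihoods, EBGM = exp of the
digamma-moment posterior mean of ln λ, EB05 by Brent root-finding on
the mixture gamma CDF. The test suite checks both against dense
log-scale trapezoid integration of the posterior density to 4
significant figures, and checks the large-count limit EBGM → O/E.

## Analyses

- **Main**: each prespecified drug × endpoint within the broad cohort,
  one database per call (databases are never pooled). The shrinkage
  prior is fitted once per call on that call's 12 pairs.
- **Regimen stratification**: bevacizumab-exposed cohort reports are
  partitioned by co-reported chemotherapy into monotherapy,
  +temozolomide, +lomustine, and other combinations (bevacizumab with
  both temozolomide and lomustine). Each focal group is contrasted
  against all other bevacizumab-containing regimens; triple
  combinations only ever contribute to the comparator cells, since the
  three-group scheme leaves them unassigned. Regimen assignment always
  uses any-role exposure. Monotherapy is the reference for presentation
  only — cells are computed identically for every focal group.
- **Sensitivity**: identical machinery with the strict cohort
  definition, or with bevacizumab exposure restricted to primary
  suspect mentions; output is tagged and reported side by side with the
  main analysis.
- **Descriptives**: per-drug counts/percentages of sex, age band,
  weight band, reporter type and seriousness, including unknown rows
  (percentages sum to 100 per block).

## Recovering 2×2 tables from published rows

Published tables print (a, ROR, PRR, χ²) per row but not b, c, d.
These statistics jointly over-determine the table up to rounding, so a
constrained integer search recovers the compatible tables: for fixed b
the ROR and PRR rounding bands confine the ratio d/c to a narrow
interval, and the chi-square band then pins c to a window found by
monotone bisection (the ratio interval is sampled at five points since
χ²(c; ρ) is not monotone in ρ). Every candidate is verified exactly
against all three bands before acceptance. Accepted intervals are the
half-ulp rounding band of each printed value, widened by a relative
tolerance (default 0.5% for the ratios, 1% for χ², both accommodating
unknown rounding modes); either chi-square variant may match. An empty
solution set raises an "unrecoverable" error; tolerances are never
widened silently.

Solution families can run to millions of tables. Exhaustive mode
enumerates them all within memory-bounded batches (used for round-trip
testing with pure rounding bands); survey mode (`per_b_cap`) examines a
stride-centered sample of each b's window, covering the full range of
feasible exposure sizes, and flags the result `sampled`.

CI verification recomputes the Woolf interval on the family and reports
per-bound agreement with the printed CI plus the spread. The
representative value is a *b-profile median* — the median over feasible
b of the within-b median bound — so each exposure size weighs equally
rather than by how many rounding-compatible (c, d) cells it admits.
Caveats established empirically and reflected in the tests: rows
printed at one decimal carry a ±3.6% ROR band and a correspondingly
wide family; rows where the printed ROR and PRR differ by <0.02, and
rows with χ² < 1, are near-degenerate (the family's b range is
effectively unbounded) and are excluded from spread assertions, though
their representative bounds still reproduce the printed values. Spread
tolerances are 2% of the bound for rows with a ≥ 100 and 5% below
(rounding perturbs a small-count interval proportionally more).

## Synthetic reporting databases

The generator emulates the structure the analysis assumes, with known
ground truth:

- **Exposure**: a log-linear joint model over the configured drugs —
  marginal probabilities (bevacizumab 0.30, temozolomide 0.35,
  lomustine 0.10, carmustine 0.02) tilted by pairwise co-prescription
  odds (bev+tmz 2.0, bev+lom 1.5), sampled by exact enumeration of the
  2^K exposure patterns. Carmustine's low marginal mirrors its sparsity
  in practice and routinely exercises the a < 3 path.
- **Events**: each endpoint fires with logistic odds
  `logit p = logit(base) + Σ_exposed ln(multiplier)`; baselines 0.06 /
  0.04 / 0.025 for VTE / CNS / GI reflect a glioma-enriched reporting
  stream. Effects are odds multipliers so the estimand matches the ROR
  exactly; defaults are patterned on the observed FAERS glioma signals
  (bevacizumab 2.3 / 1.5 / 2.3, temozolomide 1.0 / 0.8 / 1.4, lomustine
  1.4 / 0.35 / 0.45, carmustine 1.4 / 1.75 / 1.0).
  `true_odds_ratio` returns the population marginal odds ratio by exact
  enumeration — including co-prescription confounding — and is the
  recovery target for parameter-recovery tests.
- **Reports**: glioma fraction 0.80 (60% of those with strict-set
  terms, mixed case, to exercise matching); 1–4 weighted background
  PTs; 1–2 background concomitant drugs; brand-name verbatims 30% of
  the time; demographic missingness patterned on the observed
  bevacizumab column (sex 40%, age 45%, weight 71%, reporter 10%
  unknown); seriousness 18%. Duplicates (probability 0.05) differ only
  in version and one perturbed demographic field, making deduplication
  correctness observable.
- Identical config + seed gives identical output. Two sampling surfaces
  share the probabilistic core: `generate` materializes Report objects;
  `simulate_tables` returns cohort 2×2 tables straight from the arrays
  for large replicate studies. Their exact agreement is itself a test.

What the generator does not emulate: reporting delays and calendar
time, notoriety and stimulated-reporting waves, non-English indication
text, correlated endpoint reporting within a report, and
exposure-dependent cohort membership. Passing calibration tests
therefore demonstrates correctness of the statistical machinery under
the stated model, not robustness to these real-data phenomena.

## Validation study sizes

Calibration and recovery studies use: 500 replicates of 5,000-report
null databases (signal-rule false-positive fraction within
[0.02, 0.09]); 100 replicates of 200,000-report databases for
bevacizumab–VTE parameter recovery (mean ROR in (2.1, 2.5), ≥90% CI
coverage of the enumerated truth); 100 random (a, E, prior) triples for
the EBGM integration oracle; and 200 random well-conditioned tables for
search round-trips. Published-row verification surveys families with
`per_b_cap=3` and a 3-million-solution budget, which covers the full
feasible b range of each of the four verified rows.

## Known limitations

- Endpoint PT lists approximate the (unpublished) originals; both the
  cohort terms and PT sets are configuration.
- The published signal column contains one row (FAERS temozolomide–GI)
  whose printed label contradicts the stated rule's own inputs; the
  package implements the stated rule, so that row is reproduced as
  "Yes" where the source prints "No".
- IC025/EB05 closed forms are standard approximations; exact
  reproduction of the source's Bayesian bounds is not possible without
  the authors' raw extraction and is not attempted.
- The recovery oracle reports a family representative; for rows printed
  at one decimal the family is wide and the representative may differ
  from the printed bound in the last digit.
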