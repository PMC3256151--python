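# Methods

## The kinetic model

The model is the Hockin–Mann mass-action description of tissue-factor-
initiated coagulation: 34 chemical species connected by 43 elementary
reaction arrows (42 named rate constants; one first-order decay constant
is shared by the two intrinsic-tenase VIIIa-dissociation arrows). The
topology covers

- **initiation** — TF binds fVII/fVIIa; TF:VIIa (extrinsic tenase)
  activates fX and fIX, and fXa/thrombin back-activate fVII;
- **propagation** — thrombin activates fVIII and fV; fIXa·fVIIIa
  (intrinsic tenase) activates fX far faster than the extrinsic tenase;
  fXa·fVa (prothrombinase) converts prothrombin to thrombin via
  meizothrombin; fVIIIa loses its A2 subunit (VIIIa1-L + VIIIa2) with
  first-order decay of the tenase-bound cofactor;
- **termination** — TFPI traps fXa and the TF:VIIa:Xa product complex;
  AT irreversibly neutralizes thrombin, meizothrombin, fIXa, fXa and
  (switchably, on by default) TF:VIIa.

Not modeled: the protein C pathway, platelets, the contact pathway and
the vasculature. The model therefore describes the procoagulant potential
of the plasma proteome under a fixed TF stimulus, not full hemostasis.

Rate constants are transcribed in `src/coagxa/data/rate_constants.yaml`
(association in M⁻¹s⁻¹, dissociation/catalysis in s⁻¹), one auditable key
per arrow; the loader rejects missing or non-positive entries.

### Inputs and initial condition

A subject is eight percent-of-mean factor levels. Molar values are
`percent/100 ×` the literature mean concentrations
(`data/mean_concentrations.yaml`):

| factor | 100% equals | | factor | 100% equals |
|---|---|---|---|---|
| fII | 1.4 µM | | fIX | 90 nM |
| fV | 20 nM | | fX | 170 nM |
| fVII | 10 nM | | AT | 3.4 µM |
| fVIII | 0.7 nM | | TFPI | 2.5 nM |

At t = 0 the zymogens and inhibitors sit at their molar values, TF at the
trigger concentration (default 5 pM), fVIIa at 1% of the subject's molar
fVII (both VII and VIIa scale with the subject's fVII level), and every
enzyme, active cofactor and complex at zero.

### Integration

Stiff adaptive integration (LSODA) with an analytic mass-action Jacobian,
rtol 1e-8 and atol 1e-14 M, sampled on the closed 1 s grid [0, 3600]
(3601 points). Sub-tolerance negative excursions are clamped to zero in
reported trajectories only — never fed back into the solver — and the
unclamped solution is retained for conservation checks. Identical inputs
give bit-identical trajectories.

Two invariants guard the implementation: (i) every reaction conserves
each protein moiety (the A2 fragment VIIIa2 carries weight 0 in the fVIII
balance, making the VIIIa1-L-tracked balance exact), checked statically
on the stoichiometry and dynamically along trajectories to within 10×
solver tolerance; (ii) the adaptive solution agrees with an independent
fixed-step RK4 integration at dt = 1 ms to ≪ 0.5% relative on total
active fXa. The RK4 step of 1 ms is comfortably inside the stability
limit of the system's fastest rates (~10² s⁻¹ at plasma concentrations).

## Generation-curve metrics

The fXa read-out is **total active fXa** = Xa + Xa:Va + Xa:Va:II —
free fXa plus prothrombinase-resident fXa, including the substrate-bound
complex (a config switch excludes it); fXa held in TF:VIIa:Xa, Xa:TFPI,
Xa:AT or the quaternary TFPI complex is catalytically unavailable and
excluded. The thrombin read-out is IIa + 1.2 × mIIa; meizothrombin's
weight reflects its partial activity in the read-out convention of the
source model and is configurable (1.0 available).

Metric conventions, fixed for file-level reproducibility:

- MaxL = series maximum; TMaxL = earliest attaining grid time;
- rate series = 1 s forward difference assigned to the later endpoint;
  MaxR = its maximum, TMaxR = earliest attaining time;
- AUC = Σ level × step (rectangle rule), matching a per-second summed
  concentration; trapezoid would differ by ≤ one endpoint term;
- reporting units: fXa nM / pM·s⁻¹ / µM·s, thrombin nM / nM·s⁻¹ / µM·s.

All metrics are recomputable from the trajectory TSV alone (no solver
state), which the tests exploit as an independent oracle.

## Cohort risk statistics

- The 90th-percentile cutoff is the nearest-rank order statistic of the
  **pooled** cases+controls values (computed once, then applied within
  subgroups); "above" is strictly greater. On n = 899 with distinct
  values this puts 89 subjects above, ≈10%.
- Odds ratio (a·d)/(b·c) with the Woolf log-normal 95% CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); any zero cell → undefined (a
  value, not an error). This CI method reproduces the published intervals
  (e.g. 1.3–3.2 around 2.1; 1.8–135 around 15.7).
- Fisher's exact two-sided p from scipy (hypergeometric enumeration); a
  hand enumeration over all tables with fixed margins serves as the
  independent oracle in the tests.
- Group comparisons: each sample is KS-tested against a normal with its
  own moments at α = 0.05; both normal → two-sample t-test with a
  difference-of-means 95% CI, otherwise Mann-Whitney.
- Covariate trends: OLS slope with a normal-approximation 95% CI.
- Subjects missing a stratification field are excluded from that
  stratification only. Report tables round ORs/CIs to one decimal;
  machine outputs keep full precision.

## Normalization search

The discrepancy between a curve and a reference curve is the worst
relative deviation of MaxL, MaxR and AUC from the reference (times are
deliberately excluded: they are not scale-equivariant and the published
normalization judgment concerns curve magnitude). "Normalized" means
discrepancy ≤ θ, default 0.05. The search is exhaustive over the 2⁸
factor subsets by increasing cardinality (each subset = one simulation;
the reference curve is simulated once), returning the first cardinality
that passes, ties broken by smallest discrepancy — no greedy heuristic,
so the minimality claim is witnessed by the recorded per-cardinality
trace. Adjusting all eight factors makes the compositions identical, so
θ > 0 always terminates. With θ = 0.05 on the published OC mean
compositions the search returns {fIX, TFPI} for fXa (discrepancy 0.034;
the runner-up pair {fVIII, TFPI} sits at 0.20) and {fII, fIX, AT, TFPI}
for thrombin (0.032, with {fIX, TFPI} at 0.125 and {fIX, TFPI, AT} at
0.053 — just missing θ, consistent with four factors being needed).

## Synthetic cohorts

Per group and factor, draws come from a normal with the published mean
and SD truncated to the published range (scipy truncnorm; exact inverse-
CDF sampling, no rejection loop). Factors are independent by default
because inter-factor correlations are unpublished; a correlation matrix
can be supplied and is applied as a Gaussian copula on the truncated
marginals. Demographics use plausible marginals chosen once: sex
fractions from the published subgroup Ns (57.5% / 59.6% female), age
~N(45, 13) truncated to 18–71, BMI ~N(25.5, 3.8) truncated to 16–45, OC
use among women under 50 at the published subgroup frequencies (34% /
43%). Sampling is deterministic under a seed (PCG64, recorded in output
metadata), with independent spawned streams per group.

What the generator does **not** emulate: inter-factor correlation
structure, the matched case-control design, measurement error, and any
factor-demographic dependence (factor levels are sampled independently
of age/BMI/OC status). Consequently synthetic cohorts reproduce the
*pipeline arithmetic* (pooled ~10% above cutoff; case-shifted factor
distributions → OR > 1; null spec → OR ≈ 1) but are not expected to
match the published OR magnitudes, BMI/age slopes, or OC-subgroup
contrasts, which in the real data ride on correlations the tables do not
publish.

## Problem sizes and numerical choices in the checks

The end-to-end checks run one 899-subject cohort (the published group
sizes) for the pooled-count and OR-direction checks, and 20 null
replicates at 150 subjects per arm for the null CI-coverage check — the
null check estimates a coverage proportion, which does not require the
full cohort size per replicate. Solver cross-validation uses five
compositions drawn uniformly within the published control ranges.
A simulation takes ~25 ms (LSODA + compiled right-hand side), so the full
suite and the acceptance script each run in minutes on one CPU.

## Known limitations

- Risk statistics on synthetic cohorts inherit the independence
  assumption above; treat them as pipeline validation, not biology.
- The model omits protein C, platelets, contact activation and flow;
  absolute thrombin/fXa peaks in plasma-only empirical systems differ.
- The minimal normalizing subset can depend on θ near its boundary (the
  three-factor thrombin subset misses θ = 0.05 by 0.003); the search
  trace is always reported so the θ-sensitivity is visible.
- TMax values are grid-quantized to 1 s; MaxR, being a forward
  difference, slightly underestimates the instantaneous peak rate.
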