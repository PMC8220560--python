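# Methods

`hohla` implements a hierarchically organized haplotype (HOH) analysis of
HLA-DRB1 protein variation, with two arms: a case-control arm that
fine-maps disease association down to amino-acid motifs, and a birth-cohort
arm that validates motifs against time-to-seroconversion outcomes derived
from longitudinal islet-autoantibody panels.

## The hierarchy step

Alleles are represented as aligned residue vectors on the β-chain numbering
(mature chain β1..β237, signal peptide −29..−1).  Sequence dissimilarity is
the normalized Hamming distance over mature-chain positions, with residues
missing in either allele excluded pairwise; the signal peptide is excluded
by default because the functional contrast concerns the expressed chain
(`include_signal_peptide=True` restores it).  The hierarchy is UPGMA
(average linkage), so merge heights are half the average inter-cluster
distance and the tree is ultrametric.  Ties between candidate merges are
broken lexicographically on the smallest member name, making the tree a
deterministic function of the catalog.  A cluster (e.g. "DR4") is the
smallest subtree covering a set of seed alleles.

No claim is made that UPGMA on Hamming distance is the uniquely correct
organization; it is the simplest deterministic choice that reproduces the
expected behaviour that alleles sharing nomenclature (DRB1*04:xx) form one
clade.  Bootstrap support and alternative linkages are out of scope.

## Residue screening within a cluster

Chromosome copies are counted over the whole sample (two per subject); an
allele with fewer than 3 copies is *rare*.  For each candidate position:

* **monomorphic** — one amino acid across all cluster alleles;
* **near_monomorphic** — one amino acid across the non-rare alleles
  (variation confined to rare alleles);
* **rare** — polymorphic among non-rare alleles but every minor amino acid
  totals fewer than 3 copies (only reachable through missing-data
  exclusions, since an amino acid carried by a non-rare allele inherits at
  least its 3 copies);
* **collapsed_LD** — the amino-acid assignments at this position and an
  earlier kept position form a bijection across the non-rare alleles
  (complete LD); the later position in scan order is dropped and its
  partner recorded;
* **kept** otherwise.

Alleles missing a residue at a position are excluded from that position
with a logged warning.

## Association statistics

Frequencies are chromosome-based.  For a category *c* (allele, amino acid,
or motif) with case and control frequencies $f_1(c), f_0(c)$, the
**virtual-reference odds ratio** is

$$\mathrm{OR}(c) = f_1(c) / f_0(c),$$

which avoids electing a reference category and is invariant to how the
remaining categories are partitioned.  Significance comes from the score
statistic of the per-subject chromosome dosage $d_i \in \{0,1,2\}$ in a
logistic model of case status: with null fitted probabilities $\mu_i$
(intercept-only by default; covariates optional),

$$U = \sum_i (y_i - \mu_i) d_i,\qquad
V = \sum_i w_i d_i^2 - c^\top I^{-1} c,\qquad w_i = \mu_i(1-\mu_i),$$

where $c$ is the cross-information between dosage and the null design and
$I$ the null information; $Z = U/\sqrt{V}$ with a two-sided normal
p-value.  Positive $Z$ means enrichment in cases.  Without covariates
$Z^2$ is exactly the Cochran–Armitage trend chi-square, which the test
suite verifies by exhaustive enumeration of small tables.  The standard
error, when reported, is the derived $\mathrm{SE} = \log(\mathrm{OR})/Z$;
it is not independently estimated.  A constant dosage returns $Z=0,
p=1$; a degenerate design ($V \le 0$) raises.  p-values are reported raw,
with no multiplicity correction, throughout.

Within-cluster analyses (per-residue and per-motif tables) restrict to
subjects carrying at least one cluster allele and count only cluster
chromosomes.  Patient-only autoantibody association replaces case status
with the antibody positivity flag and reuses the same machinery; patients
lacking the measurement are excluded with a logged count.

## DR-DQ haplotypes

Phase across (DRB1-motif, DQA1, DQB1) is resolved by the standard EM
algorithm under Hardy–Weinberg mixing: the E-step weights each subject's
compatible ordered phase configurations by current haplotype frequencies,
the M-step re-estimates frequencies from expected counts.  The start is
uniform over compatible haplotypes (deterministic), convergence is a
log-likelihood gain below 1e-10, and haplotypes with mass below 1e-6 are
pruned afterwards.  Frequencies for the report come from group-specific EM
runs (cases and controls separately, mirroring per-group frequency
columns); the score test uses posterior dosages from a pooled fit so the
null model is shared.  Direct counting over phase-unambiguous subjects is
available as a config switch (`use_em=False`).  Haplotypes absent from one
group are reported with counts and flagged; absent-in-cases haplotypes get
OR = 0 and no Z.

## Seroconversion endpoints

Panels carry per-visit GADA/IAA/IA-2A values and thresholds.  Crossing is
strict (value > threshold) and the event time is the crossing visit's time
— no interval midpoints and no interpolation.  Antibody-specific
seroconversion is the first crossing visit; overall seroconversion is the
earliest of those; double seroconversion is the time at which a second
distinct antibody has ever crossed, i.e. the second order statistic of the
antibody-specific times (cumulative ever-positive status rather than
same-visit co-positivity — the alternative can be obtained by prefiltering
the panel, but is not a built-in switch).  No event means censoring at
last contact.  Requiring confirmation at consecutive visits is not
implemented; single-visit crossing is the definition.

## Survival models

Incidence is 1 − the Kaplan–Meier product-limit survival; group contrasts
use the standard log-rank statistic (both via lifelines).  Cox models
maximize the partial likelihood by Newton iterations with step-halving,
Efron tie handling by default (visit schedules produce many ties;
Breslow is available), convergence at max |score| < 1e-8, and standard
errors from the inverse observed information.  Monotone likelihoods
(separation) are detected by coefficient divergence (|β| > 20 during
iterations, or |β| > 10 at a converged score — on a log-hazard scale a
genuine effect of e10 is not a plausible fit, while score decay below
tolerance near an infinite optimum is exactly the separation signature)
and raise an error naming the term; exhaustive comparison against
brute-force maximization on all tiny no-tie instances backs this solver.

Model builders: one-vs-rest fits code carriage (≥ 1 chromosome) of one
category against everyone else; the multivariable fit codes one carriage
indicator per non-reference motif group; the genotype dose-response model
codes heterozygote and homozygote indicators against the zero-copy
reference (the homozygote term is omitted, with a log message, when no
homozygotes exist).  All models adjust for sex, family history, and
location (fixed-effect dummy coding against the first level; no frailty).

Proportionality is checked with the Grambsch–Therneau test: Schoenfeld
residuals $r_k$ at the fit are paired with a transform $g$ of event times
(Kaplan–Meier transform by default, $g(t) = 1 - S_{KM}(t^-)$), and with
$d$ events, information $I$ and $u = \sum_k (g_k - \bar g) r_k$ the global
statistic is $d\, u^\top I^{-1} u / \sum_k (g_k-\bar g)^2$ on one degree of
freedom per term.  The implementation is cross-checked against the
reference implementation in lifelines and calibrated by simulation under
proportional hazards.  The test is reported; interpretation (and any
remodelling under violation) is left to the user.

## The synthetic-data generators

The generators define the study conditions under which the pipeline is
validated; their latent truth (linear predictors, latent event times) is
returned in a sidecar that analysis code never reads.

**Case-control.**  Genotypes are two independent draws from a configured
allele-frequency vector; disease follows a logistic model,
$\mathrm{logit}\, P(y=1) = \alpha + \sum_m \beta_m\, \mathrm{copies}(m)$,
with effects keyed by motif (per-copy by default; carriage and
genotype-coded variants available).  Case and control arms are filled by
rejection sampling to their target sizes, matching a design where the two
arms are recruited separately.  Patient antibody flags come from optional
per-antibody logistic models.  Default frequencies are a plausible
Northern-European-like spectrum over the fixture alleles; the default
baseline log-odds of −4 keeps disease uncommon.

**Birth cohort.**  Each antibody has a latent event time from a Weibull
proportional-hazards model, $T = \lambda (E/e^\eta)^{1/k}$ with $E \sim
\mathrm{Exp}(1)$; η sums motif effects and covariate effects (sex 0.1,
family history 0.4 with 10% prevalence, four sites with small offsets).
Default Weibull baselines (scale 180/220/350 years, shape 0.8/0.7/1.0 for
GADA/IAA/IA-2A) give roughly 9/11/3% baseline incidence by the 10-year
horizon — a risk-enriched cohort with decelerating incidence, and enough
events for the validation fits.  Visits run quarterly to age 4 and
semiannually to 10 years; dropout is exponential at 0.02/year.  Measured
values are placed below threshold before the latent time and above it
after (log-normal spread around a fixed exceedance margin), so the
observed crossing visit is exactly the first visit at or past the latent
time — a property the tests check against the sidecar.

What the generators do **not** emulate: real HLA allele spectra and LD
beyond the configured DR→DQ map, assay noise that can dip back below
threshold after seroconversion (observed positivity here is absorbing),
ascertainment by HLA genotype with family-history exceptions, competing
risks, or clinical-onset endpoints.  Passing recovery tests therefore
demonstrates that the estimators recover what the models define on data
satisfying their assumptions — not that real cohort estimates are
unbiased.

## Validation study conditions

Chosen once, as package policy, before results were inspected:

* **Oracle sweeps.**  Score vs. trend: all case/control × binary-dosage
  tables up to 40 subjects plus all three-level-dosage tables up to 12
  subjects.  Cox vs. brute force: every no-tie instance of 2–8 subjects
  with one binary covariate (rank-ordered times; monotone-likelihood
  instances identified structurally and required to raise).  EM vs.
  counting: 400 phase-unambiguous three-locus subjects, exact equality.
* **Calibration.**  Score test: 2000 null case-control replicates of 500
  subjects; Grambsch–Therneau: 1000 proportional-hazards replicates of 200
  subjects; both required to land inside the 99% binomial band around 5%.
* **Recovery.**  Case-control: per-copy log-OR log 3.64 planted on a motif
  at frequency 0.02 with 1% baseline risk, 200 replicates of 2000+2000 —
  the frequency-ratio OR approximates the per-copy logistic OR only in
  this rare-allele, rare-disease limit, which is why the recovery design
  uses an uncommon risk motif.  Cohort: carriage log-HR log 1.74 at
  n = 6000, 100 replicates (the effect is planted on carriage because
  carriage is what the one-vs-rest model estimates).  Dose-response:
  genotype-coded (log 2.07, log 2.65) at n = 4000, 100 replicates,
  scored on the recovered ordering HR₂ > HR₁ > 1.

## Known limitations

* The score test relies on asymptotic normality; rare categories are
  flagged rather than exact-tested (Fisher comparisons are available for
  two-category contrasts).
* EM assumes Hardy–Weinberg phase mixing within each group it runs on.
* The Cox layer offers no time-varying coefficients; the diagnostic only
  reports proportionality violations.
* The packaged DR4 catalog is synthetic: it pins the documented screening
  dispositions and motif correspondences plus neutral backbone drift, and
  is not a substitute for a curated reference alignment.
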