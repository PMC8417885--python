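# Methods

## Scope and data model

The unit of analysis is one subject's **metacommunity**: a matrix of
non-negative integer read counts, species × time points, where each time
point is one **local community** (for the hybrid model, one **niche**).
Counts are used as observed; there is no rarefaction or normalization,
because both models condition on the per-sample depths
N<sub>i</sub> (the column sums).  Subjects are modeled independently;
species labels are opaque strings and are never matched across subjects.

## Multi-site neutral model (MSN)

### Model

- Metacommunity relative abundances: β ~ Stick(θ), θ > 0 the fundamental
  biodiversity number.  Larger θ means more species and a rarer-skewed
  abundance distribution; the expected richness of N draws is
  θ(ψ(θ+N) − ψ(θ)).
- Local community i: π<sub>i</sub> | I<sub>i</sub>, β ~ DP(I<sub>i</sub>, β);
  counts X<sub>i</sub> ~ Multinomial(N<sub>i</sub>, π<sub>i</sub>).
  Marginally the counts are Dirichlet-multinomial with concentration
  I<sub>i</sub>·β.  The migration probability is
  m<sub>i</sub> = I<sub>i</sub>/(I<sub>i</sub>+N<sub>i</sub>−1);
  I<sub>i</sub> → ∞ recovers multinomial sampling directly from β.
- Hyperpriors: θ ~ Gamma(1.0, rate 0.1) and I<sub>i</sub> ~ Gamma(1.0,
  rate 0.1), weakly informative (prior mean 10) and configurable.  The
  Gamma form is part of the model; the shape/rate values are this
  package's choice.

### Gibbs sampler

Per iteration, in order:

1. **Ancestral (table) counts**: t<sub>ij</sub> ~ CRT(x<sub>ij</sub>,
   I<sub>i</sub>β<sub>j</sub>) for every positive count, using the exact
   Bernoulli-sum representation.  This is vectorized over all reads of
   the matrix (one flat array of per-read Bernoulli trials per
   iteration), which is what makes 5,000–50,000 iterations practical.
2. **Metacommunity**: (β<sub>1..S</sub>, β<sub>u</sub>) ~
   Dirichlet(t<sub>·1</sub>, …, t<sub>·S</sub>, θ), where β<sub>u</sub>
   is the unseen-species mass.
3. **θ**: Escobar–West beta–gamma auxiliary update given S occupied
   components among Σt tables.
4. **I<sub>i</sub>**: the same auxiliary update per site, given
   t<sub>i·</sub> tables among N<sub>i</sub> customers (vectorized
   across sites).

Defaults follow the published protocol: 50,000 iterations, the first
half discarded as burn-in, every 10th retained draw kept for testing
(2,500 parameter sets); summaries are chain medians with 2.5%/97.5%
quantiles.  Reported θ is the chain median; the M-value is the mean over
sites of the chain-median m<sub>i</sub>.  Desk-scale analyses and the
test suite use 1,000–5,000 iterations, which the parameter-recovery
check shows is sufficient at depth ~2,000: the correctness of the
concentration updates was verified against grid integration of the exact
single-site Dirichlet-multinomial posterior.

### Neutrality tests

For each retained parameter set k, the observed log-likelihood L₀ₖ is
the sum over sites of the Dirichlet-multinomial log-likelihood under
(I<sub>k</sub>, β<sub>k</sub>), evaluated on the observed-species
support plus one pooled "unseen" category carrying β<sub>u</sub>.  A
simulated dataset is then drawn at the observed depths:

- **metacommunity level** — a fresh β* ~ Stick(θ<sub>k</sub>); its first
  S components map onto the observed support, the remainder pools into
  the unseen slot;
- **local level** — β fixed at β<sub>k</sub> (testing local neutral
  assembly around a fitted, possibly non-neutral metacommunity).

The pseudo P-value is the fraction of sets whose simulated likelihood
does not exceed the observed one (ties count as ≤); a model *passes* at
threshold P<sub>t</sub> iff P > P<sub>t</sub>.  Pooling simulated
out-of-support species into the unseen category keeps observed and
simulated likelihoods on a common support; other conventions exist, so
absolute L₀ values are comparable only within a run.

**Power caveat.**  This statistic rejects only when the observed data fit
*worse* than the model's own simulations.  Temporally rigid communities
(e.g. a fixed dominance profile with little sampling noise) sit at or
near the mode of the fitted Dirichlet-multinomial and therefore fit
*better* than typical simulations — they are never rejected, and per-site
immigration rates additionally act as free dispersion parameters that
absorb many structured alternatives.  A green neutrality pass therefore
establishes compatibility with neutral sampling, not evidence against
all deterministic structure; the dominance-structured synthetic control
documents this limitation empirically.

## Niche-neutral hybrid model (NNH)

Each niche's SAD is the negative binomial
p(n) = (1−x)<sup>γ</sup>/Γ(γ) · x<sup>n</sup>Γ(n+γ)/n! with x = b/d ∈
(0,1) and γ > 0; γ = 1 reduces to the geometric distribution.  The
expected species count ⟨φ<sub>n</sub>⟩ = θ x<sup>n</sup>Γ(n+γ)/n! is
implemented exactly in this form — any constant factor is absorbed into
θ, which is estimated by matching Σ<sub>n≥1</sub>⟨φ<sub>n</sub>⟩ =
θΓ(γ)((1−x)<sup>−γ</sup>−1) to the observed richness, so expected and
observed totals agree by construction.

Per-niche (x, γ) maximize the zero-truncated likelihood (only species
present in a niche are observable), optimized in (logit x, log γ) by
Nelder–Mead from three starts at tolerance 1e-8.  Niches with fewer than
3 species, or fits at the parameter boundary (e.g. all-singleton SADs
driving x → 0), are flagged and excluded from averages and tests.

Goodness of fit pools abundances into Preston doubling octaves [1],
[2–3], [4–7], …; expected counts below 1.0 are merged into their
neighbor from the right tail inward; χ² = Σ(E−O)²/E with df = bins − 1
and an upper-tail P; R² = 1 − SS<sub>res</sub>/SS<sub>tot</sub> on the
same bins.  Because two parameters per niche are estimated, df is
generous and the test errs conservative; with the heterogeneous-niche
synthetic generator, rejection at 0.05 is below nominal.  The per-niche
local tests reuse the same machinery on each niche alone; the migration
coefficient reported in summaries is the convention
m<sub>i</sub> = γ<sub>i</sub>/(γ<sub>i</sub>+J<sub>i</sub>−1), mirroring
the MSN concentration→migration map (the quantity is otherwise
undefined for this model; its magnitudes, 10⁻³–10⁻², match the scale of
published summaries).

## Synthetic data

Three pure-function-of-seed generators:

- **neutral** — the exact MSN generative chain (stick-breaking β,
  Dirichlet site compositions, multinomial counts), with ground truth in
  a manifest for recovery tests;
- **hybrid** — K niches drawing zero-truncated negative-binomial SADs
  with their own (x, γ), species subsampled from a shared pool;
- **non-neutral control** — a deterministic geometric-series SAD with a
  fixed dominant species (dominance = top share) replayed at every time
  point, with 5% of reads re-drawn multinomially.

The cohort generator mirrors the study layout: groups of 6, 15, 4, 32
and 22 subjects with 66–70, 59–70, 66–69, 25–33 and 3–8 time points
respectively (≈2,700 local communities in total).  Per-sample depth is
desk-scaled to ~2,000 reads (the study's averages were ~2,700–5,300) and
the species pool capped at 60 so a full cohort fits in minutes; subject-
level truths are θ ~ U(4, 25) and I<sub>i</sub> ~ Gamma(2, scale 10),
bracketing the magnitudes of the published per-subject fits.  What the
generators deliberately do **not** emulate: real taxon identities,
menses/covariate structure, and longitudinal autocorrelation beyond the
models under test — so green tests establish self-consistency of the
inference machinery, not realism of vaginal community dynamics.

## Numerical choices

- Unsigned Stirling numbers of the first kind are built once per process
  by the log-space recurrence with `logaddexp` (exact to N = 200 within
  1e-10 normalization error).
- Stick-breaking truncates when the residual mass drops below 1e-10 and
  folds the residual into the last weight.
- Dirichlet draws use Gamma variates floored at 1e-300; categories with
  zero concentration are excluded from likelihoods (they can carry no
  counts).
- Ties in the Monte-Carlo test count toward passing ("not exceeding"
  read as ≤); reported P-values are rendered to 3 decimals in tables,
  percentages to 1 decimal.
- All randomness in a run flows from one integer seed via
  `numpy.random.Generator`; identical seed + configuration reproduces
  chains, simulations and artifacts bit-for-bit.

## Known limitations

- The neutrality pseudo P-value has essentially no power against
  under-dispersed (rigid) alternatives (see the power caveat above).
- Absolute observed log-likelihoods depend on the support convention for
  unseen species and are not comparable across implementations.
- χ² degrees of freedom ignore the per-niche parameters estimated, so
  hybrid P-values are conservative; exact published P-values are not
  reproducible without the original binning.
- Whole-cohort runs at the full published MCMC length (50,000
  iterations × 79 subjects) are supported but take hours on one CPU;
  desk-scale settings are the default everywhere else.
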