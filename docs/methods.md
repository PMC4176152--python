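# Methods

## The model

`tfdyn` implements a mechanistic dynamic model of a hormone-inducible
synthetic transcription factor in *Saccharomyces cerevisiae*.  The factor is
a fusion of the bacterial LexA DNA-binding protein, the hormone-binding
domain of the human estrogen receptor, and one of four activation domains
(ADs): B42, B112, Gal4AD or VP16.  Without beta-estradiol the factor is held
in the cytoplasm by an inhibitory protein (an Hsp90-like chaperone);
hormone binding releases it, it enters the nucleus, occupies the lexA
operator boxes of a synthetic target promoter, and recruits RNA polymerase II
through its AD to express a yellow fluorescent reporter.

The state is a vector of 29 species concentrations (nM) spanning the
extracellular hormone (clamped), intracellular hormone pools, free and
hormone- or inhibitor-bound factor in both compartments, free polymerase,
the AD-polymerase ("squelching") complex, the four genes with their
polymerase-bound forms, the free and factor-bound operator, four mRNAs, the
immature and mature yellow reporter, and a constitutively expressed red
reporter.  Dynamics follow dc/dt = N v(c, u, k): N is the integer
stoichiometric matrix of the 55 elementary reactions, v the flux vector,
u the hormone input (a step at t = 0), k the rate constants.  Fluxes are
mass action except for three auxiliary laws:

1. **Growth.**  The specific growth rate is a Hill function of the
   moiety-weighted total polymerase concentration PT,
   mu = mu_max PT^h / (K^h + PT^h) with h = 2 and K calibrated so the
   hormone-free steady state sits at PT = 3 K (mu = 0.9 mu_max).  Every
   protein, complex and mRNA is diluted at rate mu; genes and operators are
   not (replication balances dilution at constant copy number, 1 nM per
   gene), and free hormone is neither diluted nor degraded.  mu_max is a
   condition constant: 0.0046/min (SDC, glucose), 0.0028/min (SGlyC,
   glycerol), 0.0030/min (SDP, proline nitrogen) — typical exponential rates
   at 25 C.

2. **Steric recruitment.**  The per-box occupancy is
   p = O_TF / (O_TF + O_free).  The printed steric factor is
   N_OP(p) = p (1-p)^(n-1) for n boxes; the recruitment propensity is
   k_rec Pol_nuc G_rep n N_OP(p), i.e. the binomial probability that exactly
   one of n independently occupied boxes is occupied (a single polymerase
   fits sterically).  Without the factor n the propensity would *decrease*
   with box count at fixed occupancy, contradicting the observed
   approximately linear scaling of output with box number; the factor is a
   config switch (`nop_n_factor`) so the verbatim form can be studied.  The
   recruitment rate constant is k_act / Kd(AD): the variant's AD-polymerase
   dissociation constant controls both recruitment strength and squelching,
   which is what makes one parameter per variant explain both induction
   strength and toxicity.

3. **Translation scaling.**  All translation propensities (and the
   growth-coupled constitutive red-reporter source) are multiplied by a
   quadratic in mu normalised to 1 at the reference (glucose) rate
   mu_ref = 0.00414/min, with shape 0.5 + 0.3 (mu/mu_ref) + 0.2 (mu/mu_ref)^2.
   The 0.5 floor encodes that ribosome content does not vanish in arrested
   cells; it also guarantees the polymerase autocatalysis (below) has a
   viable low-growth basin, so equilibration cannot spuriously collapse.

**Toxicity.**  Polymerase has a dual role: it transcribes, and it is the
resource on which growth depends.  Its own gene requires free nuclear
polymerase (autocatalysis).  A strong AD sequesters polymerase into the
squelching complex, which is co-degraded at the unstable factor's turnover
rate — draining polymerase, depressing its autocatalytic production, and
lowering growth through the Hill law.  With the published affinities
(0.8 mM B42, 4 uM B112, 200 nM Gal4AD, 27 nM VP16) this reproduces the
observed ranking: no B42 toxicity up to 2500 nM hormone, mild B112 effects,
intermediate Gal4AD inhibition, and strong VP16 inhibition above ~15 nM,
including the late-time decay of the VP16 reporter signal at high dose.

**Operator turnover.**  The factor bound to an operator box is degraded at
the TF turnover rate, regenerating the free box.  This bounds the achievable
occupancy below 1 even for arbitrarily strong operator binding, which is why
a 10^4-fold increase in operator affinity buys only about 2-fold more output
(nonlinear saturation), while the default occupancy (~3% at saturating
hormone) keeps box-count scaling near-linear up to four boxes.  Without
bound-factor turnover, occupancy would approach 1 at high affinity and the
steric factor would annihilate recruitment — qualitatively wrong.

## Measurement models

Fluorescence (A.U.) is s_F * [mature reporter] + background (the background
is set so un-induced strains sit below the detection limit).  Flow-cytometry
noise: standard deviation linear in the mean above the estimated detection
limit of 2037 A.U.; every point below the limit is assigned a fixed variance
of 2344 (A.U. scale).  The statement "linear regression on variance (s.d.)"
is ambiguous between variance and s.d.; we take the s.d. as linear in the
mean and use its square, with the default slope calibrated for continuity at
the limit, (slope * 2037)^2 = 2344.  Relative mRNA is s_M * [reporter mRNA]
(the constitutive reference is absorbed into s_M).  Growth rates carry a 10%
relative error.  Synthetic mRNA noise is 15% relative with a floor of 0.02
relative units (the original error propagation on raw PCR data is not
reproducible from published information).

## Parameters

Units: nM and minutes.  The default set marks exactly 45 parameters free —
43 kinetic constants plus the two measurement scales — matching the size of
the original estimation problem; fixed a priori are the hormone export/return
transport rates, the passive TF shuttling rates, reporter maturation
(1/30 min) and the red-reporter source.  Default bounds are +/-3 decades
around each value, searched in log10 space.

The four AD-polymerase dissociation constants default to the published point
estimates.  All other constants are calibration values: we fixed the
qualitative regime (fast hormone equilibration ~5 min; hormone affinity
~100 nM; mRNA half-lives ~14 min; TF half-life ~14 min — an unstable
activator; polymerase loss dominated by dilution) and then calibrated five
scale factors (polymerase and TF translation rates, operator on-rate,
recruitment and basal-recruitment constants) by fixed-point iteration so that
the hormone-free steady state and the induced B42 state hit design targets:
per-box occupancy 0.03 and target-promoter occupancy 0.031 at 2000 nM,
induction fold ~250, and PT = 3 K.  These targets follow analytically from
the behaviours the model must reproduce (see above); the calibrated set ships
as the package default and is not re-tuned anywhere.

## Estimation

The objective is the weighted least-squares chi-squared: for experiment i
with n_i points, sum over points of squared standardised residuals, divided
by n_i, summed over experiments.  Optimisation uses a self-contained CMA-ES
(rank-1 plus rank-mu covariance updates, cumulative step-size adaptation,
population 4 + floor(3 ln d)), seeded and deterministic, with box constraints
handled by projection plus a quadratic penalty.  Simulation failures at a
candidate return a 1e9 penalty instead of raising.  The strategy sits behind
a function interface so a plain (mu, lambda)-ES can be swapped in.  Fit
adequacy is the left tail of the chi-squared distribution at
dof = points - free parameters; validation predictions re-estimate nothing
(only the condition constants mu_max and the translation scaling argument
change per medium), so validation dof equals the validation point count.

## Synthetic data

No public raw datasets exist for the system, so the pipeline is exercised on synthetic
data generated from the model itself.  The default design mirrors the
original: a two-fold dose ladder 0-2500 nM through the doses named in the
text (15, 125, 312, 2000, 2500 nM); fluorescence at 1, 2, 3, 5, 10, 20, 24
and 28 h; reporter mRNA within the first 2 h (10 points, anchored at the
15 min first-signal and 45 min half-induction times); growth rates 5 h after
induction.  The training partition — all four variants with four boxes in
SDC — totals exactly 446 points (401 degrees of freedom + 45 parameters);
the validation partition totals 1014 points: box-count series (1, 2, 3, 8)
for B42 and B112, B42 in SGlyC and SDP (fluorescence, mRNA, growth), and a
high-dose VP16 time course in SGlyC.  Noise is Gaussian per the measurement
models, truncated at zero (a mild, deliberate misfit stressor); the recorded
standard deviations are the generating ones, so a noise-free dataset gives
chi-squared exactly 0 at the generating parameters.

What the generator does *not* emulate: per-cell flow-cytometry
distributions, gating artifacts, plate-reader absorbance curves, or any
systematic biology the model lacks.  In particular, SGlyC and SDP differ
from SDC only through mu_max and the translation scaling; the real system's
SDP/SGlyC difference is not explained by growth rate alone, so that known
misfit is reproduced by construction, not corrected.  Passing recovery tests
therefore demonstrates that the pipeline is consistent and identifiable
under the model's own assumptions, not that the model is complete.

## Numerical choices

LSODA (stiff-capable) at relative tolerance 1e-8 and absolute tolerance
1e-10 nM.  The right-hand side is numba-compiled and deliberately smooth: no
hard clipping of small negative concentrations (clipping creates derivative
discontinuities that stall step-size control near steady states); the only
guards are the operator-total and zero-polymerase branches.  Hormone-free
initial conditions come from integrating a seed state (genes at copy number,
a viable polymerase pool) until max |dc/dt| / (|c| + 1e-6) < 1e-8 or
5000 min, whichever is first; the result is cached, keyed only on the
parameters that can affect a zero-hormone steady state (the entire hormone
pathway, the affinities among it, is provably inert there, which makes
repeated equilibration free during affinity fitting).  Equilibration raises
if the polymerase subsystem diverges or collapses.  Steady-state readouts
use the 28-h time point; ties in threshold crossings resolve to the earliest
grid time.

Problem sizes: the shipped recovery experiment fits 4 affinities to the
446-point training partition with an evaluation budget of 5000; in practice
the strategy stagnates (and stops) after roughly 900 evaluations and
recovers all four affinities within a few percent.  The single-parameter
demonstration uses a 17-point design and ~200 evaluations.

## Known limitations

* The reaction table is a canonical reconstruction: every mechanism described
  for the system is realised with exactly 29 states, but the original enumeration
  (e.g. whether a ternary factor-hormone-inhibitor complex existed) is not
  public, and the non-affinity constants are calibration values, not
  estimates from data.
* Growth feedback is phenomenological (polymerase as the single resource);
  the Michaelis-Menten/Hill constants of the growth law and the quadratic
  translation anchors are design choices.
* The chi-squared left-tail test assumes independent Gaussian errors; the
  generator's zero-truncation mildly violates this at sub-background
  fluorescence values.
* Cell-to-cell variability, delays, and explicit ribosomes are out of scope;
  flow data are summarised by their central tendency only.
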