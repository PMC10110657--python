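# Methods

This note documents the models implemented in `retropbtk`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate.

## Whole-body model

The body is resolved into 13 anatomical compartments — a lumped plasma pool,
ten perfusion-limited tissues (adipose, bone, brain, heart, kidneys, lungs,
muscle, skin, spleen, gut tissue), the gut lumen, and the liver — plus
virtual depots (peritoneum for i.p. dosing) and terminal pools (urine, bile,
unabsorbed, gut metabolites, liver metabolites). Amounts are in nmol,
volumes in mL, time in hours; doses are entered in mg/kg bodyweight and
converted through the molar mass of retrorsine (351.44 g/mol, C18H25NO6).
Gut and spleen drain portally into the liver; all flows are treated as
plasma-equivalent flows, and the configured per-tissue flows define the
cardiac output as their sum, so the venous-return balance holds by
construction.

The liver follows the extended clearance concept: a lumped
vascular/interstitial (vi) space exchanges with a cellular space through
active uptake (`CL_act_in`), passive diffusion (`PS_diff`, with the efflux
direction attenuated by the neutral-fraction ratio `fn_c/fn_int` from the
Henderson–Hasselbalch speciation at intracellular pH 7.0 vs interstitial pH
7.4), and active efflux (assumed negligible for retrorsine). From the
cellular space the compound is excreted into bile (`CL_bile`, rat only; no
bile data exist for mouse) or metabolized with Michaelis–Menten kinetics in
the unbound cellular concentration. The metabolic flux splits into fixed
fractions forming glutathione conjugates (DHR:GSH), protein adducts
(DHR:PROT), DNA adducts (DHR:DNA) and other metabolites; the fractions sum
to one exactly and the constraint is enforced, never renormalized. GSH
conjugates and protein adducts deplete monoexponentially. DNA adducts are
modelled as two pools — formation into a fast pool that empties at `λ1` and
transfers at `k` into a slow, repair-resistant pool emptying at `λ2`; the
observable is the pool sum, which is asymptotically biexponential with
terminal slope `λ2`.

Renal elimination is glomerular filtration of unbound drug from the plasma
pool (`CL_uri = fuP·GFR`, 4.80 mL/min/kg with fuP = 0.600 and GFR = 8.0
mL/min/kg in both species). Gut-tissue metabolism shares the hepatic `K_M`
and uses one tenth of the whole-liver `V_max` (the liver/10 rule), acting on
the unbound gut-tissue concentration — this reproduces both the quoted gut
clearances (2.73 and 7.58 mL/min/kg) and the quoted shares of total
clearance. Oral dosing places `F_a`·dose into the gut lumen (first-order
absorption into gut tissue at `k_a`) and routes the remainder to an
unabsorbed pool; peritoneal absorption (`k_per` = 166 1/h, a 15-second
half-life) drains into the liver's portal inflow.

Integration uses LSODA with relative tolerance 1e-8 and absolute tolerance
1e-10 nmol by default; the derivative kernel exists twice — a pure-python
reference and a numba-compiled twin — and a test asserts their exact
equality. Mass balance (body + terminal pools = administered) holds to
machine precision and is asserted at 1e-6 relative tolerance across routes
and doses 0.001–100 mg/kg.

## Parameter provenance and calibration

Species physiology and compound constants ship as packaged YAML
(`src/retropbtk/data/`). Anatomical volumes follow standard rodent
reference compilations. Several constants are not independently measurable
from the public record and were calibrated once, analytically, so that the
package reproduces the published anchor values; they are package defaults,
not free fitting parameters:

* **Liver mass per kg** (54.8 g/kg mouse, 36.6 g/kg rat) back-solved from
  the gut clearances under the liver/10 rule.
* **Hepatic flow per gram liver** (2.1154 and 1.5927 mL/min/g) solved from
  the extended-clearance closed form so overall hepatic clearance is
  14.8 / 14.6 mL/min/kg; the portal (gut + spleen) and arterial flow
  entries in the config sum to exactly these totals.
* **Medium-loss scaling** — incubation volume 0.5 mL, 2.5·10^5 cells,
  hepatocellularity 1.422·10^8 cells/g — gives the shared factor
  4.74 mL·h/min/g that maps the depletion rates onto `CL_act_in` =
  0.516/0.887 and `PS_diff` = 0.190/0.394 mL/min/g.
* **Microsomal scaling** — 0.85 mg protein/mL and 40 mg microsomal
  protein/g liver — maps 0.586 → 27.6 and 1.95 → 91.7 nmol/min/g with one
  constant set.
* **Partition-model inputs** — logP 1.18, a single basic pKa of 8.2,
  blood:plasma ratio 0.792 (from which the acidic-phospholipid association
  constant is back-derived) — give K_adi 0.186, K_bon 0.588 and near-unity
  muscle/brain/gut coefficients with the packaged rodent composition table.
* **Liver sub-compartment partition** `K_liv_int,u:vi` (0.355 mouse, 0.333
  rat; `K_liv_vas:vi` = 1). The derivation of these coefficients in the
  framework this model descends from is not public; the packaged values are
  calibrated so that the simulated whole-body disposition reproduces the
  reported elimination pattern (mouse 63/11/25% liver/gut/urine; rat
  55/26/16% plus ~3% bile). Note that the closed-form organ clearance
  (14.8/14.6 mL/min/kg) contains only active uptake in its influx term
  while the ODE influx carries `CL_act_in + PS_diff`; the two descriptions
  cannot be made numerically identical with one partition constant, and the
  package resolves the tension in favour of the simulated disposition
  pattern. The closed form is exposed separately in
  `ivive.extended_clearance` and verified against an independent
  steady-state micro-model.
* **Caco-2 → F_a correlation**: implemented as a logistic in permeability
  with half-maximal absorption at 2·10^-6 cm/s and unit slope; the exact
  constants of the published correlation are not reproduced here, so the
  packaged "measured" permeability (7.216·10^-6 cm/s absorptive,
  1.263·10^-5 secretory; efflux ratio 1.75) is a synthetic stand-in chosen
  to give F_a = 78.3%. The efflux ratio uses the standard secretory/
  absorptive definition.
* **Metabolite defaults** (f_GSH 0.10, f_PROT 0.05, f_DNA 0.002, f_other
  0.848; λ_GSH 0.10, λ_PROT 0.02, λ1 0.06, λ2 0.004, k 0.01 1/h) are
  representative values of the magnitudes such adduct kinetics show; they
  serve as generator truths for the recovery studies and do not influence
  any clearance or disposition result.

Consequences worth knowing: the simulated plasma and muscle peak fractions
after a 1 mg/kg oral dose (≈1.3%/10.5% mouse, ≈0.8%/8.2% rat) agree with
the reported 0.7%/12% and 0.5%/9% only within a factor of about two for
plasma — the peak depends on the blood-pool topology (arterial/venous
split, blood-to-plasma handling at organ inlets), which the lumped plasma
pool simplifies. Disposition shares, total elimination times and liver peak
concentrations are insensitive to this simplification.

## In vitro fits

Medium-loss depletion is fitted by least squares of log concentration on
time (multiplicative noise; replicates pooled). The 4 °C rate is attributed
entirely to passive diffusion with no temperature correction; the active
component is the 37 °C excess, floored at zero.

Microsomal depletion uses an end-product inhibition model: the
Michaelis–Menten rate is attenuated by the factor `1/(1 + P/IC50)` with
product `P = C0 − C(t)` — accumulated reactive metabolites irreversibly
disable the enzyme, half-maximally at IC50. The joint fit across start
concentrations (1/15/50/200 µM, technical duplicates) runs in log-parameter
space with multi-start over K_M scales because the likelihood has a
Vmax–K_M ridge. At the default 10% assay noise the individually reported
posterior spreads are not reproduced: K_M is weakly identified (the strong
product inhibition stalls depletion after a small fractional loss, so the
saturation bend is barely expressed in the data), while the linear
clearance `Vmax/K_M` — the quantity the organ model consumes — is recovered
within ±20–35%. Noise-free data are recovered exactly, and the limiting
model (IC50 → ∞) collapses to plain Michaelis–Menten depletion.

Cytotoxicity concentration–response uses the sigmoidal inhibition model
`v = 1/(1 + (C/IC50)^h)` with the control plateau fixed at 1.

## Kinetic data preparation

All observations convert to nmol: identity, µg (mass), µg/mL × matrix
volume, ng/g × organ mass, and percent-of-dose dialects are supported;
every record carries its conversion chain, and unsupported units raise.
Mass-spectrometric peak-area ratios pass through unconverted, flagged
relative, and are excluded from training likelihoods. Summary records
(mean, sd, n) are de-aggregated on the arithmetic scale: normal draws are
affinely rescaled so the empirical mean and sd match the summary exactly
(seeded, hence reproducible; redraws and a shrinking one-sided fallback
prevent negative amounts). De-aggregation on the log scale would be the
main alternative; arithmetic matching keeps the summary-level likelihood
invariant to the seed.

## Estimation

Ten parameters are estimated from in vivo data: `k_a`, rat `CL_bile`, and
the eight metabolite constants. Summary records are de-aggregated into
exact-moment pseudo-individuals before entering the joint likelihood. The
observation model is lognormal with one noise variance per matrix
integrated out analytically under a Jeffreys prior (each matrix
contributes −n/2·log RSS); marginalizing rather than profiling σ keeps the
heavier tails that short chains need for calibrated intervals. Priors on
the parameters are non-informative (log-uniform) within positivity bounds,
and the formation-fraction simplex is enforced by rejection. The sampler
is Metropolis–Hastings with delayed rejection (one extra stage at 0.2×
proposal scale) and adaptive proposal covariance (2.38²/d scaling of the
chain history). Before sampling, a short Nelder–Mead search and a
central-difference Hessian form a Laplace approximation of the posterior;
it seeds the initial proposal covariance, and the three chains start from
draws of the two-fold-inflated approximation — overdispersed relative to
the posterior, yet close enough that desk-scale chains converge.
Convergence is declared at Gelman–Rubin < 1.1 per parameter (computed on
the log scale); posterior modes come from a kernel-density peak and
intervals are 95% highest-density intervals.

Likelihood evaluations exploit the model structure: the retrorsine
disposition depends only on (`k_a`, `CL_bile`), so each study group's
trajectory is simulated once per distinct value pair and cached, while the
metabolite pools — linear ODEs driven by the hepatic metabolism flux — are
propagated by an exponential-trapezoidal convolution on a log-dense grid.
A test pins this fast path against the direct whole-system likelihood.

Default chain length is 3 × 20,000 draws with 50% burn-in. The recovery
study run by the test suite uses 3 × 2,000 draws and 8 replicate datasets
(study arms: oral and i.p. mouse plasma, mouse conjugate time courses to
48 h, DNA-adduct time courses to 336 h at two dose levels, rat i.v.
urine/bile, and an evaluation-only liver arm) — sizes chosen so the whole
study completes on a single desktop core in minutes. At this sample size
the DNA-adduct triple (λ1, λ2, k) sits on a strongly curved ridge and its
maximum-likelihood estimates scatter more widely than the local curvature
predicts — a genuine small-sample nonlinearity — so interval coverage is
assessed pooled across parameters rather than per parameter in isolation.

## Reverse dosimetry and benchmark doses

The in vitro concentration is equated with the unbound peak concentration
in the liver vascular/interstitial space (`fu_invitro·C = fuP·Cmax`;
`fu_invitro` = 1 for the serum-free medium). `Cmax(dose)` is strictly
increasing, so the inverse is found by bracketed Brent iteration on the
actual simulator (0.1% dose tolerance); full concentration grids are
translated through a monotone log-log interpolant of `Cmax(dose)` built
from 25 simulations. Viability maps 1:1 to "liver integrity" in percent.

BMD analysis fits exponential (`a·exp(−b·x^d)`, `a·(c+(1−c)·e^{−bx})`,
`a·(c+(1−c)·e^{−bx^d})`) and Hill (`a·(c+(1−c)·b^d/(b^d+x^d))`) families
under normal and lognormal error, weights the fits by AIC (with the
log-transform Jacobian included so the two error scales are comparable),
and derives the BMD for a 5% change in mean response relative to the
fitted control. Uncertainty comes from a parametric bootstrap: each
replicate regenerates responses from an AIC-weight-sampled fitted model,
refits the suite, reweights, and contributes one weight-sampled BMD; the
5th/95th percentiles give the 90% interval (BMDL5, BMDU5). Noise-free data
collapse the interval to the central estimate. Whether the original
web-tool interval is bootstrap- or Bayesian-model-averaged is not
specified; intervals from this implementation are expected to be
comparable in location, not identical. 1000 bootstrap draws by default
(150–200 in the tests).

The synthetic cytotoxicity truths use IC50 148 µM (mouse) and 153 µM (rat)
with Hill slope 2.5; the mouse generator adds inter-replicate lognormal
IC50 variability (sd 0.4 on the log scale) emulating the reported
hepatocyte-donor sensitivity differences, which widens and lowers the
mouse interval relative to the rat exactly as observed.

## What the synthetic data do and do not show

The generators produce data with the assumed statistical structure
(multiplicative assay noise, CV 10%; lognormal in vivo noise, log-sd 0.2;
the literature mix of individual and summary records). Passing recovery
tests therefore demonstrates internal consistency — the pipeline inverts
its own generative model at realistic noise — not that the published animal
data would yield the same posteriors; digitization error, inter-study
heterogeneity, model misfit and relative-unit series are absent from the
synthetic world. Deterministic stages (unit conversion, IVIVE arithmetic,
the closed-form clearances, the ODE itself) are validated against
independent oracles and published values directly.

## Known limitations

* Single lumped plasma pool; no arterial/venous split (affects peak plasma
  fractions, see above).
* No transporter-level kinetics or transport saturation; active uptake is
  phenomenological.
* Biliary excretion is terminal (no enterohepatic recirculation).
* No inter-individual variability model; one parameter vector per species.
* No toxicodynamic component: DNA-adduct kinetics are described, but the
  link to genotoxic response is outside the model.
* Human or other-species extrapolation would require replacing the
  physiology configs; only mouse and rat ship.
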