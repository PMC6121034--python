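# Methods

## Schemes and generator matrices

A kinetic scheme is a list of states (closed, open, flipped,
desensitized; conductance weight > 0 exactly for open states; ligand
stoichiometry per state) and directed transitions carrying a named rate.
Concentration-dependent transitions (order 1) hold a bimolecular rate in
M⁻¹s⁻¹ that is multiplied by the ligand concentration when the generator
matrix is built; all other rates are s⁻¹. Binding-site statistical
factors are written out explicitly in the fixtures (2·k_on into the
mono-liganded state, 2·k_off out of the di-liganded state) rather than
folded invisibly into the rate values.

Validation rejects undeclared states, non-positive document rates,
duplicate rate names and disconnected graphs, each with an error naming
the offending entry. Programmatically a rate may be set to exactly zero
(`with_rates`) to realize limiting cases such as a silenced spontaneous
branch; scheme documents cannot ship zeros. A detailed-balance audit
reports the product ratio around every independent cycle of the state
graph (the shipped fixtures are trees, so their reports are empty).

Steady states solve pQ = 0 with Σp = 1 on the unique closed communicating
class; states that are transient at the given concentrations (the
liganded branch at zero agonist) receive zero mass. Two or more closed
classes — no unique stationary distribution — raise an error listing the
states involved.

## Macroscopic simulation

Within a protocol segment the concentration is constant and the
propagation `p(t+dt) = p(t)·exp(Q dt)` is exact, so the output sampling
interval `dt` (default 0.1 ms) controls resolution only. Occupancies are
clipped and renormalized each step, keeping |Σp − 1| at machine precision
over arbitrarily long protocols. Long segments are sampled at most
40 000 points. Finite solution exchange is modelled as an exponential
concentration relaxation at segment boundaries (time constant
`exchange_tau`; defaults offered are 250 µs for theta-glass and 25 ms for
multibarrel perfusion, the midpoints of the respective instrument
ranges), integrated over the first 8 τ with four sub-steps per output
sample, each frozen at the analytic mean concentration of the sub-step.

Protocol builders cover the standard designs: single pulses, modulator
pretreatment (modulator in wash and pulse; initial state equilibrated
with modulator) versus co-application (modulator in the pulse only),
paired 500 ms-conditioning/test pulses with variable washout, a
modulator-only application, and an open-channel-blocker segment. The
blocker is idealized as conductance silencing: occupancy dynamics are
untouched and only the P_open readout is nulled during the blocked
segment, which is sufficient for the baseline-shift readout it serves.
Current conversion is `I = −N·i·P_open` (inward-negative); N and the
unitary current must be given explicitly, and plots that invert the sign
are a display choice only.

`simulate_overshoot` runs wash–pulse–wash on a combined scheme (liganded
and spontaneous branches sharing R) and summarizes the baseline P_open,
the post-deactivation minimum, their difference (the overshoot) and a
log-linear resensitization time constant. The overshoot exists when the
spontaneous baseline exceeds the small re-opening flux of receptors
returning from slow desensitization; it vanishes smoothly (within ~10⁻⁴
in P_open) when the spontaneous branch is silenced, so the zero-case
check uses an absolute tolerance of 10⁻³.

## Single-channel theory, simulation and fitting

Open (shut) sojourn densities follow from the class submatrix Q_AA:
`f(t) = φ exp(Q_AA t)(−Q_AA)1`, with the entry vector φ proportional to
the steady-state flux from the complementary class. Eigendecomposition
yields the mixture time constants (−1/λ) and area fractions; components
with zero entry weight are dropped. The mean of the open mixture is
checked in the tests against the independent occupancy/flux ratio
computed directly from Q.

Stochastic trajectories are exact CTMC realizations (per-state
exponential sojourns, embedded-chain jumps), reproducible by seed; an
ensemble variant propagates 10 000 trajectories in parallel to serve as
the Monte-Carlo oracle for the deterministic propagation. The oracle
comparison uses ~25 checkpoints spanning onset, desensitization and
deactivation; with pointwise binomial standard errors the 3-SE criterion
then has comfortable slack, whereas a dense grid would turn it into a
maximum over hundreds of correlated z-scores.

Dead-time censoring merges any event shorter than the dead time into the
enclosing dwell of the opposite class (durations summed, alternation
restored); leading unresolved events are dropped. The default dead time
is 0.1 ms — a calibration choice standing in for an idealization
resolution that is never stated explicitly for the recordings the
generator emulates — and the operation is idempotent at fixed dead time.

Exponential-mixture fitting maximizes the left-truncated likelihood.
Because exponentials are memoryless, truncation at the dead time reduces
to an ordinary mixture on the excess durations, which EM maximizes from
10 deterministic multi-starts (quantile-based initial time constants with
seeded log-normal jitter); the best log-likelihood wins and time
constants are reported ascending. Burst analysis groups openings
separated by shut dwells below a critical time. The default critical time
solves equal-percent misclassification between the two adjacent shut
components with the largest ratio when they are at least 20-fold apart;
for effectively single-component shut distributions (burst-free
spontaneous activity) it falls back to the 1% quantile of the fastest
shut component, so at most ~1% of genuine inter-event gaps concatenate
openings and the expected openings-per-burst stays within ~1% of 1.

## Trace metrics

10–90% rise time uses first crossings with linear interpolation and is
invariant to amplitude scaling and time shifts. Decay fits (1 or 2
exponentials, optional constant) are least squares with a deterministic
log-spaced multi-start over initial time constants; two-component fits
report the fast component first and amplitudes as fractions summing to 1,
with τ_mean = ΣA_iτ_i. Baselines default to the mean of the pre-pulse
window; peaks are the earliest global extremum within the agonist
segment. FR10/FR500 are anchored at the peak sample (the definition
"fraction remaining after 10/500 ms" does not state its anchor; the peak
is chosen because desensitization is defined from the peak, and the
choice is flagged here). Recovery fraction is
(I2peak − I1end)/(I1peak − I1end); the spontaneous-activity enhancement
ratio is (A_PTX + A_FLU)/A_PTX.

## Energetics and dose-response

K_D = exp(ΔG/RT) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298 K. The
temperature is not recorded with the docking energies; 298 K is adopted
because it reproduces all three quoted dissociation constants (GABA
1.54×10⁻⁴ M, P4S 1.22×10⁻⁵ M, flurazepam 4.93×10⁻⁷ M) to three
significant figures, while room-temperature values (293–296 K) do not.
Rate splitting uses an association-rate prior of 10⁷ M⁻¹s⁻¹, an
order-of-magnitude convention refined, when needed, by the rate-fitting
stage. Hill fits are unweighted least squares with an EC50 multi-start
grid; EC50 and n are scale-equivariant in the responses.

## Rate calibration

The historical procedure — iterative manual adjustment of selected rates
until simulated traces reproduce summary metrics — is formalized as
bounded derivative-free minimization (Nelder–Mead in log-rate space) of
weighted squared relative residuals on the metric targets, with
opening/closing rates held fixed. The objective acts on summary metrics
rather than trace least-squares because the calibration targets *are*
summary metrics. Multi-start results are always reported, and the
relative spread of near-optimal solutions is an explicit
non-identifiability diagnostic: with an extensive two-desensitized-state
scheme, distinct rate sets can yield near-identical traces, and the
fitter must say so rather than hide it.

## Synthetic data

The generators define the study conditions. Macroscopic datasets scale a
noiseless simulated P_open trace to current (default 500 channels ×
2 pA), add per-sweep additive Gaussian noise (default SD 2% of peak) and
geometric per-sweep rundown (default 2%/sweep, 5 sweeps); sessions whose
cumulative rundown exceeds 20% are flagged rejected, mirroring the
inclusion rule for real recordings. Channel-count binomial fluctuation is
not simulated by default. Single-channel datasets are dead-time-censored
Gillespie dwell lists, five files of 2000 openings each with per-file
seeds spawned from the master seed, and a truth sidecar holding the
generating mixtures. The dose-response generator produces Hill-shaped
replicates (default: EC50 46 µM, n = 1.4 — a typical low-cooperativity
value for this receptor, as no coefficient is quoted for the calibration
curve — R_max 1, 8 log-spaced concentrations from 1 µM to 3 mM, 5
replicates, 5% multiplicative Gaussian noise).

What the generators deliberately omit — capacitive/series-resistance
artifacts, baseline drift other than geometric rundown, multi-channel
patches, idealization errors on noisy records — bounds what passing tests
show: they validate the analysis chain on data that satisfy the Markov
and noise assumptions exactly, not the robustness of idealization or
clamp quality on real recordings.

## Fixture calibration

Absolute rate values for the shipped fixtures are package calibrations,
not measured constants: the sources the schemes are drawn from publish
topologies and directional effects, not complete rate tables. Values were
chosen so that the canonical phenotypes hold on simulated traces — mutant
flipping slowed in the order leucine > alanine > cysteine (rise times ~6,
9, 16 ms at saturation); wild-type fast desensitization strong (FR500
≈ 0.17); modulator multipliers raising spontaneous P_open ~2-fold in wild
type and cysteine mutant alike while prolonging both open lifetimes with
unchanged fractions; cysteine + modulator raising the peak and
shortening the rise time with slow desensitization preserved; leucine +
modulator lowering the peak, accelerating fast desensitization and
raising FR500; P4S + modulator raising the peak while adding a prominent
rapid desensitization component (FR500 down); co-application
potentiating more than pretreatment; overshoot increasing with the
spontaneous opening rate; paired-pulse recovery slow and monotone. The
slow-desensitization exit rate (r′ = 0.02 s⁻¹ across liganded fixtures)
sets a deliberately long recovery time scale (~50 s): fast enough to
watch resensitization within a 30 s wash, slow enough that the recovery
flux through the open state stays below the spontaneous baseline, which
is the condition for the overshoot to be visible at all. Modulation-set
magnitudes differ per fixture (the same signs throughout) because each
variant needs different fold changes to clear its phenotype margins.

## Numerical choices and limitations

Steady states use a least-squares solve with a residual guard of 1e-10;
dwell eigendecompositions reject complex eigenvalues beyond roundoff;
EM stops at a relative log-likelihood change of 1e-10 or 2000 iterations;
Nelder–Mead runs with xatol 1e-4 in log-rate space. Tests fix every seed,
so stochastic checks are deterministic in CI. Known limitations: no exact
missed-event likelihood (dead-time handling is the merge rule, not an
HJC-style correction); no spatial agonist diffusion or clamp artifacts;
PTX block has no kinetic states; identifiability is diagnosed by
multi-start dispersion, not a full posterior.
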