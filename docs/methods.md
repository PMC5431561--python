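# Methods

## Model

A leaky integrate-and-fire neuron with membrane time constant `tau = 20 ms`,
threshold `v_th = 10 mV` and reset `v_re = 5 mV` (all configurable) receives
a DC current `mu0` and instantaneous post-synaptic kicks arriving as Poisson
streams: excitatory kicks (rate `R_e`, exponentially distributed amplitudes
with mean `a_e`) and inhibitory kicks (rate `R_i`, amplitudes from one of
four laws with support on the negative axis):

| law  | parameters | mean | variance | skewness |
|------|-----------|------|----------|----------|
| delta (DD) | `a_i` | `a_i` | 0 | 0 |
| exponential (ED) | scale `ā` | `−ā` | `ā²` | −2 |
| uniform (UD) | `[l1, l2]`, `l1 < l2 ≤ 0` | `(l1+l2)/2` | `(l2−l1)²/12` | 0 |
| truncated Gaussian (TGD) | peak `a_p ≤ 0`, width `σ_G`, support `(−∞,0]` | `a_p − σ_G λ(β)` | standard upper-truncated-normal form | from the moment recursion |

with `β = −a_p/σ_G`, `λ = φ(β)/Φ(β)`. The TGD variance uses the standard
truncated-normal formula `σ_G²(1 − βλ − λ²)`; the third moment comes from
`E[Zⁿ|Z≤β] = (n−1)E[Z^{n−2}] − β^{n−1}λ`. Sampling uses `scipy.stats.
truncnorm`, which also serves as an independent cross-check of the moment
formulas in the tests.

Different input configurations are compared at matched effective input
`mu_T` and noise intensity `sigma²`:

    mu_T   = mu0 + tau R_e <a_e> + tau R_i <a_i>
    sigma² = Σ_x R_x tau (<a_x>² + var[a_x]).

`solve_drive` inverts this map: for a DC drive the pair `(R_i, mu0)` is
unique (configurations landing at `mu0 ≤ v_th` are flagged *silent*, not
rejected — a sub-threshold DC drive with purely inhibitory kicks can never
fire); for mixed shot-noise drive the balanced convention `R_e = R_i`,
`<a_e> = <|a_i|>` closes the system.

## Exact statistics

The generating function of the free (threshold-removed) stationary voltage
is `Z0(s) = H_e(s) exp(mu0 s + tau ∫_0^s Q_i)`, where the Laplace kernel of
an amplitude law is `Q(s)/R = E[(e^{sa}−1)/s]` (so `Q/R → <a>` as `s → 0`).
Closed forms:

* DD: `∫_0^s Q/R = −Ein(|a_i| s)` with the entire function
  `Ein(x) = γ + log x + E1(x)`;
* ED: `−log(1 + ā s)`;
* UD: combination of `Ein` terms (see `UniformDist.kernel_integral`);
* TGD: the kernel is written through the *scaled* complementary error
  function, `Q(s)/R = −(1/s)(1 − erfcx(y)·e^{−a_p²/2σ_G²}/(2Φ(β)))` with
  `y = (sσ_G² + a_p)/(√2 σ_G)` — an exact identity that never overflows, and
  whose large-`y` limit is the usual `erfc` asymptotic branch; its
  antiderivative is averaged over fixed Gauss–Legendre amplitude nodes.

Everything operates on `log Z0`, assembled in the centered form
`mu_T s + tau R_i (ψ(s) − <a_i> s) + (excitatory part)` so that the deep
diffusion limit (`|a_i| → 0` with `mu0, R_i → ∞`) stays fully accurate.

Sign conventions were re-derived from the transformed continuity equation
and validated against simulation: `F(s) = e^{s v_th}/(1 − s a_e) − e^{s v_re}`,

    1/(tau r0) = ∫_0^x̄ F(c)/(c Z0(c)) dc,

with `x̄ = 1/a_e` for exponential excitation and `x̄ = ∞` for a
supra-threshold DC drive. Combining a supra-threshold DC with excitatory
shot noise leaves no valid `x̄`; such configurations are flagged and refused.

ISI moments follow from the angular-frequency expansion of
`q̂(ω) = N/(N+D)`, `N = ∫ s^{iωτ} A' ds`, `D = ∫ s^{iωτ} B' ds`:

    <t>   = −d1_im = 1/r0,    d1 = i tau ∫ log s · B'(s) ds
    <t²>  = −2 (d2 + d1 n1 + d1²),
    n1    = i tau ∫ log s · A'(s) ds,   d2 = tau² ∫ (log s / s) B(s) ds.

The `<t> = 1/r0` identity is computed through two genuinely different
integrals and asserted to 1e−6 relative in the tests.

## Numerics

* **DC drive (`x̄ = ∞`).** All integrals use the substitution `u = log s`
  on a uniform Simpson grid (`du = 0.002` for moments, `0.001` for spectra),
  spanning `u ∈ [−40, u_max]` with `u_max` extended until the integrands are
  below 1e−13 of their peak. The deep lower limit matters: the integrands
  decay only like `e^u` as `u → −∞`, and truncating that tail leaves a
  spurious power-law branch that dominates the (exponentially small)
  high-frequency signal of `N` and `D`.
* **Exponential excitation (finite `x̄`).** The substitution
  `1 − s a_e = e^{−w}` turns the integrable endpoint factor
  `(1 − s a_e)^{tau R_e − 1}` into `e^{−tau R_e w}` exactly; since `B'`
  diverges at `x̄` when `tau R_e < 1`, the denominator moments use the
  always-convergent `B/s` forms (`d1` from the rate, `d2` directly).
* **Spectral ceiling.** `N(ω)` and `D(ω)` decay exponentially in `ω` while
  the Simpson sums accumulate roundoff of order `eps · Σ|w g|`; the
  spectrum truncates its grid where `|D|` falls below 1024·eps times that
  scale (typically 200–300 Hz for the reference configurations). The
  spike-train spectrum `Ĉ = r0(1−|q̂|²)/|1−q̂|²` is reliable over the
  0–100 Hz band used for all reported quantities.
* **ISI density.** A supra-threshold DC drive with purely inhibitory kicks
  produces a genuine delta atom in the ISI density at the deterministic
  passage time `t* = tau log((mu0−v_re)/(mu0−v_th))` with weight
  `e^{−(R_e+R_i) t*}` (the probability of a kick-free passage). Its
  transform does not decay, so it is removed analytically before the
  inverse FFT (grid `Δt = 0.25 ms`, conjugate period `T = 1/Δf`) and
  reported separately. `isi_peak` returns the maximum of the *continuous*
  part; in a binned histogram the atom bin can exceed the bulk peak. The
  jump of the continuous part at `t*` limits transform decay to `1/ω`, so
  some ripple of order `|q̂(f_max)|` remains near `t*`.
* **Characteristic timescale.** `dominant_period` returns the period
  `1/f_peak` of the spike-train-spectrum maximum (parabolic refinement).
  For the reference delta-kick configurations at `mu_T = 9 mV`,
  `sigma² = 2 mV²` this gives 40.2 ms (`|a_i| = 0.1`) and 53.9 ms
  (`|a_i| = 1`), while the literal argmax of the continuous ISI density
  lies at 45.5 and ≈55 ms — the two quantities differ because the density
  is skewed; both are exposed.
* **Diffusion approximation.** `e^{x²}(1+erf x) = erfcx(−x)` makes the rate
  integrand overflow-free; the CV double integral is recast with
  `y = x − t`, bounding `e^{x²−y²} = e^{2xt−t²}` in the regimes of interest.
* **CV minimum in the amplitude sweep.** At `mu_T = 9 mV`, `sigma² = 2 mV²`
  the CV-vs-`|a_i|` curve is flat to ~1e−4 across `[0.65, 1.0] mV`; two
  independent quadrature routes put the refined argmin at ≈0.76 mV, and
  3×10⁷-ISI simulations confirm CV(0.75) < CV(0.90) at ≈2.3 combined
  standard errors. The commonly quoted location ~0.9 mV appears to be a
  read-off of this flat curve; the package reports the computed argmin.

## Event-driven simulator

Between events the membrane relaxes exactly; event times come from one
merged Poisson clock (type chosen Bernoulli `R_e/(R_e+R_i)`), drift
crossings between events are solved in closed form, and excitatory
overshoot at a kick instant spikes and resets immediately. There is no time
step, so the integration is exact to floating point; identical seeds
reproduce trains bit-for-bit. An ensemble of independent trains runs in
lock-step numpy arrays (~10⁷ events per second per core), providing
10⁵–10⁶ ISIs for the 3–4 standard-error theory-vs-simulation gates in the
test suite at desk scale. Burn-in (default 400 ms = 20 tau) is discarded;
ISIs are pooled across trains of a renewal process, so pooling is unbiased
up to the finite-window censoring of the last interval per train (kept below
the Monte-Carlo error by the chosen train lengths; the simulation gates
allow 4 SE rather than 3 for this reason).

The empirical spike-train spectrum bins counts at 1 ms, removes the mean,
and averages `|FFT|²/T` over realizations, so its high-frequency plateau
estimates the rate in Hz and is directly comparable to the analytic `Ĉ`.
Of the two spectral plateaus `{r0, r0 CV²}`, the computed `Ĉ` attains
`r0 CV²` at `ω → 0` and `r0` at high frequency, the standard renewal
assignment.

## Heterogeneous sparse network

Each of `N` neurons receives exactly `K` presynaptic inputs (no self-
connections); presynaptic neuron `k` delivers kicks of size
`a_i(k) = −g(k)/K`, one coupling `g(k)` drawn per neuron at construction;
excitabilities `mu(j)` are i.i.d. uniform. The direct simulation is
event-driven over the network (analytic drift between spikes, O(N) updates
per spike). Silent neurons — no spike in the retained window — are excluded
from the population statistics, and the measured active fraction `n*` feeds
the mean field.

The mean field assumes uncorrelated Poisson input: a neuron sees pooled rate
`R_i = K n* r̄0` (K random neighbours, of which a fraction `n*` fire at the
active-population mean `r̄0` — the pooled rate uses the all-neuron mean).
`r̄0` solves the damped fixed point `r̄0 = <r0(mu; R_i)>` over the active set
(top-`n*` excitabilities, 64 Gauss–Legendre nodes; damping 0.5, tolerance
1e−8 Hz, warm-started from the diffusion-approximation fixed point), and the
population CV averages the single-neuron CV over the same set. The active
set's weight `Δ` is its probability mass under the excitability law. The
description is valid only for asynchronous collective states; no synchrony
detector is built in.

## What the synthetic protocols do and do not show

All test data are generated internally: single-neuron Poisson shot noise at
prescribed `(mu_T, sigma²)` grids, balanced excitatory/inhibitory
configurations, and the N=400/K=20 uniform-excitability network. These
reproduce the idealized conditions of the theory — instantaneous synapses,
exactly Poisson arrivals, uncorrelated inputs, no refractoriness. Passing
tests therefore validate the mathematics and its numerical realization,
not the model's adequacy for real neurons: finite synaptic time constants,
input correlations, synchrony and refractory effects are all outside the
model class (and outside scope). Problem sizes in the default suite
(10⁵–10⁶ ISIs per gate, 150 000-spike network runs) were chosen as the
smallest giving decisive 3–4 SE comparisons.

## Known limitations

* Analytic spectra and ISI densities are implemented for DC excitatory
  drive only (the finite-`x̄` oscillatory integrals would need a dedicated
  endpoint treatment); rate and CV cover both drive kinds.
* The double-precision spectral ceiling (~200–300 Hz) bounds how sharp a
  feature the ISI-density inversion can resolve; quantities reported from
  spectra use the 0–100 Hz band.
* Very deeply sub-threshold diffusion-CV evaluations (`(v_th−mu_T)/σ > 25`)
  are refused rather than computed inaccurately.
* The mean field takes `n*` from simulation; it does not determine the
  active fraction self-consistently.
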