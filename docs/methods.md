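# Methods

## The cell model

Each cell is a four-variable model of the catalysed
Belousov–Zhabotinsky (BZ) reaction in a flow reactor, in molar units with
time in seconds:

    dx/dt = -k1 x y + k2 y - 2 k3 x^2 + k4 x (c0 - z)/(c0 - z + cmin) - k0 x
    dy/dt = -k1 x y - k2 y + k9p v z - k0 (y - y0)
    dz/dt = 2 k4 x (c0 - z)/(c0 - z + cmin) - k9p v z - k10 z
    dv/dt = 2 k1 x y + k2 y + k3 x^2 - k9p v z - k13 v - k0 v

with x = [HBrO2] (activator), y = [Br-] (inhibitor), z the oxidised
catalyst, v = [BrMA], and the composite rates k1 = k1'h, k2 = k2'h^2 A*,
k4 = k4'h A*, k10 = k10'[MA], cmin = sqrt(3 kr k10 c0)/kred.  The bromate
concentration entering k2 is identified with A* = [NaBrO3] = 0.25 M, the
only bromate symbol the recipe defines; with that identification the model
reproduces independently computed steady states to six significant digits.
Cells that receive excitatory pulses carry silver ions as a fifth variable;
silver scavenges bromide at the diffusion-limited rate kdiff = 1e8 /M/s,
which is how an excitatory pulse removes inhibitor.

Two knobs set a cell's regime: the acidity `h` and the bromide inflow
`y0`.  At `y0 = 0` the cell oscillates with natural period T0 ~ 144.6 s at
h = 0.3 M, decreasing with h.  Raising y0 through the Hopf threshold
(y0H ~ 1.3330 mM at h = 0.3) leaves a stable focus that is excitable: a
large enough perturbation fires one full spike.

No nondimensionalisation is performed, so published constants are usable
verbatim.  Concentrations must stay non-negative and z <= c0; the
integrator contract checks both on every trajectory.

## Linear stability and excitability

Steady states are found by Newton iteration with the analytic Jacobian,
continued from a deeply stable state at large y0 down to the requested one
(reliable on both sides of the Hopf point), and polished to residuals at
round-off.  The spectrum of the 4x4 Jacobian at the steady state supplies
the focus frequency omega0 = Im(lambda) and the damping ratio Im/Re; the
reported pair is the complex pair with the largest real part, because at
high acidity a real eigenvalue overtakes it without carrying the focus
frequency.  The Hopf threshold is a bracketing root-solve on Re(lambda) of
the leading eigenvalue (tolerance 1e-10 M in y0).

The Jacobian is hand-derived rather than numerical because eigenvalue
targets need five-digit accuracy; a central finite-difference oracle checks
it to 1e-6 relative in the tests.

The closed-form subthreshold response
`y(t) = y_SS + y_ini cos(omega0 t) exp(2.3 Re(lambda) t)` is provided as a
diagnostic only.  The 2.3 factor in the exponent is kept as printed in the
model's source description even though linear theory gives
exp(Re(lambda) t) — it looks like a base-10/e conversion slip, and the full
ODE is authoritative everywhere in this package.

The single-pulse excitability threshold C_ex^min(y0, dt) is measured by
direct simulation: a cell at its steady state receives one silver pulse of
width dt, and the amplitude separating "no spike within 450 s" (three
natural periods — a spike elicited by one pulse arrives within seconds) from
"spike" is bisected to 0.1%.  This measured threshold is what the amplitude
reader's band logic consumes, keeping the reader internally consistent with
the model as integrated here.

## Network integration

Coupling is purely pulsatile.  A spike of a source cell (upward crossing of
the activator through theta_spike) opens, `delay` seconds later, a
rectangular injection window of width `width` on each of its targets;
inhibitory windows add to dy/dt, excitatory windows to d[Ag]/dt, and
overlapping windows sum.  External periodic signals S(t) =
H(sin(omega t) - 0.99) trigger one window per forcing period; the trigger
delay of external signals is ignored, since only the period and the width
matter for a periodic train.

The integrator is LSODA (absolute tolerance 1e-12 M, relative 1e-9;
concentrations span six orders of magnitude) restarted exactly at every
window boundary, so pulses are perfectly rectangular.  Spikes of cells that
drive others are terminal solver events: integration stops at the crossing,
the delayed windows are scheduled, and integration resumes — so coupling is
causal, with no post-hoc approximation.  Simultaneous crossings (exact in
symmetric modes) are collected in one stop; an arming/rearming hysteresis
(rearm when x falls below theta/2) prevents re-triggering on restart.
Everything is deterministic.

Spike detection defaults: theta_spike = 3e-6 M, refractory 20 s.  BZ spikes
in this model rise three orders of magnitude above the interspike baseline
in about a second, so any threshold within a decade gives spike times within
one second (tested); solver-tolerance refinement moves spike times by less
than 0.05 s over 2000 s (tested).

Feed-forward reader cells (which drive nobody) are integrated individually
against the precomputed windows of the upstream spike trains — exactly
equivalent for a unidirectional architecture and much faster than carrying
them in the coupled system.

## Mode taxonomy and classification

The four all-to-all inhibitory oscillators settle into five base patterns —
in-phase (IP), triplet–singlet ('3+1'), anti-phase (AP),
doublet–singlet–singlet ('2+1+1') and splay — which split into 26 sub-modes
under oscillator permutation (1 + 4 + 3 + 12 + 6).  A sub-mode is stored as
the cyclic firing order of its clusters, canonicalised to start with the
cluster containing oscillator 1.

Classification measures the global period (per-oscillator mean inter-spike
interval after discarding transients; the means must agree within 1%),
forms circular-mean phase offsets relative to oscillator 1, and matches
them against the canonical offsets of all 26 labels by circular least
squares over a global rotation.  The nearest label wins; if the largest
per-oscillator error exceeds 0.08 T the pattern is labelled irregular.
The cluster tolerance delta = 0.05 T and the 0.08 T radius are this
package's choices: settled sub-modes deviate from their nominal offsets by
a few percent of T (the '3+1' singlet settles near 0.56 T rather than
0.5 T, the '2+1+1' singlets near 0.37 T and 0.69 T), and the radius must
cover those deviations while keeping all 26 canonical patterns mutually
distinguishable (tested as a 26/26 round trip).

## Seeding modes

The study never states how a mode is reached; here each oscillator is
placed on the isolated cell's limit cycle at the phase offset of its
cluster.  The limit-cycle fixture discards 25 spikes before sampling one
period (the relaxation onto the cycle is slow, with the interval shrinking
geometrically over ~15 cycles), anchors phase 0 at the spike upward
crossing, and stores 2048 linearly interpolated samples; its closure error
is below 1e-3 relative.  Seeded this way, all 26 sub-modes persist and
classify back to their seed at the delay-study coupling (see below).

## The three readers

**Delay (polychronization) reader.**  One excitable cell per sub-mode
(y0 = 4 mM, per-pulse C_ex = 1.3e-6 M/s, dt = 5 s: four overlapping pulses
clear the single-pulse threshold, three do not).  Conduction delays are
tau_d(i) = tau_s + ((-offset_i) mod T) with tau_s = 0.1 T, so all four
pulses arrive simultaneously exactly when the CPG runs in the cell's
sub-mode.  The offsets used are measured from each sub-mode's own settled
pattern (a calibration run per label): the threshold band tolerates only
~0.5 s of arrival stagger, and settled offsets deviate from canonical ones
by up to 5 s.  Tuning delays to the realised pattern is precisely the
polychronization prescription; the canonical offsets (with the singlet of
'3+1' at T - T/2.2) remain the default when no measurement is supplied.
The delay-study CPG runs at C_inh = 2e-5 M/s, tau = 1 s, where all 26
seeded sub-modes persist.  Activation is at least one spike within four
global periods after a four-period transient (the tuned cell may fire
subharmonically — in the AP demonstration it fires at half the volley
rate).  Over all 26 seeded sub-modes the 26x26 activation matrix is the
identity.

**Amplitude (cluster-summation) reader.**  Cells fed without delays, with
thresholds graded to fire on k or more simultaneous pulses.  The per-pulse
amplitude of a kP cell is C_ex^min/(k - 1/2) (and 1.5 C_ex^min for k = 1),
placing k pulses above and k-1 below threshold, with C_ex^min recomputed
from this model at each cell's y0.  Case i: four cells on all inputs with
y0 = 8/6/4/2 mM (4P/3P/2P/1P) — active counts 4/3/2/2/1 for
IP/'3+1'/AP/'2+1+1'/S, with AP and '2+1+1' indistinguishable.  Case ii:
four 3P cells, one per triplet, separating the '3+1' permutations.  Case
iii: six 2P pair cells — AP activates two, '2+1+1' one, permutations give
distinct active sets.

**Resonance reader.**  A stable-focus cell driven by a periodic pulse train
spikes once the amplitude exceeds a critical value C_ex^cr(omega) whose
minimum sits at the focus frequency omega0 = Im(lambda) (verified: the
curve minimum falls on omega0 within the grid resolution for all three
published cells, with subharmonic local minima at omega0/2 and 2 omega0).
C_ex^cr is bisected to 1% between "no spike in 20 forcing periods" and
"spike", warm-starting each frequency from the previous critical value.
The full method — `tuned_resonance_study` — measures the pulse rate
2 pi n / T of the IP, AP and splay configurations, tunes one cell to each
rate by a nested bracketing solve (inner: y0 just above the Hopf threshold
until the damping ratio matches; outer: h on the focus frequency), and
selects per-pulse amplitudes from the critical-amplitude curves: just above
the cell's own threshold (factor 1.12), because the fragile edge of the
selectivity band is the cross-mode one — the slow modes excite the faster
cells at their omega0/2 subharmonic.  A damping ratio target of 50 is used:
this implementation's mode frequencies are more closely spaced than the
published ones, and the deeper, sharper resonance of a weaker-damped focus
is what opens a selective band (the method's own dial for resonance
sharpness).  The tuned 3x3 mode-versus-cell activation matrix is the
identity.  The splay CPG for this demonstration runs at h = 0.29,
C_inh = 1e-5 M/s, tau = 5 s, a parameter point where the splay state is an
attractor of this implementation.

**Frequency dispersion.**  With oscillator acidities h0 ± eps, h0 ± eps/2
(eps = 0.01 M), the "synchronous" spikes of the near-in-phase state are
staggered, and the IP-tuned delay cell misses at the standard pulse width;
widening the pulses restores the overlap and the response.  In this
implementation the dispersed, frequency-locked state carries offsets of up
to ~25 s, so recovery needs widths of ~20 s.

## Fidelity to the published coupled-network values

The uncoupled layer of this implementation matches the published numbers to
a fraction of a percent: steady states and eigenvalue spectra to 5–6
significant digits, the Hopf point to 4 digits, the natural period to 0.4%.
The pulse-coupled layer does not: at the published IP parameters the
self-consistent global period here is 109.1 s versus the published 124.2 s,
the anti-phase period 117.4 s versus 130.6 s, and at the published splay
parameters no splay orbit exists at all — a single-cell entrainment
analysis shows the locked firing phase always falls on another cluster's
arrival slot, so the clusters merge into in-phase (the event-driven engine
was cross-validated against an independent fixed-grid integration with
prescheduled windows; the two agree to 0.01 s).  Excitation thresholds
under pulses sit 15–30% above the published ones, while an
instantaneous-removal experiment shows the basin boundary lies deeper than
the (y_SS - y_SS^H) heuristic the published thresholds follow.  No
reinterpretation of the pulse convention (amplitude scaling, window
summation, trigger definition, amplitude-as-concentration) reconciles all
published coupled values at once.  The package therefore implements the
printed equations and parameters literally, reports its own coupled-network
numbers, and demonstrates the three recognition methods against the modes
this model actually produces.

## Problem sizes and numerical defaults

Calibration and reader runs use 8–20 global periods per simulation; the
26-mode delay study is 26 calibration runs plus 26 recognition runs (each
a 4-oscillator CPG and 26 individually integrated reader cells); resonance
curves use 11 frequencies per cell spanning omega0/2 to 2 omega0.  Solver
tolerances are rtol 1e-9 / atol 1e-12 throughout, trajectory sampling 1–5 s,
and every pipeline is deterministic — identical configurations produce
identical outputs.

## Known limitations

- The pulse-coupled quantitative targets discussed above are reproduced
  qualitatively (mode persistence, reader selectivity, dispersion
  sensitivity) but not numerically.
- The irregular regime is a single bucket: no chimera taxonomy.
- The optional inhibitory coupling between reader cells (for suppressing
  unwanted activations) is modelled by the same window machinery but is not
  enabled in any shipped scenario, as no parameters are published for it.
- Networks are desk-scale (tens of nodes); no performance engineering
  beyond the compiled right-hand sides.
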