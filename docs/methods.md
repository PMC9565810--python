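# Methods note

## Compartment geometry and event detection

The receptor is reduced to a cylinder-based region model along the membrane
normal z (Å, increasing from the intracellular to the extracellular side):
an intracellular bath (IC) below the pore mouth plane `z_ic`, the
transmembrane PORE up to the vestibule floor `z_ec`, the VESTIBULE cylinder
(radius `r_vest`) up to its ceiling `z_vest_top`, FENESTRATION tunnels
through the side wall within a z band `fen_band` and radial depth
`fen_width`, and the extracellular bath (EC) everywhere above and outside.
All parameters are tunable (`RegionModel`); the defaults describe an
open-channel pLGIC-like construct (40 Å pore, 30 Å vestibule, 15 Å vestibule
radius, 5 Å apical aperture, fenestration band 45–60 Å). The vestibule
ceiling plane is a modelling choice — in a real structure the boundary
between central and outer vestibule is a constriction, not a plane — and is
deliberately exposed as a parameter.

Detection is a per-ion state machine over the *terminal* compartments
{IC, VESTIBULE, EC}. An ion's committed region changes only when a frame
lies at least the hysteresis margin δz (default 2 Å) inside every bounding
surface of the new region; frames inside the margin, or in the transit
regions (PORE, FENESTRATION, membrane exterior), never commit. This
suppresses thermal boundary recrossings. Events are emitted on committed
terminal transitions:

- VESTIBULE→IC / IC→VESTIBULE: transmembrane, inward/outward.
- EC↔VESTIBULE: lateral or apical, classified from the transit segment
  between the last committed source frame and the commit frame. The rule:
  lateral if any raw frame lies in FENESTRATION, or if the relevant
  frame-pair segment (last entry step into the vestibule for entries, first
  exit step for exits — mirror images, preserving time-reversal symmetry)
  pierces the side-wall cylinder r = `r_vest` at a height inside `fen_band`;
  apical if it pierces the ceiling disc within `r_apical` of the axis;
  otherwise the side of the non-vestibule endpoint decides. Cylinder
  crossings are solved exactly (quadratic in the segment parameter). This
  interpolation rule for frames that jump the boundary in one step is a
  reconstruction: any sub-frame classifier consistent with the region
  definitions would do, and the package's tests pin this one with an
  independent bisection-based oracle.
- Direct IC↔EC committed transitions (coarse sampling) decompose into a
  transmembrane plus an access event.

Directions are geometric: *inward* means chloride moving EC→IC. For an
anion this carries an outward (positive) electrical current; the sign
mapping is applied once, in the currents module, so event bookkeeping stays
free of electrophysiological conventions.

Periodic wrapping along z is removed by minimal-image unwrapping,
`dz_unwrapped = dz − L_z·ceil(dz/L_z − 1/2)`, which maps each frame-to-frame
displacement into (−L_z/2, +L_z/2] (exact half-box displacements resolve to
the positive sign).

## Currents and I–V statistics

A constant field E_z over a periodic box of height L_z imposes
V_m = E_z·L_z. The current estimate from N net transmembrane events over T
ns is I = N·e/T (e/ns = 160.218 pA·ns per event), with Poisson counting
error σ = I/√N and conductance g = I/|V_m|. Replicas at the same voltage are
pooled by summing counts and times before dividing, which is the maximum
likelihood estimate for a Poisson process.

The lateral permeability ratio of a construct is the outward lateral event
rate over the transmembrane event rate carrying the same chloride flux
(both are geometric "outward" events at strongly negative voltage, where
chloride flows IC→vestibule→EC), normalised to the wild-type mean so that
wild type is 1.00 by construction. Replicas without transmembrane events
are excluded with a warning. The apical fraction is the apical share of all
EC↔vestibule events.

Branch slope conductances are ordinary (optionally 1/σ²-weighted) least
squares lines through the negative-voltage and positive-voltage points
separately, V = 0 excluded; slopes convert pA/mV → pS. Intercepts are left
free: forcing lines through the origin would hide junction/offset effects
the two-line presentation is meant to absorb. The rectification index is
the inward/outward slope ratio, reported to two decimals; percent
reductions versus a reference are reported to the nearest integer percent.

## Three-compartment kinetic model

Compartments: extracellular bath (clamped concentration A0) ⇌ vestibule (B)
⇌ intracellular bath (clamped at A0). Lateral (k_l, k_−l) and apical
(k_a, k_−a) exchange is voltage independent. Transmembrane exchange depends
on the reduced voltage v = |V|/V_c: the rate along the electrochemical
gradient is k_t·(1 + v) (linear growth) and the rate against it is
k_−t·e^(−v) (exponential suppression), both reducing to the base rates at
V = 0. Only the qualitative assumptions (linear along, exponential against,
voltage-independent access) are fixed by the physics; these functional
forms are the minimal concrete choices and are stated explicitly for that
reason. V_c = 50 mV maps the ±250 mV range onto v ∈ [0, 5].

Setting d[B]/dt = 0 gives, for V ≥ 0 (transmembrane drives vestibule→IC):

    B_ss = A0·(k_l + k_a + k_against) / (k_−l + k_−a + k_along)
    J    = k_along·B_ss − k_against·A0

and the mirrored expressions for V < 0 (flux reported negative). The
implementation keeps the general mass balance (k_−l + k_−a in the
denominator); with the symmetric reference constants (k_l = k_−l = 0.5,
k_a = k_−a = 0.025, k_t = k_−t = 0.1) it coincides with the symmetric form.
Consequences: vestibular depletion at positive voltage and pumping at
negative voltage; a positive-branch flux plateau at the total vestibule
supply (k_l + k_a)·A0 = 0.525·A0 (0.03·A0 with the lateral rates scaled by
1/100); no ceiling on the negative branch; and inward rectification that
grows as lateral access is hindered. Mutant scenarios scale k_l and k_−l
together — a fenestration that conducts worse does so in both directions.

The same jump process is simulated exactly with the Gillespie direct method
(vestibule count B the only fluctuating species, propensities rate·n_A for
entries and rate·B for exits, B0 initialised at the rounded analytic steady
state to remove the transient). The stochastic results serve as an
independent oracle for the closed forms and agree within sampling error
across the voltage sweep.

## Synthetic trajectory generator

The generator emulates what matters to the detector — compartment dwelling,
thermal jitter, continuous pathway-specific crossings — without physics (no
electrostatics, no ion–ion interaction). Crossings are scheduled per
(pathway, direction) stream as Poisson processes (events/ns, ensemble
totals); transmembrane streams are voltage modulated like the kinetic model
(×(1 + drift_gain·|V|) along, ×e^(−drift_gain·|V|) against). Each scheduled
crossing claims an idle ion in the source compartment (or is dropped — so
realized rates are starvation-capped at high intensity) and is rendered
over `n_render` frames through gate waypoints: through the pore on the
axis, through the fenestration band via an approach that stays outside the
fenestrated wall, or through the apical aperture on the axis. Idle ions
perform mean-reverting jitter around compartment anchors. Crossings are not
scheduled in the last `n_render` frames (a truncated excursion would be an
uncommitted "true" event). Every rendered crossing is recorded as ground
truth with its mid-excursion time; identical configuration and seed give
byte-identical output. For vestibular occupancy studies, the scheduled-exit
stream acts like a single-server queue, giving the closed-form intensity
λ = churn·m/(1 + m) for a target mean occupancy m (`occupancy_rates`).

Known limits: realized rates fall below scheduled rates when sources
starve; the lateral permeability ratio recovered from generated ensembles
can sit a few hundredths above the configured rate scaling because faster
streams are starvation-capped slightly more (an estimator property on
finite ensembles, not a detector error).

## Single-channel simulation and fitting

Traces are two-state (closed/open) continuous-time Markov chains with
exponential dwells discretised onto the sample grid (20 kHz default), an
ohmic open level γ(V)·(V − V_rev) with separate branch conductances,
Gaussian noise, and an optional 5-pole low-pass Bessel filter (1 kHz) as in
an acquisition chain. The all-points histogram (default bin width 0.1 pA —
a few times smaller than typical noise SDs, so the two modes are resolved
without empty-bin noise) is fitted with a sum of two Gaussian components;
initial means come from the two most prominent histogram peaks. The open
amplitude is the distance between the component means. Fits whose
components collapse (< 3 bin widths apart) or whose trace spans less than 4
bin widths raise "open state not detected" — at low voltage and low
conductance the open level genuinely sinks below the noise floor, and such
patches should be dropped, not forced. Per-voltage amplitudes over patches
give mean ± SEM I–V points (sign restored from the side of V_rev), fed to
the same branch slope fits as above. Dose–response data are fitted with a
one-site Hill equation R = R_max·c^n/(EC50^n + c^n) by least squares.

## Validation strategy

- An independent brute-force detector (terminal-run compression plus
  bisection-located surface crossings, `tests/oracle.py`) must agree with
  the production state machine event-for-event on synthetic ensembles and
  on unstructured random walks.
- Time-reversal symmetry: reversing a track reverses the event sequence
  with directions flipped and pathways unchanged.
- Generator ground truth: every rendered crossing must be detected with the
  correct label (0 missed / spurious / misclassified across seeds), and
  pooled stream rates must match scheduled intensities within Poisson
  error.
- The Gillespie simulator cross-checks the closed-form kinetics; the patch
  pipeline must recover its generator conductances within fit error.
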