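# Methods

## The model

Prostaglandin H synthase-1 (PGHS-1, COX-1) converts arachidonic acid (AA)
into prostaglandin H2 (PGH2) through two coupled activities housed in one
catalytic domain: a cyclooxygenase (COX) site that oxygenates AA to the
hydroperoxide PGG2 (consuming two O2 per turnover), and a peroxidase (POX)
site that reduces PGG2 to PGH2 at the heme, oxidising an exogenous reducing
cosubstrate (RC, e.g. phenol or adrenaline) in the process.  In the
branched-chain picture the POX cycle generates the Tyr385 radical that the
COX site needs to abstract hydrogen from AA, after which COX turnover can
proceed on its own; the model also carries the tightly-coupled alternative
(direct H abstraction by the porphyrin radical cation) so the two routes can
be compared by flux analysis.

`pghs1net` represents the enzyme as microstates: the Cartesian product of

* heme state — Fe(III),PP (ground), Fe(IV),PP*+ (two oxidising
  equivalents), Fe(IV),PP (ferryl);
* Tyr385 — ground or tyrosyl radical;
* COX-site occupancy — empty, AA, arachidonyl radical AA*, or PGG2 radical.

That gives 24 catalytic states (E1..E24), plus three COX-dead states
(peroxidase-only, one per heme state) and one fully-inactive species (FIE).
The resting holoenzyme [Fe(III),PP; Tyr; empty] is E1; labels for
compositions the literature leaves unnamed are assigned to the remaining
slots and recorded in `network.py`; dynamics depend only on composition.

Reactions are generated, not listed: eleven catalytic templates (ligand
binding, H abstraction, oxygenation, product release, the peroxidase step,
three RC reductions, two intramolecular electron transfers) and three
self-inactivation templates are applied to every species whose composition
matches.  Reactions of one template share a rate constant, giving the
18-parameter unified set (defaults in `ParameterSet`); the two binding
templates are reversible with koff = kon x Kd.  Two constants are
occupancy-conditional: the tyrosyl-radical reduction by RC runs at k5 with
an empty or PGG2*-occupied site but at k10 when AA blocks the channel, and
the intramolecular electron transfer runs at k9 = 310 1/s with an empty or
PGG2*-occupied site but at k11 = 1.1 1/s when AA/AA* is bound.  Treating
the PGG2 radical like the empty site in both rules is a deliberate design
choice: the slow constant is documented for the AA-occupied peroxidase
cycle, the analogous RC-reduction of the two-radical state with PGG2* in
the site is documented to take the fast constant, and the mechanistic
rationale in the source literature is specifically that *AA* in the channel
blocks access.  Applying the slow constant to PGG2*-occupied states instead
traps the enzyme in the two-radical COX cycle, where it self-inactivates
within seconds and the cosubstrate/substrate stoichiometry collapses to
~0.1 — far outside every published behaviour.

Self-inactivation has three routes: POX death to FIE from every
porphyrin-radical-bearing species (kin1, including the COX-dead peroxidase
cycle), POX death from the four documented ferryl/tyrosyl intermediates
E5, E9, E15, E20 (kin2), and COX-site death to a COX-dead species with the
same heme state (kin) from the eight documented sources — every
tyrosyl-radical state with an empty or AA-occupied site plus the two-radical
states E17 and E4 on the ferryl heme.  The source enumerations are treated
as exhaustive rather than generalised to all twelve tyrosyl-radical states;
the four extra routes that generalisation would add (from E18, E22, E23,
E24) sit on the main peroxidase return path and would suppress the RC/AA
consumption ratio below its published band.  A ligand discarded on
inactivation is routed to an explicit damage-sink pool so arachidonate
accounting stays closed.

Two network policies exist: `COMPOSITION_COMPLETE` (the default closure,
83 reactions) and `PAPER_ENUMERATED` (only the 55 transitions with a
published reaction number, for comparison).  The published count of 66
reactions cannot be reconciled exactly with either closure from the
available text; all structural invariants (one enzyme in, one enzyme out;
FIE absorbing; full reachability from E1) are enforced by
`validate_network`.

## Simulation

Mass-action ODEs over 35 states (28 enzyme species, six metabolite pools,
damage sink), assembled from the reaction list.  Each reaction contributes
k x [enzyme] x prod [consumed metabolite]^n; O2 enters squared in the
oxygenation step; reversible bindings add koff x [complex].  Integration
uses the stiff BDF method with the analytic Jacobian, rtol 1e-8 / atol
1e-10 (1e-5 uM on a nM-uM problem).  Fluxes are evaluated on the stored
output grid after integration, which is geometric by default so the
sub-millisecond ignition transient is resolved.  Enzyme total, RC+OC and
the arachidonate moiety (free AA + PGG2 + PGH2 + site-bound + sink) are
conserved to better than 1e-6 relative on every tested trajectory;
conservation is checked, never used to eliminate states.

Seeding: the peroxidase cycle needs a peroxide to ignite, so runs start
with a configurable PGG2 seed (default 0.01 uM); the activation-threshold
analysis depends on this choice.  O2 defaults to an air-saturated 200 uM
(optionally clamped); at k3 = 173 1/(uM^2 s) oxygenation is never
rate-limiting above ~50 uM O2.  All enzyme starts in E1 unless configured
otherwise.

## Observables

* V_O2(t) = 2 x sum of oxygenation fluxes; its time integral equals the O2
  consumed (exact stoichiometric identity, tested).
* Dose-response: one simulation per AA value, reporting max-over-time V_O2.
  The apparent Km is extracted by half-maximum interpolation after a
  plateau check (last two grid points within 5% of the maximum) rather
  than a hyperbolic fit, because the curves turn sigmoidal at high RC.
* Eadie-Scatchard coordinates (V/E vs V/AA/E) with a mean-second-difference
  concavity diagnostic; Michaelis kinetics gives an exactly straight line
  with slope -1/Km (oracle), positive cooperativity a downward-concave set.
* Activation threshold: log-space bisection on initial AA until PGH2 at
  t = 300 s crosses the criterion (default 0.02 uM) to 1% relative bracket
  width; unreachable criteria report the bracket boundary with a flag.
* Consumption stoichiometry: (RC0 - RC(t)) / (AA0 - AA(t)) at t = 30 s,
  undefined below 1e-9 uM of AA consumption.
* Flux table: max-over-time fluxes of the nine per-cycle production and
  connection reactions, at 35 nM enzyme and 80 uM AA (the conditions of the
  flux-analysis figures; the published table's own conditions are not
  stated).  "Rate" is read as max over time because the rates are strongly
  time-varying and the dose-response analysis uses maxima.
* Enzyme-activity duration: width of {t : V_O2 >= 5% of max}; the
  published description is only "about 20 sec".

## Calibration

The experimental curves behind the original parametrisation exist only as
figures, so calibration is specified against dataset files (records CSV +
conditions YAML) and validated by parameter recovery on synthetic
fixtures generated by `pghs1net.fixtures`: PGG2/PGH2 production kinetics
(35 nM enzyme, 80 uM AA, phenol at 100/1000/5000 uM), AA-consumption
kinetics (0.5-20 uM enzyme, 1000 uM phenol) and adrenochrome accumulation
(adrenaline 0.32-3.22 uM, 1050 uM H2O2, no AA, with the adrenaline/H2O2
POX block).  Values the figures do not state and that were fixed here
once: AA0 = 80 uM for the consumption scenario, 0.1 uM enzyme for the
peroxidase-only scenario, ten log-spaced sampling times per scenario span,
multiplicative Gaussian noise (sigma = 5%) clipped at zero.  These files
are synthetic stand-ins, not digitised data.

The objective is the weighted SSE with per-series weights 1/max(value)^2
(scale-free); failed simulations contribute a large finite penalty so
optimisers continue.  Fitting runs in log10 space within +/-3 decades of
the defaults, with seeded Latin-hypercube multistart and local
least-squares refinement; the grouping of reactions to constants is fixed
to the template map (re-deriving the grouping is out of scope).  On the
5%-noise PGG2/PGH2 fixtures the identifiable constants k2, k4, kin are
recovered within 10% (tested at the +/-25% gate); the near-zero k6/k8 of
the adrenaline block are weakly identifiable and flagged by flat profiles
or bound hits, matching the original report that k8 is "about zero".

## Sensitivity analysis

Morris elementary-effects screening over all 18 constants, log-uniform one
decade either side of the defaults (ranges, levels and trajectory counts
are not stated in the source; p = 4 levels, r = 100 trajectories and the
signed mean are this package's declared choices).  The output functional
is the trapezoidal AUC of the PGH2 time course at 35 nM enzyme, 80 uM AA,
100 uM RC over 1200 s.  Ranking = sqrt(mu^2 + sigma^2) exactly.  At
r = 100 the screening reproduces the published qualitative orderings:
kin and kin1 among the most sensitive parameters, kin1 above kin2, Kd12
well above k12.  Signed mu can cancel for non-monotone parameters; sigma
(and hence the ranking) still flags them.

## Problem sizes and numerical choices

The default test and analysis runs use 35 nM enzyme and spans of 60-1200 s;
dose-response grids use 10 AA values; the Morris screening 1900 model
evaluations; recovery fits 16 starts with a 60-evaluation cap per start.
Geometric output grids with ~800 points keep max-over-time flux extraction
stable; halving solver tolerances moves reported endpoints by < 1e-4
relative (tested).  Ties and degenerate inputs: zero enzyme yields zero
fluxes and a zero activity duration; a zero activation criterion returns
the lower search bound; reactions whose selected rate constant is exactly
zero are dropped at network build, so switched-off routes are absent
structurally as well as numerically.

## Known limitations

* The published per-cycle flux table cannot be reproduced quantitatively
  under the assumed 35 nM / 80 uM conditions: its V8 values (0.63-0.69
  uM/s) exceed the hard ceiling k4 x total enzyme = 0.455 uM/s, and its
  V22/V4 ratios imply a COX1-COX2 connecting constant of ~13 1/(uM s)
  where the unified set gives k6 = 0.58, consistently across all three RC
  rows.  The model reproduces the table's qualitative structure (V8
  dominant and rising with RC, V4 falling, V11 flat and small, V52 small)
  at roughly 2x lower absolute scale, and V22 at the scale Table 2's k6
  actually implies.
* The enzyme-activity duration at the validation condition comes out at
  ~42 s against the published "about 20 sec"; the inactivation reading
  that shortens it (COX death from all twelve tyrosyl-radical states)
  simultaneously breaks the consumption-stoichiometry band, so the
  text-enumerated reading was kept.
* Synthetic fixtures share the model's own structure, so recovery tests
  demonstrate identifiability of the calibration machinery, not the
  correctness of the model against real measurements; real data would add
  instrument error structure, baseline drift and condition uncertainty
  that the multiplicative-noise generator does not emulate.
* NSAID/inhibitor binding, the PGHS-2 isoform, dimer allostery and
  stochastic simulation are out of scope.
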