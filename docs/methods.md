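# Methods

## Model

`plastnet` simulates a network of N identical-in-form Hodgkin–Huxley (HH)
neurons whose *functional* connectivity is itself a dynamical variable.
Three layers interact:

1. **Membrane dynamics.** Each neuron is the classic four-variable HH
   point model, state x = (V, n, m, h):

       C_M dV/dt = −g_Na m³h (V−E_Na) − g_K n⁴ (V−E_K) − g_L (V−E_L) + I_ext + I_cpl
       dx/dt     = α_x(V)(1−x) − β_x(V) x,   x ∈ {n, m, h}

   Voltage convention: the reversal potentials (55, −72, −49.4 mV) are the
   original dimensionless-formulation values shifted by −60 mV, so the
   classic rate functions are evaluated on u = V − V_rest with
   V_rest = −60 mV.  The removable singularities of α_n (u = 10) and α_m
   (u = 25) are evaluated through w/(e^w − 1) with an explicit limit branch
   for |w| < 10⁻⁸.

2. **Structural network.** Each neuron owns a periodic axis-aligned box
   ("domain") on a global periodic plane of side L = 100; two neurons are
   physically wired iff their domains intersect on the torus (boundary
   touching counts).  The simulation scenario is a √N × √N torus of
   domains.  Equal squares cannot yield a 4-regular lattice: any square
   wide enough to reach its edge neighbor also clips the diagonal
   neighbor's corner, giving the 8-regular king graph.  The lattice
   therefore uses a checkerboard of rectangles (long side s(1+f) along
   alternating axes, short side s(1−f/2), s = L/√N, overlap fraction
   f = 0.25 by default), which intersect edge neighbors only and give the
   exact 4-regular torus for even √N.  Odd √N picks up extra seam edges
   where the checkerboard parity wraps inconsistently; the graph stays
   connected.

3. **Plasticity rule.** Each neuron carries a position r_i confined to its
   domain (wrapped with half-open convention [lower, upper)).  Every
   `update_period` ms:

       r_i ← wrap( r_i + γ Σ_{j∈η_i} û(r_j − r_i) · V_i V_j ),
       η_i = { j ≠ i : |r_j − r_i| ≤ R }   (minimum-image metric, inclusive)

   Same-sign potential pairs attract, opposite-sign pairs repel.  The
   functional adjacency is the 0/1 graph of pairs within R, masked by the
   structural overlap graph (configurable off), and the coupling strength
   is c_i = ε/N_η,i (0 for isolated neurons; a neuron is excluded from its
   own neighborhood, whose zero-distance term would have no direction).
   The product form V_i V_j inside the sum is the default reading of the
   attraction function; the alternative global-prefactor reading
   V_i (Σ_j V_j) Σ_j û_ij is available via `pair_product=False`.

   The coupling enters the voltage equation as the diffusive current
   I_cpl,i = c_i Σ_{j~i} (V_j − V_i) — a consensus controller that
   vanishes identically when all potentials agree.  It is computed in
   exactly that difference form (not as a Laplacian matrix–vector
   product), so the consensus state gives bitwise-zero input.

## Simulation protocol

Phase 1, [0, 400) ms: all neurons isolated.  Phase 2, [400, 3000] ms
(defaults): alternate between integrating the 4N equations with the
topology frozen over one update period and rebuilding positions/topology
from the end-of-window potentials.  Integration uses scipy's adaptive
Dormand–Prince pair (`RK45`, rtol 10⁻⁶ / atol 10⁻⁸), restarted at every
window boundary because the vector field is discontinuous there.  Output
is sampled on a uniform 0.1 ms grid; gating variables are clipped to
[0, 1] at window boundaries and on stored samples (adaptive steppers can
overshoot by ~10⁻¹⁰).

### Initial conditions and heterogeneity

Two defaults here were genuinely open and were set by the following
considerations:

* **Random-phase initialization (`init_mode="phase"`).**  A cold start
  with V(0) ~ U(−70, −50) and gates at steady state fires one anomalously
  tall first spike (peak 45–52 mV, because h∞ at hyperpolarized voltages
  leaves excess sodium availability), far above the 35.4 mV steady spike
  peak and outside the −100..40 mV envelope the model is meant to respect.
  The default therefore samples every neuron at an independent random
  phase of the isolated spiking orbit (a reference neuron is integrated
  past its transient and sampled at uniform random times over a 50 ms
  window, ≈3.4 periods).  The uniform cold start remains available as
  `init_mode="uniform"`.

* **Per-neuron drive jitter (`i_ext_jitter=0.1`).**  With identical drive
  currents the diffusively coupled identical oscillators reach complete
  synchronization; potentials then share sign, the update rule becomes
  purely attractive, and the functional topology freezes.  A ±10% spread
  of the 10 μA/cm² drive keeps the neurons slightly detuned: the network
  stays weakly synchronized (index S(t) crossing zero), attraction and
  repulsion alternate, and the topology keeps evolving — the regime the
  model is designed to exhibit.

* **Update cadence (`update_period=0.1` ms).**  Each update displaces
  positions by ~γV²N_η ≈ 2·10⁻³ lattice units *per update* regardless of
  the period, so a coarse cadence (1 ms) produces only O(1) edge flips per
  second of simulated time — an effectively frozen network.  At the
  spike-resolving 0.1 ms cadence the default 64-neuron run rewires in
  ≈90% of its 26 000 windows while γ keeps its tabulated value 6·10⁻⁷.

## Diagnostics

* **Synchronization index.**  S(t) = −ln σ(t) with σ the population
  (divisor N) standard deviation of the membrane potentials over the
  network or any subset; S > 0 ⟺ σ < 1 mV.  σ is floored at 10⁻¹²
  (S ≈ 27.63) with a clamp flag, so perfectly synchronized groups stay
  finite in tables.

* **Per-window stability certificate.**  On each fixed-topology window
  the Laplacian A = 𝒜 − D (negative semidefinite, zero row sums) has
  second-largest eigenvalue λ₂,max, strictly negative iff the snapshot
  graph is connected.  Exponential synchronization on the window is
  certified when λ₂,max ≤ d̄ < 0 (default margin d̄ = −10⁻³) and the
  symmetrized variational matrix Ψ(d) = (Df + dΓ)ᵀG + G(Df + dΓ) is
  negative definite at the reference state, with Df the analytic 4×4
  membrane Jacobian, Γ = diag(1,0,0,0) (voltage coupling only) and G = I.
  Negative definiteness is tested by Sylvester's criterion on the leading
  principal minors; the critical d (the supremum of certifiable d, which
  is monotone because d enters only Ψ₁₁) is bracketed by doubling and
  bisected to relative 10⁻⁶.  Ψ is assembled from the analytic Jacobian
  rather than hand-transcribed entries.  The evaluation state is
  configurable (the theory evaluates Df along the isolated reference
  trajectory; at the resting state the critical d is ≈ −4.5·10³ — the
  certificate is state-dependent and reported with its evaluation state).

* **Communities.**  Per window, greedy agglomerative (CNM-style)
  modularity optimization on the 0/1 coupling matrix: repeatedly merge the
  community pair with the largest ΔQ = l_ij/m − d_i d_j/2m² until no gain
  is positive, ties broken by the lowest community-index pair — fully
  deterministic, and merges are only proposed across existing edges, so
  disconnected components are never merged.  Edgeless graphs partition
  into singletons (Q reported as 0 for this undefined case).  Across
  windows, P_ij is the fraction of windows in which i and j share a
  community; the stable communities are the connected components of the
  graph {P_ij ≥ 0.70} (threshold inclusive, configurable; a cliques-only
  aggregation was considered and rejected as overly conservative for the
  transitive co-membership patterns the runs actually produce).

## Numerical choices

* The ε = 0 consistency check (windowed run vs single-sweep continuation)
  is run at rtol 10⁻⁸/atol 10⁻¹⁰: the two computations follow different
  step sequences, and at default tolerance the accumulated phase drift
  over 200 ms of spiking (≈2·10⁻³ mV) would dominate the comparison; at
  the tightened tolerance the discrepancy (≈10⁻⁵ mV) is pure
  discretization noise, well below the 10⁻³ mV band asserted.
* λ₂,max via `numpy.linalg.eigvalsh` after validating symmetry and zero
  row sums (tolerance 10⁻⁹); graph connectivity statements use the
  equivalent λ₂ < −10⁻⁹ test or `scipy.sparse.csgraph`.
* Determinism: one `SeedSequence` per run, spawned into independent
  streams for initial states and position jitter, so adding a consumer
  never perturbs the others; identical config + seed reproduces the trace
  bitwise.
* Reported problem sizes: the test suite exercises the reduced 4×4
  scenario (16 neurons, 1000 ms) and two/three-neuron fixtures; the full
  8×8, 3000 ms scenario is exercised by the acceptance script (≈1.5 min
  on one core).

## What the synthetic scenarios do and do not show

All inputs are generated programmatically (no external data): torus
lattices of domains, mutual-overlap pair/triangle fixtures, and clique
graphs with known optimal partitions.  They establish that the
implementation honors the model's invariants and reproduces its
qualitative regime (evolving degree, forming/dissolving communities,
weakly synchronized network with strongly synchronized stable
communities).  They do not model biological realism beyond the HH
membrane: no inhibition, no conduction delays, no spike-triggered
plasticity, identical channel kinetics across neurons, and a planar
periodic geometry rather than anatomical morphology.  Conclusions about
real neural tissue should not be drawn from passing tests.

## Known limitations

* Stability is certified only within fixed-topology windows, not across
  switching instants.
* The community optimizer is greedy; it attains the exhaustive optimum on
  the small benchmark graphs in the test suite but carries no global
  optimality guarantee on arbitrary graphs.
* Domains are axis-aligned boxes in d = 2; arbitrary manifolds, 3-D
  domains, weighted or directed coupling, and inhibitory neurons are out
  of scope.
* With odd √N the lattice overlap graph is connected but not exactly
  4-regular (checkerboard parity seam).
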