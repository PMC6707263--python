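# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `nmsis`. Everything stated here is computed by the test
suite or the example scripts; nothing is quoted from elsewhere.

## Waiting-time laws

A waiting-time law is carried as four redundant views — density ψ, survival
Ψ, hazard ω = ψ/Ψ, cumulative hazard H = −log Ψ — with closed forms per
family:

| family | parameters | Ψ(x) | hazard |
|---|---|---|---|
| Weibull | shape α, scale β | exp(−(x/β)^α) | (α/β)(x/β)^{α−1} |
| Beta(1, γ) | γ | (1−x)^γ on [0,1) | γ/(1−x) |
| Exponential | rate | e^{−rate·x} | rate (constant) |

Weibull with α = 1 is exactly the exponential with rate 1/β (tested to
1e−12). Shapes α < 1 give a density and hazard that diverge at age 0 and a
heavy tail; α > 1 gives an increasing hazard. Beyond a finite support the
evaluation triple is (0, 0, ∞): the infinite hazard is a documented
sentinel, not an error, because age-grid solvers may touch the endpoint
even though the event-driven simulator never does.

Sampling inverts the survival function, Ψ(x) = u with u uniform on (0, 1]
(closed form in all three families); correctness is checked by
Kolmogorov–Smirnov at 10⁵ draws. Quadrature (Laplace transforms,
normalization checks) uses adaptive rules at absolute tolerance 1e−10.

**Grid hazards.** Discrete solvers never evaluate ω pointwise on a grid;
they use exact bin averages (H(τ_{k+1}) − H(τ_k))/Δ, which stay finite for
singular endpoint hazards and make the discrete survival ratio
exp(−ω̄Δ) = Ψ(τ_{k+1})/Ψ(τ_k) exact.

## Networks

Undirected simple graphs with nodes 0..N−1. Generators: G(N, p) with
p = ⟨k⟩/(N−1); Barabási–Albert with m attachments (⟨k⟩ → 2m); a power-law
configuration model (degrees ∝ k^{−γ} above k_min, stub matching, then
degree-preserving swaps to remove self/multi edges, giving up after 100·E
attempts). Edge-list files accept arbitrary integer labels (remapped,
mapping kept), collapse duplicates/reversals, and drop self-loops with a
warning. The outbreak threshold is 1/Λ_max with Λ_max from a sparse
eigensolver (dense below 200 nodes), relative tolerance 1e−10.

A note on magnitudes: for G(N, p) with ⟨k⟩ = 10 the leading eigenvalue
concentrates near ⟨k⟩ + 1 ≈ 11, giving thresholds near 0.090 at N = 10⁴;
BA graphs with m = 5 come out near 0.035–0.037. These are what the
generators above actually produce, averaged over seeds, and they are what
`scripts/acceptance.py` reports.

## Event-driven simulation

Every infected node holds an absolute recovery time; every active directed
edge holds an absolute transmission time; a binary min-heap delivers events
in order. Rescheduling uses lazy invalidation — each (re)arm or cancel
bumps a per-entity version counter and stale heap entries are skipped on
pop — which has the same asymptotics as decrease-key with far less
bookkeeping. Ties (probability zero under continuous laws, possible at a
bounded support endpoint) break lexicographically by (time, recovery before
transmission, entity id), so runs are bit-for-bit reproducible given
(config, seed).

Mechanism rules, with directed edge e: src → dst:

* type-I: active iff src infected and dst susceptible. Transmission
  consumes e and infects dst; dst's incoming edges deactivate, its
  out-edges toward susceptible neighbors arm fresh. When a node becomes
  susceptible again, incoming edges from infected neighbors arm fresh.
* type-II: active iff src infected. Transmission re-arms e from age zero
  and infects dst if susceptible (otherwise only re-arms). On infection all
  out-edges arm fresh; recovery disarms all out-edges.

Initial conditions: ⌈ρ₀N⌉ seed nodes drawn without replacement, infection
ages zero; initially active edges draw fresh transmission ages. A
consistency audit (the active-edge predicate and node clocks recomputed
from scratch and compared against the heap state) runs every 1024 events by
default and is exercised at every event in tests.

Ensemble averages are unconditional: extinct realizations contribute zeros
after extinction. This matches transient curves that decay to zero; no
survival conditioning is applied anywhere.

Randomness: one master seed expands into named substreams (per realization,
per component) via `SeedSequence` spawn keys, so ensembles are reproducible
and order-independent.

Stationary densities are estimated as time averages over (burn-in, t_max];
the standard error comes from the spread of independent per-realization
time averages (batch means over 10 batches for a single realization, since
time samples are autocorrelated).

## Age-structured mean-field theory

State: per-node age densities I_i(τ;t) and S_i(τ;t) on a uniform grid with
Δτ = Δt (structurally enforced). One step: (1) infection pressure; (2)
transport one bin right, infected mass decaying by the exact survival ratio
Ψ_rec(τ+Δ)/Ψ_rec(τ) and susceptible mass by exp(−Φ_i(τ)Δ); (3) the
recovered and newly infected outflows re-enter age bin 0. Mass older than
the grid cutoff pools in the terminal bin and decays at the terminal-age
hazard, so per-node total probability is conserved to round-off (asserted
at 1e−6, measured at ~1e−16).

Infection pressure: type-II uses a single adjacency mat-vec of the
η-weighted infected mass, where the renewal intensity η solves the Volterra
equation η = ψ_inf + η∗ψ_inf by forward substitution with product
integration (η piecewise constant, kernel integrated exactly via survival
differences). This reproduces constant-hazard η ≡ rate exactly and is
stable for densities that diverge at age zero; the renewal-theorem limit
η → 1/mean is reached to O(Δ). Type-I needs the τ-resolved kernel
∫ω_inf[min(τ,τ′)]I_j(τ′)dτ′, computed in O(N_edges·n_bins) per step from a
prefix integral of ω̄·I_j plus ω̄(τ) times the suffix mass (a direct double
loop is kept as the test oracle). For bounded infection supports the min
argument is capped at support−Δ: ages beyond the support are an artefact of
the independent-age closure, and the cap kills that mass quickly without
destroying the integration.

Grid defaults: the age cutoff leaves < 1e−8 recovery survival mass; Δ =
0.02 for network-scale transients (the scheme is first order; halving Δ is
verified to at least halve the error against an independent ODE solution in
the constant-hazard limit, where the PDE collapses to the quenched
mean-field ODE). The integrator's late-time field satisfies the stationary
relations (log-slope of Ĩ_i(τ) equals −ω_rec, and Ĩ_i(0) = S̃_i(0))
to the grid tolerance, and its stationary density converges to the QMF
fixed point at λ_eff as Δ → 0.

Transient duration is measured by window stability: the earliest t such
that I stays within ε of I(t) for a full window (defaults ε = 1e−3,
window ≈ several mean infectious periods). This is a pragmatic, declared
metric — a monotone relaxation of length T yields ≈ T, and a trajectory
that never settles returns ∞.

## Effective rates and steady states

* δ_eff = 1/∫Ψ_rec (closed form per family).
* λ_eff (type-II) = ∫ η Ψ_rec dτ on a fine grid (Δ = 1e−3), with the
  closed form rate·mean for constant infection hazard. Interpreted as
  expected transmissions per infectious period per edge; verified against
  Monte-Carlo renewal counting.
* Ω(τ) = δ_eff ∫₀^τ ∫₀^∞ ω_inf[min(τ′,τ″)]Ψ_rec(τ′) dτ′ dτ″, its inverse
  ϑ, and λ*_eff = 1/[δ_eff ϑ′(0)] = ω_inf(0)/δ_eff. The derivatives
  ϑ^{(n)}(0) come from power-series reversion of Ω's exact Taylor series
  (hazard and survival expanded analytically per family — this restricts
  the series machinery to hazards analytic at 0: exponential, Beta(1, γ),
  integer-shape Weibull; a Weibull shape ≥ 2 has ω(0) = 0 and the
  reversion correctly refuses). A finite-difference inversion of the
  numerically integrated Ω serves as an independent oracle in tests.
* The type-I stationary relation 1/Ĩ_i = (1/S̃_i) Σ_n δ_eff ϑ^{(n)}(0)
  x_i^{−n} (x = A Ĩ) is an *asymptotic* series: stationarity gives
  S̃_i = δ_eff Ĩ_i ∫₀^∞ e^{−x_i Ω(τ)} dτ, and Watson's lemma shows
  ϑ^{(n)}(0) grows like n!·cⁿ. The solver therefore truncates each node's
  sum at its smallest term (raising n_max beyond the optimal point changes
  nothing) and flags nodes whose smallest term exceeds 1% of the sum —
  precisely the small-neighborhood-mass regime where the expansion breaks.
  An exact resummation via the Laplace integral is available as
  `method="integral"` and agrees with the optimally truncated series to
  ~1e−5 at high density.
* Scaling: multiplying the Beta shape γ by θ multiplies ω_inf and hence Ω
  by θ and divides ϑ^{(n)}(0) by θⁿ (the inverse maps u → ϑ(u/θ));
  verified numerically for θ = 2.
* The QMF fixed point Ĩ_i = λ S̃_i (AĨ)_i is solved by damped iteration
  (damping 0.5, start 1/2, sup-norm tolerance 1e−12), short-circuiting to
  zero below the spectral threshold. The Markovian reference pairs
  exponential recovery at δ_eff with exponential infection at
  λ_eff·δ_eff. Inverting the infection scale β_I from a target λ_eff uses
  monotone bisection in log β over [1e−3, 1e3].

## What the experiments emulate, and what passing tests show

The bundled experiments mirror the canonical study conditions: Weibull
recovery with shape 2, scale 0.5; infection shapes α_I ∈ {0.5, 1, 2, 4}
with β_I = 1 or tuned to a target λ_eff; 1% random seeds with age zero for
transients and 10% for stationary estimates; ER/BA graphs of 10⁴ nodes at
full scale and 10³ at desk scale (50 transient realizations, 8–10
stationary realizations of length 60–120 time units). Test problem sizes
were chosen so the whole suite runs on one CPU in minutes.

Two intrinsic gaps are worth stating plainly, because they bound what any
agreement test can show:

* The first-order closure ignores age correlations between neighbors. On
  sparse graphs (⟨k⟩ = 10) its transient and stationary predictions carry a
  systematic 0.01–0.03 bias in infected density relative to simulation —
  far larger than the ~0.002 standard error of a 50-realization ensemble
  mean. On dense graphs the bias essentially vanishes (on a complete graph
  of 300 nodes the theory tracks simulation to 0.002).
* The type-II/Markovian equivalence is exact at the level of the
  stationary mean-field equations, and exact in distribution only where
  the closure is exact. Finite sparse-network simulations of the two
  processes differ by genuine correlation effects (up to ~0.04 in density
  near threshold at ⟨k⟩ = 10) that do not shrink with more realizations.
  The package's equivalence tests document both facts: agreement within
  Monte-Carlo error on dense graphs, and the quantified sparse-graph gap.

## Known limitations

* First-order closure only; no pairwise (second-order) theory.
* The type-I series machinery requires hazards analytic at age zero.
* Weibull shapes below ~0.3 make event counts explode (bursts of nearly
  immediate transmissions); simulations remain exact but slow.
* The configuration-model generator targets simple graphs only and may
  fail (with an error) for infeasible degree sequences.
* Undirected, unweighted, static networks throughout.
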