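# Methods

`endonet` quantifies the dynamics of a closed "core endogenous network" of
master transcription factors — here the eight-TF network of early pancreatic
lineage decisions (PDX1, PTF1A, NKX6.1, SOX9, HES1, NGN3, ARX, PAX4) — under
the hypothesis that stable cell types are the attractors of that network and
intermediate progenitors are the saddles between them.  Three complementary
model layers are computed from the same signed edge table, plus a
least-action analysis of noise-driven transitions and a single-cell
matching stage.

## Coarse-grained Hill ODE

Each TF's concentration is normalized to [0, 1].  With activator index set
`act(i)` and inhibitor set `inh(i)`, the dynamics of gene *i* are

    dx_i/dt = [ c·A_i / (1 + c·A_i) ] · [ 1 / (1 + c·R_i) ] − x_i ,
    A_i = Σ_{u ∈ act(i)} x_u^n ,   R_i = Σ_{r ∈ inh(i)} x_r^n ,   c = 1/K^n

All regulators of the same sign pool inside one shared Hill term (a single
fraction over the summed x^n), inhibition is a multiplicative factor, and
production and decay rates are absorbed into the normalization (η = τ = 1).
The dissociation constant is K = 0.5 — a regulator at half level produces a
half-maximal response — so c = 2^n.  The Hill coefficient defaults to
n = 4, the smallest value at which the production term spans most of
[0, 1]; the robustness sweep re-solves the system at n = 5–7.  Two boundary
conventions matter: a gene with no activators has zero production (it can
only decay), and a gene with no inhibitors has inhibition factor 1 (only
HES1 exercises the latter in the pancreas network).

Both Hill factors lie in [0, 1], so `dx_i/dt ∈ [−x_i, 1 − x_i]` and the
unit box is forward-invariant; every biologically meaningful equilibrium
lies inside it.

### Equilibrium atlas

Equilibria are found by damped Newton iteration (step halving against the
sup-norm residual, ≤ 200 iterations, ≤ 50 halvings, convergence at
‖f‖∞ < 1e−10) run in batch from the deterministic grid {0, 1/2, 1}^G —
6561 starts for G = 8, covering every on/half/off orthant — optionally
augmented with seeded uniform starts.  Roots are deduplicated at Euclidean
distance 1e−6 and roots outside [−0.05, 1.05]^G are discarded as numerical
artifacts (forward-invariance makes them meaningless).  Each root is
classified by the real parts of its analytic-Jacobian eigenvalues: all
negative → stable; exactly one positive → transition state; two or more →
hyper-transition state; any real part within ±1e−8 of zero → degenerate
(reported, never silently classified; none occur for the pancreas network
at n = 4).  States are sorted by class then lexicographically and labeled
S1…, T1…, H1…, so labels are reproducible across runs.  For the canonical
network at n = 4 the census is 11 stable, 16 transition and 8
hyper-transition states, and every attractor persists with an identical
on/off pattern at n = 5, 6 and 7.

The limit-cycle scan integrates 200 seeded random initial states and
verifies that each trajectory comes to rest (‖f‖∞ < 1e−8) at an atlas
equilibrium (squared distance < δ₂); a trajectory that never settles would
flag a possible cycle.  None is found.

### Landscape topology

Transition relationships are found by perturbing each saddle along its
unstable subspace — the span of Jacobian eigenvectors with positive real
part (real representatives for complex pairs, re-orthonormalized) — with
squared amplitude below δ₁ = 0.25e−8 (radius 4.5e−5), integrating forward,
and recording the first equilibrium approached within squared distance
δ₂ = 1e−6 (the perturbed saddle itself is excluded).  For one unstable
direction the two signed axis directions are used; for k ≥ 2, the 2k signed
axis directions plus seeded random unit combinations inside the subspace
(8 by default).  The integrator is fixed-step RK4 with dt = 0.01 and
t_max = 500 (an explicit-Euler mode exists for fidelity comparisons; the
edge set is integrator-agnostic).  The resulting directed graph — saddles
pointing at the states they relax to — is the topological adaptive
landscape.  The transition-mediated edge set is invariant to doubling
t_max and to shrinking δ₁ tenfold; edges from hyper-transition saddles
(codimension-≥2 basin boundaries) are stored but flagged, since one random
in-subspace direction legitimately changes target under a tenfold smaller
amplitude, and the main landscape excludes them regardless.

### Cell-type identification

The 11 binarized attractor patterns are pairwise distinct, so the stable
cell types (acinar/tip, AciP, AciP2, TiP, TrP, trunk, ductal, Iα, Iβ, the
NKX6.1-only state, and the all-off state) are identified by exact marker
patterns.  Three progenitors are saddles and share binarized patterns with
attractors, so they are identified by landscape wiring instead: LEP is the
transition state whose perturbations reach both immature islet attractors
(Iα, Iβ), EEP bridges TrP and LEP, and MP bridges TiP and TrP.  The
recovered hierarchy — MP → {TiP → AciP/AciP2 → acinar; TrP → trunk →
ductal; TrP → EEP → LEP → Iα/Iβ} — is a computed result, not an input.

## Boolean layer

The synchronous Boolean model uses weight +1 per activator and −100 per
inhibitor (dominant inhibition: one active inhibitor overrides any number
of activators) with the strict threshold `x_i(t+1) = 1 iff Σ_j w_ij x_j(t) > 0`,
so a zero input sum yields "off".  All 2^8 = 256 states are enumerated
exhaustively (guarded at 24 genes) and fixed points X(t+1) = X(t) are
extracted; cyclic attractors are not chased.  Every binarized ODE attractor
is a Boolean fixed point and vice versa — the multistability is a property
of the wiring, not of the Hill parameters.  Softening the inhibition weight
is possible but warns, because it abandons the dominant-inhibition
convention.

## Least-action transition paths

Fluctuation-driven transitions between states are summarized by the most
probable path minimizing the Freidlin–Wentzell-type action with identity
diffusion, discretized on N equal steps of a duration-T path with a
trapezoidal drift average:

    S = (Δt/4) Σ_k Σ_i | (x_i^{k+1} − x_i^k)/Δt − (f_i^{k+1} + f_i^k)/2 |²

Endpoints are hard-clamped (the action is a boundary-value functional);
the (N−1)·G interior coordinates are optimized by L-BFGS-B with the
analytic gradient

    ∂S/∂x^m = (r^{m−1} − r^m)/2 − (Δt/4)·J(x^m)ᵀ(r^{m−1} + r^m)

starting from the straight line between the endpoints.  Defaults T = 10,
N = 100; the refinement check re-solves at (T, N) = (20, 200) and reports
both the action change and the time-rescaled pointwise path deviation.
Along the endocrine chain the maximum action change is ~3e−4, far below
the 0.01 convergence bound.  Downhill (flow-following) segments cost
essentially zero; uphill exits pay the quasi-potential barrier, and on the
1-gene self-activator the minimized 0 → saddle action matches the
closed-form quadrature barrier ∫(x − H(x))dx ≈ 0.0585.  Note that exact
monotonicity of the minimized action in N does not hold: the trapezoidal
functional at coarse N slightly under-counts the barrier (second-order
discretization bias), so refinement changes shrink as O(Δt²) rather than
one-sidedly.  The underlying stochastic decomposition (A-type SDE with
BBᵀ = 2εD, potential U, circulation Q, steady state ρ_ss ∝ exp(−U/ε)) is
the theoretical motivation and is documented in the module docstring but
not computed; only the D = I action above is evaluated.

## Single-cell matching

Expression matrices (genes × cells, raw counts or TPM) are shifted by a
pseudocount (Exp = value + 1), optionally log2-transformed (recorded in
output metadata), and binarized: a gene is "on" in a cell when its raw
value is ≥ 5 — an order of magnitude above typical off-state leakage and
below a typical expressed level, so the call is insensitive to the exact
cut (a detection cut of "≥ 1 count" is far too permissive for realistic
off-state leakage: with the default generator an off gene fires ≥ 1 count
in 36% of cells).  A per-gene quantile rule is available.  Cells are
assigned by exact equality of their binarized core-gene vector against the
catalog patterns; anything else is "unmatched" — deliberately conservative,
mirroring validation by exact expression patterns.  Exploratory grouping
uses average-linkage hierarchical clustering on 1 − Pearson r; cells with
constant profiles (undefined correlation) are placed at zero distance from
each other and distance 1 from everything else, with a warning.  t-SNE or
other embeddings are intentionally out of scope.

## Synthetic data generator

The generator emulates droplet scRNA-seq counts for cells pinned at
catalog patterns: per core gene, negative-binomial counts with mean 50
("on") or 0.5 ("off") and dispersion 2 (variance m + m²/2 — strong
overdispersion typical of raw droplet counts), dropout zeroing on-genes
with probability 0.1, and 50 background NB(0.5) genes so gene-resolution
code paths are exercised.  With 200 cells per state these defaults give
~75% exact-pattern recovery with every catalog state detected.  What the
generator does not emulate — library-size variation, batch effects,
ambient RNA, gene–gene correlation beyond the state pattern, realistic
transcriptome size — bounds what passing tests show: they validate the
assignment logic under calibrated noise, not performance on real GEO
datasets.  Toy fixtures (the 1-gene self-activator with bisection-oracle
roots {0, 1/2, ≈0.92}; a 2-gene self-activation + mutual-inhibition toggle
whose saddles sit on the axes at (0, 1/2) and (1/2, 0) — the shared-Hill
inhibition admits no off-origin diagonal equilibrium) carry their expected
dynamical properties as metadata.

## Problem sizes and determinism

All default problem sizes (6561 Newton starts, 200 limit-cycle starts,
N = 100–200 path points, 2200 synthetic cells) run in seconds to a couple
of minutes on one core; they are the analysis' own study conditions, with
randomness confined to explicitly seeded generators (grid search and
Boolean enumeration are fully deterministic).

## Known limitations

* Root finding is multistart Newton, not certified global root finding;
  completeness of the atlas rests on grid density (every on/half/off
  orthant) plus the cross-model Boolean agreement.
* Hyper-transition connectivity depends on the sampled directions within
  the unstable subspace and on perturbation amplitude; only the
  transition-mediated landscape is claimed stable.
* Lineage paths are solved per stage pair, not as one global path, so no
  claim is made about relative rates of multi-stage routes.
* Exact-pattern cell assignment has no tolerance for partially matching
  cells; real datasets would likely need the quantile binarization and a
  nearest-pattern relaxation.
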