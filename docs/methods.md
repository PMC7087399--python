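# Methods

This note documents the models implemented in `tandemloop`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish.

## Coarse-grained locus model

The chromatin fiber is a chain of fixed-width genomic bins (default 600 bp,
roughly three nucleosomes ≈ one 10 nm monomer). Genomic intervals are
0-based half-open; `ceil((end-start)/bin_bp)` bins tile the interval and a
short final bin is kept. Under this convention the reference human *Pcdh*
interval chr5:140160700–140920300 has length exactly 1266 × 600 bp and maps
to L = 1266 monomers.

**CTCF stalling.** A CBS with ChIP fold enrichment `x > 0` stalls an
opposing cohesin head with probability `T(x) = 1/(1+exp(-x/ζ-μ))`, ζ = 40,
μ = 4; a bin with no site (`x = 0`) never stalls. Orientation convention: a
*forward* CBS stalls heads translocating toward decreasing bin index, a
*reverse* CBS stalls heads moving toward increasing index, so a
forward…reverse pair is convergent and anchors a loop. A bin containing
sites in both orientations keeps two independent stall probabilities.
Multiple same-orientation sites in one bin combine into one effective
barrier via the array-permeability recursion below.

**Array permeability.** For sites `c_1..c_n` (distal→proximal) with pass
probabilities `p_i`, the mean number of attempts to clear the array obeys
`x_n = p_n x_{n-1} + (1-p_n)(1+x_n)` with `x_0 = 1`, giving
`x_n = Σ 1/p_i − n + 1` and overall permeability `1/x_n`. A Monte-Carlo
simulation of the retry process is kept as an independent cross-check in the
tests.

**Cohesin loading.** 80% of loading events are distributed proportionally to
NIPBL-like coverage per bin, 20% uniformly (`targeted_fraction`
configurable).

## 1D lattice loop extrusion

`⌊L/d⌋` two-headed cohesins occupy the lattice at mean separation `d`. Per
step: each cohesin drops off with probability `2/λ` (processivity `λ` = mean
extruded loop size; a replacement loads immediately from the loading
distribution, so the count is conserved), then every surviving head attempts
one outward step. An attempt fails if the target bin hosts another cohesin's
head, or — if the target bin carries an opposing barrier — with the bin's
stall probability, retried independently each step (geometric waiting,
consistent with the mean-attempt recursion). Design choices the source
material left open:

- drop-off/reload for all cohesins first, then head moves in a fresh random
  permutation of heads (removes index bias when two heads contend);
- freshly reloaded cohesins move only from the next step;
- fiber ends are reflecting; a periodic mode (unwrapped coordinates) exists
  for steady-state property tests;
- heads of one cohesin share a bin only at load time.

On a barrier-free fiber the stationary mean loop size equals `λ`
(memoryless lifetimes at rate `2/λ`, growth 2 bins/step); the test suite
verifies this within 10% at λ = 100, L = 1000, d = 500 over 10⁵ steps.

## 3D polymer dynamics

Reduced units: monomer mass (100 Da), diameter (1 nm) and k_BT (300 K) are
the units of mass, length and energy; the time unit is
`τ = (σ²m/k_BT)^{1/2}` ≈ 6.33 ps, making the dimensionless friction
`αγ = γτ ≈ 0.0633` at γ = 0.01 ps⁻¹. The chain lives in a periodic cube of
side `(L/ρ)^{1/3}` at density ρ = 0.2 (L = 1266 → 18.4984) and starts from
a boustrophedon self-avoiding walk on a unit cubic lattice (compact start),
with Maxwell–Boltzmann velocities.

**Force field.** Truncated purely repulsive pair term
`U = REPe·{1 + (r·REPrmin/REPsigma)^{12}[(r·REPrmin/REPsigma)² − 1]/REPemin}`
with REPe = 1.5, REPrmin = √(6/7), REPsigma = 1.05 and
REPemin = 6⁶/7⁷ = |min_{x>0} x¹²(x²−1)|; both the energy and the radial
force vanish at r = REPsigma, the natural truncation radius, and U ≡ 0
beyond. Harmonic bonds `k(r−d)²` connect backbone neighbours (k = 100,
d = 1) and the monomers currently hosting the two cohesin heads (k = 25,
d = 0.5; the bond is re-pointed, not re-equilibrated, when a head moves).
Bending stiffness `2(1−cos θ)` acts on consecutive bond-vector angles
(0 for a straight chain; chain ends carry no angle term). The repulsive
pair force is capped at 200 reduced units so overlaps from the lattice
start cannot blow up the integrator; the finite barrier also means chains
may cross — no topological constraint is imposed, intentionally. Pair
interactions use a cell linked list under the minimum-image convention.

**Integrator.** Langevin velocity Verlet:
`v += (Δt/2)f + b·dW₁`; `r += c·v`; `f = f(r)`;
`v = a·v + b·dW₂ + (Δt/2)f`, with `a = (2−αγΔt)/(2+αγΔt)` and
`c = 2Δt/(2+αγΔt)`. The kick amplitude is `b = √(αγΔt)`: with two
independent kicks per step this is the unique choice satisfying
fluctuation–dissipation, giving stationary velocity variance
`⟨v²⟩ = 1 + O(Δt²)` per component (verified against the discrete
Ornstein–Uhlenbeck recursion; an amplitude of `√(αγΔt/2)` would equilibrate
at exactly half the target temperature). With αγ = 0 the scheme reduces to
deterministic velocity Verlet; energy conservation of a harmonic dimer is
tested at O(Δt²).

**Time step.** The default is Δt = 0.05 reduced time units, comfortably
inside the stability limit of the stiffest mode (backbone bond, ω = √200,
stable for Δt < 0.14). Published step sizes for this class of model are
quoted in instrument-specific sub-units that do not map onto the reduced
system unambiguously; Δt is therefore an explicit configuration parameter.

**Interleaving and schedules.** A `Schedule` is
(1D-anneal steps, 3D-anneal blocks, MD steps per block, sampling blocks);
every block performs exactly one lattice extrusion step (re-pointing cohesin
bonds) followed by the block's MD steps, and one conformation is recorded
per sampling block. The full-scale reference schedule is 10⁶ / 2000 / 1250 /
50000. All tests and the acceptance script run reduced schedules (typically
2×10⁴ / 2000 / 40–100 / 400–20000 at L ≤ 401); these sample the same
stationary process at lower resolution. Thorough 3D annealing matters more
than long blocks: an under-annealed chain remembers the compact start, its
apparent contact decay keeps falling with genomic separation instead of
flattening to the periodic-box background, and loop-anchored signals drown.

## Contact maps and 4C rescaling

`p_ij` is the (weighted) fraction of sampled conformations with minimum-image
distance ≤ the capture radius ℂ (reduced units; 2 by default). Fragment-level
4C profiles are re-gridded to bins proportionally to overlap length.
Profiles from different viewpoints are not on a common scale; the model
`u_ij ≈ k_i s_ij^{-α}` is fitted by minimizing the geometric standard
deviation of `u_ij/(k_i s_ij^{-α})` — equivalently ordinary least squares of
`log u` on `−log s` with viewpoint offsets, `k_1 = 1` fixed — and `u_ij/k_i`
is returned. Zero-mean pairs are excluded. On noiseless power-law input the
recovery is exact; adding viewpoint scales can only reduce the GSD relative
to `k_i ≡ 1` (nested least squares).

## Relative maximum entropy

The loop-extrusion ensemble is the prior `P₀(q)`; the corrected distribution
`Q` is the one closest to `P₀` in KL divergence that reproduces target mean
contacts `ξ_ij = min(1, k·ū_ij + min(p_ij, p̂))`, where
`k = Σm²/Σūm, m = max(0, p−p̂)` maps frequencies to probabilities and the
median map entry `p̂` absorbs the high uniform background contact
probability induced by the small periodic box. Gaussian slack variables with
variance `σ²_ij = max(σ²_min, replicate variance of k·u_ij)` (σ²_min = 0.01;
with a single replicate σ² = σ²_min everywhere) prevent overfitting and make
the dual

`Γ(λ) = log Σₙ exp(−Σ λ_ij c_ij(qₙ)) − log N + Σ λ_ij ξ_ij + ½ Σ λ²_ij σ²_ij`

strictly convex (Hessian = reweighted contact covariance + diag σ² ≻ 0). It
is minimized by trust-region Newton with analytic gradient
`ξ − ⟨c⟩_λ + λσ²` and Hessian, log-sum-exp stabilized; at the optimum
`⟨c⟩_λ − λσ² = ξ` (the slack posterior mean is `−λσ²`) and Γ equals the
achieved relative entropy, which is why the mean converged Γ across capture
radii {2,3,4} ranks (processivity, separation) grid cells. Multipliers
fitted on one (wild-type) sample can reweight another (mutant) ensemble.
Conformation weights are `∝ exp(−Σλ_ij c_ij(q))`.

Trust-region specifics (start at λ = 0, gradient tolerance 1e-8, ≤ 500
iterations) are implementation choices; non-convergence is reported on the
result object, not raised.

## The gourd ("hulu") toy model

Four CBS (forward, forward, reverse, reverse) spaced 100 bins apart, stall
probability 0.97, loading 30× enriched between the inner convergent pair,
processivity = separation = 400 (one cohesin on the 401-bin fiber), capture
radius 2. Cohesins anchor at the inner pair, occasionally slip through
(pass probability 0.03 per step per site) and re-anchor at the outer pair,
so inner–inner and outer–outer contacts are enriched while mixed
inner–outer anchors never stabilize — two stacked loops sharing a waist.
Because an outer-anchored episode arises only ~once per 1500 lattice steps
and lasts ~15, resolving the outer–outer enrichment needs many sampled
blocks, not long blocks: the quantitative runs use 80000 conformations at
25 MD steps per block after 2000 annealing blocks (the interactive default
is 100 steps per block for better-decorrelated conformations). Enrichment
is measured observed-over-expected, where the expected level at each
genomic separation is the mean map entry over pairs away from any CBS;
this removes the distance-decay confound (the mismatched pairs are
genomically closer than the outer–outer pair) and credits the mismatched
windows with their genuine transit signal — the cohesin passes through the
mismatched geometry while sliding from the inner to the outer anchors,
which is why their enrichment sits near 1.5 rather than 1. The contact map
is converted to dissimilarities `d_ij = 1/h_ij` (zero-contact pairs get
10× the largest finite dissimilarity) and embedded by non-metric MDS.

**Non-metric MDS.** SMACOF-style alternation of isotonic regression of the
embedded distances on the dissimilarity order (ties pooled — Kruskal's
secondary approach) with a Guttman majorization update, minimizing
normalized stress-1 `√(Σ(d−d̂)²/Σd²)`; initialization is classical metric
MDS of the dissimilarities, which is exact for perfectly Euclidean input.
The stress trace is exposed and non-increasing.

## Allelic EM decomposition

A cell's observed expressed set R over G clustered genes is the union of two
independent draws S, T — one per chromosomal allele — from a common
distribution over subsets with |S| ≤ H (default H = 2; observations with
|R| > 2H are a model violation and raise). EM on the hidden counts
N_{S,T}: M-step `P(S) ∝ Σ_T N_{S,T}`; E-step `N_{S,T} ∝ P(S)P(T)`
constrained to total N_R within each observed union; initialized with the
uniform split `N_{S,T} = N_R/|pairs(R)|`. Convergence when
`max|ΔP| < 1e-9` (≤ 10⁴ iterations). The observed-data log-likelihood is
recorded each iteration and is non-decreasing (standard EM monotonicity,
asserted numerically). Support enumeration is `Σ_{k≤H} C(G,k)` subsets in a
fixed order (79 for G = 12, H = 2). EM fixed points on the probability
simplex boundary are possible; the deterministic uniform start is the
default and the likelihood trace is returned for diagnosis.

## 5C quality control

Pipeline order: depth-normalize each sample to 10⁶ total counts → Loess
distance-decay fit and Z scores → primer filtering → singleton removal →
BAC normalization → replicate-mean log2 ratio maps.

**Loess.** Local weighted polynomial (degree 2) at each point over the
`⌈span·n⌉` nearest predictors (span 0.01; widened with a log message when
the window cannot support the polynomial) with tricube weights
`(1−(|x−x̂|/d)³)³`. The local fits assemble into the smoother matrix L;
under homoscedastic Gaussian errors the residual covariance is
`σ²(I−L)(I−L)ᵀ` with `σ² ≈ εᵀε / tr[(I−L)(I−L)ᵀ]` estimated from **all**
residuals, and `SD_i` is the square root of the i-th diagonal entry.
Estimating σ² per local window instead would let any blowout inflate its
own variance estimate, capping attainable Z scores near √(window size) and
making a Z > 12 rule unsatisfiable — hence the global estimate.
`Z_i = (y_i − ĝ(x_i))/SD_i` (SD floored at 1e-12, logged).

**Primer filtering.** Per dataset, each primer's own Loess curve (same
degree, span 0.4 of its pairs) is compared to the global curve at the
primer's pair distances; the primer is flagged when the median ratio leaves
the symmetric band [0.85, 1/0.85]. Primers flagged in > 40% of datasets are
removed from all datasets. The aggregation statistic (median) and the
symmetric reading of the 0.85 band are configurable design choices.

**Singleton removal.** Entries with Z strictly greater than 12 are removed
one at a time (largest Z first), refitting after each removal: a dominant
blowout both inflates the global σ estimate (masking smaller singletons)
and makes the local quadratic ring around the spike (inflating neighbours'
Z). Iterating to a fixpoint removes exactly the planted singletons on
synthetic matrices; one-shot removal does not.

## Insulator Bayesian networks

Per promoter fragment `[s_i, t_i]` and condition: total enhancer strength
`E_i = Σ e_j` over contacted enhancer fragments, enhancer-weighted mean loop
strength `L_i = Σ e_j l_ij / E_i` and insulator strength
`U_i = Σ e_j u_ij / E_i`, where the CTCF signal `u_ij` counts only when the
margin-shrunk separating interval `[min(t_i,t_j)+a, max(s_i,s_j)−a]`
(a = 500 bp) is nonempty, else 0. Promoters with `E_i = 0` are excluded
(logged). Each variable is discretized per promoter by its rank across
conditions (1 = smallest; ties broken by condition order and flagged), so
each promoter-condition pair is one sample over four 3-state variables.

The structure score is the exact Dirichlet marginal likelihood with
hyperparameters from a uniform unit mass over joint states:
`α_ijk = Π_{v ∉ {i}∪Pa_i} r_v`, which makes every family's equivalent
sample size the total joint-state count (score-equivalent across Markov
classes; verified on reversed edges). Note this differs from the common
BDeu convention of a fixed user-chosen ESS. The structure prior is uniform.
Search is either exhaustive DAG enumeration (543 DAGs over four nodes;
refused above six) or MMHC: a score-based max-min parents-children filter
(a candidate neighbour must improve the family score against every subset
of the current candidate set, forward and backward, symmetrized) followed
by add/delete/reverse hill-climbing restricted to the candidate skeleton,
with per-family score caching. Hill-climbing scores are non-decreasing by
construction.

## Synthetic data and scope of the tests

Every generator is a pure function of (parameters, seed) and emits a
ground-truth record. Noise on count-like quantities is multiplicative
lognormal, matching the geometric-SD machinery. Defaults chosen once for
realism at desk scale: 4C decay exponent and scales user-set (noiseless
mode for exactness tests); 5C matrices 40×40 primers with irregular
(±25% jittered) spacing, decay exponent 0.5, GSD 1.05, singletons ×20;
expression tables with 3 conditions, 3 enhancers per promoter, GSD 1.1,
planted effects on the log scale.

What passing tests show: the algorithms recover planted structure under
their own generative assumptions at realistic sizes. What they do not show:
performance on real sequencing data with over-dispersion, mappability and
copy-number artefacts, heteroscedastic 5C noise at extreme dynamic range,
doublets/dropouts in single-cell data, or confounded genome-wide
enhancer–promoter tables. Polymer claims are verified at reduced ensemble
sizes (hundreds to 2×10⁴ conformations, L ≤ 401) rather than the
~1.3×10⁶-conformation production scale, and parameter-grid selection is
exercised on self-consistency rather than on experimental 4C data.

## Known limitations

- The extrusion lattice step has no absolute time calibration; processivity
  and separation are in bins, not minutes or kilobases per second.
- The repulsive force cap slightly softens near-overlap collisions
  (equilibrium statistics at ρ = 0.2 are unaffected in practice).
- MMHC's constraint phase uses the Bayesian score as its association
  measure rather than a frequentist independence test.
- `AlleleDistribution` EM is identifiable only up to the usual boundary
  fixed points; the multi-start option is manual (run with perturbed
  initial hidden counts).
- Loess assumes homoscedastic errors on the raw frequency scale; strongly
  heteroscedastic matrices should be variance-stabilized upstream.
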