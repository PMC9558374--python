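# Methods

This note records the models, conventions, and design choices behind
`cybospec`, in the order the pipeline runs them.

## Units and conventions

Lengths are Å, times ps, energies hartree, charges elementary. Coulomb
sums are evaluated in atomic units with a single Å→bohr factor
(1.8897259886) defined in `cybospec.units`; no other module converts
units. Coordinates are right-handed Cartesian and never wrapped: the
workflow is non-periodic by construction (a finite solvation sphere,
not a periodic cell). Exports use 6-decimal fixed-point floats, enough
for meV-level electrostatics at typical charge magnitudes.

## Solvation-sphere builder

The builder replicates a solvent unit cell (origin + three generally
non-orthogonal lattice vectors) until the replica block covers the
requested sphere. Coverage is established from the fractional
coordinates of the sphere's circumscribing-box corners, with one extra
replica of margin per axis — crude but provably sufficient, including
for strongly sheared cells, and verified in the tests by sampling 10⁴
points of the sphere against the instantiated replica boxes.

Carving keeps whole molecules whose **centroid** (unweighted mean of
atom positions) lies within r_max; the boundary is inclusive. Overlap
pruning is **atom-wise**, not centroid-wise: a solvent molecule is
deleted if any of its atoms lies strictly closer to any solute atom
than `overlap_scale × (r_a + r_b)` with Bondi van der Waals radii by
default (overridable per atom in the topology). A pair exactly at the
threshold survives; the strict inequality makes the boundary
deterministic. Virtual sites have zero radius and never trigger
deletion. The builder reports the solvent count and implied number
density rather than enforcing a target count: matching a specific
density is the user's choice of cell and radius.

## Structural analysis

RDFs in a finite sphere need a density estimate that avoids the
depletion bias near the rigid wall: ρ_B is taken from the partner sites
inside a concentric sub-sphere of radius `r_norm` (default: the full
analysis radius; a smaller fraction is advisable for boxes with strong
wall layering). g(r) is the frame-averaged pair histogram divided by
N_A·ρ_B·4πr²Δr, with 0.05 Å bins by default. Coordination numbers
integrate 4πρ_B g r² by trapezoid with endpoint interpolation at r_cut.
The first-shell boundary is located on a moving-average-smoothed curve
(5 bins, edge-padded so monotone input yields no spurious boundary
extremum); a curve with no local maximum raises an error rather than
silently returning an endpoint. The default coordination cutoff is the
**first minimum after the first peak**: integrating a narrow first peak
only up to its maximum would halve the physical shell population, so
"up to the first peak" is read as shorthand for the first-shell
boundary. Both cutoff choices are exposed.

The hydrogen-bond score is separable, f(R)·g(ϑ), with R the donor-H to
acceptor-O distance and ϑ the angle at the donor oxygen between its H
and the acceptor (0° for a linear bond). The radial factor is 1 up to
R₀ = 1.85 Å and decays as a Gaussian of scale σ_R·R₀ beyond it; σ_R =
0.20 is treated as a dimensionless fraction of R₀ (≈0.37 Å scale). The
angular factor is a Gaussian of width σ_ϑ = 10°. Scores below 10⁻⁴ are
returned as exactly zero. The empirical parameterisation fixes the
properties of the score — range [0, 1], maximal at (R ≤ R₀, ϑ = 0),
monotone decay, hard zero floor — but not a unique algebraic form; the
form above is the package's rendering and is implemented as a
swappable strategy so an alternative radial/angular profile can be
dropped in without API changes.

## Feature space and clustering

Per frame, the two solvent candidate atoms nearest the N–O bond
midpoint define A₁ and A₂, shared by all six distance features (N–A₁,
N–A₂, O–A₁, O–A₂, LP1–A₁, LP2–A₂). A shared anchor keeps the six
numbers geometrically coherent (they describe the same pair of
molecules); a per-site-nearest variant is available behind a flag.
Candidates default to solvent oxygens; solvent-specific candidate
lists are configurable. Distance ties break on the lower atom index.
Features are centred but **not** standardised before PCA — they are
all Å distances of comparable scale, and standardising would inflate
low-variance features. The smallest number of principal components
reaching the explained-variance target (default 90%) is kept.

PAM runs with Euclidean dissimilarity in the reduced space: greedy
BUILD followed by best-improvement SWAP until no single medoid
exchange lowers the total cost. Single-swap descent provably has
spurious local optima even at n = 10, k = 3, so `pam()` restarts SWAP
from the BUILD solution plus four seeded random initialisations and
keeps the best local optimum; the procedure is deterministic given the
seed and, on every enumerable instance in the test suite, reaches the
exhaustive optimum. k is selected over a scanned range by vote:
Silhouette, Dunn, and Calinski–Harabasz each vote their argmax; WSS
votes the interior k maximising the discrete second forward difference
WSS(k−1) − 2WSS(k) + WSS(k+1) (the sharpest slope break). Three votes
elect a k; otherwise the smallest k among the modal vote count is
returned with a low-confidence flag. Silhouette scores singleton
clusters as 0.

## Representative frames and collective frames

The total representative-frame budget is a user parameter (default ≈5%
of the clustered frames). It is apportioned across clusters by
largest-remainder (Hamilton) allocation — exactly proportional floors,
leftovers to the largest fractional remainders, ties to the larger
cluster then the lower index, every cluster guaranteed one frame.

Within a cluster, GRASP minimises J(S) = ‖mean_{f∈S} φ(f) − mean
cluster φ‖² over subsets of the prescribed size, with φ the reduced
feature vector (an electrostatic-potential φ is a config option). Each
restart draws construction steps uniformly from the restricted
candidate list of the best ⌈α·remaining⌉ candidates (α = 0.3 default,
α = 0 collapses to pure greedy), then applies swap local search:
best-improvement single exchanges, plus one bounded 2-exchange pass
when single swaps are exhausted, because some optima are not reachable
one swap at a time. Fifty restarts by default, one spawned RNG stream
per restart, fully reproducible.

A collective frame concatenates the solvent atoms of the N selected
frames with charges q/N and the rigid solute taken once from the
cluster medoid. By linearity of the Coulomb sum its potential at any
point equals the arithmetic mean of the per-frame potentials — an
exact algebraic identity, tested to 1e-10 relative on random
instances — so one embedding computation stands in for N.

## Perturbed Matrix Method

The perturbed Hamiltonian in the basis of the n reference eigenstates
(default 11) is H̃_ij = E_i δ_ij + Σ_a q_a^ij ΔV_a, a first-order
atom-site expansion in which atomic transition charges couple states
through the difference ΔV between the current and reference solvent
potentials at the solute atoms. Higher multipole terms are deliberately
omitted; the builder is the extension point if they are ever needed.
Exact symmetrisation guards against accumulation of rounding in the
einsum. Diagonalisation uses `eigh`; excitation energies are
differences of sorted eigenvalues, with no state tracking across
frames (sorting is deterministic; diabatization is out of scope).
Perturbed transition dipoles are the eigenvector rotation of the
reference dipole matrix; dipole blocks not supplied by the reference
computation (typically excited–excited couplings) default to zero,
which affects intensities but not band positions. Oscillator strengths
are f_k = (2/3)ΔE_k|μ̃_0k|² in atomic units.

Sticks are broadened with Gaussians of HWHM 600 cm⁻¹ on the wavenumber
axis, each normalised so its integrated molar absorptivity is
f/4.319×10⁻⁹ M⁻¹cm⁻² (the standard band-area convention), evaluated on
a 200–800 nm grid at 0.1 nm. Per-cluster spectra average point-wise
with the cluster populations. A potential-site within 0.1 Å of a solute
atom raises a singularity error naming the pair.

## Shift-table composition

Per cluster, Total = λ_cf + (λ_+2QM − λ_0QM) + (λ_vib − λ_PMM): the
collective-frame maximum, corrected by the explicit-QM-solvent effect
evaluated at the centroid and by the vibronic displacement. The
externally computed inputs (centroid band positions with and without
QM solvent molecules, vibronic positions) enter through the config's
shift-table block. Arithmetic runs at full precision; rounding to
0.1 nm happens only at reporting, so aggregates computed from rounded
published rows can differ from the package's full-precision aggregates
by ~0.1–0.3 nm — the tests assert only arithmetically consistent
cells. Per-solvent averages are population-weighted; shifts are taken
against a user-named reference solvent.

## Synthetic fixtures

The trajectory generator emulates the one physical signal the analysis
stack consumes: distinct solvation regimes of a rigid solute. Frames
are split into contiguous blocks per regime (mimicking dwell episodes);
each regime places 0–2 donor molecules with exact (R, ϑ) hydrogen-bond
geometry sampled from tight truncated Gaussians (R = 1.85 ± 0.02 Å,
ϑ half-normal with 2° scale — tight enough that planted bonds score
F_HB ≈ 1, so the planted bond count is recoverable), and fills the rest
of a 12 Å sphere with uniformly placed bulk molecules at ≥2 Å
separation. It does **not** emulate force-field energetics, solvent
structure beyond the planted shell, polarisation, or exchange dynamics
— passing tests demonstrate the analysis machinery recovers planted
structure, not that any force field is accurate. The QM-reference
generator emits ascending energies with a ~0.1 hartree first gap (a
visible band), symmetric transition charges with the diagonal sum rule
enforced exactly, and random ground-state transition dipoles. The cell
generator packs rigid molecules by rejection at a target mass density;
at real-water density the minimum atom–atom distance is capped at
2.0 Å, the tightest constraint random (non-equilibrated) packing can
satisfy there. All generators are pure functions of their seed.

## Lone-pair virtual sites

The two lone-pair sites on the nitroxide oxygen are generated from the
N–O geometry: at a configurable distance (default 0.3 Å) from O, in
the plane bisecting the C–N–C framework, symmetric about the N–O axis
at a configurable half-angle (default 45°). These values are exposed in
the config and asserted nowhere: the published force-field geometry
behind them is not restated in the sources this package follows.

## Problem sizes

Default test and example sizes — 90–120 frame trajectories, ~15
solvent molecules, 11-state references, 0.5 nm spectral grids in the
pipeline smoke tests — are chosen so the whole suite runs in well
under a minute on one core while every check retains its statistical
power (Poisson RDF bounds, ±0.1 tolerances on planted counts, exact
enumeration oracles at n ≤ 12).

## Known limitations

* The PMM expansion is first-order in atomic transition charges; no
  multipole or polarisation corrections.
* No state tracking through near-degeneracies across frames.
* The GRASP budget is a user choice; no stopping rule infers it.
* The RDF normalisation assumes approximate homogeneity inside
  `r_norm`; strongly structured small boxes bias ρ_B.
* The f_hb algebraic form is one concrete realisation of the stated
  empirical behaviour (see above).
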