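# Methods

Model formulation, parameter choices and numerical methods behind
`angiomesh`, including known behaviours and deviations. Units throughout:
lengths mm, time s, pressure mmHg, viscosity mPa·s, flows mm³/s; stresses
reported in dyn/cm² (1 mmHg = 1333.22 dyn/cm²).

## 1. VEGF diffusion (meshless RPIM)

The steady VEGF field Φ solves

    Dx Φ_xx + Dy Φ_yy − g Φ + Q = 0

on the rectangular region of interest, with a volumetric release rate Q
over the hydrogel disk and essential (Dirichlet) boundary conditions on
configured edges. The Radial Point Interpolation Method builds shape
functions per query point from the multiquadric basis

    r_i(x) = ((x_i − x)² + (y_i − y)² + c²)^p

over the influence domain (the `n_influence` nearest nodes, distance ties
broken by lowest node index), augmented with a constant polynomial term so
the interpolant has the delta property and partition of unity. The weak
form is integrated on a fixed background mesh of quadrilateral cells with
tensor-product Gauss–Legendre rules; essential BCs are imposed by
row/column elimination.

| Parameter | Default | Notes |
|---|---|---|
| c (shape) | 1e-4 mm | absolute length; small c keeps the basis near piecewise-distance |
| p (exponent) | 0.9999 | near-linear multiquadric, standard for this solver family |
| n_influence | 16 | nearest nodes per influence domain |
| gauss_order | 2 | points per cell axis (2×2 per cell) |
| D (VEGF) | 1.16e-6 mm²/s | hydrogel-released VEGF diffusivity |
| Q (release) | 5.0e-4 (source units)/mm³ | volumetric release over the disk |

Verification: on the unit square with D = 1, uniform source R = 1 and
zero BCs on the left/right edges, the exact solution is the strip parabola
φ(x) = x(1 − x)/2 (max R·L²/8D = 0.125). Measured max nodal errors over
spacings 0.2 / 0.1 / 0.05 / 0.025 are 2.7e-3 / 8.2e-4 / 3.1e-4 / 1.6e-4 —
monotone convergence, 0.25 % of the solution maximum at spacing 0.05.

During growth, sprout nodes are appended to the node cloud (deduplicated
against existing nodes at 5 % of the lattice spacing to protect moment-
matrix conditioning). A shape-function cache re-evaluates only the
integration points whose influence domain can change — a point is stale
only if a new node lands closer than its current farthest influence node —
making the per-iteration re-assembly incremental; the cached assembly is
tested bit-comparable against a fresh one.

## 2. Sprouting growth

One iteration represents ≈ 6.7 h. Per iteration each active tip cell:

1. **Migrates** one step along the unit VEGF gradient rotated by a
   perturbation θ ~ U(−0.24, 0.24) rad. The step length is the distance
   between the tip's current and previous positions (bootstrapped by one
   endothelial cell length, 0.05 mm, on the first step). A landing point
   within the snap tolerance (0.025 mm) of an existing node adopts that
   node; zero gradient falls back to the previous direction; stepping
   outside the domain deactivates the tip.
2. **May branch** once the distance travelled since its last branch
   exceeds d(O) = 0.9286·exp(−0.219·O) mm for capillary order O (1 =
   highest calibre). The daughter takes order O+1 (capped at 3, in which
   case the same-order angle law applies) and its first segment is laid
   along the sampled branch direction, so junction geometry carries the
   sampled angle. Branch angles are drawn from CAM-calibrated normals —
   mean 68° between same-order capillaries (observed range 45–127°), mean
   86° across orders (range 44–117°) — with σ set so the nearer range
   extreme is 3σ from the mean, clipped to the range; the sampler recovers
   the calibration means within sampling error (tested at n = 500).
3. **May anastomose**: a tip within 0.025 mm of a node or segment not in
   its own recent trail (its last two segments and their nodes) connects
   there and deactivates; segment-interior hits split the segment at the
   projection. Head-on tip meetings deactivate both. A tip must have laid
   ≥ 2 own segments before it may fuse ("maturation"), preventing
   re-fusion with the structure it just left.

The merge radius equals the snap tolerance (half an EC length) rather
than a full EC length deliberately: migration is purely gradient-driven
with no momentum term, so a newborn daughter runs parallel to its parent
trail at a lateral offset of sin(86°)·0.05 ≈ 0.0499 mm; a merge radius of
0.05 mm would re-fuse every daughter into its own tree within two steps.

## 3. Hemodynamics

Poiseuille's law per segment, Q = g·ΔP with conductance
g = πD⁴/(128 μL) (converted so mm/mPa·s/mmHg inputs give mm³/s), and
nodal conservation ΣQ = 0 at interior nodes close the linear system — a
weighted graph Laplacian with Dirichlet pressures (artery 45 mmHg, vein
22 mmHg) at tagged parent terminals. Blood viscosity μ = 3.5 mPa·s
(Newtonian; no Fåhræus–Lindqvist correction). Solvers: SOR (ω = 1.5,
relative residual < 1e-8) and a direct sparse factorisation used as an
independent oracle and as the fast path during adaptation; they agree to
< 1e-6 relative. Dead ends naturally carry zero flow. Wall shear stress
τ_w = 32μ|Q|/(πD³).

## 4. Structural adaptation

Per round, with all logs base 10:

    S_τ = log(τ_w + τ_ref)                          shear stimulus
    τ_e(P) = 100 − 86·exp(−5000·(log log P)^5.4)    set-point stress
    S_p = −log(τ_e)                                 pressure stimulus
    S_m = log(Q_ref/(Q_b·H) + 1)                    metabolic stimulus
    ΔD  = [S_τ − k_p·log τ_e + k_m·S_m − k_s]·D·Δt

with the flow re-solved after every round until the maximum relative
applied diameter change falls below `conv_tol`. Q_ref is the largest
segment flow in the network, recomputed every round. Parent-vessel
diameters are frozen; free diameters are clamped to [d_min, d_max].
Segment pressure for τ_e is the mean of the two node pressures, floored
at 10.5 mmHg so the nested log stays defined. Zero segment flow is capped
at 1e-6·Q_ref in S_m.

| Parameter | Default | Parameter | Default |
|---|---|---|---|
| τ_ref | 7.73e-5 mmHg | Δt | 0.1 (dimensionless) |
| k_p | 0.68 | d_min | 0.004 mm |
| k_m | 0.7 | d_max | 0.25 mm |
| k_s | 1.72 | conv_tol | 1e-4 |
| H | 0.45 | max_rounds | 5000 |

**Stimulus stress scale.** S_τ and the τ_e comparison are evaluated with
stresses in dyn/cm² — the scale on which this stimulus formulation and
its constants were originally calibrated (Pries et al., Am J Physiol
1998) — with τ_ref converted from mmHg internally (0.103 dyn/cm²). On a
mmHg scale the same constants would place the wall-shear equilibrium of
the update law at τ_w ≈ 280 mmHg, i.e. diameters near 0.1 m, leaving no
interior fixed point between the clamps.

**Fixed point and stability.** On a 4-segment loop fed through frozen
parent segments, the iteration converges (69–100 rounds from starting
diameters 0.02–0.2 mm) to an interior equilibrium D ≈ 0.16–0.17 mm with
|update bracket| < 1e-3, locally stable under ±10 % single-segment
perturbations. The parent feed resistance is what stabilises the loop: a
free loop directly between two fixed-pressure nodes has τ_w ∝ D and is
structurally unstable — the expected Pries-model behaviour for a single
vessel between pressure clamps.

**Known behaviour: unperfused dead ends dilate.** A dead-end segment has
Q = 0, so S_τ = log(τ_ref) ≈ −0.99 (dyn/cm² scale) while the capped
metabolic stimulus is large (k_m·S_m ≈ 4.5 at the 1e-6 flow floor); the
bracket is positive and the segment grows to d_max. Biologically,
unperfused sprouts regress; this formulation has no pruning term (removal
of vessels from the graph is out of scope), so the artifact is accepted
and documented. It inflates post-adaptation area fractions of tree-like
(unperfused) networks.

**Known deviation: perfused-loop wall shear exceeds 13 dyn/cm².** The
targeted upper range for neo-vessel wall shear after remodelling is
≤ 13 dyn/cm². On the default synthetic scenario the perfused loops
converge to 16–24 dyn/cm² (seeds 0–7). This is the exact interior
equilibrium of the update law, log τ_w = k_p·log τ_e − k_m·S_m + k_s:
the loops hang off the *arterial* half of the single parent vessel at
~37 mmHg, giving τ_e ≈ 59 and (with S_m ≈ 2.3) an equilibrium
τ_w ≈ 20 dyn/cm² — verified to three significant figures against the
converged state. Networks whose neo-vessels sit at lower, venous-side
pressures (τ_e(20 mmHg) ≈ 17) would equilibrate near 9 dyn/cm², inside
the target range; the single-parent desk-scale scenario simply does not
produce such low-pressure loops. The corresponding acceptance test is
left honestly failing rather than re-tuning the scenario toward the
bound. Seeds whose anastomoses are all intra-tree have *no* perfused
neo-vessels at 30 iterations; their maximum neo τ_w is ~0 and the bound
holds trivially.

## 5. Quantification

- **Volume fraction** (2D projected area fraction, matching image-based
  quantification of assay photographs): per patch of the 5 × 5 grid,
  Σ(clipped segment length × diameter)/patch area, with Liang–Barsky
  clipping and half-open interior patch boundaries so gridline segments
  are counted once. The patch decomposition is exact: the grid mean
  equals the whole-ROI computation to 1e-9.
- **Branch angles**: recorded branching events are used when present
  (exact sampled angles); otherwise angles are reconstructed
  geometrically at junctions of degree ≥ 3 (the lowest-generation
  incident segment is the parent; the straightest same-order outgoing
  segment is its continuation and is excluded).
- **Stress summaries**: min/max/quantiles of τ_w, τ_e and the total
  effective stress τ_T = (τ_w + τ_ref)/τ_e^{k_p} — the exponentiated net
  hemodynamic stimulus 10^(S_τ + k_p·S_p); the definition is isolated in
  one function (`quantify.total_effective_stress`) so it can be swapped.

## 6. Synthetic scenario generator

`generate_cam_like_scenario(seed)` emulates the assay geometry: 5 × 5 mm
ROI, 8 mm-diameter hydrogel disk centred on a corner (default
lower-left), a straight parent vessel along the opposite edge with
diameter ~ U(0.17, 0.2) mm (artery at the left end, vein at the right),
zero-concentration VEGF BC along the parent edge, and 3–6 initial tips.
Tips are placed as a dense cluster on the stretch of vessel facing the
hydrogel (first tip at x ~ U(0.8, 1.8) mm, neighbour gaps
~ U(0.1, 0.3) mm), reflecting that sprouting localises where VEGF is
highest with neighbouring sprouts a few cell lengths apart. Tips spread
evenly along the whole vessel (~1 mm apart) produce near-parallel sprout
trees for which inter-tree anastomosis is geometrically unreachable
within 30 iterations (~1.5 mm of travel); whether loops form within 30
iterations remains seed-dependent even with clustering.

All randomness derives from the single scenario seed through named
substreams (`scenario`, `migration`, `branching`), so adding draws to one
stage does not perturb the others and fixed-seed runs are bit-identical
end to end (hashes of the canonical edge tables are compared in tests).

## 7. Problem sizes and runtimes (one CPU)

Default scenario: 41 × 41 lattice (1681 nodes, + ≤ ~350 sprout nodes),
40 × 40 background cells × 4 Gauss points; 30 growth iterations ≈ 10–20 s;
direct flow solve < 10 ms; adaptation to convergence (~80 rounds with
warm-started direct solves) ≈ 2–5 s. The full test suite runs in ~30 s.
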