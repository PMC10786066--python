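# Methods

`transmech` re-implements, on synthetic data with known ground truth, the
computational machinery used to characterize alternating-access transport in
a 12-TM-helix membrane transporter of the LeuT fold (the NKCC1
Na⁺–K⁺–2Cl⁻ cotransporter is the motivating system): discriminant
collective-variable (CV) design from interhelical distances, coordination
CVs through a rational switching function, OPES-Explore enhanced sampling
with free-energy reweighting, helix-geometry mechanism metrics, water-wire
permeability and flux counting, pore profiling, and basin/barrier/binding
analysis of free-energy surfaces. This note records the models, the defaults
and why, the numerical choices, and what the synthetic conditions do and do
not establish about real trajectories.

## Synthetic study conditions

Real μs-scale trajectories of the transporter are not publicly available, so
every pipeline input is generated in-package with planted ground truth.

**Two-state helix bundle.** Twelve ideal helices (28 residues, 1.5 Å rise
per residue) stand on an 18 Å circle with the membrane normal along +Z and
the extracellular side at +Z. Each residue carries four backbone
pseudo-atoms (N, CA, C, O) placed antisymmetrically within 1 Å of the ideal
Cα trace so that every residue's backbone center of mass coincides exactly
with the trace — this makes the COM-based angle metrics exact on noiseless
data. Helices are arranged with the mobile pair (TM4/TM9) adjacent on one
side and the static scaffold (TM1/TM2/TM6/TM7) across the bundle, as in the
inverted-repeat fold; this also keeps the angle reference arm (mobile
intracellular COM → scaffold intracellular COM) long (~35 Å), so the bundle
angle is well conditioned. State B rotates the mobile pair rigidly by the
planted angle (default 14°, the rocking-bundle motion) about an axis through
the intracellular tip COM of the pair, perpendicular to the plane spanned by
the bundle axis and the anchor direction. Because a COM is
affine-equivariant, that pivot is exactly invariant and the measured bundle
angle changes by exactly the planted rotation. The kinked helix (TM10)
changes its intrahelical angle between planted values (defaults 151.2° in
the inward-open state, 169.2° in the outward-open state, the corking
motion); it bends radially outward so intermediate kink angles cannot
collide with ring neighbors. Per-frame Gaussian coordinate noise (default
0.3 Å in the noisy ensembles) stands in for thermal fluctuation. The
generator refuses rotations that bring distinct helices within 2 Å.

**Water slab.** Water oxygens random-walk (0.5 Å/frame/coordinate) in a box
spanning the membrane slab (leaflet planes at ±15 Å). Decoys are reflected
at the walls of their own compartment (below the inner leaflet, between
leaflets, above the outer leaflet) and therefore can never complete an
ordered three-plane crossing; only scripted waters traverse, on linear z
paths over a stated frame window. Ground-truth crossing times are computed
in closed form from the linear path (first frame strictly past each plane),
independently of the scanning event tracker — recovering the scripted list
exactly is therefore a genuine dual-route check. For permeability studies a
denser slab near the percolation threshold (700 waters in a 24 Å box) is
used, where wires form intermittently and episode lifetimes are meaningful.

**Distance feature ensembles.** Two-state Gaussian ensembles of 90 pair
distances, 5,000 frames per state, σ = 0.5 Å. Five planted informative pairs
switch between a contact mean (8 Å) and a non-contact mean (12 Å) across
states, alternating direction so both contact polarities are exercised;
the rest sit at a state-independent 11 Å.

**Langevin toys.** Overdamped Euler–Maruyama dynamics,
x ← x − (dt/γ)∂(U+V) + √(2kT·dt/γ)ξ, on analytic potentials (flat with
reflecting walls, harmonic, 1-D/2-D double well h(x²−1)² + tilt·x). The
scheme is the simplest correct choice at toy scale; stability requires
dt·U″/γ ≪ 1 and divergence raises rather than silently corrupting. kT
defaults to 310 K (0.6160 kcal/mol).

What passing these tests shows — and does not. Exact recovery on planted
data validates the estimators (angle definitions, event logic, filter
algebra, reweighting identities), not the biology: the generators have no
force field, no lipids, no hydrogen-bond geometry, Gaussian rather than
correlated noise, and scripted rather than diffusive permeation. Published
trajectory-scale numbers for the real transporter (transition counts, flux
totals, kcal/mol barriers) are out of reach at this scale and are not
asserted anywhere.

## Conformational CV

All Cα–Cα pairs across distinct helices are cataloged (intra-helix pairs
flagged and dropped by the filter's first stage). The three-stage filter
then (2) keeps pairs from adjacent helices — adjacency is not uniquely
defined by helix numbering, so the default is spatial (helix pairs whose
minimum mean Cα distance is below 12 Å in either state), with
sequence-adjacent and all-interhelix selectable; (3) keeps pairs whose mean
distance is below the 10 Å contact cutoff in exactly one state; (4) drops
pairs whose state means lie within 2 standard deviations of each other,
using max(SD_A, SD_B) by default (pooled and min selectable, since the SD
convention is a genuinely open choice).

The discriminant is a Fisher linear discriminant:
w ∝ (S_w + εI)⁻¹(μ_B − μ_A) with pooled within-class covariance S_w and
ridge ε = 10⁻⁶·tr(S_w)/d for numerical stability. An exact affine map then
places the projected training-state means at −2.6 (inward open) and +2.6
(outward open). A nonlinear (neural feature map) variant would require an
optional torch dependency and is not built; the linear discriminant is the
reference mode. Near-identical state distributions yield a separation
statistic ≈ 0 and a warning instead of a meaningless normalization.

## Coordination CVs and OPES-Explore

The rational switching function s(r) = (1 − xⁿ)/(1 − xᵐ) with
x = max(r − d₀, 0)/r₀ maps a distance smoothly onto [0, 1]; the removable
singularity at x = 1 evaluates to n/m. Vestibule-water coordination uses
r₀ = 8.0 Å, d₀ = 0, n = 2, m = 8 (the water-flushing CV); ion-site
coordination uses the same form with r₀ = 2.35 Å. A coordination CV is the
sum of s over partner distances to a virtual center.

The bias engine implements the Explore flavor of on-the-fly probability
enhanced sampling: a Gaussian kernel is deposited on the *sampled* (biased)
marginal every `stride` steps (defaults: barrier ΔE = 20 kcal/mol, stride
500, 310 K, initial σ 0.1/0.3 and minimum σ 0.05/0.15 per CV, bias factor
γ = ΔE/kT). The bias is

V(s) = (γ−1)·kT·[ln(p̃(s)/Z + ε̃) − ln ε̃],  ε̃ = exp(−ΔE/((γ−1)kT)),

with Z the running mean of the kernel density at the deposited centers
(maintained incrementally in O(n) per kernel), shifted so V = 0 in
unexplored regions and clipped at ΔE, so the bias range never exceeds the
barrier parameter by construction. Kernel bandwidths shrink adaptively as
sampled-SD/√n, floored at the minimum σ. Two deliberate simplifications at
toy scale: no kernel compression/merging (kernel counts stay ≤ ~10⁴), and
during integration the bias force comes from a cached grid (501 points,
linear interpolation, with each new kernel's density added incrementally)
rather than the exact kernel sum — the exact sum remains the public evaluation path, and
reweighting uses the bias actually applied, so the free-energy estimate is
consistent with the dynamics regardless of these shortcuts.

Free energies are recovered by reweighting, F(z) = −kT ln Σ_t w_t K(z−s_t)
with w_t ∝ exp(V_t/kT), min-normalized to 0. K is histogram binning at the
grid resolution by default (which makes zero-bias reweighting identical to
Boltzmann inversion) or a Gaussian kernel of user-set width; the first 20%
of samples are discarded by default in the drivers to drop the bias
build-up transient. On the 5 kcal/mol double well, a 2×10⁶-step biased run
recovers the barrier within 0.5 kcal/mol and well-to-well symmetry within
0.3 kcal/mol.

## Geometry metrics

The bundle angle α is measured at vertex B between B→A and B→C (A/B the
mobile pair's extracellular/intracellular backbone-tip COMs, C the scaffold
anchor's intracellular tip COM; tips are the 4 terminal residues of each
helix end — the tip window size is a package choice). The source material
lists the three COM points but not the vertex; placing it at the mobile
intracellular COM reads the motion as rotation about the bundle's
intracellular pivot, and is exposed as a flag rather than asserted as the
only reading. The intrahelical angle θ is measured at the bend-window COM
between the arms to the two tip COMs (180° = straight).

The elevator test reports the state-mean change of the mobile bundle's
Z offset against the static-domain COM. The default observable tracks the
bundle's intracellular-tip (pivot) COM rather than the whole-helix COM: a
rigid 14° tilt of a 40 Å helix lowers its whole-helix COM by ~0.5 Å purely
through cosine foreshortening, which is not an elevator signal, while the
pivot is exactly invariant under rocking and translates one-for-one under a
genuine elevator displacement; `mode="full"` restores the whole-COM variant.
The verdict rule uses thresholds of 5° and 2 Å (package defaults — the
contrast is reported qualitatively in the source material): rocking-bundle
iff Δα ≥ 5° and |Δz| < 2 Å, elevator iff the reverse, mixed when both
exceed, indeterminate otherwise.

Superposition uses least-squares rigid fitting (SVD-based, via
scipy's rotation alignment) with RMSD scored on an optional separate
selection; sample SD (n−1) is used everywhere a spread is reported.

## Water analysis

A frame is permeable when the O–O distance graph (cutoff 4.0 Å) connects
the extracellular and intracellular bulk. Bulk waters (beyond the leaflet
planes) are collapsed into two terminal super-nodes; an in-slab water joins
a terminal when it is within the cutoff of any bulk water. Wire size is the
number of waters on one shortest terminal-to-terminal path (BFS). An
optional cylindrical mask restricts wire nodes to the channel. Permeable
episodes are maximal runs of consecutive permeable frames; lifetimes are
run length × frame interval.

Flux events are counted per water by a finite-state machine over the
ordered crossings of the inner-leaflet, midplane and outer-leaflet planes
(midplane = arithmetic mean of the leaflet planes unless configured).
A water that left one bulk completes an event on reaching the other bulk;
dips back toward — but not into — the origin bulk keep the first-plane
crossing (most recent consistent prefix, the default strict reading), while
re-entering the origin bulk resets progress; a lenient mode additionally
resets on any backward plane crossing. Crossings are stamped at the first
frame observed on the far side of a plane; under time reversal, events map
efflux↔influx exactly in identity and direction and within one frame
interval in their endpoints (the stamp is one-sided). Waters jumping more
than half the box per frame are excluded with a warning. Trapped waters are
cavity-region waters not connected to either terminal in the same O–O graph.

## Pore profile

For each Z slice the profile reports the largest sphere centered in that
plane that overlaps no atom (min over atoms of center distance minus van
der Waals radius, Bondi set by element, overridable), maximized over
in-plane centers within 8 Å of the running axis. The per-slice search
refines the previous slice's optimum by Nelder–Mead first and accepts a
coarse-grid seed only when strictly better — off-axis clearance ties (e.g.
mirror positions outside a ring of atoms) must not hijack the axis. Radii
at or above the 10 Å cap are flagged bulk. This is a simplified variant of
the classic sphere-fitting profilers (no Monte-Carlo sphere walk, no curved
axes), adequate for near-axial channels.

## FES analysis

Basins are found by persistence flood fill: grid points are visited in
ascending free energy, components grow and merge, and a component whose
depth at its first-contact saddle is below `min_depth` (default
1.0 kcal/mol) is absorbed. Inter-basin barriers are minimax path heights
(the lowest level at which two basin minima join, computed by sorted-edge
union-find over the grid graph), reported per direction relative to each
basin floor — a reading of a 2-D FES, not a rate theory. Region free
energies use the log-sum-exp over member points
(−kT ln Σ exp(−F/kT)) rather than bare minima, so binding ΔG =
F_bound − F_unbound accounts for basin width; the binding barrier is the
minimax saddle measured from the unbound floor. All results are invariant
under adding a constant to F (grids are min-normalized on construction).

## Problem sizes in the shipped runs

The drivers and the reproduction script use: 1,000-frame two-state bundles
(500/state, 0.3 Å noise); 90 × 2 × 5,000 feature ensembles; a 2,050-water,
5,000-frame flux slab with 50 scripted events; 500 random 300-water frames
for wire/oracle agreement; 2×10⁶ Langevin steps (dt 0.002) for the OPES
double-well runs; 0.5 Å pore z-steps. These sizes give exact or
3-SEM-bounded recovery for every planted quantity while keeping a full
reproduction run in the minutes range on one CPU.

## Known limitations

* The OPES engine targets toy CV spaces (1-D/2-D, ≤ ~10⁴ kernels); it is
  not coupled to an MD engine and omits kernel merging and multi-walker
  support.
* The flux tracker assumes pre-imaged, continuous water paths; periodic
  re-imaging is a documented precondition, not performed.
* The pore profiler assumes a near-axial channel; strongly curved pores
  would need a curved-axis search it does not implement.
* Helix annotations come from configuration; there is no secondary-structure
  detection.
* The elevator/rocking verdict is a threshold rule on two scalars; real
  mechanisms mixing rotation with translation report as "mixed" and need
  inspection.
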