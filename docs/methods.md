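# Methods

This note documents the models implemented in `rootrace`, their
assumptions, the parameters that matter, and what the synthetic test
conditions do and do not show about real data.

## Coordinate and unit conventions

Right-handed coordinates with the z axis vertical: the soil surface is
at z = 0 and depths are negative. Voxel index (i, j, k) maps to the
physical center `origin + (i·dx, j·dy, −k·dz)`, i.e. the slice index
grows downward, matching how axial slice stacks of a soil column are
ordered. Lengths are millimetres internally; reported traits use the
conventional units (RL in cm, RLD in cm cm⁻³, r_mean in mm). Hydraulic
potentials are in hPa; since 1 hPa ≈ 1 cm of water column, the
equivalent conductance Q/Δψ in cm³ d⁻¹ hPa⁻¹ is reported under the
conventional label cm² d⁻¹.

## Volume extraction with gap bridging

**Cost model.** For voxels at or above the minimum intensity (default
30% of the image maximum, the standard starting threshold for segmented
root images), the traversal cost is a convex blend of two pieces of
root evidence: normalized intensity Î = I/I_max and the normalized
Euclidean distance transform D̂ of the supra-threshold mask (a local
tube-radius proxy — tube axes score high):

    cost(v) = 1 − (w_I·Î(v) + w_R·D̂(v)),    defaults w_I = 0.7, w_R = 0.3.

Sub-threshold ("gap") voxels get a constant elevated cost c_gap = 2,
giving the enhanced gap/no-gap contrast the bridging search needs.

**Search.** Edges join 26-neighbors and are weighted by
`((cost(u)+cost(v))/2 + ε)·‖u−v‖` with physical edge lengths (the
anisotropic slice spacing makes index-space metrics wrong) and
ε = 0.01 so zero-cost plateaus still prefer short paths. A
label-setting Dijkstra over states (voxel, current gap-run length)
extracts every voxel reachable under two constraints: cumulative cost
≤ T_path, and every consecutive run of gap voxels ≤ L_gap (entering a
gap voxel adds the edge length to the run; any supra-threshold voxel
resets it to zero). Dominance pruning keeps only labels whose gap run
is strictly smaller than every run already settled at that voxel —
correct because labels pop in increasing cost. Gap voxels enter the
output only when they lie on the optimal path of an accepted
supra-threshold voxel, so the result is the shoot-connected volume with
gaps bridged and noise clusters farther than L_gap excluded.

**Defaults.** `L_gap = 4 mm`: the synthetic study conditions blank
axial intervals of 1–3 mm, and a bridging path crosses such a gap
diagonally, so the budget carries about one voxel diagonal of slack.
`T_path = 25`: measured on desk-scale volumes, genuine root paths
(including their bridged gaps) accumulate ≤ ~17 while excursions that
daisy-chain isolated noise voxels add ≈ c_gap × hop length per hop;
the threshold cuts that tail. Both scale with image and root-system
size and are exposed in `TraceConfig`.

**Automatic start.** The collar seed is the supra-threshold voxel with
maximal distance-transform value in the uppermost slice containing
signal — the most tube-interior voxel of the shoot — overridable in
config.

## Skeletonization

Distance-ordered homotopic thinning: simple points (deletion preserves
both the 26-connected object topology and the 6-connected background
topology in the 3×3×3 neighborhood, the Malandain–Bertrand
characterization) are deleted in increasing order of the Euclidean
distance transform, and curve endpoints (≤ 1 object neighbor) are never
deleted, so root tips survive and homotopy (components and cycles) is
preserved exactly.

Deletion order matters more than it first appears: any sequential scheme
that can delete two adjacent candidates in a row will consume a
structure that is one voxel thick along the scan direction end to end
(a 2-voxel-wide ribbon never exposes a protected endpoint). The
implementation therefore peels in six face-direction subiterations per
pass, each split into the eight parity subfields (i%2, j%2, k%2) — no
two voxels of one subfield are 26-adjacent, so no deletion can expose
its own successor within a round — with simplicity re-checked at
deletion time. Verified behavior: straight and oblique tubes of radius
0.7–1.5 mm on anisotropic grids keep their full axial span with tip
retraction of at most ~1 voxel per peeled layer, and a solid torus
thins to a one-cycle ring.

## Topology derivation

Skeleton voxels are classified by 26-neighbor count (1 = end, 2 = chain
interior, ≥ 3 = junction); maximal chains between classified vertices
become edges of a multigraph annotated with physical length, mean
traversal cost, accumulated Dijkstra edge weight, and per-voxel radius
(distance-transform values of the pre-skeleton mask). Then:

1. **Spur pruning.** Terminal chains shorter than
   max(2 × junction radius + one voxel diagonal, 3 mm) are removed —
   thinning stubble on thick or noise-roughened tubes; 3 mm is a
   few-voxel minimum detectable root.
2. **Cycle breaking.** Touching roots merge in the extracted volume and
   produce cycles; the minimum-total-weight spanning tree (edge weight
   = accumulated cost along the chain, which encodes root-likelihood)
   breaks them. Dangling remnants of broken cycles are pruned again.
3. **Tap selection.** The tap root is the collar-to-leaf path reaching
   the minimum z coordinate; ties go to the longer path.
4. **Branch grouping.** At every branch point the child chain whose
   initial direction deviates least from the incoming direction extends
   the current root; all other children start laterals of order + 1.
5. **Geometry.** Node positions are physical voxel centers; optional
   3-node moving-average smoothing (off by default) counteracts the
   staircase inflation of voxel-grid polylines, which otherwise
   overestimates RL by ~4–10%. The benchmark runner enables it.

Rules 3 and 4 are deliberately explicit and isolated: tap
mis-identification and branch mis-grouping are the known failure modes
of automated tracing, and alternative strategies can be swapped in.

## Root measures

RL is the sum of node-to-node Euclidean lengths; RLD = RL / container
volume (default container: a cylinder 21 cm tall, 5.6 cm inner
diameter, 517.3 cm³); HMD = (π·RLD)^(−1/2), the half mean inter-root
distance for randomly placed parallel roots; r_mean is length-weighted
(robust to uneven node spacing across reconstruction methods);
recovery = 100·RL/RL_ref against an independent reference length. CNR
is (mean root − mean background)/background sd with the background
taken outside a 1-voxel dilation of the root mask to exclude
partial-volume boundary voxels.

## Hydraulics

Standard root hydraulic architecture network: segment i of length L_i
and radius r_i has radial conductance K_rad,i = kr_i·2π·r_i·L_i and
axial conductance K_ax,i = kx_i/L_i. Node-wise mass balance under a
uniform soil potential (half of each segment's radial conductance
lumped to each end node — the radial flux uses the mid-segment
potential, approximated by the endpoint mean) gives a sparse SPD
system, solved by direct factorization with a Dirichlet condition at
the collar. The discretization converges to the analytic single-root
solution K_rs = √(2πr·kr·kx)·tanh(L·√(2πr·kr/kx)) (verified to
< 0.01% at 100 segments; tested bound 0.5%).

Scenarios: *constant* (kr = 1.8·10⁻⁴ cm hPa⁻¹ d⁻¹,
kx = 0.1 cm³ hPa⁻¹ d⁻¹ cm for every segment) and *variable* (kr, kx
looked up by order class — tap vs lateral — and segment age,
piecewise-linear). Segment age falls linearly from the root base to 0
at the tip; a lateral's base age is the age of the parent node it
attaches to. The shipped tables are order-of-magnitude values for young
lupine (laterals ~2–3× more radially permeable than the tap; radial
conductivity declining and axial conductance rising with tissue age)
and are meant to be replaced by measured tables via the scenario YAML;
the qualitative property that high-kr shallow laterals pull zSUF upward
is asserted in the tests, the absolute K_rs/zSUF values are
parameterization-dependent.

## Synthetic data generator

Each root grows by fixed 2 mm steps whose direction is the renormalized
blend `w_p·d_prev + w_g·(0,0,−1) + w_n·u` with persistence w_p,
gravitropism w_g, isotropic perturbation u and noise weight
w_n = (1−w_p)(1−w_g) (zero in the deterministic limit). Laterals
initiate along the parent as a renewal process — minimum spacing plus
an exponential remainder, with basal and apical unbranched zones, the
standard architecture-model parameters — leave at a branching angle
uniform in a configured interval with uniform azimuth, and receive a
much weaker gravitropism weight than the tap (laterals are
plagiotropic; with a shared weight they bundle along the container axis
and physically merge, which no tracer can undo). Per-order base radii
taper linearly with arc length; lateral target length is a uniform
fraction of the parent's. Growth stops at the container wall.

Rendering marks a voxel as root iff its center lies within the linearly
interpolated tube radius of some segment (capsule test). Noise draws
background and root intensities from zero-truncated normals; spherical
dropouts (rate per cm of root, the root length estimated from the
rendering as V/(πr̂²) with r̂ = 3× the mean interior distance
transform) emulate local signal losses from ferromagnetic particles.
Gaps blank flat-ended axial intervals (Poisson centers along arc
length, lengths uniform in range), so each realized gap is at most the
configured maximum — though two independent gaps may land adjacently
and form a longer composite gap that exceeds the bridging budget;
this is the dominant residual failure mode in the benchmark.

**Benchmark study conditions** (chosen once): 64×64×64 voxels at
0.5 × 0.5 × 1.0 mm (anisotropic like an axial slice stack), a
scaled-down lupine (container 60 mm × Ø28 mm, tap 40–55 mm, first-order
laterals only), soil 10 ± 10 / root 120 ± 10 intensity (nominal
CNR = 11, the difficult low-contrast regime; a soil mean near zero is
also what makes a 30%-of-max threshold meaningful, as in segmented
images), gap rate 0.5 cm⁻¹ with lengths 1–3 mm. Tests use these
desk-scale sizes throughout; the default grid for the library is the
full 256×256×70 at 0.273 × 0.273 × 1.0 mm.

**What the synthetic conditions do not show.** The noise model is
statistically stationary Gaussian — real soil noise is textured and
spatially correlated; gaps are clean axial cuts — real signal loss is
gradual and radius-dependent; root radii here are always above the
voxel size — real systems contain sub-resolution fine roots that no
tracer can recover (recovery against ground truth here is therefore
higher than recovery against a destructive measurement would be); and
the zero-truncated noise slightly biases the *measured* CNR above the
nominal (μ_root−μ_soil)/σ_soil when μ_soil/σ_soil is small (≈ +23% at
soil 10 ± 10) — the CNR estimator is therefore calibrated on
parameter sets with negligible truncation mass.

## Known limitations

* Under low-CNR noise the traced RL overshoots the ground truth by
  ~10–15% on average: noise voxels within one gap hop of the root
  attach and survive as short branches, and touching roots merge and
  get double-traced. Count inflation of higher-order laterals follows.
* Composite gaps (two adjacent random gaps) can exceed L_gap and
  disconnect a branch; recovery then drops for that case.
* Skeleton chains shortcut the inner bend of curved tubes; together
  with tip retraction (~1 tube radius per end) this biases RL slightly
  low on clean data (~2–4% with smoothing on).
* The thinning and the distance transforms use physical spacing, but
  centering within a 1–2 voxel thick structure is still quantized to
  the grid; radii below ~1.5 voxels are reported at ~the voxel scale.
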