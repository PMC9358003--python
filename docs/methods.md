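# Methods

`poreflow` detects and characterizes channels (pores) in molecular
structures by purely geometric means.  This note records the model, the
numerical choices, and what the synthetic test bed does and does not show.

## Model

A molecule is a union of balls, one per atom, each inflated by the solvent
probe radius (default 1.4 Å for water).  The inflated balls induce a
**weighted Delaunay (regular) triangulation** of the atom centers, computed
by the standard lifting: a center $(x, y, z)$ with weight $w = (r +
r_\mathrm{probe})^2$ maps to $(x, y, z,\; x^2+y^2+z^2-w)$, and the lower
convex-hull facets in 4D project to the tetrahedra.  Each tetrahedron
carries its **orthocenter** and signed squared **orthoradius**: the center
and common value of the sphere with equal power distance
($|x-c|^2 - w$) to its four weighted vertices.

The molecule's occupied region (the alpha complex at $\alpha = 0$) is the
set of tetrahedra with orthoradius$^2 \le 0$; the rest is the complement.
Complement tetrahedra are ordered by the **discrete flow**: a tetrahedron
flows across a face when its orthocenter lies strictly beyond that face's
plane.  Tetrahedra with a flow path to infinity (through a convex-hull face
crossed outward, transitively) are bulk solvent.  The remaining complement
tetrahedra — the ones whose flow terminates at interior sinks — form
face-connected **cavity components**.  A component's **mouths** are the
edge-connected clusters of faces where it meets bulk solvent or the hull:
0 mouths is an enclosed void, 1 a pocket, ≥ 2 a channel.  The channel is
the largest-volume component with at least two mouths (a flag relaxes this
to largest volume overall).

*Design note (bulk separation).*  Separating bulk solvent from cavities is
the one step the flow literature leaves open to implementation.  We use
the sink-based rule above because it is parameter-free and behaves
correctly on convex-position inputs: in a cylindrical pore every wall atom
is a hull vertex, so any rule keyed to "vertices on the hull" degenerates,
while drainage-to-infinity cleanly separates the lumen (whose tetrahedra
are flow sinks) from the exterior.

## Channel surface

The molecular surface is the zero level set of
$f(x) = \min_i\, (|x - c_i| - r_i)$, triangulated by marching cubes on a
regular grid (default 0.5 Å).  This union-of-balls surface stands in for a
rolling-probe surface: for a tube whose wall balls of radius $r$ sit at
axis distance $R$ it gives the analytic lumen radius $R - r$.  An
externally computed surface mesh (OFF/PLY) can be supplied and is treated
identically.  The **channel surface** is the subset of mesh triangles whose
barycenter lies inside some channel tetrahedron (exact barycentric test,
k-d-tree accelerated); each triangle is annotated with its nearest atom
(minimizing distance to the ball surface), which yields the residue table
of the pore lumen.

## Skeleton and core-path pruning

The skeleton is the Delaunay-dual graph of the channel: one node per
channel tetrahedron, edges between face-adjacent tetrahedra.  A node sits
at its tetrahedron's orthocenter whenever that point lies inside the
channel region, else at the barycenter.  Orthocenters are power-diagram
vertices, i.e. medial points of the cavity: on a cylindrical pore they
coincide with the axis to ~10⁻⁵ Å.  Per-node **clearance** is the distance
to the nearest inflated atom surface.

The core path maximizes the score
$$ s(\gamma) = \frac{\mathrm{length}(\gamma)^2}
                    {\max(\mathrm{tortuousness}(\gamma), \varepsilon)} $$
over the shortest paths (edge-count metric) between all node pairs, where
*length* is the edge count and *tortuousness* is the mean distance of all
path nodes (endpoints included) from the straight line through its
endpoints.  Long straight paths win; short or curved ones lose.  Numerical
choices:

- $\varepsilon = 10^{-4}$ Å floors the denominator.  It sits two orders of
  magnitude above the degeneracy-jitter scale (below), so paths that are
  straight up to jitter noise are treated as exactly straight and the
  length term decides among them; it is four orders below any physically
  meaningful tortuousness.
- Paths of a single edge are excluded from the election (their
  tortuousness is identically zero by construction, which would let any
  edge outscore every real path) unless the graph is complete.
- Shortest paths are not unique.  Up to 200 nodes the implementation
  minimizes tortuousness exactly over each pair's shortest-path DAG
  (dynamic program per pair); beyond that it scores one canonical path per
  pair — the lexicographic (edge count, Euclidean length) minimizer from a
  single Dijkstra pass — which is exact on trees and tight against the
  straight chord in tube-like skeletons.  The cutoff is a documented
  performance fallback; worst-case pruning cost is $O(v\,e + v^2\,d)$ for
  diameter $d$.
- Ties break toward the longer path, then the lexicographically smallest
  endpoint pair, making runs reproducible.

## Centerline, Frenet frames, radius

The centerline is the minimum-cost skeleton path between the pruned
endpoints with edge cost $\ell / \bar{c}^{\,2}$ ($\ell$ edge length,
$\bar c$ mean endpoint clearance): inverse-squared clearance pulls the path
toward maximal inscribed spheres and strongly penalizes wall-hugging (the
exponent is configurable).  The path is smoothed with a centered moving
average (window 5, shrinking at the ends so the entrances stay anchored)
and resampled at uniform arclength (default 0.5 Å).

Curvature $\kappa = |c' \times c''| / |c'|^3$ and torsion
$\tau = (c' \times c'') \cdot c''' / |c' \times c''|^2$ are evaluated with
Savitzky–Golay derivative stencils (window ≤ 11 points, polynomial order
4): raw central differences on a piecewise-linear resampled polyline have
impulsive second derivatives, whereas the local polynomial fit keeps the
estimator deterministic and accurate to < 1% on closed-form helices at the
default step.  Where $\kappa < 10^{-9}$ the normal/binormal are undefined;
such frames are flagged and torsion is reported as 0.

The per-point **local radius** is the distance to the nearest
channel-surface vertex; its accuracy is bounded by the surface grid
spacing.  Radius profiles bin $(z, r)$ samples along the global z axis
(sample SD, single-sample bins report SD 0); z is the conventional
membrane normal of pre-aligned trajectories.

## Cross-sections

At a centerline point $p$ with unit tangent $t_p$ the channel surface is
cut by the orthogonal plane through $p$: all triangle–plane segment
endpoints, deduplicated at 10⁻⁶ Å, expressed in a deterministic in-plane
basis.  A proximity graph connects points closer than a threshold
(default 3× the median nearest-neighbor distance — scale-free and robust
to mesh resolution).  Visibility from $p$: rays sweep the plane (default
360) and each ray selects the closest point lying within the proximity
threshold of the ray (perpendicular distance); the union of the selected
points' graph components is the visible contour.  A metric — rather than
angular — ray tolerance keeps the result invariant once rays are denser
than the contour sampling and prevents far lobes from capturing rays that
fall between near-lobe samples.  Per-section metrics: closest/farthest
visible distances, a direct least-squares ellipse fit (≥ 5 points) and its
eccentricity $e = \sqrt{1 - b^2/a^2}$.

## Trajectories

Frame 0 runs the full pipeline.  Subsequent frames rebuild geometry but
skip pruning: the previous frame's skeleton endpoint coordinates are
snapped to the nearest new skeleton nodes within a capture radius (default
5 Å).  If no node is captured, or the new centerline's symmetric mean
closest-point distance to the previous one exceeds a threshold (default
5 Å), the frame is reinitialized with a fresh pruning pass.  Failed frames
carry a reason and do not abort the run.  On a static trajectory warm and
cold starts are bit-identical because the same endpoint nodes are
recaptured.

## Degeneracies and determinism

Cospherical/coplanar configurations are resolved by a deterministic jitter
of at most 10⁻⁶ Å per coordinate, seeded from the atom count alone, so a
given input always produces the same triangulation, components and paths.
Exactly coplanar inputs are rejected (jitter cannot rescue them).
Tetrahedra with orthoradius² in (0, 10⁻⁹] are absorbed into the interior
to guard roundoff.

## Synthetic test bed

The generator builds walls of overlapping balls (grid step 1.2× ball
radius, so diagonal neighbors stay within 1.5×, keeping probe-inflated
walls watertight; walls are two layers thick because a single layer of
balls in convex position has no volumetric interior) around analytic
cavities: an open cylinder (lumen radius $R - r$), a solid torus
(through-hole), a blind hole (pocket), a sealed shell (void), a helical
tube (closed-form curvature $a/(a^2+b^2)$ and torsion $b/(a^2+b^2)$) and a
five-lobed pore.  Trajectories add i.i.d. uniform coordinate jitter with a
fixed seed.

These fixtures have exact ground truth but are idealized: uniform radii,
perfect symmetry, no side chains, thermal noise only as uniform jitter,
and no lipid environment.  Passing tests therefore demonstrate the
geometric machinery (triangulation, flow segmentation, pruning, Frenet
analysis, sectioning) is correct, not that biological channels with
irregular walls or transient fenestrations are characterized to the same
accuracy.  Problem sizes used in the test suite (hundreds to a few
thousand atoms, 2 000-node pruning graphs) were chosen to exercise the
asymptotic behavior while keeping a full run interactive.

## Known limitations

- The internal surface is a union-of-balls level set, not a true
  solvent-excluded surface with reentrant patches; supply an external mesh
  when SES fidelity matters.
- The skeleton derives from the Delaunay dual, not mean-curvature-flow
  contraction of the surface; an external skeleton CSV can be imported and
  fed to the same pruning and centerline machinery.
- Pruning above 200 nodes scores one canonical shortest path per pair
  (see above); on heavily cyclic, highly irregular skeletons the elected
  endpoints may differ from the exhaustive optimum.
- Ion-path comparison measures plain geometric displacement from the
  centerline; it carries no energetic or electrostatic information.
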