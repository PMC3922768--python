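# Methods

`retivessel` separates a retinal vessel network, given as a segmentation of
a color fundus image, into individual vessel trees (a primary vessel plus
its branches and sub-branches) and classifies each tree as artery or vein.
This note records the model, its assumptions, the parameters that matter,
and the numerical choices behind the implementation.

## Model and assumptions

A healthy retinal vessel varies smoothly: consecutive stretches of one
vessel have similar orientation, gradually tapering width, and gradually
changing brightness. Two vessels that overlap in the 2-D projection of the
fundus are, with high probability, of different kinds — at an
artery-venous (AV) crossing one vessel is an artery and the other a vein.
Arteries carry oxygenated hemoglobin, which absorbs less light in the green
band, so arteries appear brighter than veins in the green channel. The
pipeline is built entirely on these three facts.

Violations the method does not model: two vessels running parallel or
overlapping over many pixels (they thin to one skeleton line and cannot be
separated), interrupted segmentations (gaps break the connectivity the
search relies on), and strong non-uniform illumination (a locally darkened
artery can drop below the venous brightness). These are known failure
modes, not bugs.

## Pipeline

1. **Preprocess** (`preprocess`). A vessel probability image in [0, 1] is
   binarized with Otsu's threshold computed on a 256-bin histogram (ties
   resolved toward the lowest threshold so the result is deterministic);
   an input that is already binary (at most two distinct values) skips
   thresholding. The optic-disc (OD) circle — supplied as config, center
   plus radius, defaulting to 0.12 x image height — is removed from the
   mask: vessels at the OD are too intertwined to trace. The mask is
   thinned to a single-pixel skeleton (topology-preserving morphological
   thinning).

2. **Topology** (`topology`). Skeleton pixels are analyzed in their 3x3
   neighborhood (8-connectivity throughout): one neighbor marks a vessel
   endpoint, more than two a junction pixel. Removing junction pixels cuts
   the skeleton into junction-free runs; each run is a *vessel segment*,
   with an *end region* of up to 15 skeleton pixels at each end (shorter
   segments use the whole path for both ends). Binary-mask pixels are
   assigned to the nearest segment skeleton pixel.

   Thinning renders a transversal crossing of two vessels of width w at
   incidence angle psi not as one degree-4 pixel but as two degree-3
   bifurcations separated by roughly w/tan(psi/2) pixels. Since the AV
   constraint needs crossings to be recoverable as degree-4 junctions,
   junctions are consolidated in two stages: junction pixels within
   chessboard distance 2 merge into one cluster, and runs of at most
   `connector_max_len` (default 5) pixels joining two clusters are absorbed
   into a single merged junction. Degree-3 junctions are branch points,
   degree >= 4 crossings. Two cleanups control thinning noise: spurs
   shorter than 3 pixels ending in an endpoint are pruned (including the
   residual "bump" pixel left when a spur's base touches the line
   diagonally), and junction clusters whose incident-run degree ends up
   <= 2 — corner artifacts, not junctions — are demoted back into the
   runs.

3. **Features** (`features`). Per end region: the orientation theta in
   [0, pi] is the principal axis (total least squares) of the end-region
   pixel coordinates, which is robust to pixel jaggies; the travel
   direction is the unit vector from the terminal pixel toward the segment
   interior. Width is the median over the end-region pixels of a diametric
   measurement perpendicular to theta; intensity is the median green value
   over the end-region pixels. Width and intensity are normalized by their
   maxima over the connected component of the segment-adjacency graph —
   the tree itself is unknown before the search, and the component is its
   pre-search superset.

   The width ray integrates the bilinearly interpolated mask along the
   perpendicular (midpoint rule, 0.25-px steps, stopping at the first true
   background sample on each side). Nearest-neighbor sampling was tried
   first and is direction-biased on rasterized staircase boundaries (up to
   ~1.75 px error on oblique bars); the integral form measures area per
   unit length, is exact on axis-aligned strokes and 1-px lines, and stays
   within 1 px over widths 2-10 at angles {0, 30, 45, 60, 90} degrees.
   Coordinate convention: x = column rightward, y = -row (angles
   counter-clockwise, mathematical orientation).

4. **Tree search** (`treesearch`). Segments are graph nodes; segments
   meeting at a junction are joined by an edge carrying three costs
   between the two meeting end regions: `c_theta`, the angle between the
   incoming segment's continuation direction and the outgoing segment's
   travel direction (0 for a straight continuation, pi for a U-turn);
   `c_w` and `c_I`, the absolute normalized width and intensity
   differences scaled by pi so all three costs share [0, pi] (the scale
   matching prevents unit bias; pi is the natural choice since
   orientation already lives there). Degenerate single-pixel ends get the
   maximal orientation cost.

   Each tree grows from a root: the unassigned segment owning a free
   endpoint closest to the OD rim (minimal |distance to OD center − OD
   radius|), since vessels enter the retina there. Dijkstra's algorithm
   then finds minimal-sum paths, costing each relaxation hierarchically:
   orientation difference by default; if two of a node's orientation
   differences are equal within `eps_theta` (0.05 rad — floating-point
   equality needs a tolerance) the width difference decides for that tied
   set; if widths also tie (within 0.05 pi) the intensity difference
   decides. The summed cost to each reachable endpoint segment is divided
   by the number of nodes on the path (seed and endpoint included); the
   endpoint minimizing this normalized cost defines the primary vessel
   path (ties: more nodes, then lower id; the seed is excluded as its own
   candidate endpoint, whose normalized cost of zero would always win).
   Branches are mapped recursively by the same principle from unassigned
   segments at degree-3 junctions of the claimed path, searching only
   unassigned nodes; at crossings (degree >= 4) the tree keeps only the
   continuation chosen by the search itself, leaving the transversal pair
   for another tree. Root selection, search, and branch mapping repeat
   until no endpoint-bearing segment is left; leftovers are noise. All
   ties break toward the lowest id — the module is deterministic and
   seed-free.

   A consequence of normalizing by node count: a path that takes one
   expensive turn onto a long, smooth foreign vessel can average cheaper
   than the correct short path, so a tree occasionally runs straight
   through a crossing onto its partner. This is the method's documented
   failure mode and is visible (rarely) in the synthetic benchmarks.

5. **AV classification** (`avclass`). Crossings found during mapping pair
   the trees: each degree-4 junction whose incident segments belong to
   exactly two trees yields a pair (repeat crossings deduplicate; >2 trees
   at one junction is skipped and logged). For any comparison of two
   trees, centerline pixels are taken only from segments wider than 60% of
   the tree's maximum width (thin peripheral segments have unreliable
   color), and each pixel is described by [mu_g, sigma_g, mu_h, sigma_h]:
   mean and population standard deviation of green and hue over its 3x3
   neighborhood (clipped at borders). The pooled pixels are standardized
   (zero mean, unit variance per feature — green spans 0-255 while hue
   spans [0,1), and an unstandardized Euclidean metric would see only
   green) and clustered by fuzzy C-means with c = 2, fuzzifier m = 2,
   tolerance 1e-5 on the membership change, at most 300 iterations, and
   deterministic initialization from the two points farthest apart in
   feature space (no seed needed; the objective is non-increasing and
   memberships row-sum to 1). Pixels whose two membership degrees differ
   by at most 0.2 are indeterminate noise and are dropped; the cluster
   whose (unstandardized) centroid has the higher mean green is arterial.

   Within a pair, the tree with the higher arterial-pixel proportion is
   the artery. Because a tree can cross several partners, pairs are not
   labeled independently: each connected component of the pairing graph is
   2-colored (BFS), and the color class with the higher pooled arterial
   proportion becomes the arteries — identical to the per-pair rule for a
   single pair, and it guarantees opposite labels across every crossing.
   A non-bipartite component (an odd cycle of crossings, anatomically
   impossible but conceivable in noisy data) falls back to per-tree labels
   and is logged.

   Unpaired trees are grouped by single-linkage on their centroid pixels
   at a threshold of 0.25 x image width (localized groups damp
   illumination gradients; the fraction makes the threshold resolution
   independent). A singleton group merges into the spatially nearest
   group. Every pair within a group is compared as above, giving each tree
   one soft label per pairing (artery = 1, vein = 0); the hard label is
   the median of a tree's soft labels, a median of exactly 0.5 resolving
   by the tree's mean arterial proportion. A lone unpaired tree with no
   possible partner is clustered against the pooled pixels of all trees
   and labeled by its majority class (logged).

## Synthetic scenes (`synthetic`)

The generator emulates exactly the assumptions above, with ground truth:
trees radiate from the OD rim as smooth polylines (per-step turn limited
to 0.08 rad at 1.5-px steps), widths taper linearly from root (5 px
arteries, 6 px veins — veins are wider) to 2-px tips, and each tree
spawns a branch at a 0.35-0.65 rad angle. Each crossing pair is built by
choosing a point on the artery, drawing the vein *backward* from that
point to the OD rim (gentle steering toward the OD) and forward with a
random tail — so the crossing point and its incidence angle (drawn from
55-80 degrees; steep enough that thinning yields a recoverable degree-4
junction) hold exactly. Non-crossing vessels keep a 7-px clearance;
infeasible draws retry boundedly and then raise. Colors: background
(190, 110, 60), veins (130, 55, 50), arteries offset by +15 in green
(= 3 x the noise SD of 5) and +35 in red, Gaussian blur sigma 0.7 for
gradual edge transitions, additive Gaussian noise, optional linear
illumination ramp, everything deterministic in the seed. `degrade_mask`
adds boundary jitter and per-pixel gaps for robustness experiments.

What the scenes do **not** contain: parallel-running vessel pairs,
segmentation interruptions, pathology (microaneurysms, beading), strong
vignetting, or central light reflexes. Passing the synthetic benchmarks
therefore demonstrates the machinery is correct under the method's own
assumptions, not performance on clinical images.

## Evaluation (`evaluation`)

Structural accuracy matches predicted to reference trees by maximal pixel
overlap (Hungarian assignment) and counts segments whose matched tree
equals the majority reference id over their skeleton pixels. Segment-level
AV misclassification is binned by width (1<=w<4, 4<=w<=6, 6<w<=9, w>9;
empty bins report no rate), with a summary rate for widths above 4 px.
Pixel-level misclassification is the fraction of vessel pixels under a
wrong label, optionally split into crossing-paired vs unpaired trees. AV
labels are absolute; only tree identities need matching.

`scripts/acceptance.py` regenerates 20 scenes (compositions cycling 2-6
trees, every scene with at least one AV crossing), runs the full pipeline,
and reports structural segment accuracy, AV tree accuracy, AV pixel
misclassification, and the paired/unpaired split. Problem size — 256x256
scenes, roughly 250 segments and 77 trees over the batch — keeps a full
run in seconds while covering every code path (pairs, multi-pair
components, unpaired groups, lone trees).

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `od_radius_frac` | 0.12 | OD mask radius as fraction of image height |
| `spur_min_len` | 3 px | prune skeleton spurs shorter than this |
| `junction_merge_dist` | 2 px | chessboard merge distance for junction pixels |
| `connector_max_len` | 5 px | absorb runs this short between junction clusters |
| `end_region_len` | 15 px | skeleton pixels per segment end region |
| `eps_theta` | 0.05 rad | orientation-cost tie tolerance |
| `eps_wI` | 0.05 pi | width-cost tie tolerance |
| `width_fraction` | 0.6 | keep segments wider than this fraction of tree max |
| `membership_margin` | 0.2 | fuzzy membership margin below which a pixel is noise |
| `fuzzifier` | 2.0 | fuzzy C-means exponent m |
| `grouping_threshold_frac` | 0.25 | unpaired grouping distance / image width |

## Known limitations

- Parallel or long-overlapping vessels are not separable (single skeleton).
- The node-count-normalized cost can carry a tree through a crossing onto
  its partner when the foreign continuation is long and smooth.
- Classification rests on color contrast; under strong local illumination
  changes an artery can be labeled vein (the localized grouping only damps
  this).
- Junction consolidation can in principle merge a true branch point into a
  nearby crossing if they fall within the connector length; the generator
  keeps branches away from crossings, real data need not.
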