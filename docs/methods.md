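# Methods

## Data model

A lineage file has one row per detected nucleus per timestep:
`node_id,predecessor_id,timestep,time_hp,x,y,z,validated,identity,death`
(CSV, UTF-8, header mandatory). `predecessor_id` links a nucleus to the
same cell — or, across a mitosis, to its mother's nucleus — exactly one
timestep earlier; a missing predecessor is an empty field, not a sentinel.
`time_hp` is hours post fertilization (wild type, estimated 8 h postcoitum)
or post activation (clones); timesteps are 0-based and spaced by the frame
interval (15 min by default). Coordinates are µm in the microscope frame;
no axis reorientation is applied. Booleans are written 0/1, floats with
`repr`, so write∘read is exact field-for-field (verified down to the last
ulp). A *track* is a maximal chain between divisions; tracks therefore
partition the nodes, and `#tracks = #roots + 2·#divisions`. A node with
three or more successors is rejected as a format error; a death-flagged
node with a successor, a gap in a track, or `time_hp` inconsistent with
the timestep spacing fail validation. Nodes with `validated = 0` are
excluded from every downstream statistic, mirroring the restriction of
curated datasets to their verified portion.

## Inner/outer identity

Identity is a per-track attribute, constant between divisions; the usual
"identity prior to the next mitosis" rule then reduces to the daughter
track's identity. Leaf tracks are classified at their last observed
timestep: a nucleus is **outer** iff it is a vertex of the frame's 3D
convex hull, or its distance to the nearest hull facet plane is ≤
`shell_tolerance` × (mean nearest-neighbor distance of the frame).
Defaults: `shell_tolerance = 0.5`; ties at the tolerance classify as outer
(conservative toward trophectoderm continuity; both configurable).
Classification needs ≥ 5 non-coplanar nuclei; degenerate frames raise
rather than guess. The hull is taken over the nucleus point cloud, not a
reconstructed surface — the only geometry available in tracking data.

Backward propagation processes tracks leaves → roots. Agreeing daughters
pass their identity to the mother. Disagreeing daughters mark an
asymmetric division; the mother's identity is then taken from a curated
annotation (the `identity` column on her last nucleus) when present, else
from the geometric rule applied to her last position. Death records
inherit the dying track's identity; deaths are input data (curation or
simulation), never inferred from geometry, since cell death is recognized
morphologically, not positionally.

Two bookkeeping conventions matter for exact ledgers: a division is
timed at the frame where the daughters first appear, and a dying nucleus
is observed through its terminal (death-flagged) frame, so the inner-count
flux identity reads
`ΔN_in(f−1→f) = sym-inner-divisions(f) + asym-outer-divisions(f) − inner-deaths(f−1)`.

## Temporal rescaling

The embryo volume series is the convex-hull volume of all validated nuclei
per timestep. The first blastocoel collapse is the earliest timestep `t+1`
with `V(t+1) < (1 − θ)·V(t)`, θ = 0.10, strict inequality ("more than
10%"), reported at the later frame of the pair — the first frame showing
the reduced volume. No smoothing is applied before detection. Normalized
age is `na(t) = t_hp / t_collapse_hp`, fixing 0 at
fertilization/activation and 1 at the collapse; detection commutes with
uniform time dilation, so na-values of events are dilation-invariant.
Cohorts are compared on the intersection of their observation windows in
n.a.; series are evaluated on a common grid by step-function lookup
(counts) or linear interpolation without extrapolation (continuous
series).

## Statistics

- **PIC** = N_in/(N_in+N_out) per grid point; group curves average
  per-embryo proportions unweighted.
- **OAD/IAD**: per half-open bin `[lo, lo+w)` (w = 0.05 n.a., bins
  anchored at the common-window lower bound; an event on an edge belongs
  to the right bin), the fraction of asymmetric divisions among divisions
  of outer/inner mothers. Empty denominators are flagged NaN, never
  zero-filled.
- **Normalized death ratio** of type T per embryo:
  `r_T = (D_T/D) / (N_T/N)`, with D_T deaths of type T inside the window,
  D all deaths, N_T distinct validated tracks of type T alive at any point
  in the window, N all such tracks. Exposure is counted as distinct tracks
  rather than cell-time: it is the simplest definition under which
  type-independent death gives r_T = 1 exactly and the identity
  `Σ_T (N_T/N)·r_T = 1` holds per embryo; an exposure-weighted variant
  would be a drop-in replacement. Embryos without deaths in the window are
  excluded with a warning. Group dispersion is reported both as sample
  s.d. and standard error, since both conventions circulate.
- **CV** across embryos per grid point: sample standard deviation (n−1)
  over mean, ≥ 2 embryos, NaN at zero mean.
- **Neighborhood composition**: for each dividing mother, the fraction of
  its k = 8 nearest neighbors (Euclidean, at the mother's last frame)
  whose identity differs from hers; k-NN rather than a fixed radius so the
  measure is robust to embryo growth; fewer than k available neighbors are
  used in full and flagged.
- **Founder clones**: every validated cell at the first validated timestep
  roots a clone; `N_mit` counts divisions in its subtree and satisfies
  `N_mit = final cells + deaths − 1` on a binary tree (asserted in tests).
- **Relative developmental speed**: 100·(t_collapse(clone)/mean
  t_collapse(wild types) − 1); the published phrasing of "percent slower"
  does not pin a formula, so this ratio-of-collapse-times definition is
  declared here and in output metadata.

## In silico symmetrization

An annotated lineage is compiled into a *division program*: root
identities plus, per division, a symmetric flag or the off-type daughter.
Forward replay (root → leaf) reproduces the backward annotation exactly —
asserted on simulated ground truth. The transformation replays the
program, and at each division first evaluates the mother's **current**
identity under the transformed dynamics; if it equals the target type and
the division was asymmetric, both daughters inherit. This recursive
selection is the default because it is the only reading that leaves zero
residual target-type asymmetric divisions and makes every inner cell's
ancestry purely inner under outer-symmetrization; selection on the
original annotation is available (`recursive_selection=False`) for
sensitivity analysis. Topology, positions and times are shared objects
across conditions — only identities differ — so total counts are conserved
by construction and the transformation is idempotent.

## Synthetic embryo generator

The generator emulates the statistical structure of the study's data: five
embryos imaged from the ~32-cell stage to hatching at 15-min frames, two
compartments, a wave of outer-cell asymmetric divisions, type-biased death
in clones, and a volume trajectory with one scripted collapse.

Defaults (wild-type-like preset): 23 outer founders on a jittered
golden-spiral lattice of a sphere (even epithelial spacing keeps the hull
volume stable) and Poisson(9)-distributed inner founders (clamped ≥ 1;
inner founder counts vary strongly between real embryos, e.g. 3 vs 9),
window 61.5–86 h, collapse at 80 h; cycle times log-normal with mean 13 h
and CV 0.2, founders desynchronized by a uniform age; outer asymmetry
probability a Gaussian bump (peak 0.25 at 0.85 n.a., σ = 0.1 n.a.); inner
asymmetry constant 0.05; death hazard 0.0015 per cell-hour, unbiased.
Clone-like preset: 3 expected inner founders, activation clock with window
72–101 h and collapse at 94 h (≈17% slower), hazard 0.002 with inner bias
β = h_in/h_out = 4, inner asymmetric divisions only after 0.95 n.a.
(delayed and scarce). Geometry: radius 55 µm growing 0.4 µm/h, inner cells
at 0.5 R, jitter 1 µm, daughter directions dispersed 0.15 rad around the
mother's; asymmetric divisions displace the off-type daughter to the other
compartment's radius. The collapse parameter is a fractional **hull-volume**
drop (default 0.15); the radius is scaled by its cube root from the
collapse frame on. With these choices the frame-to-frame hull-volume noise
is ~2–4%, well separated from the 10% detection threshold — scripted drops
within noise distance of the threshold are indeterminate by construction,
so tests probe drops ≥ 15% (detection) and ≤ 5% (no detection).

An optional feedback mode for inner asymmetry sets
`p = clip(base + gain·(PIC − target), 0, max)` (defaults 0.3 + 3·Δ,
capped 0.8). The sign is deliberate: inner asymmetric divisions slow
inner-pool growth (1 inner → 1 inner + 1 outer), so a probability that
*rises with* PIC is the stabilizing direction and settles the cohort mean
PIC near the target — a testable form of the regulation hypothesis that
inner asymmetric divisions trim the inner population.

These defaults are conventions chosen to echo the observed scales
(~32 → ~120 cells, common window ≈ 0.77–1.07 n.a.), not estimates of
rabbit parameters; the true time profiles of asymmetry probabilities are
only qualitatively known. The geometry is phenomenological — no
mechanics, no compaction or cavitation, no cell-cell exclusion beyond
jitter — sufficient for hull, shell-classification and k-NN operations.
Passing tests therefore demonstrate correctness of the *analysis* under
the assumed generative structure, not fidelity of that structure to real
embryos; on real data the geometric classifier additionally faces
segmentation errors, anisotropic point densities and genuine blastocoel
geometry that the generator does not model.

Determinism: per-embryo seeds derive from the master seed via
`SeedSequence(master, spawn_key=(index,))`; identical (parameters, seed)
give byte-identical tables.

## Verification strategy and problem sizes

Every operation is tested against an independent oracle where one exists:
brute-force point-to-facet distances for shell classification, hand-walked
recursions for propagation and replay, closed-form hull volumes, linear
scans for collapse detection, and a count-level branching-process
Monte-Carlo (re-implementing only the event rules, no geometry or lineage
machinery) for growth and death-ratio calibration. End-to-end checks use
20 simulated embryos for exact ground-truth recovery, 100 random
parameterizations for collapse detection, 100 random lineages for the in
silico invariants, 50-embryo cohorts (with 10× oracle replicates) for
death-ratio and OAD-peak recovery; the acceptance script analyzes a
study-scale cohort (3 + 2 embryos) plus 12-embryo groups for
event-hungry statistics. These sizes keep the full suite around a minute
while leaving Monte-Carlo standard errors small against the tested
effects.

## Known limitations

- The geometric mother-resolution rule at asymmetric divisions is this
  package's convention; curators of real datasets resolved such cases
  manually, and curated annotations take precedence whenever present.
- Track-based (rather than exposure-weighted) death-ratio denominators
  slightly favor short-lived tracks when windows are narrow.
- The import dialect is fixed; externally deposited lineage files with a
  different column layout need a thin adapter.
- No statistical hypothesis testing between groups is provided, and no
  survival analysis of whole embryos.
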