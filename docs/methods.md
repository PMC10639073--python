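# Methods

This note records the models, conventions and numerical choices behind
`polsensor`, in the order a user meets them.

## Coordinate model and conventions

Coordinates are Cartesian ångströms in a right-handed frame; all angles are
degrees. Atoms are addressed by `(chain, author residue number, atom name)`
so the catalytically meaningful residues of the Pol ϵ catalytic core keep
their familiar numbers (Y645, N828, D640, M644, Y831, D877). Atom names are
normalized on input: whitespace stripped, PDB v2 primes (`*`) mapped to v3
(`'`), and an extensible synonym table applied afterwards — deposition
dialects disagree on ligand atom spellings, and the deposited ligand codes
for the various (d)NTPs are not standardized, so both the synonym table and
the nucleotide ligand code are configuration, not convention.

Alternate locations are resolved before any geometry is measured. The
default policy keeps the highest-occupancy conformer, ties broken to the
lexicographically smallest altloc identifier; a `prefer_label` policy keeps
the smallest identifier outright. Waters (HOH) and metal ions are parsed as
HETATM and retained: the crystal forms this package analyses contain Ca²⁺
in the catalytic site, and the H-bond auditor needs the waters.

The writer uses strict fixed columns (`%8.3f` coordinates) and refuses
coordinates ≥ 10 000 Å rather than corrupting the layout. A read→write→read
cycle is the identity on every field, with coordinates at 3-decimal
precision; tests verify the column layout against an independent PDB
library (gemmi) serializing the same record.

## Rigid superposition

Superpositions are unweighted least-squares rigid fits (Kabsch). The
rotation is obtained from `scipy.spatial.transform.Rotation.align_vectors`
on centred point sets, which returns a proper rotation; reflections are
excluded by construction because mirrored biomolecular coordinates are
meaningless. Fits require ≥ 3 matched points and reject collinear sets
(second singular value < 1e-8 relative) as degenerate. Three preset residue
schemes are provided, matching the comparisons this analysis is built for:

| scheme        | Cα atoms                  | use                                   |
|---------------|---------------------------|---------------------------------------|
| `finger_palm` | 828, 831, 833, 645        | superimposes the incoming nucleotides |
| `palm`        | 877, 640, 556, 645, 836   | palm-frame comparisons                |
| `palm_b`      | 640, 644, 645, 556, 836   | variant palm frame                    |

Scheme atoms are matched by residue number and atom name through each
structure's site map, so chain-naming differences between depositions are
absorbed by configuration. Whether a deposition spreads scheme atoms over
several chains is made explicit in the site map rather than guessed.

Optimality is property-tested: on random instances the analytic fit is
never beaten by a random-rotation search with optimal translation, and on
noisy instances it agrees to 1e-6 with a multi-start numerical minimisation
over rotation-vector parameters.

## Active-site descriptors

* **Sensor angle** — interior angle at the sensor Cγ between the sensor Cα
  and the O2B β-phosphate oxygen of the incoming nucleotide. For a valine
  sensor (the N828V variant) Cγ1 plays the Cγ role; a sensor with no γ
  carbon at all (e.g. alanine) is rejected as unsupported. A wide angle
  (near 160°) is the locked conformation, in which the asparagine can keep
  its loose H-bond to the β-phosphate; a decreased angle is unlocked.
  The locked/unlocked boundary defaults to 140° — the two modes are
  characterised only qualitatively, so the boundary sits between them and
  is an explicit configuration item echoed into every report. Angles
  exactly at the boundary classify as locked.
* **Gate distance** — Euclidean distance from Cδ1 of the steric-gate
  tyrosine to C2′ of the incoming nucleotide's sugar. Ribonucleotides sit
  ~0.6 Å further out.
* **Catalytic gap** — distance from the backbone Cα of D877 to the hydroxyl
  oxygen (atom `OH`) of Y645. "Hydroxyl group" is read as the O atom:
  crystal structures carry no hydrogens, so the oxygen is the only
  well-defined choice. Likewise the "Cα of D877" is the backbone Cα.
* **Per-atom displacement** — the moving structure is superposed on the
  reference by a scheme, then matched target atoms' Euclidean displacements
  are reported individually plus max and mean. Because the literature
  figure for the sensor shift does not name a single atom, the convention
  here is to report every side-chain atom (CB, CG, OD1, ND2 — or CG1/CG2
  for valine) and summarise by the maximum.
* **Base-pair coplanarity** — angle between total-least-squares planes
  (smallest right singular vector of the centred ring coordinates) of the
  templating base's and the incoming base's ring atoms, folded into
  [0°, 90°]; 0° is a planar nascent pair. Ring sets are the purine
  9-ring and pyrimidine 6-ring; down to 3 atoms per ring are tolerated.

All descriptors are invariant under proper rigid motion of the whole
structure; this is asserted to 1e-6 under batteries of random motions.

## Hydrogen-bond audit

The audit grades an explicitly supplied donor–acceptor pair list — the
contacts a polar-filter mechanism would require — rather than discovering
bonds, matching how such proposals are evaluated in practice. Evaluation is
heavy-atom-only (crystal structures lack hydrogens): the donor–acceptor
distance must not exceed a ceiling and the angle at the donor, measured
antecedent–donor···acceptor with the antecedent taken from a small
extensible chemistry table (Ser/Thr/Tyr hydroxyls, Asn/Gln/Lys/Arg/His/Trp
nitrogens, backbone N, nucleotide O2′/O3′ and base exocyclic/imino
nitrogens), must not fall below a floor.

Two criteria sets are evaluated at once. Defaults: strict ≤ 3.5 Å and
≥ 120°, relaxed ≤ 3.9 Å and ≥ 100° — the relax convention of interactive
structure-analysis H-bond tools (slacken by 0.4 Å and 20°). The exact
thresholds used in the published audit live in supplementary material that
this package does not consume, so these defaults are a documented stand-in,
fully configurable, and printed in every report header. The relaxed set
must dominate the strict set (checked, configuration error otherwise),
which makes the strict⊆relaxed monotonicity structural; verdict
monotonicity under criteria tightening is property-tested over random
geometries.

Pairs failing even relaxed criteria are screened for a bridging water: a
water oxygen whose two legs both satisfy the distance ceiling, with the
angle floor applied on the partner side where an antecedent exists (the
water oxygen has none in a hydrogen-free model). Among qualifying waters
the one minimising the summed leg distances is reported. Water-mediated
contacts are counted within `fail` but flagged separately, so the three
verdict counts always sum to the number of input pairs.

## Trajectory analysis

A trajectory is one topology structure plus an `(n_frames, n_atoms, 3)`
array; the constant-roster invariant is enforced by construction, and
descriptor series over tens of thousands of frames are vectorised while
remaining bit-identical to frame-by-frame evaluation (tested). Input
formats are multi-model PDB and a plain per-frame coordinate table
`(frame, atom_id, x, y, z)`; binary MD formats are out of scope — convert
with any standard trajectory tool to multi-model PDB first.

Defaults mirror the sampling protocol the descriptors were designed
against: frames stored every 2.5 ps; the first 30 ns of each production
run discarded as extended equilibration; analysis frames extracted every
12.5 ps. Three 130 ns replicas analysed over their final 100 ns therefore
contribute 3 × 8000 = 24 000 frames per system. Subsampling selects stored
frames only — the stride must be an integer multiple of the storage
interval, and timestamps are never interpolated. The bookkeeping helpers
also encode the equilibration schedule (three 500 ps heating stages, five
200 ps restraint-release stages, one 500 ps unrestrained stage; 3 ns
total) and the aggregate production sampling (4 systems × 3 replicas ×
130 ns = 1.56 μs), consumed as arithmetic only — this package never runs
dynamics.

State populations are threshold classifications of the sensor-angle
series: `p_locked` is the fraction of frames at or above the boundary,
with per-state mean/SD (descriptive only; no autocorrelation correction).
Replica summaries report per-replica means, their sample SD (ddof = 1)
across replicas, and the frame-weighted pooled mean. 2D densities conserve
the frame count by clipping out-of-range values into edge bins and
reporting the clip count.

Frame clustering follows the sieve convention: every *k*-th frame
(default 5) is clustered by hierarchical agglomeration — average linkage
by default, via `scipy.cluster.hierarchy` — on pairwise best-fit RMSD of
the selected atoms, cutting the dendrogram at the cutoff distance
(default 2.0 Å); remaining frames join the cluster whose representative
(the medoid of its sieved members) is nearest by RMSD. The linkage
criterion and the assignment rule are not specified by the clustering
tools this emulates, so both are explicit parameters; exact reproduction
of another tool's clusters is not claimed, but on ≤ 50-frame instances the
sieve-free path is equivalence-tested against a naive O(n³) agglomerative
oracle. Pairwise RMSD uses best-fit superposition, not raw coordinates.
Fewer than two sieved frames yields a single cluster with a warning.

## Synthetic data

Fixtures are minimal (≈ 45 atoms), not whole-protein models: every
analysis operation addresses named atoms only, so minimality is sufficient
and keeps the full test suite in seconds. Construction is analytic and
exact — the sensor Cα and the nucleotide O2B sit on a circle of fixed
2.5 Å arms about the sensor Cγ, so the requested angle is realized
identically; the gate Cδ1 is placed at the requested distance from C2′
along a fixed axis; Y645's OH at the requested gap from D877's Cα; the two
base rings are built in planes meeting at exactly the requested dihedral.
Re-measuring any noiseless fixture returns its construction parameters to
1e-6. Deoxy fixtures omit O2′. No attempt is made at internally consistent
residue stereochemistry, rotamer realism, force-field energetics or
solvent; passing tests demonstrate the correctness of the *measurement*
machinery, not the realism of the fixtures, and conclusions about real
depositions still require the real coordinates.

Two-state trajectories draw a Bernoulli state per frame, then the sensor
angle from that state's normal mode (locked 160°, unlocked 110°; SDs 8°
and 10° — conventional choices, as no measured mode widths exist — all
configurable) and the gate distance from a normal (mean 3.4 Å, SD 0.3 Å)
plus a 0.6 Å offset when the site is ribonucleotide-bound. Draws are
clipped to valid ranges with clip counts reported in the trajectory
metadata, never silently resampled. The random stream is consumed
identically for ribo and deoxy runs, so equal seeds give gate series
differing by exactly the offset. A fixed seed gives bit-identical output
everywhere.

One caveat the tests respect: a threshold classifier on overlapping normal
modes measures the mixture's exceedance probability, not the mixing weight
itself. With the default modes the two differ by at most ≈ 0.006, which is
comparable to 3 binomial standard errors at 24 000 frames when the mixture
is extreme (p = 0.9); the population-recovery tests therefore check the
estimator against the analytic exceedance probability at binomial
precision and separately bound its distance to the mixing weight.

The H-bond fixture builds each proposed contact as an isolated serine-OG
donor / carbonyl-O acceptor pair, 50 Å from its neighbours, with distance
and donor angle solved from the requested verdict class relative to the
supplied criteria (so the construction adapts to non-default thresholds);
requesting relaxed-only pairs under coinciding strict and relaxed criteria
is rejected as unrealizable. The optional water bridge doubles one failing
pair's length and places a water at its midpoint.

## Pipeline and reports

Campaigns are driven by a single YAML config; unknown keys are rejected.
Reports are JSON with a provenance block (package version, config digest,
seed, thresholds, criteria) so that no analysis constant is implicit.
A failing job is recorded and the remaining jobs proceed; the CLI exits 0
on full success, 2 on partial failure, 3 on configuration errors.

## Known limitations

* mmCIF input, anisotropic displacement parameters, symmetry expansion and
  sequence records are not parsed.
* H-bond scoring is geometric only — no energies, no hydrogen placement.
* Sugar-pucker phase analysis is not implemented.
* Reported spreads are descriptive; time-correlation-aware error estimates
  are deliberately out of scope.
* The sieve-clustering assignment rule and linkage are this package's
  documented choices; other tools' cluster memberships may differ near the
  cutoff.
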