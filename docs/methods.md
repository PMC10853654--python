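# Methods

## Scope and model

The package implements the quantitative core of a presurgical MEG
workflow: equivalent-current-dipole (ECD) source analysis of interictal
spikes, spatial classification of the fitted dipoles, scoring of the
localization against the surgical resection and against other diagnostic
modalities, and exact inference on the resulting outcome tables. Raw
signal processing (filtering, spike marking), image acquisition and
coregistration are outside scope: one spike topography arrives already
marked, and all spatial inputs share a single head-frame coordinate
system (right-handed, millimetres, origin at the conductor center).

### Conductor and sensors

The head is a homogeneous spherically symmetric conductor (default radius
90 mm, centered at the origin). The field of a current dipole in such a
conductor has the Sarvas closed form; volume currents are fully accounted
for analytically and a purely radial dipole produces no external field.
Units are mm, nA·m and femtotesla; the single conversion constant
`1e5 fT·mm²/(nA·m)` absorbs μ0/4π and the unit scalings.

Sensors are point magnetometers sensing the radial field component,
placed quasi-uniformly (Fibonacci lattice) on a hemisphere of radius
110 mm. Real whole-head systems mix magnetometers with planar
gradiometers; the radial-magnetometer simplification keeps the forward
physics exact and one-line while preserving everything downstream stages
depend on. Channel count and helmet radius are configurable; 102 channels
is the default.

### Inverse fit

At a fixed position the measurement is linear in the moment, so the
three moment parameters are solved by least squares against the 3-column
lead field and the nonlinear search runs over position only. The search
is a 10-mm cubic grid over the sphere interior (ridge-stabilized so the
degenerate center node, where every moment is silent, stays solvable)
followed by Nelder–Mead refinement with up to three restarts and a Powell
polish — restarts guard against premature simplex collapse, which
otherwise leaves occasional millimetre-scale errors on noiseless data.
Ties in the grid stage break toward larger goodness of fit, then toward
the lexicographically smallest position, making the fit deterministic and
invariant to channel ordering. Goodness of fit is
`1 − Σ(b−b̂)²/Σb²`, clipped to [0, 1]; dipoles with GOF strictly above
0.85 are accepted. Noiseless round trips recover position to well under
1 mm; pure-noise topographies fit at GOF ≈ 0.1, far below threshold.

### Parcellation

A toy gyral parcellation stands in for a cortical atlas: regions are
Voronoi cells of seed points inside an 85-mm brain sphere on a 76³ grid
of 2.5-mm voxels, which makes every region connected and tiles the brain
mask exactly. Each gyrus carries a lobe label from {parietal, occipital,
posterior_temporal, non_posterior}; gyral adjacency is derived from voxel
face-contacts (or can be specified explicitly). The default layout has
12 gyri (4/3/2/3 per lobe). Points in unlabeled voxels snap to the
nearest label within 5 mm; beyond that a dipole is unassignable and is
treated as an outlier.

### Pattern classification

Clusters are single-linkage components at 10 mm — the operational
reading of "at least five dipoles within about 1 cm³", which fixes no
region shape; a component needs ≥ 5 members to count. Clusters whose
gyrus sets share a gyrus or touch through adjacency are merged (two
clusters in adjacent gyri are one focus). A merged cluster is *valid* if
its gyrus set is one gyrus or two adjacent gyri. Exactly one valid
cluster → `single_cluster`; two or more → `multiple_clusters`
(necessarily non-adjacent after merging); anything else → `scattered`.
The definitions in the clinical literature leave a gap (what is a
patient with six dispersed dipoles forming no cluster?); the precedence
rule — cluster detection first, zero valid clusters means scattered —
closes it while keeping the three labels exhaustive and exclusive.
Dipoles outside every valid cluster are outliers.

### Resection and concordance scoring

The resection is a binary voxel mask. Distance from a point to the
resection is read from a Euclidean distance transform (scipy) sampled at
the containing voxel; with ≤ 2.5-mm voxels the discretization error is an
order of magnitude below the 10-mm clinical tolerance, so sub-voxel
interpolation is not attempted (verified against brute-force voxel-center
distances on small grids). A single-cluster localization is *completely
resected* when every cluster member lies within tolerance of the mask;
outliers are ignored; multiple-cluster and scattered localizations are
noncomplete by definition.

Lobar concordance with MRI, PET and interictal EEG is nonempty
intersection of lobe sets; joint ("MEG + MRI and PET") concordance
requires concordance with every listed modality. A negative study (empty
lobe set) counts as discordant — the literature's bookkeeping requires a
ruling here and never states one; this is the documented choice.
MRI–resection discordance (the subgroup where MEG should add value) is:
MRI negative, or MRI lobes not contained in the resection lobes, with
resection lobes taken as lobes of gyri holding ≥ 5% of mask voxels (the
threshold ignores incidental spill across a gyral border). SEEG is scored
at the gyral level: a gyrus is sampled if a contact lies in it (3-mm
snap); sampling is complete when all MEG gyri are sampled; SOZ
concordance is complete when the MEG gyri are a subset of the SOZ,
partial on mere overlap. Configurations the two-level schemes leave
undefined (no MEG gyrus sampled; no SOZ overlap) map to the partial
category with an explicit warning flag.

### Exact statistics

Fisher's 2×2 test enumerates the hypergeometric support directly with
exact integer binomial weights. One-sided = the smaller tail containing
the observed table; two-sided = total probability of all tables no more
probable than observed (point-probability rule, with a 1+1e-7 relative
slack for interface parity with mainstream packages — with integer
weights the comparison is exact anyway). The 2×K test enumerates all
tables with the observed margins (guarded by a 10⁷-table budget) and
reduces to the two-sided 2×2 test at K = 2. Pearson chi-squared is also
reported for completeness. Every comparison carries both sidedness
conventions because small surgical series in the clinical literature mix
them: the analysis layer records, per comparison, the convention that
reporting tradition uses (one-sided for the pattern/resection/concordance
tables, two-sided point-probability for the SEEG tables) and exposes both
raw values. One subgroup comparison (single-cluster, MEG + MRI and EEG)
is flagged in the report because no standard convention reproduces the
value historically attached to that table; the report publishes both
computed values instead.

Outcomes dichotomize as Engel I (seizure-free) vs II–IV by default — the
split every cohort table uses; an Engel Ia-only rule is available as an
option and requires subclasses on class-I entries.

## Synthetic cohorts

The generator consumes a per-patient roster (pattern, resection status,
Engel class, per-modality concordance category, SEEG categories) and
realizes each patient geometrically:

* clusters are Gaussian clouds (σ = 3 mm) around the deepest point of a
  gyrus, rejection-sampled into the gyrus and resampled until they form
  one single-linkage component at 10 mm (a planted "cluster" must
  actually be a cluster); straddling patients are seeded on the centroid
  of the shared interface of two adjacent gyri;
* multiple-cluster patients get two such clouds in non-adjacent gyri
  ≥ 20 mm apart; scattered patients get 2–3 lone sources in mutually
  non-adjacent gyri;
* moments are tangential, 250 nA·m — a typical averaged interictal-spike
  ECD strength, giving ~200–900 fT rms topographies at the sensors;
  default channel noise is 40 fT, representative of a well-averaged
  spike map;
* each source's topography is simulated, fitted and GOF-filtered, so the
  emitted dipole tables have passed the same inverse stage a real
  workflow applies;
* complete resections are unions of 8-mm balls around every target
  (distance 0 by construction); noncomplete resections either cover only
  the first gyrus's group (when targets span several gyri) or are
  displaced to another gyrus of the same lobe, and the construction is
  verified to leave ≥ 1 target beyond the 10-mm tolerance;
* modality lobe sets are constructed relative to the lobes the planted
  sources implicate (e.g. "concordant with extra lobe" = one MEG lobe
  plus one lobe outside both MEG and resection), SEEG contacts are
  placed in the gyri the roster marks as sampled, and the SOZ is a
  superset (complete) or partial overlap (partial) of the MEG gyri.

The ground-truth label table is returned separately from the records, so
the pipeline can be scored blind. Identical config and seed give a
byte-identical serialized cohort.

The packaged roster (`data/study_roster.json`, loaded by
`study_cohort_config`) is one hand-constructed joint assignment of 39
patients that simultaneously realizes the pattern × resection × outcome
cells, all single- and multi-modality concordance margins, the
single-cluster subgroup tables, the MRI–resection-discordance subgroup
and the SEEG sampling/SOZ tables of the reference series. The
reproduction config runs the measurement simulation noiselessly so the
realized cohort equals the configured one exactly; cohort generation at
the default 40-fT noise is the condition under which the ≥ 95%
label-recovery property is checked (in practice recovery stays at or
near 100%: the fit errors of 1–3 mm are small against the 10-mm linkage
radius, the gyrus-interior planting margins and the 10-mm resection
tolerance).

What the generator does **not** emulate: realistic head geometry (BEM),
gradiometer physics, spike waveform morphology and averaging,
mislocalization from extended or deep sources, inter-reader variability
in spike marking, or anatomically realistic gyral shapes. Passing tests
therefore demonstrate internal correctness and robustness of the rules
and statistics, not clinical performance on real recordings.

## Numerical choices and problem sizes

* Lead-field grid: 10-mm spacing, 5-mm surface margin (~2.5 k nodes for
  the default sphere), built once per array and cached.
* Fit tolerances: `xatol` 1e-3 mm, `fatol` 1e-6 on the normalized
  residual; refinement confined to radius − 2 mm.
* Distance fields and region growth on 76³ voxel grids at 2.5 mm.
* The test suite fits a few hundred dipoles (two full 39-patient cohort
  regenerations plus 100 single-source round trips) and sweeps all 2×2
  tables with N ≤ 40 against an enumeration oracle; it completes in a few
  minutes on one core, as does the acceptance script.

## Known limitations

* The sphere/radial-magnetometer forward model cannot be compared
  quantitatively against vendor ECD outputs; only internal round-trip
  correctness is claimed.
* The Voronoi parcellation has convex regions and a small gyrus count;
  adjacency is denser than in a real atlas, which makes the
  "non-adjacent gyri" requirements *harder* to satisfy, not easier.
* The roster fixes one joint realization of the reference margins; other
  joint assignments exist and are equally consistent with the published
  tables.
* Bilateral localizations are not a separate category (they classify as
  multiple clusters), and dipole orientation is not used anywhere in the
  classification.
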