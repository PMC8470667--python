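# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Structures and ensembles

A structure is an ordered list of atoms with PDB-convention names,
elements, and residue identity `(chain, residue number, insertion
code)` taken verbatim from the file — author numbering is never
rewritten, because gate residues, secondary-structure ranges and
region filters are specified in author numbering.  A trajectory couples
one topology to a frame stack with a frame spacing `dt` (ps) and an
absolute time origin `t0`; frame *i* sits at `t0 + i·dt`, so slicing an
analysis window twice equals one slice with intersected bounds.

Conventions where the formats leave room:

* **Alternate locations**: the highest-occupancy conformer is kept;
  ties go to the alphabetically first alt-loc id.
* **Insertion codes** are part of residue identity.
* **Hydrogens** are kept when present, never required; selectors expose
  a heavy-atom mode.  Crystal structures typically carry none.
* **Multiple chains** are analyzed jointly by default; every selector
  accepts a chain filter.
* **HETATM** records (ligands, waters, heme) are parsed but flagged
  non-protein; `strip_nonprotein` removes them and is idempotent.
* The residue count used as the per-100-residue denominator is the
  number of distinct standard amino-acid residues actually resolved in
  the topology.  Densities depend on this denominator; when the
  reference count should instead be a full construct length, an
  explicit override is accepted everywhere a density is computed.

PDB parsing and writing go through biotite; DCD and XTC frames are
attached to an existing topology through MDAnalysis coordinate readers
behind a format-adapter registry.  DCD round-trips float32
coordinates exactly; XTC is compressed and round-trips to ~10⁻³ nm.
No periodic-boundary handling is performed: inputs are assumed
whole-molecule/unwrapped, and a guard logs a warning when consecutive
Cα–Cα distances exceed 5 Å in the first frame.

## Salt bridges

Member atoms are the charged-group heteroatoms: Asp OD1/OD2 and Glu
OE1/OE2 (acidic); Lys NZ, Arg NE/NH1/NH2, His ND1/NE2 (basic).  Arg NE
is included alongside NH1/NH2, and His carries both ring nitrogens
regardless of protonation, because crystal inputs carry no protons and
His-mediated bridges are part of the phenomenology of interest.  His
can be excluded by flag; chain termini (N-terminal amine, OXT) can be
included by flag and default off.

A residue pair is *formed* in a frame when the minimum distance over
its O×N member-atom cross pairs is **≤ cutoff** (inclusive; default
3.2 Å).  Simultaneous multi-atom contacts count once — pair identity
is residue–residue.  Pairs formed in at least one frame enter the
inventory; the lifetime is the fraction of frames formed, converted to
ns by the trajectory duration.  Categories: short < 2%, medium 2–20%
with both boundaries inclusive, long > 20%.

Two densities are reported: the distinct-pair density
`100 · n_pairs / n_residues` (rounded to one decimal when reported as
a headline number) and the per-frame density series, whose time average
is the default density for family-scale comparisons of short
trajectories.  The per-frame series counts bridges formed in each frame
(no smoothing window).

## Flexibility descriptors

**Superposition.** Rigid-body fits use the Kabsch construction via
SVD of the weighted cross-covariance, with the reflection branch
suppressed (det R = +1), vectorised over frames.  Trajectory alignment
is two-pass: fit every frame to frame 0 on the alignment selection
(default: all Cα), compute the mean structure of the fitted frames,
re-fit everything to that mean.  A frozen ensemble is returned
unchanged, making "frozen ⇒ zero fluctuation" exact.

**RMSF** is per residue: the squared displacement of the residue's
selected atoms (default one Cα) about their time-mean positions,
averaged over frames and atoms, then rooted.  The protein-level
summary is the arithmetic mean over residues.  Secondary-structure
aggregation averages per-residue RMSF inside named author-numbered
ranges; overlapping ranges are computed with a warning.

Because the fitted rotation and translation absorb six degrees of
freedom, the RMSF of an ensemble of independent Gaussian displacements
with per-axis σ recovers σ√3 only up to a shrinkage factor
≈ √(1 − 6/3N) for N fitted atoms — about 1% at N = 100, 5% at N = 20.
Recovery tests therefore use chains of ≥ 100 residues.

**MSD.** MSD(τ) averages |r(t+τ) − r(t)|² over selected atoms (default
heavy atoms; a Cα or name-list selector can mimic other observables)
and over strided time origins, at most 1000 origins per lag.  The
default lag grid is log-spaced, 20 points per decade over 10 ps–10 ns,
truncated to the trajectory length; lags incommensurate with `dt` are
rounded to the nearest frame with a warning.  For i.i.d. Gaussian
frames the curve plateaus at 6σ² = 2·(RMSF)², which links the two
descriptors and is asserted as a cross-check.

**Gate distance** is the per-frame Euclidean distance between two named
atoms (default the Cα of each named residue, since gates are specified
by residue).  All scalar fluctuations are sample (n−1) standard
deviations, returned as exactly 0 for constant series.

## Pocket volume

The inclusion region is a union of user-defined spheres — automatic
pocket detection is out of scope, matching how grid-based pocket tools
are used in practice.  A cubic lattice at `grid_spacing` (default
1.0 Å), anchored at the first sphere centre, covers the region; every
point within `vdw(element) + padding` of any atom is deleted.  The vdW
table defaults to Bondi-style radii (H 1.20, C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, other 1.70 Å) and the padding to a water-probe-like
1.09 Å; both are configurable.  With contiguity on (default), only the
6-connected component containing the lattice point nearest the seed
(default: first sphere centre) is kept; a seed whose nearest point was
deleted raises an error suggesting a seed move.  Volume = surviving
points × spacing³.

The lattice is fixed in space and does not follow the protein, so
trajectory series require aligned frames (guarded by a flag).  The
estimator carries a surface-discretisation error of order one voxel
shell; the empty 5 Å sphere at 0.5 Å spacing is within 0.5% of the
analytic 4/3·π·r³, and halving the spacing changes it by < 1%.
Comparisons against the continuum Monte-Carlo oracle use a finer
0.12 Å grid so that discretisation sits below the Monte-Carlo standard
error.

## Elastic-scan MSD

The elastic intensity of a scan at one temperature is modelled as
`ln I(q) = a − (MSD/6)·q² + c·q⁴`: the Gaussian approximation with the
leading non-Gaussian (quartic) correction.  MSD = −6 × (q²
coefficient) of an ordinary least-squares fit on the design (1, q²,
q⁴) over the window [0.25, 1.75] Å⁻¹ by default; the standard error is
propagated from the coefficient covariance.  A convention switch
reports the displacement variance ⟨u²⟩ = −3b (= MSD/2) instead, since
both factor conventions circulate in the literature.  Weighted fits
(inverse variance on ln I) are used when the scan carries
uncertainties.  The fit is exact on any noiseless scan from the model
family, invariant to intensity rescaling, and window-stable on model
scans.  Multi-temperature tables optionally normalise every scan by
the lowest-temperature scan (removing the static structure factor)
before fitting.

## Family correlation

Each protein is summarised by the chain
strip → window slice → align → salt-bridge densities → mean RMSF →
gate fluctuation → pocket fluctuation, with each stage's parameters
recorded in provenance and stage failures reported with the stage
name.  The gate and pocket sections are optional; missing descriptors
are handled pairwise (not listwise) in the correlation stage, with
excluded counts logged.  Pearson's r is computed per descriptor pair
over proteins carrying both values; fewer than three complete pairs
skips that correlation with a warning, and constant inputs raise an
error rather than returning NaN.  Per-category descriptor means and
counts accompany the correlations.  Category labels are user-supplied
manifest data; no taxonomy inference is attempted.

For families of short equilibrated trajectories the default density is
the time-averaged per-frame count over the analysis window; the
distinct-pair inventory density is always carried alongside, because
over long trajectories the inventory keeps growing with rare contacts
while the per-frame average stays stationary — the two answer
different questions.

## Synthetic generators

The generators emulate exactly the statistical structure the analyses
assume, no more:

* **Toy proteins** are extended Cα chains (3.8 Å spacing) with
  single-point pseudo side-chain charged atoms carrying correct PDB
  atom names.  Detection depends only on named-atom distances, so this
  is sufficient; nothing about real side-chain geometry or packing is
  represented.
* **Gaussian ensembles** add i.i.d. per-axis normal displacements of
  known per-residue σ to the reference (RMSF = σ√3, MSD plateau =
  6σ²).  Frames are temporally independent by default — lifetimes are
  unaffected by autocorrelation — with an optional AR(1) switch for
  MSD-shape tests.
* **Programmed bridges** draw an independent Bernoulli per frame at
  the target occupancy; member atoms of both partners are pinned to
  reference geometry and the basic nitrogens placed so the minimum
  O–N distance is exactly 2.8 Å (formed) or 6.0 Å (broken), straddling
  the 3.2 Å cutoff.  The realized formed series is returned as ground
  truth.  Bridge partners are spaced ≥ 4 residues apart so stray
  contacts between different charged groups are geometrically
  excluded at realistic σ.
* **Families** (default n = 146, mirroring a family-wide survey of one
  short run per protein) draw densities uniformly on 2–8 bridges per
  100 residues, realised as ⌊d⌋ always-formed bridges plus one
  fractional-occupancy bridge on a 100-residue chain, and set each
  protein's σ so that mean RMSF = 2.0 − 0.1·density + N(0, 0.3437) Å.
  The noise s.d. is derived analytically from the programmed
  population correlation: for uniform densities (variance 3) and slope
  −0.1, r = −0.45 requires σ_noise = 0.1·√3·√(1/0.45² − 1) = 0.3437.
  Each member is a 20 ns ensemble (500 frames at 40 ps) of which the
  second 10 ns is the analysis window, mirroring a short equilibrated
  production run.  Proteins in the denser half are labelled Bacteria,
  the rest Animalia.  What passing recovery tests shows is that the
  pipeline measures these programmed quantities without bias at this
  noise level — not that real proteins behave like independent
  Gaussian beads.
* **Elastic scans** invert the fit model exactly, with multiplicative
  log-normal noise.

All generators are deterministic under a fixed seed (bit-identical
outputs); the bridge Bernoulli stream is seeded separately from the
noise stream so adding bridges does not reshuffle the displacements.

## Problem sizes and tolerances

Verification runs are sized so each stage's estimator noise sits well
inside its tolerance: 10 000 frames for occupancy recovery (binomial
99% intervals), 4000–5000 frames for RMSF/MSD (≤ 5% bands), 10⁶
Monte-Carlo samples for pocket volumes (3-standard-error bands), 50
replicates for the noisy elastic fit (2% on the mean), and 50 seeds of
the 146-protein family for the correlation band (±0.10 covers the
sampling distribution of r at n = 146, which has s.d. ≈ 0.066 at
ρ = −0.45 — the band is inherently close to the 90% coverage level).
Command-line smoke tests use reduced family sizes (5–8 proteins, tens
of frames) since they exercise plumbing, not statistics.

## Known limitations

* Headline numbers from cluster-scale studies of real CYP450s
  (densities near 7.4 vs 3.5 for specialist vs generalist, family
  correlations near −0.4) are not reproducible from desk-scale
  synthetic inputs; the package verifies the estimators, not those
  values.
* The quartic-corrected OLS is one member of the family of "q⁴"
  elastic-scan estimators; published variants differ in weighting and
  window handling, so absolute MSD values from different tools can
  differ by a convention factor.
* The pocket grid inherits the usual POVME-convention ambiguities
  (anchoring, connectivity); results at matching spacing/padding are
  comparable within a voxel shell, not identical.
* At large per-axis σ (≳ 1 Å) a nominally broken programmed bridge
  can transiently satisfy the cutoff through its second oxygen; the
  generator pins bridge-member atoms to reference geometry precisely
  to exclude this, so realized occupancy is exact by construction.
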