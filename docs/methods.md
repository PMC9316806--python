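# Methods

## Scope and data model

`tetrastab` analyzes the quaternary stability of a four-chain bundle —
canonically the p53 tetramerization (TET) domain, a dimer of dimers with
chains paired A–B and C–D — from trajectory data, and quantifies the
functional consequence of destabilizing mutations from reporter-assay
plates.  It does not run molecular dynamics: trajectories are inputs
(DCD or a plain-text multi-frame dialect), assumed solute-only and
whole.  Simulation provenance (force field, thermostat, box) can be
recorded as `MDProvenance` metadata but never influences any
computation.

Internal units are Ångström for coordinates and nanoseconds for time;
conversion happens only at I/O boundaries.  Residues keep the author
numbering of the input PDB (canonical p53 numbering: Arg337, Asp352) and
are never renumbered.  Histidine force-field dialects (HID/HIE/HIP,
HSD/HSE/HSP) are collapsed to HIS for addressing, because protonation
variants of the same mutation must select identically; the tautomer is
metadata on the `SystemLabel`.  Atomic masses come from a frozen
internal table so mass-weighted centers are bit-for-bit reproducible;
an element missing from the table is a hard error, never a default.

## Rigid superposition and RMSD

The minimized RMSD uses the Kabsch closed form: SVD of the weighted
cross-covariance of the centered point sets, with the reflection branch
corrected by the determinant sign so only proper rotations are returned.
The residual is evaluated *explicitly* after applying the fitted
rotation rather than via the `E₀ − 2Σσᵢ` identity, which suffers
catastrophic cancellation for near-identical large-coordinate sets; the
explicit form is exact at zero and stable to ~1e-12 Å.

Degenerate inputs (coincident or collinear point sets, which leave the
rotation underdetermined) are rejected by an eigenvalue-rank check on
the weighted spread, tolerance 1e-8 relative.  Planar sets are fine.

Defaults, chosen where the underlying analysis convention is not fixed
by the data:

* selection — Cα atoms of all chains, uniform weights.  Cα is the
  standard whole-fold stability readout and is insensitive to
  side-chain differences between mutants; mass weighting is available.
* reference — frame 0 of each system's own trajectory, so each system's
  drift is measured internally and sequence differences between systems
  are not conflated into the RMSD.  An external reference `Structure`
  (e.g. the minimized starting model) can be passed instead; the
  synthetic-validation tests use the clean generator reference, for
  which the closed-form expectation below holds.
* histograms — 50 bins by default; a pooled range can be passed so
  several systems share bin edges in overlays.  A constant series gets
  one unit-width bin so the density still integrates to 1.
* equilibration — no frames are discarded by default; a frame range is
  a config option (`Trajectory.slice_frames`).

## Salt-bridge geometry

Functional groups are fixed heavy-atom sets per residue type: ARG
{NE, CZ, NH1, NH2}, ASP {CG, OD1, OD2}, HIS {CG, ND1, CD2, CE1, NE2},
CYS {SG}, GLU {CD, OE1, OE2}; user-overridable.  Hydrogens are excluded
even if present so that protonation variants (identical heavy-atom
groups) are directly comparable.  Listed atoms missing from a residue
are skipped with a warning, but at least one must resolve.

For each chain pair (X, Y) the two ordered arrangements i-in-X/j-in-Y
and i-in-Y/j-in-X are kept distinct, never pooled — the reciprocal
bridges of a dimer can break independently.  Occupancy is the fraction
of frames with group-COM distance at or below a cutoff.  The default
cutoff of 4.5 Å is the conventional charged-group interaction threshold;
it is an explicit parameter everywhere (the two-state validation uses
6 Å, the midpoint between its 3.5 Å bound and 9 Å unbound state means).
Occupancy is monotone nondecreasing in the cutoff by construction.

## Contact maps

Contacts are scored with the rational switching function
C(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ), m > n, using one representative
point per residue (Cα by default, mass-weighted heavy-atom COM as an
option).  Defaults r₀ = 8.5 Å, n = 6, m = 10 are the conventional
Cα-contact parameterization of this functional form; all three are
explicit configuration.  The removable singularity at r = r₀ returns
the limit n/m (|r/r₀ − 1| < 1e-12); the function is strictly decreasing
and decays as (r/r₀)^(n−m) — note that with the default exponents the
tail is only ~1e-4 at 10·r₀ and reaches 1e-5 beyond ~18·r₀.

Maps are exactly symmetric with diagonal 1 by convention; averages are
elementwise over frames.  Difference maps are elementwise
|target − reference| with zero diagonal, and require byte-identical
residue label lists (chains in topology order, residues ascending);
any mismatch is an error naming the first discrepancy — silent
realignment would corrupt the comparison.  Because maps are built on
representative atoms, WT and mutant maps are comparable despite
different side chains at the mutated position.

Flagging: a residue is flagged when the maximum over its row of the
difference matrix reaches the threshold (default 0.25, the lower end of
the conventional 0.25–0.5 reading band); a per-pair rule and an option
to ignore same-chain |i−j| ≤ 2 neighbors (default off) are available.
Reports are sorted by descending per-residue maximum, name as
tie-break.

## Stability verdict and ranking

The per-system profile aggregates mean/std RMSD, per-arrangement
occupancies, the flagged-residue count, and the mean absolute contact
difference.  A target is called **destabilized** against a reference
when any of: mean RMSD exceeds the reference's by ≥ 0.5 Å; occupancy
drops by ≥ 0.3 in at least two ordered arrangements (an interface is
considered lost only when detected in at least two residue pairs); or
at least one residue is contact-flagged.  These thresholds are an
explicit operationalization of otherwise qualitative judgments — there
is no accepted quantitative destabilization metric — and all live in
`ReportConfig`.  Raising any threshold can only move verdicts toward
WT-like.  Ranking is a stable sort by severity (mean-RMSD excess, or a
composite) with lexicographic name tie-break.

## Synthetic generator

The generator is a statistical fixture factory, not an MD surrogate.
The toy tetramer is four idealized helical Cα traces (rise 1.5 Å/residue,
helix radius 2.3 Å, 100°/turn) antiparallel on a cylinder of radius
8.5 Å, 41 residues per chain numbered 320–360.  Position 337 of each
chain carries a guanidinium-like group and position 352 a
carboxylate-like group, placed so the reciprocal group-COM distances
across each primary dimer are exactly 3.5 Å in the reference (a typical
formed salt-bridge distance); placements that would collide with the
backbone raise a construction error.  The same structure serves as the
package's synthetic stand-in for deposited TET-domain coordinates where
a static bridge count is validated — synthetic geometry, not
experimental data.

Trajectory models, all reproducible from one integer seed:

* **stable** — frames are the reference plus iid per-coordinate
  Gaussian noise of scale σ.  There is no covariance structure; this is
  deliberately the simplest model with closed-form expectations.  The
  minimized RMSD against the clean reference then concentrates at
  √3·σ (the per-atom displacement norm has second moment 3σ²; the ~6
  degrees of freedom absorbed by superposition bias this down by
  < 1% at ≥ 150 fitted atoms).
* **drift_open** — additionally translates the second chain of each
  selected pair along the interface normal, linearly 0 → `open_shift`,
  a progressively separating interface.
* **two_state** — per-frame Bernoulli bound/unbound (bound probability
  p) with the unbound state shifted by `open_shift`; the default 5.5 Å
  takes the 3.5 Å bridge to a 9 Å open state.  Occupancy estimates then
  have an exact binomial reference: at 2000 frames, ±0.03 is ≈ 3
  standard errors around p = 0.7.
* **perturbed segment** — a residue range of one chain rigidly displaced
  radially outward in every frame, giving known ground truth for
  contact-difference flagging.

What passing these validations shows — and does not.  They establish
that the estimators are unbiased and correctly calibrated under known
perturbation models of the right geometry and magnitude.  Real MD has
correlated fluctuations, anisotropic interfaces, side-chain rearrangements
and slow relaxation that the generator deliberately omits, so recovery
here does not certify statistical power on real trajectories; it
certifies the arithmetic and the detection logic.

Reporter plates: each well reads OD × (background + dose-scaled
activity) × lognormal noise with mean-1 noise factor of coefficient of
variation `noise_cv`; OD uniform in [0.3, 0.8]; empty-vector wells carry
activity 0.  Defaults: 5 transformants per allele (the assay's standard
replication), activity scale ~100, background 10 — an order of magnitude
below a strong allele, consistent with a low reporter-independent
expression.  The noiseless plate round-trips exactly through the
analysis pipeline.

## Transactivation analysis

Normalization is luminescence/OD600 per well; background is the mean of
the matched empty-vector wells per (strain, dose) — the lowest-variance
unbiased choice where a pairing scheme is not recorded.  Negative net
values are retained (clipping would bias means near background) and
flagged.  Aggregation reports t-based 95% confidence intervals
(configurable level) and fold = allele mean / WT mean at the same
strain and dose.

Many-to-one testing uses Dunnett's procedure: pooled within-group
variance and the many-to-one multivariate-t reference distribution
(scipy's implementation, quasi-Monte-Carlo integration seeded for
reproducibility).  With a single treatment group the procedure is
mathematically the two-sided two-sample pooled-variance t-test, and
that closed form is used directly — it is exact where the QMC
integration is only approximate.  Stars follow the conventional tiers
(* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001, ns).  Under the null
(3 groups, n = 5) the simulated family-wise error rate at nominal 5%
stays within Monte-Carlo noise of 0.05.

The statsmodels-style surface (`TransactivationModel.from_dataframe(...)
.fit() → TransactivationResults.summary()`) wraps the same functions;
replicates are analyzed per transformant (not pre-averaged), since the
transformant is the independent biological unit.

## Numerical choices and problem sizes

* Kabsch degeneracy tolerance 1e-8 (relative eigenvalue rank check);
  rigid-motion invariance holds to 1e-9 Å on synthetic sets.
* Validation problem sizes: 200-frame trajectories for scale recovery,
  2000 frames for occupancy (binomial ±0.03), 100 replicates for
  ranking recovery, 1000 replicates for the Dunnett null, 50 random
  configurations against the rotation-grid brute-force oracle
  (hierarchically refined to 0.48°).  These sizes make every
  Monte-Carlo bound a ≥ 3-standard-error statement while keeping the
  full validation suite around ten seconds.
* Determinism: one explicitly seeded generator per simulation call;
  reruns of the full pipeline produce byte-identical summary JSON.

## Known limitations

* The iid-Gaussian fluctuation model has no physical kinetics; time
  stamps are bookkeeping.
* Contact maps offer Cα and residue-COM representations only; no
  all-heavy-atom minimum-distance definition.
* No RMSF, per-residue RMSD decomposition, conformational clustering,
  free-energy or ΔΔG estimates; His protonation enters only as distinct
  labelled systems.
* Dose–response is analyzed per dose; no curve fitting across galactose
  levels.
* PDB only (no mmCIF); DCD is the supported binary trajectory format.
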