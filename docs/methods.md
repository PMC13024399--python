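# Methods

## The deviation map

For a CT volume and a binary left-ventricular myocardium mask, every
in-mask voxel is mapped to

    map(v) = (HU(v) − μ) / ν

where μ is the mean attenuation over *all* in-mask voxels and ν is the
population (divide-by-n) variance of the in-mask values after trimming to
the closed interval [Q10, Q90] of their empirical distribution.
Quantiles use the standard linear-interpolation definition, and the trim
is inclusive of both boundary values. The subtracted mean is deliberately
not trimmed, so the in-mask map mean is exactly zero.

Design choices worth stating:

* **Variance, not SD, as the default divisor.** The map then carries
  units HU⁻¹, which is unusual; a `normalizer="sd"` option yields the
  dimensionless z-score form. The default matches the normalization that
  deviation colormaps of this kind use; the two differ only by a global
  scale per scan, so rendering and rank-based analyses are unaffected by
  the choice. Note that under variance normalization the lesion–remote
  separation is *not* monotone in lesion contrast (the divisor grows
  quadratically with the lesion offset); the z-score form is monotone and
  is what the monotonicity test asserts.
* **Numerical anchoring.** Values are anchored at their in-mask minimum
  before any reduction. Mathematically a no-op; numerically it makes the
  map's shift invariance hold bit-for-bit for integer HU inputs (CT data
  are integer-valued), not merely to rounding error.
* **Degenerate input.** A constant myocardium (or a trim that leaves
  fewer than two values) gives a zero divisor; the map is then defined as
  all-zero with a `RuntimeWarning` instead of raising, so batch pipelines
  survive pathological cases. Out-of-mask voxels carry NaN, never 0, so a
  renderer can distinguish "no deviation" from "not myocardium".
* **Rendering.** The overlay is a symmetric diverging map: blue for
  negative deviations, red for positive, alpha proportional to |value| up
  to a clip, exactly transparent at zero. The default clip is the
  equivalent of ±3 SD (3/√ν map units under variance normalization).

## The phantom

The generator produces the features the pipeline consumes, not cardiac
anatomy: two concentric ellipsoids define a blood pool (350 HU) and a
myocardial shell of 10 mm radial thickness (100 HU) over a −50 HU
background, with i.i.d. Gaussian noise (default SD 10 HU). At the default
64³ grid of 1.5 mm voxels the field of view is 96 mm and the shell holds
roughly 33,000 voxels.

Lesions are wedges of the shell in the short-axis plane: territory
centers at 90° (LAD, anterior/septal), 0° (CX, lateral) and −90° (RCA,
inferior) with a 40° half-angle. Subendocardial lesions are restricted to
voxels within half the shell thickness of the blood pool (Euclidean
distance transform in mm); transmural lesions span the full thickness.
Lesion voxels are offset by −80 HU by default, the upper end of the
attenuation difference reported for acute infarction. Cohorts assign
transmural lesions to STEMI cases and subendocardial lesions to NSTEMI
cases, with territories drawn uniformly.

The "automatic" myocardium mask is the truth mask degraded by iterative
random boundary flips (equal-probability removals from the inner boundary
and additions on the outer boundary) until the Dice score against the
truth first drops to the target (default 0.973, emulating the agreement
between an automatic deep-learning segmentation and its manual revision).
Each flip moves Dice by ~1/|mask|, so on realistic shells the achieved
score is well inside the ±0.005 acceptance band; on masks too small for
that, the generator raises rather than silently approximating.

What the phantom does **not** model: cardiac anatomy and motion, ECG
gating, contrast kinetics, beam hardening, scanner-specific
reconstruction, partial-volume effects, or spatially correlated noise.
Tests passing on phantoms therefore validate the *computational* pipeline
(normalization, masking, statistics), not clinical detectability of real
lesions.

## The simulated reader panel

Readers are simulated as independent Bernoulli processes at specified
operating points: P(rating "yes") equals the reader-condition sensitivity
on lesion cases and 1 − specificity on lesion-free cases. The certainty
category is drawn on the side of the rating ("yes" splits evenly between
"probably yes" and "definitively yes"; "no" likewise), so the
"intermediate" category is never emitted by simulation — a deliberate
simplification. The assigned territory is the true culprit territory for
true positives, a uniform draw among RCA/LAD/CX for false positives, and
"none" for "no" ratings. Reading times are log-normal (σ = 0.5) around
per-condition medians of 27 s (without overlays) and 25 s (with), the
medians reported for human readers.

The default panel adopts the per-reader, per-condition
sensitivity/specificity of the six human readers of the reference reading
study (see `myomap.datasets`), so the default synthetic study spans the
same range of reader behavior. This model has no case-difficulty or
reader-correlation structure: all readers err independently, which makes
variance across simulated readers smaller than across human readers.

## The MRMC design and statistics

The design is a crossed two-session crossover: readers are randomly split
into two groups, cases into two ordered halves (first ⌈n/2⌉ and the
rest); in session one each reader group sees one case group with overlays
and the other without, and session two crosses the conditions. Every
reader reads every case exactly once per condition — 6 readers × 119
cases × 2 = 1428 readings at the default study size.

* **Diagnostic metrics** are plain ratios from the per-reader 2×2 table
  (positive reading = "yes"; positive case = adjudicated STEMI or
  NSTEMI), computed at full precision; ratios with zero denominators are
  NaN, never 0. Percent rounding happens only at the reporting layer.
* **McNemar's test** on the paired with/without ratings (restricted to
  cases for the sensitivity comparison, non-cases for specificity): exact
  two-sided binomial when the discordant count b+c < 25, chi-square with
  continuity correction otherwise; the variant used is recorded in the
  result.
* **Cohen's kappa** is unweighted on the binary rating; the five ordered
  certainty categories use linear weights. Both raters constant and
  identical is reported NaN (undefined), not 1.
* **Binary NRI** = (up_e − down_e)/n_e + (down_ne − up_ne)/n_ne, range
  [−2, 2] for the two-part sum. Denominators default to the cell sums of
  the reclassification table but can be supplied explicitly: the shipped
  worked example's stated totals (49 events / 70 non-events) disagree
  with its cell sums (50 / 69), and only the stated totals reproduce its
  published value of 0.21 (cell sums give 0.20). The printable table
  reports both variants with a caveat rather than hiding the discrepancy.
* **Territory metrics** pool all readers; a reading is territory-T
  positive only if it is a "yes" *and* assigns territory T, i.e. a
  correct detection with a wrong territory does not count as a
  territory-level true positive.
* **Reading times** are compared with the two-sided Wilcoxon signed-rank
  test on reader×case pairs — chosen because the times are paired and
  right-skewed; all-zero differences return p = 1.

## Reproducibility

Every stochastic operation takes an explicit seed and is bit-reproducible
given it. The pipeline's single seed fans out to per-stage seeds (cohort,
design, readers) via `numpy.random.SeedSequence`, so stages can be re-run
independently. CSV reports from identical config+seed are byte-identical;
the SHA-256 of the canonical YAML config is written into the run's
provenance manifest. Default problem sizes — 119-case cohorts on 64³
grids, 10,000-case panels for operating-point recovery checks — were
chosen so a full synthetic study runs in seconds on a single CPU.

## Known limitations

* Phantom realism is bounded as described above; no claim about human
  detection performance follows from simulation.
* The reader model ignores case difficulty, reader learning and
  correlation between readers; kappa values from simulated panels are
  therefore systematically near the chance-adjusted independence level.
* ROC/AUC variance-component MRMC models (DBM / Obuchowski–Rockette) are
  out of scope; the suite reports the fixed-reader statistics listed
  above.
* NRI confidence intervals are not computed.
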