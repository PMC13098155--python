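# Methods

`nodusym` quantifies and compares the symbiotic efficiency of the two major
bacteroid developmental fates — terminally differentiated, swollen
bacteroids in indeterminate (pea-type) nodules versus undifferentiated,
rod-shaped bacteroids in determinate (bean-type) nodules — by chaining four
measurement models and expressing every physiological rate across a common
set of normalization denominators. This note records the models, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Nodule volumes from 2-D sections

Determinate nodules are modelled as spheres. A longitudinal section
provides the section area A and Feret's diameters F_dmax/F_dmin; for a
great-circle section of a sphere, A = πr² and F_d = 2r, so

    V = (2/3) · A · F_d.

The max- and min-Feret estimates are computed separately and averaged
*after* volume computation. An alternative `convention="radius"` evaluates
V = (4/3)·A·F_d, which is the same sphere only if F_d is read as a radius;
it is retained because field protocols differ in how the caliper diameter
enters the formula, but the diameter convention is the default because
Feret's diameter is, by definition, a diameter, and because cohort-level
calculated volumes then agree with volumes measured independently by fluid
displacement.

Indeterminate nodules are modelled as a cylindrical infected body plus an
uninfected spherical cap at the distal (meristem) end. The cap is sized
from the chord c and sagitta h of its circular segment. With base radius
a = c/2 the textbook cap volume is

    V_c = (π/6) · h · (3a² + h²),

and the default `chord_mode="half_chord"` uses exactly this; the
`full_chord` mode substitutes c for a. Only the half-chord form satisfies
the hemisphere identity (c = 2r, h = r ⇒ V = (2/3)πr³), and it is verified
in the tests against direct quadrature of the cap's circular cross
sections over 50 random shapes (agreement to 0.5%). The body volume uses
the average width d = A/l_c of the section:

    V_b = A · d · π/4 = (π/4) A²/l_c,

exact for a rectangular axial section of a true cylinder. Total volume is
V_n = V_c + V_b, the infected zone V_iz is the analogous inner cylinder,
and the infected volume is V_i = V_iz · f_c, where the fractional
colonization density f_c = A_i/A_iz is the fraction of infected-zone
section area occupied by fluorescently marked, actively fixing bacteroids.
Upstream image processing (background subtraction, CLAHE, thresholding) is
out of scope: the pipeline consumes measured areas and lengths.

Assumption worth stating: for spherical nodules, the infected zone is
sized from its *own* Feret pair rather than scaled from the whole-nodule
sphere; the measurement protocol provides both pairs, and using the zone's
own pair avoids assuming concentricity.

## Bacteroid census

Per-bacteroid volumes and surface areas come from manual segmentation of
serial block-face SEM stacks. Summaries report the mean of per-bacteroid
SA:V ratios, not the ratio of cohort means — the two differ for
heterogeneous cohorts, and the per-bacteroid convention matches how the
ratio is reported per cell. Segmentation tables are validated against the
isoperimetric inequality SA³ ≥ 36πV² (no closed surface has less area than
the sphere of equal volume).

Packing fractions are means of occupied/total volume over exhaustively
segmented subvolumes (8 × 8 × 2 µm by convention). Combining census and
geometry:

    total bacteroid volume per nodule = V_i × packing fraction
    bacteroids per nodule             = total volume × 10⁹ / mean single-bacteroid volume (µm³)
    protein density (pg/µm³)          = protein per bacteroid / mean volume

The mm³→µm³ factor 10⁹ lives in the unit registry and nowhere else.

Flow-cytometry enumeration of purified, fluorescently tagged bacteroids
applies three gates, all strict inequalities: FSC > 0, SSC aspect ratio
> 0.4 (singlets), fluorescence > 3,000 FI (the "yellow" population);
events on a boundary are excluded. The count is reported per ml of
analyzed volume.

## Fixation rates and the eight-scale normalization

Acetylene reduction is amount of ethylene over incubation time (µmol
C₂H₄/h). For ¹⁵N₂ assays, the isotopic signal per plant fraction is the
atom percent excess, APE = atom% − 0.36782 (natural abundance), floored at
zero with a warning — a reading below natural abundance is noise, not
negative fixation. Fixed N per fraction is

    N₂ fixed (µg/h) = (APE/100) · total N · 1/(4 · gas fraction),

the published "×5/4" factor at the standard 20% ¹⁵N₂ atmosphere
(`literal` mode, the default, which inverts exactly to the reported
per-plant rates). Because 5/4 algebraically covers only part of the
stated corrections, a `strict` mode additionally divides by the incubation
time so each correction is applied exactly once and can be audited.
Fraction values (shoot, root, nodule) are summed per plant and converted
to µmol N₂/h with a molar mass of 28.0134 g/mol.

`normalize_rate` expresses a per-plant rate at eight scales: per plant,
per g shoot dry weight, per cm³ nodule volume, per mg nodule dry mass
(nmol/h/mg — some published tables label this per µg, but the printed
magnitudes are per mg), per mm³ infected volume (nmol/h), per bacteroid
(amol/h), per pg bacteroid protein, and per µm³ bacteroid volume. The
bacteroid-level scales are computed as an exact cascade —
per_bacteroid = rate/count, per_protein = per_bacteroid/p̄,
per_volume = per_bacteroid/v̄ — so the identities hold to machine
precision by construction. Group statistics can be formed either as
ratio-of-means or mean-of-ratios; both are exposed because published
summary tables mix the conventions, and ratio-of-means is the default per
the usual fold-change footnote.

## Absolute proteome quantification (top3 + Hi3)

From a merged MaxQuant-style modification-specific peptide table, a
protein's signal in a sample is the mean of its three most intense unique
peptides after filtering: no missed cleavages; modifications restricted to
none or methionine oxidation; a sequence observed in both modification
states contributes the sum. Proteins with fewer than three qualifying
peptides are dropped in strict mode (default) or averaged-as-available
with a flag. Dividing by the top3 signal of the spiked Hi3 standard
(12.5 fmol rabbit glycogen phosphorylase, accession PHS2_RABIT) gives
femtomoles loaded, and 6.0221413 × 10⁸ copies/fmol gives copies. Copies are
then expressed at five scales using host constants: per bacteroid (÷ B_D,
the bacteroids the 380 ng load derives from: 1,202,531 bean / 608,974
pea), per bacteroid volume (÷ 0.93 / 4.50 µm³), per nodule (× 5.28 × 10⁸ /
1.63 × 10⁸), per nodule volume (÷ 6.07 / 4.61 mm³), and per pg protein
(÷ 0.32 / 0.62). B_D is taken as an explicit constant rather than derived
from 380 ng / protein-per-bacteroid, which would give a slightly different
value (the published constant embeds an unrounded protein content).

Fold changes between hosts are ratios of group means at each scale, so
cross-scale identities (FC per volume = FC per bacteroid × v̄_bean/v̄_pea)
hold exactly; Welch's two-sample t-test runs on per-replicate
per-bacteroid copies, untransformed by default with a log option, and no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists). Replicate normalization is available as a documented
median-ratio procedure but is off by default; the headline quantities do
not depend on it. Proteome skew is summarized by ranking proteins by mass
fraction and reporting the smallest n reaching 50% of proteome mass;
distributions are compared with a two-sample Kolmogorov–Smirnov test, and
transcript–protein agreement with a Pearson correlation on (optionally
log-transformed) paired values.

## Synthetic data generator

The generator emulates every raw table the pipeline consumes, from a
ground-truth parameter set whose defaults are the published cohort means
with dispersions back-computed from reported standard errors and sample
sizes (CV = SE·√n/mean; 11 plants for biomass/ARA rows, 8 nodules for
infection geometry, 240/246 bacteroids for morphology, 6 isolations for
protein content, 9/10 plants for ¹⁵N₂). Strictly positive measurements
are lognormal (means are preserved exactly: µ = ln m − σ²/2); counts are
Poisson; zero CV degenerates to the exact mean, which is what makes exact
round-trip tests possible. One top-level seed fans out to fixed per-table
child seeds, so adding a table never perturbs another.

Choices made where no value is published, fixed once:

* colonization density f_c = 0.5 (CV 10%) for both hosts — mid-range for
  sections where roughly half the infected-zone area fluoresces;
* pea cap fraction 0.12 of nodule volume and body aspect ratio 3
  (length/diameter) — a small uninfected distal cap on an elongated body;
* fixation split across fractions shoot:root:nodule = 0.55:0.15:0.30 and
  per-fraction total N of 12/6/3 mg, used only to invert APE values so the
  assay stage recovers the planted whole-plant rates;
* peptide tables use five peptides per protein, an arbitrary instrument
  response of 10⁶ intensity units/fmol, decoy rows (missed cleavage,
  phosphorylation) and a split unmodified/Met-ox pair to exercise the top3
  filter; the protein panel plants per-bacteroid copy ratios equal to the
  published per-bacteroid fold changes for a set of nitrogenase, electron
  transfer and TCA-cycle enzymes.

Sections and packing tables are generated *geometrically consistent*: a
sampled nodule volume is converted to the exact section measurements of a
sphere or cap+cylinder of that volume, so the geometry stage inverts them
exactly at zero noise, and the bacteroid count implied by
infected fraction × packing × V_n / v̄ matches the census to <1%.

What the generator does not emulate: correlations between per-plant
variables (each is sampled independently, so e.g. heavy plants do not
preferentially carry more nodules), within-nodule spatial structure,
peptide-level missingness, and instrument saturation. Passing recovery
tests therefore demonstrates that the estimators are unbiased and
internally consistent under the stated noise model, not that they are
robust to every pathology of real measurements.

## Problem sizes and numerics

Default cohort sizes mirror the study (11 plants, 8 nodules, 240
bacteroids, 3 proteomics replicates); recovery tests that need the law of
large numbers use 200–1000 synthetic plants, and distribution tests use
the study's protein counts (184/197). Degenerate statistics are defined
explicitly: zero-variance groups yield p = 1 when means agree and p = 0
otherwise; APE below zero floors to zero; top3 ties are broken by the
stable descending sort of summed intensities (permutation-invariant).
Display rounding is three significant figures; all machine-readable
output is unrounded.
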