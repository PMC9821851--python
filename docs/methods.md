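# Methods

## Problem setting

Untargeted UHPLC-HRMS metabolomics of ginseng roots yields feature
tables of several thousand ions, each a unique (m/z, retention time)
pair. One metabolite contributes many features — adducts, charge states
— and general-purpose spectral databases return hundreds of irrelevant
candidates for saponin-sized masses. The package implements a
library-guided alternative: a compound-specific ion library is expanded
from neutral formulas, features are flagged by absolute mass tolerance,
split into ginsenoside/non-ginsenoside matrices, coalesced into
metabolite groups, annotated at the MS² level, and compared between the
two sample groups (wild vs cultivated roots).

## Ion library

**Masses.** Monoisotopic masses are sums of most-abundant-isotope
masses (C = 12 exactly, H = 1.00782503, O = 15.9949146, N = 14.0030740,
S = 31.9720707, Na = 22.9897693, K = 38.9637065, F = 18.9984032,
P = 30.9737615 Da, plus a few further elements for robustness). Formulas
are plain Hill strings without parentheses, isotopes or charges — the
form compound tables actually use. The parser rejects unknown symbols
and zero counts with the offending token named.

**Ionization convention.** m/z = (M + Δm)/z, with Δm assembled from
neutral adduct masses (HCOOH = 46.00548, CF₃COOH = 113.99286,
H₂O = 18.01056, NH₃ = 17.02655, Na = 22.98977, K = 38.96371 Da) and
proton transfers at the proton mass 1.00727646 Da; cation attachment
subtracts one electron mass. Using the proton rather than neutral-H
mass shifts singly charged ions by ~0.55 mDa — relevant at the 5 mDa
matching gate, and the convention that reproduces the curated measured
m/z values most closely.

**Default species.** Negative: [M−H]⁻, [M+HCOO]⁻, [M+CF₃COO]⁻,
[M−2H]²⁻, [M+HCOO−2H]²⁻, [M+2HCOO−2H]²⁻ — formic acid is the standard
mobile-phase modifier and trifluoroacetate a common system contaminant,
and large glycosides readily form doubly charged species. Positive:
[M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺, [M+H−H₂O]⁺, [M+2H]²⁺. Both sets are
user-extensible. Note that a doubly charged single-formate species
[M+HCOO−2H]²⁻ of a 1078.6 Da compound lies at 561.29, about 23 Th above
[M−2H]²⁻ — the enumerator matches species by value, not by whatever
label a vendor tool printed.

**Library queries** are binary searches over the m/z-sorted expansion;
row count is |compounds| × |enabled species|. Duplicate compound names
are rejected: positional isomers must carry distinguishable names.

## Feature matching and coalescing

Matching uses an absolute ±5 mDa window (ppm deviation is reported
alongside for diagnostics). Every feature with ≥ 1 candidate is matched;
candidates are ranked by |Δm/z| with a deterministic alphabetical
tie-break. Compounds with identical formulas (Rc/Rb2/Rb3; Rd/Re) tie
exactly at the MS1 level — the full candidate list preserves the
ambiguity, and identity beyond the shared formula is an MS²/RT question.

Coalescing merges matched features that share a best-candidate compound
and co-elute. Within each compound, groups are seeded from the most
intense remaining feature; every feature within ±(window/2) of the seed
RT joins, guaranteeing the within-group RT spread never exceeds the
0.2 min window. (Pure single-linkage at the window cannot give that
guarantee — chains can creep arbitrarily far — which is why the seeded
fixed-radius variant was chosen.) Unique-RT counting, by contrast, is
exact 1-D single-linkage: sort and cut where the gap exceeds the window.

## MS² neutral-loss chains

Peaks (plus the precursor, if not itself listed) form a DAG: an edge
connects a descending m/z pair whose difference matches a loss within
tolerance. Losses: glycosyl −Glc 162, −Xyl/Ara 132, −Rha 146, −GlurA
176 Da; acyl −Ace 42, −But 68, −Mal 86 Da; water 18 Da; formate adduct
dissociation 46 Da, admissible only as the first edge from the
precursor. Each loss carries nominal and accurate masses; nominal mode
(tol 0.5 Da) is the default because curated spectra are printed as
integers, accurate mode (tol 0.02 Da) suits instrument data. 132 Da is
deliberately left as Xyl/Ara — pentose regioisomers are not resolvable
by mass.

The chain is the longest path in the DAG (dynamic program over the
descending-m/z topological order). Among equally long paths the
tie-break prefers fewer distinct loss types, then higher summed fragment
intensity, then the lexicographically larger ion sequence — fully
deterministic. Peaks off the chain are reported as unexplained, never
force-fitted (e.g. the 569 ion in the chicusetsusaponin IVa reference
spectrum). Correctness of the search is pinned against exhaustive path
enumeration on small spectra.

The terminal ion calls the aglycone scaffold: 459 → protopanaxadiol
(PPD), 475 → protopanaxatriol (PPT), 491 → ocotillol (OT), 455 →
oleanolic acid (OA); accurate-mass counterparts are derived from the
sapogenin formulas (C₃₀H₅₂O₃/O₄/O₅, C₃₀H₄₈O₃) minus a proton. Two
classification modes exist because the strict reading differs from the
permissive one: `terminal` requires the chain to end at a diagnostic
ion; `any` accepts a diagnostic product anywhere (the parent-ion-mapping
reading). Identification defaults to `terminal`, bulk class tallies use
`any` when a spectrum is available and the library class otherwise.

## Differential statistics

Welch t-tests (two-sided, unequal variances) per feature on raw
intensities; fold change is the ratio of arithmetic group means (median
ratio was considered and rejected as the default because curated marker
fold values are mean-based; zero denominators are replaced by half the
smallest nonzero intensity in the table and flagged). Significance
tiers use inclusive thresholds (FC ≥ 1.5, p ≤ 0.05; highly significant
p ≤ 0.01); volcano selection uses strict ones (FC > 2, p < 0.05) — the
two stages are conventionally worded differently and are implemented
exactly as worded. No multiple-testing correction by default (raw
p-values are the field's reporting convention here); Benjamini-Hochberg
q-values are available via `welch_fold(..., fdr=True)`.

Autoscaling z-scores each variable across samples (population sd);
zero-variance rows become all-zero with a warning. PCA runs on the
autoscaled matrix (samples as observations) via full SVD; with all
components the reconstruction is exact to < 1e-8. Heatmap export is a
deterministic row permutation — ascending p-value, ties broken by
feature id — rendering is left to the user's plotting stack.

## Synthetic data

The generator emulates the study design the statistics target: 12 wild
vs 19 cultivated samples. Per planted compound: one feature per chosen
adduct species at theoretical m/z + N(0, 1 mDa) (mDa-scale error to
match the mDa matching gate), a shared retention time with jitter
clipped to ±0.05 min (a quarter of the coalescing window), per-sample
log-normal intensities (CV 20% default, mean-calibrated so realized
fold changes are unbiased), the group fold change applied
multiplicatively to the wild group, and fixed adduct intensity ratios
with the formate adduct strongest. Decoys are uniform in m/z but
rejected within 10 mDa (2× the gate) of any library ion, so any decoy
match is an unambiguous error. The default scenario plants the eleven
marker ginsenosides with fold changes spanning the reported marker
ranges (wild-favored 2.3–54.5×, cultivated-favored 2.6–14.4×).

What the simulation does **not** model: chromatographic peak shapes,
isotopologue envelopes, in-source fragmentation, intensity-dependent
mass error, missing values, or batch drift. Passing recovery tests
therefore demonstrates the correctness of the matching/coalescing/
statistics logic under the stated noise model, not robustness to every
artifact of real LC-MS data.

MS² simulation inverts the fragmentation rules: a glycan plan (acyl
losses first, then glycosyls — the order such compounds fragment) is
turned into a cumulative-loss ladder from [M−H]⁻, optionally behind a
formate precursor; the plan terminal must land on the compound class's
diagnostic ion. Round-tripping through the chain decomposer recovers
plans exactly.

## Problem sizes and determinism

All validation runs at desk scale: the seed library (28 compounds, 168
negative-mode ion rows), synthetic tables of 100–200 features, 1000-
feature null panels for test calibration, and 10–200 Monte-Carlo
replicates where a sampling distribution matters; the whole suite runs
in a few seconds. Every stochastic step draws from a seeded
`numpy.random.Generator`, and the CLI writes all numeric output at fixed
precision (m/z 4 dp, p-values 3 s.f. scientific), so repeated runs with
one seed produce byte-identical files.

## Known limitations

- MS1 matching cannot separate formula-identical isomers; candidate
  lists keep them all, and the deterministic tie-break means the group
  label for such compounds is an isomer-class representative.
- Fragmentation rules cover negative-mode glycoside chemistry only;
  positive-mode fragmentation is out of scope.
- The seed library is a validation set, not a comprehensive compound
  library; real studies should load their own.
- The 46 Da first-step rule treats any 46 Da difference from the
  precursor as formate dissociation; CO + H₂O (also 46) is not
  distinguished at nominal mass.
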