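# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter.

## In silico digestion

An amplicon is the subsequence spanning the forward-primer start through
the reverse-primer binding-site end, both primers included.  Primer
matching is IUPAC-aware sliding-window Hamming matching with a
configurable mismatch budget (default 0: synthetic sequences embed exact
primer sites).  The forward primer is taken at its first acceptable
match, the reverse (as its reverse complement) at its last acceptable
match downstream, so sequence appended after the reverse-primer site
never changes the result.  Coordinates are 0-based half-open; lengths
are integer bp.

For a labeled end, the terminal fragment runs from amplicon position 0
to the cut inside the *first* recognition-site occurrence on that
labeled strand (the reverse computation is the same scan on the reverse
complement).  Lengths are primer-inclusive: the dye sits on the primer
5′ end, and capillary sizing reports the full labeled fragment — the
reference clone table's magnitudes (e.g. 90 bp for an Aeromonas MspI
fragment) are only consistent with primer-inclusive lengths.  The three
default enzymes are MspI (C^CGG), HhaI (GCG^C) and HaeIII (GG^CC); all
three recognition sites are palindromic.  Signature slots are numeric
lengths or the sentinels `NO_CUT` ("NC") and `BELOW_WINDOW` ("<50");
both sentinels behave as one categorical class in matching, since a
below-window fragment and an uncut amplicon are equally invisible in the
50–550 bp export window.

The 1492R primer sequence is configurable; the packaged default is the
standard GGTTACCTTGTTACGACTT.  Fixtures and the synthetic generator do
not depend on the exact primer literal.

## Signature planting (the generator's inverse digest)

`plant_signature` stamps the primers, places recognition sites exactly
where the requested fragment lengths imply, fills the background
uniformly over {A,C,G,T}, and then rejects every accidental recognition
site anywhere in the sequence by re-randomizing free positions until a
scan finds none.  Compatible overlaps between two planted sites merge
(e.g. CCGG and GGCC sharing a G); incompatible demands raise a
constructive failure naming the conflicting slots.  Because the default
recognition sites are palindromic, a site cut on one strand is
necessarily present on the other: a target with one slot of an enzyme
numeric and the paired slot `NO_CUT` is infeasible by construction and
is rejected with an explanatory error.  Feasible random targets for
property tests are drawn so each enzyme is either fully silent or has
both sites inside the sizing window, pairwise separated by ≥ 8 bp.
Background composition makes no biological-realism claim; it exists to
guarantee signature correctness.

## Peak processing

Order of operations: size-window export (inclusive 50–550 bp), then
signal/noise discrimination per profile, then duplicate-digest
consensus, then cross-sample binning.

**Signal/noise rule.**  Areas are relativized; the standard deviation of
the not-yet-flagged areas *about zero* is computed; every peak above
k·σ (default k = 3) is flagged as signal; the rule repeats on the
unflagged remainder until no new peak flags.  Two guards: profiles with
fewer than 3 peaks are returned unchanged (σ is meaningless), and if the
cascade never flags anything the whole profile is retained as
all-signal rather than annihilated — low-diversity true profiles with no
noise floor land here, by design.  The include-self σ variant was chosen
over a leave-one-out variant because it makes the operation idempotent
in practice: a retained signal set re-fed to the rule produces no new
flags.  The cascade does its real work when profiles carry a wide noise
floor (the generator default is 60 noise peaks), where σ shrinks pass by
pass until every true peak above ~3× the noise floor is flagged.

**Duplicate consensus.**  Each replicate is relativized first (this is
the injection-amount correction), peaks are matched greedily
nearest-first within a tolerance (default 0.5 bp; a peak matches at most
once), matched peaks keep mean size and mean relative area, unmatched
peaks are discarded, and the result is re-relativized.  Relativize →
average → re-relativize is one consistent reading of "discard and
average"; it makes consensus commutative and idempotent on identical
replicates.

**Binning.**  Peak sizes pooled over samples are clustered by
single linkage: processing sizes in ascending order, a new bin starts
when the gap to the previous size exceeds the threshold (default
1.0 bp).  Chains of closely spaced peaks therefore share one bin — a
documented property of single linkage.  Bin center = mean member size.

## Six-of-six assignment

The library is built by digesting the clone panel (or read from a TSV
accepting "NC" and "<50" tokens; a reference 24-clone table ships as
package data).  The paper-style matching was manual; the codified rule
is: a library entry matches an observed signature iff all six slots
agree — numeric slots within tol bp (default 1.0, the capillary sizing
error scale), categorical slots categorically.  Several matches resolve
to the nearest by summed absolute deviation; exact ties are UNASSIGNED
with a logged ambiguity.

How one sample's six electropherograms pair into a single observed
signature is not a published procedure; the reconstruction here is
corroboration against the primary axis: for each sample and each MspI
forward bin, an entry matches iff its MspI-forward slot matches the bin
center and each remaining slot is corroborated by *some* bin of that
sample's corresponding digest (numeric within tol; a digest with no
nearby peak is treated as below-window, which agrees only with "NC"/"<50"
slots).  Assigned areas are the primary-bin relative areas; phylotypes
sharing a group label collapse by summation (area-conserving); the
remainder is the per-sample unknown fraction, so assigned + unknown = 1.
Shrinking tol never increases the number of matched bins.

## Community statistics

Bray–Curtis BC(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on relative-abundance rows
(pairs of all-zero rows defined as 0), UPGMA via average-linkage
agglomeration (inter-cluster distance = unweighted mean of member
pairwise distances), cophenetic correlation as the Pearson correlation
between the condensed input dissimilarities and the tree's leaf-pair
merge heights, and tree cutting by removing merges above the cut height
(default 0.7).  These standard steps are backed by scipy
(`pdist`, `linkage(method="average")`, `cophenet`, `fcluster`) and
validated in the test suite against from-scratch brute-force oracles;
merge tie-breaking follows scipy's ordering, which can change dendrogram
shape but not cophenetic heights except under exact ties (measure zero
for continuous data).  Newick export encodes ultrametric branch lengths
(leaf depth = merge height / 2), so leaf-to-leaf path lengths equal
cophenetic dissimilarities.

The Kruskal–Wallis factor test uses midranks and the standard tie
correction with the χ² (k−1 d.f.) approximation.  Because the exact
response variable behind "groupings differ with respect to carbon
source" is not published, both reconstructions are provided: per-bin
relative abundances grouped by factor, and cluster-membership ranks
grouped by factor.

## Synthetic study generator

The generator emulates three data streams with full seed control
(every stage seed derives from one master seed):

- **Clone panel / communities.**  One disjoint taxon pool per carbon
  source (default 5 taxa; the acetate pool is anchored by a clone
  planted with the reference Geobacter-like signature 164/93/217/126/
  405/124; two lactate-pool members share a Desulfovibrio-style group to
  exercise collapsing).  Primary T-RFs are pairwise separated ≥ 3 bp so
  bins map uniquely onto phylotypes.  Per-sample abundances are
  symmetric Dirichlet (default concentration 5 — moderately even, as in
  low-diversity enrichments); carbon source structures the communities,
  mineral and dilution only label samples.
- **Electropherograms.**  Duplicate profiles per sample × enzyme × dye.
  True peaks sit at the taxa's T-RFs with areas proportional to
  abundance; degradation is per-replicate: Gaussian size jitter
  (default sd 0.1 bp, capillary repeatability scale), rare dropout
  (default 0.001 — dropout of major peaks in replicate digests of the
  same extract is an uncommon instrument artifact; noise, not dropout,
  is the dominant degradation), and 60 spurious peaks uniform over
  30–600 bp (exercising both flanks of the export window) with
  exponential areas (scale 40 against a true total of 10⁴, i.e. a
  ~20 % noise floor of individually sub-percent peaks).
- **Fe grid.**  3 minerals × 4 carbons × 5 dilutions × 2 duplicates
  = 120 enrichments at Fe_TOT = 25 mM.  Each (mineral, carbon) series
  has a shape tag — `decreasing` (template 1/0.85/0.55/0.25/0.10),
  `unimodal_at_third` (0.15/0.50/1/0.50/0.08, maximum at the 10⁻³
  dilution), or `flat_low` — an amplitude range, and additive Gaussian
  noise (sd 2 percentage points, truncated to [0, 100]).  Defaults:
  ferrihydrite decreasing under every carbon (acetate amplitude 84–88 %,
  others 70–90 %); goethite unimodal 56–67 % under lactate/glucose/
  mixed; hematite unimodal 56–67 % under glucose only; everything else
  flat_low with amplitude ≤ 4 % so that observed values span ~0–6 % and
  stay below the 10 % selection threshold.  Giving hematite only one
  substantially reducing carbon source (rather than mirroring goethite)
  is what reproduces the observed bioavailability ordering of selection
  fractions, ferrihydrite > goethite > hematite.  Records expose the
  pre-noise `target_percent` as generator ground truth.  Inter-replicate
  dilution offsets are deliberately not modeled.

What passing tests on these data do *not* show: robustness to real-world
pseudo-T-RFs, partial digestion, size-calling error from ladder fitting,
chimeras, shared fragments between genuinely related taxa, or
phylogenetically structured sequence composition.  The generator's job
is to make the pipeline's contracts testable, not to simulate biology.

## Reaction energetics

Energy yields are reported as −(ΔG° + RT ln Q) per mole of electron
donor: positive values are thermodynamically favorable.  ΔG° comes from
standard formation energies at 25 °C; Q uses activities equal to molar
concentrations (no ionic-strength correction — the bracketed enrichment
concentrations imply this), H⁺ at 10^−pH, solids and water at unit
activity.  Temperature is fixed at 298.15 K.  Element and charge balance
is validated against the packaged composition table before any energy is
computed; the electron bookkeeping species e⁻ (ΔGf = 0, unit activity)
permits half-reaction arithmetic, and direct whole-reaction yields equal
their half-reaction sums exactly.

The packaged table (`data/thermo_table.yaml`, editable, provenance tag
per entry) uses the classic anaerobic-metabolism compilation for the
organic and sulfur species (acetate −369.41, lactate −517.81, HCO₃⁻
−586.85, SO₄²⁻ −744.63, HS⁻ +12.05, glucose −917.22 kJ/mol), CODATA
water and Fe²⁺ (−237.18, −78.90), and mineral-compilation values for
goethite (−488.60), hematite (−742.20) and 2-line ferrihydrite (−708.5,
representative).  Built-in couples at enrichment conditions (pH 7.3;
acetate 10 mM or lactate 10 mM with acetate 1 µM; Fe²⁺ 5 µM; HCO₃⁻
10 mM; SO₄²⁻ 200 µM; HS⁻ 1 µM):

| couple | yield (kJ per mol donor) |
|---|---|
| acetate⁻ + 8 FeOOH + 15 H⁺ → 2 HCO₃⁻ + 8 Fe²⁺ + 12 H₂O | +1.3 (marginal) |
| lactate⁻ + 4 FeOOH + 7 H⁺ → acetate⁻ + HCO₃⁻ + 4 Fe²⁺ + 6 H₂O | +86.3 |
| lactate⁻ + ½ SO₄²⁻ → acetate⁻ + HCO₃⁻ + ½ HS⁻ + ½ H⁺ | +121.8 |

**Known caveat — the lactate/sulfate couple.**  Literature desk values
near +101 kJ per mole lactate circulate for this couple at these
conditions; the thermodynamically consistent evaluation above gives
+121.8.  The discrepancy is structural, not a constants issue: +101 is
recovered *exactly* if the ½ H⁺ product activity term is omitted from Q
while keeping pH-independent formation energies, and no published
formation-energy combination closes the ~21 kJ gap without breaking the
two goethite couples (which pin the Fe and organic species jointly).
This package keeps the consistent calculation; expect ~20 % disagreement
with sources that quote ~101 for this couple.  The qualitative
conclusion — sulfate reduction outcompetes goethite reduction for
lactate — is unaffected (and is in fact strengthened).

## Fe-reduction selection

percent reduced = 100·Fe²⁺/Fe_TOT; selection is strictly greater than
the threshold (default 10 %), so a record at exactly 10.0 % is excluded.
Tallies report counts, per-level selection fractions, and shares of the
selected set, by mineral and by carbon.

## Pipeline and reproducibility

`run_all` executes simulate → digest → process → assign → cluster →
stats → fe-select → thermo, writing every intermediate as headered TSV
(parameter echoes in `#` comment lines), Newick and JSON.  All
randomness flows from the single master seed; identical config + seed
reproduces byte-identical outputs.  Any stage failure aborts with the
stage name and cause.  The CLI is a thin veneer over these library
calls.

## Problem sizes

The default synthetic study is 3 carbon pools × 3 minerals × 5 dilutions
= 45 samples × 6 electropherograms × 2 replicates (540 profiles) over a
15-clone panel, matching the scale of a large enrichment campaign; the
test suite's property checks use 500 planting round-trips, ~50 oracle
digest fixtures ≤ 2 kb, and 100 random matrices (n ≤ 8) for the
clustering oracle.  The whole suite runs in well under a minute on one
CPU.
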