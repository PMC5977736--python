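# Methods

## The statistic

A transportome is summarised by the percentage of its counted members in
each of three functional classes: ATP-dependent transporters (ADT),
secondary transporters (ST) and ion channels (IC). The energy-usage
efficiency is the class-weighted average cost of a single transport
event,

EUE = (w_ADT · %ADT + w_ST · %ST + w_IC · %IC) / 100,

with default coefficients w = (2, 0.5, 0) ATP equivalents per event.
These defaults are deliberately conservative physiological bounds: ABC
transporters and the other primary active families operate near a 1:2
substrate:ATP stoichiometry; secondary transporters consume ion gradients
built by ATPases that pump ≈ 2–3 ions per ATP, so even concentrative
carriers average at most ≈ 0.5 ATP per substrate, and equilibrative
carriers cost nothing; channels mediate free diffusion. The coefficients
are configurable (`EUEWeights`), and a warning is issued if a custom
configuration breaks the ADT ≥ ST ≥ IC cost ordering, because the
"negative ΔEUE = more efficient" reading depends on it.

Assumptions worth stating explicitly:

* EUE is compositional only. Expression levels and fluxes — which set the
  *total* energy a cell spends on transport — are not modelled, so EUE
  must not be read as cellular ATP expenditure.
* Group EUE is the EUE of the group's unweighted mean composition, each
  species counting as one independent replicate. By linearity this equals
  the mean of per-species EUEs, and the ΔEUE matrix is antisymmetric and
  additive along chains of groups (checked by property tests).
* The F/V/A-type ATPases and ATP synthases energise the rest of the
  transportome; they are excluded from the ADT count. The exclusion is
  applied to *all* composition statistics through one flag
  (`exclude_energizers`, default on) so the class fractions, the
  frequency tables and the ΔEUE matrix share one denominator.

## Curation rules

Annotator output is protein-level and noisy; the filter chain makes the
conventional manual curation deterministic:

1. proteins shorter than 100 aa are excluded (strict: a 100-aa protein is
   kept; records lacking a length are kept because the rule cannot be
   applied to them, and silent dropping would bias counts);
2. multi-prediction hits (one protein, several families) keep the record
   with the lexicographically smallest family id; alternative isoforms
   (one gene, several proteins) keep the smallest protein id. Both
   tie-breaks are order-insensitive and every removal is written to the
   audit log, so the stand-in rule can be inspected and overridden by
   pre-curating the table;
3. ATP-dependent records sharing a complex id within a species —
   operon-encoded ABC importers annotated one record per subunit — merge
   into a single transporter. The rule is restricted to the ATP-dependent
   class because the multi-subunit annotation problem is specific to
   prokaryotic primary transporters; channel or carrier hetero-oligomers
   are left untouched. A complex id spanning families is treated as an
   error rather than guessed at.

Each step is idempotent, never increases counts, and the chain's order
(length → dedup → complexes) is fixed in `apply_filters`.

## Group statistics

Species are replicates. Per group the package reports the unweighted
mean, sample SD and symmetric t-interval (default confidence 0.99,
n − 1 df) of each class percentage; pairwise comparisons use the
two-sided pooled-variance Student's t-test (Welch available as an
option), computed via scipy. Because class shares are proportions, every
test is repeated on asin(√p)-transformed values as a normality
robustness check; the transform is strictly monotone, so group orderings
are preserved and conclusions should agree between scales — the pipeline
writes both p-values side by side rather than choosing one.

## The synthetic generator

The generator produces the inputs the analysis assumes, with known
truth. Per species it draws a total gene count (log-normal, group-typical
location), a transportome fraction (normal, clipped), a class composition
from a group Dirichlet, and family counts from uniform multinomials over
the group's per-class family pool; energizer members and an optional
marker family (planted into a chosen number of carrier species) ride on
top. Truth — per-species class counts and percentages, expected
post-filter totals, realised per-group family presence, carrier lists —
is recorded *before* artifact injection, so every filter has an exact
expected outcome. The four injected artifact types mirror the curation
rules one-to-one; multi-prediction decoys always use a lexicographically
larger family id than the true record so the documented tie-break
provably restores the truth.

The default scenario (`paper_like_specs`) fixes the study conditions:
six groups with species counts 78/48/30/30/30/33, Dirichlet mean
compositions chosen so group EUEs run 0.92, 0.89, 0.76, 0.65, 0.62,
0.43 ATP/event from bacteria to animals (ADT-heavy prokaryotes, ST-heavy
fungi, IC ≈ 30% animals), concentration 800 (per-species class-share SD
of ≈ 1–3 percentage points), transportome fractions of ≈ 10% of genes in
prokaryotes down to 3–5.5% in eukaryotes, and family pools planting 8
prokaryote-specific and 6 eukaryote-specific secondary families, 7 vs 18
lineage-specific channel families, and 7 bacterial carriers of the
mitochondrial carrier family.

What the generator does **not** emulate: sequence evolution and
phylogenetic correlation between species (species draws are i.i.d.
within a group), annotation errors beyond the four artifact types,
within-class family-abundance structure (uniform multinomials, where
real transportomes have a few dominant families), and any coupling
between genome size and composition. Passing recovery tests therefore
demonstrates that the pipeline's arithmetic and filters are correct
under the stated statistical model — not that real annotation pipelines
are free of biases the model omits.

## Recovery tolerances

Because the recovered per-species class share is a Dirichlet draw
realised by a multinomial of size n_t (the species' transportome), its
variance is m(1−m)(n_t + c) / (n_t (1 + c)) for mean m and concentration
c — both sampling stages matter, since for prokaryote-sized
transportomes the multinomial term is comparable to the Dirichlet term.
The analytic standard errors used by the recovery report
(`analytic_fraction_se`, `analytic_eue_se`) propagate this
Dirichlet-multinomial variance with the realised per-species sizes. The
acceptance checks require recovered group means within 3 such SEs and
the extreme-pair ΔEUE within 0.02 ATP at 30 species per group.

## Numerical and design choices

* Percentages are kept at full precision internally and displayed to 4
  decimals; the ΔEUE matrix is rendered lower-triangular at 2 decimals
  (sign preserved, −0.00 normalised to 0.00) with full precision in the
  long-format table.
* Family presence requires ≥ 1 counted member after filtering; a
  `min_species` threshold (default 1) is available against
  single-annotation artifacts. The default two-way split is
  {bacteria, archaea} vs the four eukaryotic groups; any disjoint
  supersets may be supplied.
* The bundled example registry (63 families across the three classes,
  TC-style ids) is an illustrative working set for demos, tests and the
  generator, not a reconstruction of any external database; real
  analyses should supply their own registry file.
* The Pearson correlation between transportome size and gene number is
  computed over an explicit species subset, so it can be taken with or
  without primitive eukaryotes (whose transportome-encoding gene share
  is distinctly low).
* Degenerate inputs fail loudly: zero transporters after energizer
  exclusion, singleton groups (CI undefined), constant vectors
  (correlation undefined), overlapping supersets, unknown family ids.

## Problem sizes in the shipped tests

Unit tests run on hand-sized fixtures plus six-species-per-group
simulations; the end-to-end recovery scenario uses 30 species per group
(180 species, ≈ 10⁵ annotation records) and the acceptance script the
full 249-species default — a few seconds each on one CPU.

## Known limitations

* The EUE coefficients are bounds, not measurements; relative (ΔEUE)
  statements are more robust than absolute EUE values.
* Family membership is taken from the annotation tables as given; no
  homology searching is performed, so families missed by the upstream
  annotator are invisible here.
* The deterministic dedup tie-break is a reproducible stand-in for
  expert curation, not a claim about which prediction is biologically
  right; the audit log exists so users can check what it did.
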