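# Methods

`e3prio` characterizes E3 ubiquitin ligases along the evidence dimensions
that matter for targeted protein degradation (TPD) — catalog confidence,
chemical ligandability, tumor/normal expression, protein–protein
interactions (PPIs), essentiality, subcellular location, structure and
interface availability — and exposes a conjunction-of-filters query
engine over the assembled tables. This note records the models, rules and
numerical choices, and what the synthetic test bundle does and does not
establish about real data.

## Catalog and confidence score

Three curated ligase lists are merged by harmonized gene symbol: a
literature/HMM collection with a per-gene literature-validation flag, a
domain-signature collection with a free-text function annotation, and an
E3–substrate-interaction (ESI) collection with a per-gene ESI count. Each
source contributes a sub-score:

| source evidence                           | 2       | 1          |
|-------------------------------------------|---------|------------|
| literature validation flag                | set     | predicted  |
| function text contains the token "E3"     | yes     | no         |
| number of known ESIs                      | > 5     | ≤ 5        |

The cumulative confidence is the sum over sources that list the gene
(range 1–6); a source that omits the gene contributes nothing, so a gene
cross-validated by all three lists scores at least 3. The "E3" keyword is
matched case-insensitively on word boundaries, so "UBE3A" does not match;
the matching rule is our choice, as is keeping the higher-scoring record
when a source lists a gene twice (conservative toward evidence).
Within the IAP family only BIRC2 and XIAP are retained as
representatives. The shipped co-opted list (ligases already used in
published degraders: VHL, CRBN, MDM2, KEAP1, DCAF16, DCAF11, XIAP, BIRC2,
AHR, RNF4, with VHL and CRBN flagged clinical) is a partial default and
explicitly user-overridable configuration, not an authoritative registry.

## Ligandability

Three evidence categories are aggregated: drugs (drug–gene interaction
tables), bioactive small molecules (ChEMBL-style activity records kept
only when pChEMBL ≥ 5, i.e. measured potency of 10 µM or better —
inclusive boundary, as printed), and covalent cysteine electrophile hits
from chemoproteomic profiling (a hit in any profiled cell line counts).
Ligands are deduplicated across sources via a canonical key: the shared
ChEMBL identifier when available, else a lexically normalized SMILES
(whitespace/case only; a chemistry-aware canonicalizer can be plugged in
through a hook — we deliberately avoid a cheminformatics dependency in the
core), else the source-qualified native id. Covalent hits carry no ligand
identifier in the input schema, so they are keyed by cysteine site; this
keeps the ligand set non-empty whenever covalent evidence exists, at the
cost of counting sites rather than electrophiles.

Tiers follow strict precedence: **E3drug** (any drug) > **E3chem**
(small molecule, no drug) > **E3cova** (covalent only) > **E3dark**
(nothing). Every catalog ligase receives exactly one tier.

## Expression classification

* **Bulk (tumor and normal).** Tissue level = median of log2(TPM+1)
  across the tissue's samples; High iff level > 4, strictly. Inputs are
  assumed pre-normalized TPM; no re-normalization is performed.
* **Protein staining.** High iff the fraction of samples with a
  medium-or-high staining call reaches 20%. The published wording is
  ambiguous between "over 20 percent" and "≥ 20%"; we default to the
  inclusive reading and expose `hpa_strict` for the strict variant.
* **Single cell.** A gene is High in a tissue iff the percentage of cells
  with non-zero expression strictly exceeds 12.75% **and** the mean over
  the non-zero cells strictly exceeds 2.325. These thresholds are 75% of a
  reference expression pattern regarded as safe (17% of cells, non-zero
  mean 3.1); the derivation is exactly linear in the scale factor. The
  mean is computed over non-zero cells only — the reference pattern is
  stated as a non-zero mean, and we adopt that reading throughout.

**Tumor selectivity** is the conjunction: High in ≥ 1 tumor type in both
the bulk tumor and the staining data, and Low in ≥ 70% of normal tissues
in both the bulk normal and the single-cell normal data. The 70% majority
cutoff is inclusive and is always evaluated against the tissues present
in the loaded dataset, not a fixed denominator.

For tumor single-cell data, the composition of a gene's expressing cells
over malignant/immune/other groups is reported as the within-group
expressing percentage and each group's share among all expressing cells.
All reported percentages use half-up rounding to one decimal; shares sum
to 100% up to rounding.

## PPI aggregation

Per-source retention filters: literature-curation dialects keep human
rows only; STRING-like rows need combined score > 700 (strict);
UbiBrowser-like predicted ESIs need confidence > 0.7 (strict) while
literature ESIs are kept unconditionally; HuRI-like binary assayed rows
pass as-is. Edges whose detection method falls in a configurable
physical-evidence vocabulary (yeast two-hybrid, AP-MS, 3D structures,
low-throughput experiments; keyed on PSI-MI-style names since no
identifier list is prescribed) are flagged physical. Merging is
set-semantic on unordered pairs: provenance is unioned, the physical flag
OR-ed, self-loops dropped by default (retainable by flag). The merged
edge count therefore counts unique unordered ligase-involving pairs.

Derived statistics: the target space of a ligase set (all partners,
excluding ligases themselves by default), the percent expansion of the
target space when widening the ligase set (half-up, one decimal), and
E3s-per-target counts with their median — targets with zero interacting
E3s enter the median only when an explicit target universe (a
tractability list) is supplied, matching the intended "per tractable
target" reading.

## Essentiality, location, structures, interfaces

* Essentiality: essential iff the mean dependency probability strictly
  exceeds 0.5. The headline call uses the overall mean across cell lines;
  a per-lineage grouping is also computed (the overall mean equals the
  lineage-size-weighted mean of lineage means). CRISPR-style and
  RNAi-style screens are processed independently.
* Location: COMPARTMENTS-like annotations require score > 3 (strict);
  GO/UniProt annotations pass a configurable evidence-code vocabulary.
  Cytoplasm is matched by the tokens "cytoplasm"/"cytosol", nucleus by
  "nucleus" (case-insensitive substring). Any single high-confidence
  source suffices to place a protein; cytoplasm or nucleus counts as
  favorable for degrader function, and exclusivity labels
  (cytoplasm-only / nucleus-only / both / neither) are derived.
* Structures: count of distinct experimental structure ids; a predicted-
  structure availability flag is set only when no experimental structure
  exists.
* Interfaces: counted as distinct (partner, source) pairs by default —
  the three interface sources (co-crystal, homology model, high-confidence
  prediction) are kept separate — with a collapse-to-partner mode; residue
  membership queries use 1-based inclusive ranges.

## Query engine

Searches are conjunctions of optional filters. Comparison strictness
follows the printed criteria verbatim: confidence and PPI count strictly
above their sliders, normal-tissue High fraction strictly below, tumor
High count at least the slider; an `inclusive` flag relaxes the strict
comparisons for sensitivity analysis. The shipped `case1` preset is:
confidence > 3, available ligands, High in ≥ 1 bulk tumor type, High in
< 30% of bulk normal tissues, > 100 PPIs.

Result ordering is our own choice (the original interface returns an
unordered table): confidence descending, unique-ligand count descending,
then symbol. Target-restricted searches rank by ascending PPI degree
first — the least-connected interactor is the most target-specific
candidate — then by the general key.

Partner-set enrichment uses the upper-tail hypergeometric probability
P(X ≥ k) with Benjamini–Hochberg adjustment across all tested terms;
adjusted p < 0.05 is flagged significant. The default universe is every
protein in the merged edge set, overridable.

## Synthetic bundle and what it shows

The generator plants, per ligase: source membership and sub-scores, a
ligand tier, High tissue sets for all four expression datasets, a PPI
degree, essentiality means, a location class, structure counts and
interface counts — and writes every input table in the dialects the
readers expect, plus a truth manifest of all derived values and expected
preset results.

Numerical planting choices:

* Bulk samples are drawn around the planted tissue median and shifted so
  the sample median lands exactly on target; High medians lie in
  [5, 7] and Low in [0.8, 3.4], keeping ≥ 0.5 margin from the boundary.
* Single-cell High plants use 35% non-zero cells with non-zero mean 3.0;
  Low plants fail one criterion each (5% non-zero, or non-zero mean 1.5).
  Non-zero values are exponential draws rescaled to the exact target mean.
* Essentiality probabilities are uniform draws re-centered to the exact
  planted mean (means in [0.62, 0.90] for essential, [0.08, 0.38]
  otherwise).
* Decoy rows exercise every filter: STRING scores at/below 700,
  predicted-ESI confidence at 0.70, non-human interactions, sub-threshold
  ChEMBL activities, COMPARTMENTS scores ≤ 3, an IAP-family member
  subject to the representative rule, and an aliased source symbol.
* Each table draws from an independent stream derived from the master
  seed and the table name, so bundles are byte-identical per seed and
  stable under adding tables. Default scale: 200 ligases, 1000 targets,
  10 tumor types, 10 normal tissues, 12 samples per tissue, 3000 normal
  plus 2000 tumor cells; generation plus a full pipeline run takes a few
  seconds on one CPU.

When a preset must return exactly *k* ligases, *k* planted passers
satisfy every criterion and each remaining ligase carries one forced
violation (including a near-passer with confidence exactly 3 that probes
the strict boundary). Boundary behavior of every printed threshold is
exercised by dedicated in-memory probes
(`simulate.make_boundary_fixtures`) that sit exactly on and just past
each cutoff.

The bundle is internally consistent but deliberately unrealistic: no
correlation structure between dimensions beyond what the planted specs
require, no batch effects, no compositional noise in staining calls, no
doublets or ambient RNA in the single-cell matrices, and symbols are
synthetic. Passing the roundtrip therefore demonstrates that the
derivation rules are implemented exactly as specified — not that the
rules themselves are robust to the failure modes of real exports.

## Known limitations

* SMILES deduplication is lexical by default; distinct notations of one
  structure count as distinct ligands unless a canonicalizer is plugged in.
* The ligand-count semantics for covalent evidence (sites, not
  electrophiles) differ from the drug/small-molecule categories.
* Real data-source exports need column-mapping to the documented dialects;
  no downloader is included.
* The tumor-type ↔ normal-tissue matching table for side-effect views is
  consumed as configuration, never computed.
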