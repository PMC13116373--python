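# Methods

## The staging model

The AGCES classification describes endometriosis burden with three
independent ordinal components, reported together as `A_ G_ E_`:
adenomyosis (A), genital endometriosis (G), and extragenital endometriosis
(E), each staged 1 (minimal) to 4 (severe). This package implements the
classification as a deterministic decision table: every published
criterion is one predicate paired with a stage, a component's stage is the
**maximum over fired predicates**, and the code is the triple of component
stages. Because the combination rule is a maximum over monotone
predicates, the engine is monotone by construction: increasing any
severity-relevant quantity (a spot count, a thickness, a depth, an
adhesion or obliteration grade) can only add fired predicates, never
remove a more severe one.

**Adenomyosis (A)** is staged from imaging measurements on three
sub-scales, the highest of which wins:

* *Diffuse wall thickening* — bands over the multiset of affected wall
  thicknesses: one wall ≤ 20 mm (I); two walls ≤ 20 mm or one in
  (20, 30] mm (II); one wall > 30 mm or two in (20, 30] mm (III); two
  walls > 30 mm or a globally enlarged uterus (IV). "Affected" is the
  observer's explicit judgement — the engine does not infer involvement
  from a normal-thickness cutoff, because no such cutoff is part of the
  criteria.
* *Junctional-zone (JZ) thickening* — enters staging only when JZ max
  exceeds 6 mm. With diffuse extent below 50% of the uterus, JZ max in
  (6, 8] mm is Stage I and > 8 mm Stage II; extent in [50, 80)% is
  Stage III and ≥ 80% Stage IV regardless of the JZ band.
* *Focal lesions* — staged on size-bin counts (≤ 10 mm, (10, 20] mm,
  > 20 mm): one small (I); two small or one mid (II); two mid or one
  large (III); two large (IV). Evaluating all criteria on bin counts and
  taking the maximum handles mixed sets (e.g. one 8 mm plus one 25 mm
  lesion → Stage III) without single-pattern matching.

**Genital (G)**: the spot total across all genital sites sets the bands
1–6 (I), 7–10 (II), > 10 (III). An endometrioma burden confined to a
single ovary with no cyst over 30 mm is Stage III. Dense adhesions,
bilateral endometriomas (any sizes), or any endometrioma > 30 mm force
Stage IV — these supersede the spot count.

**Extragenital (E)**: the same spot bands apply while disease stays
superficial (≤ 5 mm depth of penetration). Depth > 5 mm (the established
deep-infiltrating-endometriosis threshold), muscularis or mucosal
invasion, any cul-de-sac obliteration (partial or complete), frozen
pelvis (anterior or posterior — captured separately, staged identically),
or any organ dysfunction force Stage IV.

**Stage 0.** The published bands start at Stage I, but a component can be
entirely free of findings. The engine emits stage 0 when no criterion of
any band fires, so absence is never reported as "minimal" disease; the
canonical code grid is therefore 5×5×5. Users who prefer the published
1–4 convention can treat 0 as "component not involved".

## Interval conventions

The printed ranges ("> 20–30 mm", "≤ 6 spots") leave endpoint semantics
implicit. One reading is fixed package-wide and exported as
`agces.engine.INTERVAL_CONVENTION`: "> a–b" means (a, b], "≤ a" closes at
a, "> a" opens at a. Consequences: a 20 mm wall is band I, a 30 mm
unilateral endometrioma is Stage III, 5 mm depth is superficial, an 8 mm
JZ is Stage I, and exactly 6 spots is Stage I in both G and E. Two
boundary values are deliberately assigned to the *higher* band because
the printed bands leave a gap there: diffuse-JZ extent exactly 50%
(Stage III) and exactly 80% (Stage IV) — ties break toward higher
severity, consistent with the system's supersession philosophy. All 14
thresholds are exercised from both sides by the deterministic boundary
suite (`enumerate_boundary_cases`, 28 cases).

Two further readings were genuinely open and are fixed as follows:
multiple endometriomas on one ovary, each ≤ 30 mm, stage III (the
unilateral-burden reading of "one endometrioma ≤ 30 mm (single ovary)");
and an endometrioma case with > 10 spots but only filmy adhesions remains
Stage III, since no Stage-IV criterion fires.

## Spot counting

Spot counts are recorded per anatomical site (8 genital, 11 extragenital
sites) but staged on the sum within each component — the criteria count
total spots without per-site qualification, and the per-site detail feeds
the operative report. Clustered implants are counted as supplied by the
observer; the engine does not reinterpret clusters.

## Synthetic cases and the oracle

The generator (`agces.synth`) produces valid cases by *inversion*: given
a target (A, G, E) triple it picks, per component, one criterion region
of the target stage (e.g. for A: the wall, JZ, or focal route) and
samples measurements uniformly inside it, leaving the other routes empty.
Every case records the generator name and seed in its metadata, so any
failing case is replayable. Defaults: uniform severity weights (0.2 per
stage per component) — the generator makes no claim of epidemiological
stage prevalence, which is deliberately out of scope — and measurements
rounded to 0.1 mm / 0.1%, the precision of clinical imaging reports.
Sampling stays at least one rounding step away from every threshold, so
rounding cannot move a case across a band.

What the generator emulates is the *combinatorial structure* of findings,
not clinical reality: site involvement is uniform rather than anatomically
correlated (real disease favours ovaries and the posterior compartment),
measurement noise and inter-observer variability are absent, and
component severities are sampled independently although they correlate in
patients. Passing tests therefore demonstrate that the decision table is
implemented exactly and behaves lawfully on every reachable input — not
that the system is clinically valid, which requires prospective study.

The oracle (`oracle_stage`) re-implements the staging table as a flat
list of (predicate, stage) pairs written directly from the printed rows,
sharing no code or constants with the engine. The equivalence suite
compares the two on an exhaustive discretized grid bracketing every
threshold (wall thicknesses {0, 15, 20, 20.1, 25, 30, 30.1, 35} mm on 0–2
walls × global enlargement × JZ {5, 6, 6.1, 7, 8, 8.1, 10} mm × extents
{0, 30, 49.9, 50, 79.9, 80, 100}% × focal multisets of size ≤ 3 over
{5, 10, 10.1, 15, 20, 20.1, 25} mm; spot totals 0–15 × adhesion grades ×
nine endometrioma configurations; spot totals × depths {0, 3, 5, 5.1, 7}
mm × all categorical flags — about 5.5 × 10⁵ combinations, run per
component since the components are independent by construction and that
independence is itself a tested property) plus 10⁵ seeded random full
cases. The whole verification harness runs in well under a minute on one
CPU; problem sizes (10⁵ random cases, 10⁴ monotonicity pairs, 10³
contexts per supersession trigger, 10 inversions per stage triple) are
the package's standing self-check configuration.

## Numerical and design choices

* All measurements are floats in millimetres / percent; comparisons are
  exact (`<=`, `>`), with no epsilon — the convention table, not floating
  tolerance, decides boundaries, and serialized values round-trip exactly
  through JSON.
* Validation is non-throwing (`validate_case` returns violation
  descriptors naming field, rule, and value); the engine refuses to stage
  an invalid case.
* The JSON schema is closed (unknown keys rejected) and versioned;
  the CSV dialect uses explicit `_mm`/`_pct` column suffixes to prevent
  unit drift, and empty cells mean "finding absent".
* Traces record *every* fired criterion, not only the winner, as stable
  dotted identifiers (docs/case_schema.md); the component stage equals
  the maximum stage among them. `superseded` is true exactly when a G or
  E component reaches Stage IV, which in this system is reachable only
  through the supersession triggers.
* Report rendering is deterministic and locale-independent: fixed
  anatomical site order, fixed decimal formatting, no timestamps —
  identical input yields byte-identical output.

## Limitations

The engine stages exactly what it is given: it performs no image
analysis, no inference of missing measurements, and no reconciliation of
conflicting observations between modalities. It does not compute rASRM,
ENZIAN, AAGL, or EFI scores, and makes no symptom, fertility, or outcome
predictions. The staging thresholds encode a published expert-consensus
framework whose prospective clinical validation is still pending; this
package guarantees faithful, deterministic, auditable application of the
rules, nothing more.
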