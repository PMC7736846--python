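# Methods

## Scope and model

The pipeline ranks single amino-acid substitutions of interacting
proteins by their predicted capacity to disrupt a receptor–ligand
docking interaction. It works entirely at protein level: inputs are
categorical predictor outcomes, structure-change flags derived from
coordinate models, and post-docking comparison parameters of
mutant:wild-type versus wild-type:wild-type complexes. The pipeline
never runs the external predictors or docking engines itself; their
outputs are inputs, and the geometric comparisons usually delegated to
structure-analysis servers are computed in-package from coordinates.

## Scoring schemes

**Sequence stage.** Each of six predictors contributes a weight:
damaging-side outcomes (Deleterious, Damaging, Disease, Decrease
stability, Cancer-associated) score 1; PolyPhen2 distinguishes Possibly
damaging (1) from Probably damaging (2); benign-side outcomes score 0.
The cumulative score lies in [0, 7]. A missing outcome scores 0 — the
benign-side value — and the tool is recorded in `missing_tools`; nothing
is imputed, since inventing a predictor's behaviour would be worse than
under-scoring. Selection keeps variants whose cumulative score is
*strictly* greater than the median of the pooled cohort (midpoint
convention for even n). The default pool is all variants of all genes
and both datasets together; per-gene and per-dataset pooling are
available and the pooling used is logged and written to the manifest.
Ties at the median are excluded by the strict inequality.

**Structure stage.** Three binary scores: hydrogen-bond pattern changed
(1), steric-clash set changed (1), accessibility shift of the mutated
residue (1 for both intra- and inter-orbit shifts — the published scheme
scores any positional shift identically, although results prose reports
the two kinds separately). The combined total is the sequence cumulative
plus the structure cumulative, in [0, 10]. Top-two selection is applied
per gene × dataset × region group and is read as the top two score
*values* with all ties retained, because the published selected set
contains more than two variants per group; a group with a single
distinct value keeps everything. The druggability annotations (mean
pocket drug score and pocket count of mutant versus wild type, labelled
Neutral/Favourable/Unfavourable and Neutral/Increase/Decrease) are
informational only and never feed selection.

**Docking stage.** Seven parameters per mutant complex. Canonical
internal classes unify the two phrasings found in published tables
("more/less negative" for energies versus "increase/decrease" in the
favourable quantity): for the three energy terms a more negative mutant
value is *strengthening* (1) and a less negative one *weakening* (2);
for the three interaction counts a gain is *increased* (1) and a loss
*decreased* (2); the superposition RMSD of the mutant complex scores 1
below and 2 above the category mean RMSD; no change scores 0 throughout.
The total (0–14) is graded against the arithmetic mean total of the
mutant complexes of its docking category. Ties at the mean — not defined
by the published scheme, which uses strict inequalities — are graded
less disrupting with a `tie_flag`, conservative toward the wild-type
reference. The mean RMSD is computed over mutant complexes only; the
wild-type self-superposition (RMSD 0) is excluded, as including it would
let the reference dilute its own comparison baseline.

High-disruptor counts are distinct more-disrupting variants of a mutated
gene across all categories sharing the stated wild-type partner;
printed-name aliases of one variant (the ROBO4 tryptophan variant
appears as W367C in the prioritisation table and W397C in the docking
table) are merged before counting.

## Geometric engines

All detectors operate on a flat atom list with a covalent bond graph
inferred from single-bond covalent radii (+0.45 Å tolerance). Criteria
follow widespread conventions because the published analyses delegate
them to servers without stating thresholds; every cutoff is a config key
on `GeometryConfig`.

* **Hydrogen bonds** — donor/acceptor heavy atoms (N, O) within 3.5 Å;
  when the donor carries an explicit hydrogen the D–H···A angle must be
  ≥ 120°; in hydrogen-free models protonation is assumed and any N/O may
  donate. Intra-residue pairs and pairs within two covalent bonds are
  excluded; the 1-3 exclusion is required because the adjacent-residue
  O(i)···N(i+1) separation (~2.25 Å) would otherwise always register.
* **Steric clashes** — non-bonded heavy-atom pairs (1-2/1-3 excluded)
  with Bondi-radius overlap ≥ 0.4 Å, sorted by overlap. With only
  1-2/1-3 exclusion, ideal side-chain geometry (e.g. the 1-4 CB···O pair
  of a residue) sits at ~0.5 Å overlap and registers as a baseline
  clash; this cancels in wild-type/mutant comparisons, which difference
  the clash sets.
* **Salt bridges** — side-chain N of Lys/Arg/His to side-chain
  carboxylate O of Asp/Glu within 4.0 Å, counted once per residue pair.
* **Non-bonded contacts** — remaining cross-chain heavy-atom pairs
  within 3.9 Å that are neither hydrogen bonds nor part of a salt
  bridge.
* **Solvent accessibility** — Shrake–Rupley with a deterministic
  Fibonacci-sphere point shell (default 960 points, probe 1.4 Å) over
  heavy atoms; residue ASA is normalised by the Tien et al. theoretical
  maxima. The "orbit" of a residue — the ring of a spiral accessibility
  plot, which has no closed-form definition — is operationalised as the
  decile bin (1–10) of relative accessibility clipped to [0, 1]. A
  changed bin is an inter-orbit shift; the same bin with |Δ rel-ASA| >
  0.05 is an intra-orbit shift.
* **Superposition** — Kabsch SVD with reflection guard (determinant sign
  correction), pairing atoms by chain/residue/atom-name identity (CA by
  default); wild-type and mutant models share numbering so no sequence
  alignment is attempted. Insertion codes are unsupported and rejected.

Wild-type/mutant comparison at a site reports the hydrogen-bond outcome
as changed when the bond set involving the site differs in partners or
any shared bond's length moved by more than 0.1 Å (the published
"bond length" change threshold is unstated; 0.1 Å is this package's
choice), the clash outcome when the clash sets involving the site
differ, and the accessibility outcome from the orbit rules above.

## Input formats

No file format is defined by the source procedure, so all formats here
are package decisions: plain TSV/CSV with lower_snake_case headers and a
small alias map. Annotation tables hold one variant per row with the six
predictor labels and three structure flags; unknown labels are rejected
at parse time with the row number, and empty cells become missing
markers. Docking tables accept, per parameter, either a class column
(`<param>_class`) or a raw value pair (`<param>_wt`/`<param>_mut`, RMSD
as a single value); raw pairs are classified on load (RMSD in a second
pass against the per-category mean) and a stored class contradicting its
raw pair is an error. Amino acids are accepted in one- or three-letter
form and normalised. Reports round-trip bit-exactly through the TSV
writer/reader. PDB reading (first model, first-listed altloc, waters
excluded, non-water HETATM skipped by default) is backed by gemmi.

## Synthetic data

The generators define reproducible study conditions; a single seed feeds
all three through fixed stream ids (the generator state is seeded with
the pair (seed, stream id)), so stages can be tested independently.

* **Annotation tables** (default 100 variants, 10 planted): planted
  variants carry every worst-case outcome (combined total 10);
  background outcomes are drawn per tool from damaging-label
  probabilities defaulting to the outcome fractions reported for the
  real ROBO1/ROBO4/SLIT2 cohorts (e.g. ~45% PROVEAN-deleterious, ~85%
  stability-decreasing, ~2% FATHMM cancer-associated). No predictor
  correlation structure or real mutation spectrum is modelled.
* **Toy complexes**: ideal-geometry poly-alanine helix dimers
  (φ = −57°, ψ = −47°, standard bond lengths/angles, backbone amide
  hydrogens, ≤ 200 atoms) built from internal coordinates with no
  external template. Planted perturbations are minimal by construction:
  `remove_hbond` rotates one amide hydrogen out of the bond plane
  (breaking the i→i+4 bond at the site while leaving every heavy atom
  untouched), `add_clash` pulls a neighbouring CB to a 0.6 Å overlap,
  `bury_site`/`expose_site` toggle a clearance-checked shell of carbon
  blockers around the site (placed ≥ 3.25 Å from every heavy atom so
  they neither clash nor hydrogen-bond, while moving the site's relative
  accessibility from ~0.5 to ~0 — far across any decile boundary).
* **Docking tables** (default one category of 20 complexes, 5 planted):
  planted disruptors receive weakening-side deltas on all six
  energy/count parameters (+2 kcal/mol on energies, −3/−30/−2 on
  counts) and an RMSD of 3.0 Å versus a 0.5 Å background; the background
  drifts mildly to the strengthening side (−0.5 kcal/mol, +1/+10/+1).
  Default noise scales (0.05 kcal/mol energy, 0 count jitter, 0.05 Å
  RMSD) are far below the planted effects, so classes — and hence
  grades — are unambiguous and planted-disruptor recall and precision
  are exactly 1 over repeated seeds; raising the noise lets classes flip
  and recovery degrade. Passing tests on these data show the scoring and
  grading machinery is correct under unambiguous conditions, not that
  real docking-parameter noise is well modelled.

## Numerical choices

Neutral tolerances when classifying raw pairs: 1e-9 for energies (exact
server outputs; only machine-precision ties are "no change"), 0 for
integer counts, 1e-3 Å for RMSD (sub-milliångström superposition noise).
Drug-score equality uses 1e-9. Median and category means are plain
arithmetic; reported means are rounded only for display, grading always
uses the unrounded mean. Orbit binning is total on [0, ∞) via clipping.
The Kabsch guard flips the smallest singular vector's sign when the
optimal orthogonal transform would be a reflection, which also handles
degenerate (collinear) point sets.

## Packaged fixtures

The two packaged TSVs transcribe the published prioritisation set (45
variants: 14 ROBO1, 23 SLIT2, 8 ROBO4, each with per-tool outcomes and
the printed total of 8 or 9) and the published docked-complex score
matrix (68 rows: 26 + 22 domain-level and 11 + 9 whole-protein
complexes, with per-parameter classes, printed totals and outcomes).
Integrity is enforced in tests: every stored total equals the sum of its
component scores and the printed value, and recomputed grades match
every printed more/less-disrupting outcome. One published category mean
(10.90 for the 22-complex ROBO4.IG1-2:SLIT2.D2 set) is the truncation of
240/22 = 10.909…, whose proper rounding is 10.91; the package reports
the rounded value and grades against the exact mean, which reproduces
all printed labels regardless.

## Limitations

* Predictor outputs, docking energies and pose-derived counts are
  consumed, never computed; the pipeline's conclusions are only as good
  as those inputs.
* Geometry criteria are fixed-cutoff conventions: no hydrogen placement,
  no water-mediated contacts, no energy model.
* The orbit formalisation (deciles of relative ASA) is one reasonable
  reading of spiral-plot rings, not a reimplementation of any specific
  plotting server.
* mmCIF, insertion codes and multi-model ensembles are out of scope for
  the PDB layer.
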