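# Methods

This note documents the models, rules and numerical choices implemented in
`abcconform`, the assumptions behind them, and what the synthetic-fixture
tests do and do not demonstrate.

## Domain-hit filtering and the functional-unit rule

Chain sequences are searched against a catalog of ABC-associated Pfam
profiles (29 entries spanning the NBD profile and the TMD families of five
clans; `src/abcconform/data/profile_catalog.tsv`, editable). The pipeline
consumes HMMER3 `--domtblout` tables; running the search itself is
delegated to a locally installed `hmmsearch`.

A hit is accepted iff

* per-domain independent E-value ≤ **0.001**, and
* HMM span ≥ **90 %** of the profile length, measured on profile
  coordinates as (hmm_to − hmm_from + 1) / profile_length.

The E-value threshold is applied to the *per-domain* independent E-value
rather than the full-sequence E-value: domains are the unit being counted,
and a sequence-level threshold would admit weak secondary domains on the
strength of a strong primary one. Same-chain hits of the same category
overlapping more than 50 % mutually are collapsed to the best-E hit before
counting, so one physical domain never counts twice.

Verdicts over the whole assembly (all chains pooled, so a homodimer of a
half transporter contributes both chains' hits):

| NBD hits | TMD hits | verdict |
|---|---|---|
| ≥ 2 | ≥ 1 | functional |
| ≥ 2 | 0 | needs_review (possible novel TM fold) |
| otherwise | | not_functional |

## Superposition and structural alignment

`kabsch` computes the optimal rigid superposition by the SVD formulation
with reflection correction; rank-deficient (collinear) point sets are
flagged. `tm_score` uses d₀ = 1.24·(L−15)^⅓ − 1.8, clamped below at
**0.5 Å** (the closed form turns unusable for short chains; at L ≈ 20 it
falls to 0.32 Å).

`structural_align` maximizes the TM-score without using sequence
information:

1. **Seeds.** Gapless threading at up to 21 evenly subsampled offsets, plus
   a 5×5 grid of 24-residue fragment-window superpositions. Window seeds
   reach alignments whose rigid frame no full-length threading produces
   (different fold topologies).
2. **Iteration.** Superpose on the current pairing (with a TM-maximizing
   inclusion-subset refinement, cutoff max(d₀, 4.5 Å)), score all
   query×reference pairs as 1/(1+(d/d₀)²), re-align by semi-global affine
   dynamic programming (gap-open **0.6** score units, gap extension free,
   terminal gaps free), repeat until the pairing is stable or 30
   iterations. Each seed gets two iterations; the best three seeds are
   iterated to convergence. Ties resolve by higher TM, then more pairs,
   then seed order — deterministic.
3. **Normalization.** The reported TM-score is normalized by the
   *reference* (class template) length: family assignment asks how much of
   the canonical fold is present. The query-normalized score is stored
   alongside.

The DP inner loop is numba-jitted; everything else is numpy. The aligner
is validated against an independent established aligner (biotite's
structural-homolog superposition with 3Di alphabet) on 50 pinned same-fold
pairs spanning ten fold types at coordinate noise 0.2–3.0 Å: maximum
TM-score difference ≈ 0.01 (tests assert ≤ 0.05). The comparison is
restricted to same-fold pairs because the external aligner is specified for
structural homologs and substantially under-scores non-homologous pairs
(we verified cases where it reports 0.25 for pairs whose achievable,
superposition-verified TM is 0.8). On cross-class pairs the suite instead
asserts both tools agree on the same-fold/different-fold decision at the
0.6 threshold.

`matched_rmsd` reports superposition RMSD over a given or shared-label
pairing; optional outlier rejection iteratively drops pairs farther than
2× the current RMSD (≤ 5 cycles), which makes conformation labels robust
to a few displaced loops.

## Family assignment

The query (whole assembly by default; a TMD-only extract in `tmd_only`
mode) is aligned to every class reference; the argmax class wins if its
reference-normalized TM exceeds **0.6**, else the entry is unclassified.
Whole-assembly is the default mode because assemblies are what the
pipeline ingests; the TMD-only mode exists because the classes are defined
by TMD scaffolds, and both scores are recorded. A Pfam class hint that
contradicts the structural winner raises a flag — that pattern (a TMD
profile hit whose structure aligns poorly to that family's reference) is
precisely how a new structural class is recognized, so it must surface,
not be auto-resolved.

## Conformational classification

**Conftor rule (primary).** Anchors are transferred onto each NBD by
structural alignment to an annotated reference NBD; the anchor is the query
residue paired with the reference anchor, falling back to the nearest
paired reference position within ±2 residues (flagged) when the anchor
itself sits in a gap. Alignment TM < **0.45** flags low anchor quality;
alignment failure yields an error-state record, never a batch abort. The
two cross distances are plain Cα–Cα Euclidean distances. The state is
**closed iff both distances < 14 Å** — both composite ATP sites must be
formed; closure of one site does not close the transporter bottom. The
inequality is strict (exactly 14.0 Å counts open) and any distance within
14 ± 2 Å raises a boundary flag. EcfT-like entries keep their computed
label but always carry an `ecf_special` advisory flag: their coupling-helix
architecture holds the NBDs together even without ATP, so the open/closed
vocabulary fits them poorly.

**RMSD rule (evidence).** The nearer of the bottom-open and bottom-closed
family references labels the entry; both RMSDs are reported. Near-ties
(< 0.01 Å) stay unassigned with a tie flag. When the two rules disagree
the conftor label wins and the record is flagged — the RMSD rule is known
to mislabel structures whose global fold resembles the wrong reference
while the NBD geometry is unambiguous.

Assemblies with more than two NBDs are split into disjoint pairs by greedy
minimal-centroid-distance matching (flagged `multi_unit`); an odd leftover
is flagged.

## Synthetic fixtures: what they emulate and what they do not

The generators produce mock assemblies with planted ground truth:

* **TMDs** are ideal-helix bundles (1.5 Å rise, 100°/residue, 2.3 Å
  radius) whose helix count (4–10), helix length (13–30 residues),
  footprint (ring / row / grid / vee), tilt and vertical stagger are
  class-specific. The nine architectures were designed, once, to be
  mutually distinct (measured cross-class TM < 0.56 in both alignment
  modes) — emulating the real situation, where the classes are genuinely
  different folds.
* **NBDs** are copies of a synthetic five-helix reference NBD (~90
  residues) carrying the two annotated anchors, so anchor location by
  alignment is exercised realistically. The second NBD's placement is
  solved in closed form (two-sphere intersection over candidate rotations,
  best steric clearance wins), making the planted Walker-A→signature
  distances exact to machine precision at zero noise.
* Cohorts sample correlated distance pairs (base separation ± small
  asymmetry): closed 8.5–11.8 Å, open 21.5–80 Å (clear of the 14 ± 2 Å
  boundary band, which is reserved for explicit boundary fixtures that
  plant one distance on each side of the cutoff). The default open:closed
  mix is 60:40, reflecting the predominance of bottom-open structures in
  experimental datasets. Gaussian coordinate noise (default σ = 0.3 Å) and
  a global random rigid transform are applied last.

What passing tests show: the geometry pipeline (anchoring, distances,
rules, alignment, batch plumbing) is correct and deterministic. What they
do not show: robustness to real structural heterogeneity — missing density,
domain flexibility, degenerate NBDs that align poorly, non-ideal helices,
hetero-oligomers with extra subunits. Real-data behavior depends on the
curated reference library; the shipped one is fully synthetic (labelled as
such) and uses the same on-disk layout, so curated references drop in
without code changes.

## Numerical and engineering choices

* Multi-model files: model 1 only. Altlocs: highest occupancy, ties by
  altloc letter. Insertion codes sort after the uninserted residue.
  HETATM-only chains are excluded from residue iteration but kept as
  metadata; ligands never enter Cα math.
* Author residue numbering is the canonical label; `label_seq` (1-based
  polymer position) is kept for sequence-to-structure mapping of hit
  coordinates and assigned sequentially when the file does not provide it.
* Batch runs process entries in sorted order and emit floats at fixed
  3-decimal precision, so identical inputs give byte-identical TSVs.
* Update detection is a pure manifest diff (SHA-256 content hashes);
  scheduling is left to the deployment.
* Problem sizes in the shipped validation: mock assemblies of ~300–500
  residues, cohorts of 50 (conformation recovery) and 45–100 trials
  (family recovery), 50 oracle pairs. These sizes give stable 100 %
  recovery rates while keeping the whole suite in the minutes range on one
  CPU.

## Known limitations

* Occluded and intermediate states are deliberately collapsed into the
  two-state vocabulary; distances near the cutoff are flagged rather than
  resolved.
* The TM-align-style aligner is a reimplementation of the scoring scheme,
  not a bit-exact reproduction of the published binary.
* The 0.6 class threshold and 14 Å cutoff are fixed defaults mirroring
  their published derivations; both are exposed as configuration.
* `hmmsearch` execution, structure download and UniProt lookups are outside
  the package: it consumes files.
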