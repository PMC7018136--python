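# Methods

## Overview

`jet2dna` predicts DNA-binding sites on protein surfaces from three kinds of
signal — evolutionary conservation, physico-chemical interface propensity and
surface geometry — without any machine-learned parameters. Predictions are
*patches*: connected sets of surface residues built in three concentric
layers (seed, extension, outer layer) that mirror the support / core / rim
organisation of experimental interfaces. The same package extracts and
classifies experimental interfaces from bound complexes, so predictions can
be evaluated closed-loop.

## Per-residue descriptors

All four descriptors live in [0, 1]:

* **T_JET** (conservation). Either supplied per residue in a TSV, or computed
  as *tree traces*: for each of several phylogenetic trees, the trace of a
  query position is the topological level (leaf = 0, root = 1 after
  normalising by the query leaf's root distance) of the highest ancestor
  whose entire subtree conserves the query amino acid at that position;
  T_JET is the mean trace over trees. Trees are neighbor-joining trees built
  from percent-identity distances on uniformly subsampled alignment rows
  (default 10 trees, up to 50 sequences each, seeded). This is a
  deliberately simplified conservation engine: the original method retrieves
  homologs with PSI-BLAST and samples sequences with a Gibbs-like scheme.
  The predictor only consumes a [0, 1] per-residue signal, so any external
  conservation score can be substituted through the file provider, which is
  the higher-fidelity path.
* **PC_DNA** (propensity). A per-amino-acid propensity to occur at
  protein-DNA interfaces, scaled by its maximum (the scale this package
  emulates spans 0 to 2.534, so the most DNA-avid residue maps to 1). The
  shipped table (`data/pc_dna_propensities_synthetic.tsv`) is a constructed
  stand-in that follows published enrichment trends (Arg and Lys highest,
  polar residues intermediate, acidic and hydrophobic residues low); swap in
  a published scale for production work.
* **CV_local / CV_global** (geometry). The circular variance of an atom is
  1 − |mean unit vector to all atoms within r_c|; a residue's CV is the
  unweighted mean over its atoms. Near 0 means protruding, near 1 means
  buried/enclosed. r_c = 12 Å captures local shape; r_c = 100 Å includes
  essentially every protein atom and captures the residue's position
  relative to the global shape (high CV_global = globally concave region).
  The neighbor test uses ≤ r_c; atoms with no neighbor inside r_c have
  undefined CV and are skipped in the residue mean.

Relative accessibility (rASA) is Shrake-Rupley SASA (biotite engine,
element-based van der Waals radii, 1.4 Å probe, 500 Fibonacci sample points
per atom by default) divided by a fixed per-residue reference maximum
(Tien et al. 2013 theoretical values, shipped as config). *Surface residues*
are those with rASA ≥ 5% — the threshold is a package choice, configurable.

## Scoring schemes

Each scheme sums two descriptors per layer (scores in [0, 2]); seed and
extension always share a formula because the two innermost interface layers
can swap spatial positions:

| scheme | seed / extension | outer layer | targets |
|--------|------------------|-------------|---------|
| D-SC1 | T_JET + PC_DNA | T_JET + (1 − CV_local) | generic conserved sites |
| D-SC2 | T_JET + CV_global | T_JET + PC_DNA | "enveloping" concave sites (polymerases) |
| D-SC3 | PC_DNA + (1 − CV_local) | same | sites without usable conservation |

D-SC3 uses one combination for all three layers (no separate outer-layer
variant is defined for it).

## Expected interface size

With x surface residues, the anticipated interface fraction is
f(x) = 2.66/x + 0.03 (decreasing to the 3% asymptote). The expected residue
count is f(x)·x rounded half-up, floored at 3 so the 1–2-residue patch
filter cannot nullify predictions on very small proteins.

## Clustering procedure

Candidate pools are rank pools over surface residues: the top
⌈expected/3⌉ residues by seed score (seeds empirically cover about a third
of an interface), the top ⌈2·expected/3⌉ by extension score, and the top
expected count by outer score. The exact thresholds of the original tool are
not published in its main text; these pool fractions and the floors below
are principled defaults, all configurable.

1. **Seeds** — connected components (minimal heavy-atom distance ≤ 5 Å)
   of the seed pool. Components of 1–2 residues are dropped at this stage
   only if a component of ≥ 3 exists; otherwise they are kept for growth.
2. **Pocket avoidance** — if a seed contains more than 20% (D-SC1) or 30%
   (D-SC2) residues with CV_local > 0.9 (fewer than ~3% of surface residues
   are that buried), it likely sits on a small-ligand pocket: seed detection
   restarts once with all highly buried residues banned. The ban is kept for
   the extension and outer pools as well, so a restarted run can never
   re-admit pocket residues in a later layer. D-SC3 never restarts (it
   selects protruding residues by construction).
3. **Extension** — repeatedly admit the best-scoring unassigned pool member
   adjacent to a patch, provided its score reaches 0.8 × the patch's current
   mean (recomputed on the current layer's score scale — layer formulas
   differ, so stored scores from other layers are not comparable). A residue
   adjacent to several patches merges them (both seeds are kept).
4. **Outer layer** — the same admission loop with the outer formula and a
   0.7 floor, stopping when the total prediction reaches the expected count.
5. **Relaxation** — if the viable prediction (patches of ≥ 3 residues; 1–2
   residue clusters are unconditionally discarded later, so they do not
   count towards the budget) is below 70% of the expected count, all steps
   rerun once with pools enlarged ×1.5 and floors lowered 10%.
6. **Filtering** — 1–2 residue patches are always removed. If the remaining
   total exceeds 70% of the expected count, patches are visited from the
   smallest and removed while they fall below the 95th percentile of the
   random-patch null, stopping when the total reaches the 70% band or all
   remaining patches pass.

**Random-patch null.** A patch is "no bigger than chance" if its size could
arise from spatial coincidence of the candidate pool alone. Each of 1000
seeded draws marks `expected` random surface residues and records the size
of the connected component containing the first mark. On sparse surfaces
this percentile is small (only genuinely tiny patches are removed); on dense
surfaces chance components are large and small secondary patches are pruned
aggressively. This reimplements the cited confidence filter's spirit with a
null tied to the algorithm's own pool size.

**Determinism.** Rank ties break by higher T_JET, then chain id, then
residue number; the filter RNG is seeded. Given fixed inputs and seed the
whole procedure is bit-for-bit reproducible.

## Automated scheme selection

Seeds are first detected with D-SC1 and their mean descriptors inspected:
mean T_JET < 0.3 (or no seeds at all) → D-SC3; else mean CV_global > 0.6
with mean PC_DNA < 0.9 → D-SC2; otherwise D-SC1. The three statistics are
always recorded in the decision trace. A manual scheme bypasses the tree and
is logged as such.

## Complete and iterative modes

*Complete* adds a second clustering round with the complementary scheme
(D-SC3 after D-SC1/D-SC2; D-SC1 after D-SC3) to catch interface subregions
with a different signal character. Residues already predicted in round 1 are
reported once; their round-1 patch gains dual provenance.

*Iterative* repeats the full prediction n times (run r reseeded with
seed + r; stochasticity enters through conservation subsampling and the
filter RNG) and reports per residue the detection probability
(detections / runs). The consensus prediction keeps residues detected in at
least k runs, rebuilt into connected patches; layer labels are set by
majority vote across runs (ties resolve seed > extension > outer). Raising
k never grows the prediction. No rule for choosing k is imposed; it is a
user parameter (2 of 10 gives extended predictions, 8 of 10 precise ones).

## Experimental interfaces and the support-core-rim model

For a bound complex, rASA is computed twice: with the nucleic partner
(rasa_DNA) and after deleting all nucleic atoms (rasa_free). Interface
residues lose area (Δrasa > 0, with a 10⁻³ %-point tolerance absorbing
sampling noise of the SASA engine). Labels: support (rasa_free < 25%,
rasa_DNA < 25%), core (≥ 25%, < 25%), rim (≥ 25%, ≥ 25%); the fourth
quadrant is impossible for a residue that loses area and raises an error.
Atomic contacts are protein/nucleic atom pairs strictly closer than 5 Å,
partitioned into backbone (phosphate + sugar: P, OP1-3, O5', C5', C4', O4',
C3', O3', C2', C1' — C1' assigned to the sugar by the phosphodiester
convention; the partition table is configurable) versus base atoms. RNA
chains are treated exactly like DNA.

## Evaluation

Predictions are scored against reference interfaces as residue sets over an
evaluation universe — surface residues by default (binding is a surface
phenomenon and the expected-size model is surface-based), all residues
optionally. Six metrics are reported ×100: sensitivity, PPV, specificity,
accuracy, F1 (harmonic mean of Sens and PPV) and MCC (range [−100, 100]).
Zero denominators yield an explicit `undefined`, never a silent 0. The
"best patch combination" mode unions every subset of per-scheme predictions
and reports the max-F1 combination, matching per-protein evaluation practice.
Paired method comparisons test the differences for normality
(Anderson-Darling, 5%) and then apply a paired t-test or the Wilcoxon
signed-rank test; p < 0.05 is significant.

## Synthetic data generator

The generator emulates exactly the features the predictor consumes:

* **sphere** — residues (5-atom rigid clusters with backbone-like names) on
  a Fibonacci shell, center spacing 4.5 Å so geometric neighbors fall
  reliably inside the 5 Å contact cutoff as on real protein surfaces; a
  planted cap of arginine/lysine residues carries conservation exceeding the
  background band (uniform 0.10–0.45) by at least the contrast (default
  0.4). Optional interior residues on tightly packed inner shells are
  genuinely buried (rASA < 5%).
* **concave-envelope** — a sphere with a quadratic-profile funnel (depth
  0.9 R, half-angle 0.8 rad) whose deep lining (conserved, mid-propensity
  polar types) has CV_global > 0.6, the regime the enveloping scheme is
  designed for.
* **pocket** — a conserved, high-propensity ring of residues lining a
  spherical void inside a dense atom blob, connected to the surface by a
  narrow channel: CV_local > 0.9 (nearly isotropic enclosure) while the
  1.4 Å probe still reaches them (rASA ≈ 7–10%).
* **bound pair** — the sphere plus a pseudo-DNA duplex (standard nucleotide
  atom names, bases facing the protein) hovering 3.8 Å over the planted cap,
  so interface extraction has a constructed answer.
* **alignment** — sequences evolved along a random bifurcating tree with
  chosen invariant columns and per-branch mutation probability.

What the fixtures do *not* emulate: real side-chain packing and chemistry,
sequence-dependent DNA geometry, conformational change, and realistic
conservation structure (real alignments have phylogenetic correlation far
richer than the per-branch mutation model). Passing tests therefore
demonstrate that the algorithmic machinery behaves as specified under known
signal, not that field performance on crystal structures is reproduced;
benchmark-scale validation requires real complexes and a production
conservation pipeline.

## Numerical choices and degenerate inputs

* SASA: 500 sample points per atom by default (≈ 0.25 Å² resolution per
  atom); rotation invariance holds to the sampling tolerance.
* Residues with unknown type (no reference area / no propensity) are
  excluded from surface sets and descriptor maps with a warning.
* Conservation scores clamp to [0, 1]; surface residues missing from a
  conservation file default to 0 with a warning.
* Altlocs resolve to the highest-occupancy conformer (first on ties);
  hydrogens and waters are dropped; MSE/SEC/PYL map to their parent residue;
  author numbering plus insertion codes are preserved end-to-end.
* The problem sizes used by the shipped verification runs (150-residue
  fixtures, 20 replicates per condition, 10 iterative runs) keep a full
  verification cycle under a minute on one CPU while leaving every code
  path exercised.

## Known limitations

* The conservation engine is a simplified stand-in (see above); use the
  file provider with production conservation scores when available.
* The propensity table is synthetic (constructed, clearly labelled); the
  published scale should replace it for real predictions.
* Exact threshold values of the original tool's supplementary material were
  not available; pool fractions and cluster floors here are principled
  defaults exposed in `ClusteringThresholds`.
* mmCIF input, multi-model NMR ensembles and bound↔unbound residue mapping
  beyond chain+number identity are out of scope.
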