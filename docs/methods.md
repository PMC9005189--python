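# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations behind `couplemap`. It documents what the
code computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py` at run time.

## Data model

The unit of observation is one concentration–response measurement:
(source, receptor, Gα subtype) with pEC50, raw Emax, basal mean, interday
basal SD, curve status, ligand metadata, and flags for enzymatic-unit
concentrations and endogenous-equivalent responses. The Gα panel covers the
16 human genes in four families; GNAO1 contributes two splice isoforms
(GoA/GoB), and cross-dataset analyses use the 12 subtypes measured by both
quantitative platform types (Gs, Gi1, Gi2, GoA, GoB, Gz, Gq, G11, G14, G15,
G12, G13). Chimeric-probe platforms measure some subtypes with a physically
identical probe; the panel records these equivalence classes
({Gi1, Gi2, transducins, gustducin}, {GoA, GoB}, {Gq, G11}) and ingest
duplicates one measured value to each member. Sources reporting a single
"Go" value are expanded to both GNAO1 isoforms so isoform-resolving and
non-resolving screens pair correctly.

Literature annotations are family-level (receptor → family →
primary/secondary). A receptor absent from the annotation table is "not
annotated", which is distinct from an annotated non-coupler; expansion to
subtypes marks every member of an annotated family as
annotated-coupling-possible.

## QC filters

Filters run in a fixed order — exclusions, unconverged-curve resolution,
enzymatic pEC50 shift (+10 log units, moving enzymatic-activity
concentrations onto the common scale), basal-SD cut-off — and the chain is
idempotent. Unconverged curves are kept only when another source supports
the pair and no quantitative source contradicts it ("contradicted" means
the other screen tested the pair and called non-coupling); the support
lookup defaults to subtype level and can be evaluated at family level.

The coupler call uses a strict inequality, Emax > basal + k·SD. Strictness
only matters on exact ties; it is the convention adopted here and is
configurable in spirit by nudging k. The SD is the interday basal SD as
supplied per (receptor, G protein, source); SDs are never pooled across
G proteins because interday variability differs widely between readouts.

## Choosing the cut-off k

`optimize_sd_cutoff` scans k over 0.0–3.0 in 0.1 steps, applies the cut-off
to both quantitative sources, and scores subtype-level mean agreement over
cells tested by both (untested cells are excluded, never imputed). The
objective is the unweighted mean of per-unit agreement fractions, so the
overall number decomposes exactly into the per-family or per-subtype values
reported next to it. Ties break toward the smallest k, making the optimum
deterministic. The level (subtype vs family) is an explicit argument; the
default is subtype, the finest grain both sources share.

## Harmonization protocol

Per source and G protein, basal-subtracted Emax is min–max normalized
across receptors: the minimum is pinned at 0 (the no-agonist signal), the
maximum — the strongest responder for that G protein — maps to exactly 1.
The combined activity is log10(emax_frac) + pEC50, defined for couplers
only (emax_frac > 0); it is bounded above by pEC50 with equality iff
emax_frac = 1. Families aggregate by the maximum subtype value (the
argmax subtype's Emax fraction and pEC50 are reported alongside); mean
aggregation exists solely for protocol comparison.

Protocol comparison scores each candidate (raw Emax, min–max Emax, double
normalization across G proteins after across receptors, raw pEC50,
combined value; family aggregation by max and by mean) with:

* mean similarity: the symmetric ratio min(x, y)/max(x, y) per common
  coupler datapoint. The symmetric form keeps the mean in (0, 1]
  regardless of which source is larger; this is an interpretive choice
  where a directional ratio would straddle 1, and it is recorded in the
  run manifest.
* receptor-wise and G-protein-wise mean r²: squared Pearson correlation of
  one receptor's (or one G protein's) paired profile, averaged unweighted
  over profiles with at least three common points.

Quantitative comparisons use only common couplers — cells where both
sources produced a pEC50 and Emax — because non-couplers cannot honestly be
represented by zeros in ratio or correlation statistics. The single
exception is the co-coupling Pearson analysis (below), where zero-filling
is the explicit convention.

## Evidence classification and the unified map

The annotation source self-supports (its entries typically rest on several
publications), so: *supported* = coupler in ≥ 2 sources, or annotated with
no quantitative test of the cell; *novel* = coupler in both quantitative
screens, unannotated; *proposed* = coupler in exactly one source with no
other source having tested the cell; *unique:s* = sole coupler while
another source tested and found nothing; *missing:s* = non-coupler where
another testing source couples. Novelty requires both screens above the
active cut-off, subtype-matched after equivalence-class and isoform
mapping. Map values average the quantitative couplers' harmonized values;
a cell with one coupling and one non-coupling screen keeps the coupling
source's value and a `missing` label — it is never averaged with zero.
Contradicted annotations are annotated families where every quantitative
source tested at least one member subtype and none called a coupling.

## Selectivity and co-coupling statistics

Promiscuity counts families per receptor over the full map (annotation-only
receptors contribute family-level presence). Within-family promiscuity
requires subtype data: only receptors with every analysis-panel member
tested enter the denominator. The Golf bookkeeping (receptors tested for Gs
but not Golf leave the Gs-family subtype counts; Golf counts only beside a
supported Gs coupling) activates when a testedness grid is supplied.

Co-coupling represents each G protein by its supported-activity vector over
receptors (per cell, the mean of the available source means). Pearson r and
two-tailed p (scipy `pearsonr`) use zero-filled vectors; Jaccard indices
and mean activity differences use coupler-only data. Significance stars
mark raw p ≤ 0.05/0.005/0.0005 without multiplicity correction, since the
matrix is reported descriptively. The correlation tree is average-linkage
clustering on the distance 1 − r; the tree is built from the correlation
matrix rather than from raw vectors (an open choice, fixed here), leaf
order is scipy's deterministic dendrogram order without optimal-leaf
reordering, and the tree serializes to Newick.

## Tissue expression

Input is a gene × tissue nTPM matrix in the Human Protein Atlas consensus
dialect. Conventions the statistics depend on, fixed here: the
first-quartile threshold uses linear-interpolation percentiles over all
matrix cells; tissues-above-threshold counts are inclusive (≥); per-gene
z-scores use the population (n) SD; the heatmap display cap is the median
of per-gene maxima. Real-atlas numbers depend on the data release and are
treated as validation-only: the package's tests run entirely on a
synthetic, HPA-shaped 16 × 50 fixture generated deterministically in code
(ubiquitous GNAS/GNAI2, retina-restricted transducins, gut-restricted
gustducin, and a brain-enriched block spanning all four families).

## Synthetic study conditions

The generator's defaults are the study conditions, not tuning knobs:

* family coupling prevalence (Gs 0.34, Gi/o 0.69, Gq/11 0.52, G12/13 0.19)
  — the full-scale family coverage fractions, giving ≈ 1.74 expected
  families per receptor;
* within-family member activation probability 0.9 (at least one member is
  always drawn for a coupled family), producing all-member activation
  fractions that fall with family size, as observed;
* true pEC50 ~ Normal(7, 1); fractional Emax uniform on (0.4, 1.0) with a
  15% weak tail on (0.05, 0.25) emulating couplings near the detection
  limit;
* assay models: basal 10 units (±10% per probe), interday basal SD ~ 2
  units (±50%), measurement noise 0.5–1 unit on Emax and 0.1 on pEC50;
  the heterogeneous scenario gives screen A asymmetric windows (Gs 40,
  G12 70, G15 1000, otherwise 100 units — small windows emulate
  low-signal readouts, the huge G15 window its three-order dynamic range)
  with reduced Gs/G12 sensitivity, and screen B chimeric probes with
  reduced G15 sensitivity;
* annotation reporting probability 0.8 per truly coupled family, 0.2 for
  G12/13 (historically under-assayed), strongest family ranked primary.

The threshold-recovery generator injects a detection threshold k\*
directly: weak couplers sit just above k\*·SD with independent per-screen
margins spread beyond the scan grid, non-couplers carry converged
near-basal curves whose noise tail (0.5·k\*·SD) reaches just below the
threshold. Agreement between the two screens is then maximal at k\* by
construction; the scan recovers it within one grid step for k\* in the
grid interior (≈ 1.2–2.9). All generators are bit-reproducible under a
fixed seed.

What the simulation does *not* model: mechanistic ligand–receptor
kinetics, receptor classes (all simulated receptors behave like one
class), ligand bias between sources, correlated interday drift, and
receptor-specific assay failures. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability under the
stated noise model — not that any particular biological coupling is real.

## Problem sizes and numerical notes

Tests and the acceptance script use 80–300 simulated receptors: 300 for
end-to-end recovery (precision/recall ≥ 0.95 in the low-noise regime),
150–200 for agreement, map-composition and co-coupling checks, 120–150 for
threshold recovery. These sizes give stable statistics (binomial SEs well
below the asserted margins) at a few seconds per run. Degenerate inputs
are defined: empty coupler sets flag Jaccard cells as NaN, constant
vectors yield NaN correlations (reported missing, excluded from trees),
all-non-coupler families aggregate to non-couplers, and receptors whose
every measurement falls below the cut-off stay in the receptor universe
with zero couplings. Agreement ties in the cut-off scan resolve to the
smallest k; argmax comparisons use a 1e-12 tolerance to avoid
floating-point ties.

## Known limitations

* The wide-layout workbook reader expects `<token>_pec50` -style columns or
  the canonical long layout; arbitrary third-party spreadsheet geometries
  need conversion first.
* Receptor synonym handling is minimal: identifiers must match across
  sources (an alias table can be applied upstream).
* The similarity symmetrization and the subtype-level optimization
  objective are documented interpretive choices; both have switches.
* No plotting: Venn regions, matrices and trees are emitted as
  counts/TSV/Newick for external rendering.
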