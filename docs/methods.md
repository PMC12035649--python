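# Methods

This note documents the models, parameter choices and numerical decisions
behind `mpith`, in the spirit of a package methods appendix. It states no
empirical result that the test suite does not itself compute.

## 1. Synthetic cohorts (`mpith.synthetic`)

**Count model.** Counts are negative binomial with gene mean μ and size
(dispersion) θ, so Var = μ + μ²/θ. NB rather than Poisson because droplet
scRNA-seq counts are overdispersed and the downstream NMF must tolerate
that noise floor. Defaults: `baseline_mean = 1.0` (a typical per-gene UMI
mean for moderately expressed genes at ~3k UMI/cell depth on a reduced
gene panel) and `dispersion = 2.0` (variance 1.5 at μ = 1, a mid-range
droplet value). Both are exposed in `CohortConfig`.

**Planted programs.** A planted program is a fixed gene set (default 50
genes, matching the downstream program size). Program activity is *binary*
per cell — each cell is independently active with probability
`activity_rate` — because binary truth makes recovery checks unambiguous
(a cell either carries the state or not). In active cells the NB mean of
every program gene is multiplied by `effect_size`. The default world is
**8 samples × 300 cells, 600 genes, three disjoint shared programs,
effect size 8, activity rate 0.2**: recurrent, strong co-expression
modules present in every sample. 600 genes keeps the expected chance
overlap between two random 50-gene lists at 50·50/600 ≈ 4.2 genes, safely
below the 8- and 10-gene clustering thresholds, while keeping a
44-sample × 6-rank NMF sweep inside a desktop runtime.

**What the generator does not emulate.** No doublets, no ambient RNA, no
batch effects, no gene–gene correlation outside the planted modules, no
continuous activity gradients, and a flat baseline mean across genes
(expression bins in the control scoring are therefore nearly degenerate —
the scoring still behaves correctly, but the bin-matching is exercised
more realistically in real data). A green recovery test therefore
establishes that the pipeline recovers strong, recurrent, disjoint modules
from overdispersed noise — not that it resolves subtle or correlated
states in real tumours.

**Spatial slides.** A slide is an `n_rows × n_cols` square lattice (a
simplification of the hexagonal Visium array, chosen because the
neighbourhood definition used downstream is the eight adjacent spots; a
6-neighbour hex mode exists for real array coordinates). Each planted MP
gets a smooth activity field in [0, 1]: uniform white noise box-filtered
over 3 × 3 windows, then min–max scaled. Smoothing matters — the
neighbourhood score of a spot reads its *neighbours*, so without spatial
autocorrelation in activity a planted association would be invisible to
the neighbourhood statistic. Per-spot cell-type weights are Dirichlet
draws with base concentration 2.0 per type; an `(mp, cell_type, slope)`
association adds `slope × activity` to that type's concentration (default
slope 6 against a total base mass of 10 across 5 types — a strong but not
degenerate tilt). Tumour spots (by default the interior rectangle at
margin 4, giving 1024 tumour spots on the default 40 × 40 grid) carry
NB expression in which MP genes are boosted by
`1 + (effect_size − 1) × activity`. The slide's planted modules occupy the
same gene blocks as the cohort's shared programs, so meta-programs
discovered from the cohort score coherently on the slide.

**Determinism.** Every generator call derives per-sample / per-stage
streams from `numpy.random.SeedSequence` spawns of the config seed;
identical configs give byte-identical Matrix Market output.

## 2. QC and normalisation (`mpith.preprocess`)

Cells are kept when detected genes > 300 **and** total counts < 7500
(strict inequalities, as the thresholds are conventionally quoted); genes
when detected in ≥ 100 cells; samples when ≥ 200 cells carry the malignant
flag. Malignant-cell identification itself (reference-based annotation)
and doublet removal are out of scope — the pipeline consumes a malignant
flag column, and the synthetic data contains no doublets.

The NMF input is `log2(1 + CPM/10)` per cell, mean-centred per gene across
cells, negatives clipped to 0. Centring focuses the factorisation on
relative expression differences between cells; clipping is forced by NMF's
non-negativity. A constant matrix therefore normalises to exactly zero,
and a cell with zero total counts is an error (named in the message)
rather than a silent NaN.

## 3. Per-sample NMF programs (`mpith.nmf`)

scikit-learn's coordinate-descent NMF with **nndsvd** initialisation,
`max_iter = 500`, `tol = 1e-4`. The deterministic double-SVD
initialisation makes gene lists reproducible under a fixed seed without
restarts; one run per (sample, K) is the default. Stopping at the
iteration cap is accepted behaviour (the downstream consumer is the top-50
gene ranking, which stabilises long before full convergence). Top-gene
ties break lexicographically on gene id so program content never depends
on input ordering.

## 4. Robustness filter (`mpith.robust`)

Percent thresholds are interpreted against the fixed program size of 50
genes: 70 % → ≥ 35 shared genes (criterion 1, against a different-K
program of the same sample), 20 % → ≥ 10 (criterion 2, against any program
of another sample), 30 % → dedup drops a candidate overlapping a retained
same-sample program by > 15 genes. Criterion 3 runs after 1–2 and
processes candidates in order of decreasing maximal inter-sample overlap
(ties: lower K, then factor index), so the more cross-sample-supported
copy of a redundant pair survives — the criterion's purpose is robustness.

**Idempotence.** A filtered `ProgramSet` carries a reference to its
original candidate universe, and the recurrence criteria are always
evaluated against that universe. Without this anchor a second application
would empty the set: de-duplication removes exactly the cross-rank
partners criterion 1 looks for.

**Monotonicity.** The criteria-(1,2) pass set is inclusion-monotone in the
thresholds by construction. The composite filter is **not**
inclusion-monotone: greedy de-duplication keeps exactly one member of a
redundant pair, and raising a threshold can eliminate the retained blocker
and un-block its duplicate. What holds, and what the tests assert, is
criteria-level ⊆-monotonicity plus non-growth of the composite output
size.

## 5. Meta-program clustering (`mpith.cluster`)

Founders need > 5 supporting programs at ≥ 8 shared genes (strict: 6
supporters, i.e. a 7-program family). The cluster seeds with the founder
and its highest-overlap partner; the consensus list is completed to 50
genes by ranking on (member frequency desc, mean NMF weight across
carrying members desc, gene id asc) — the frequency-first rule generalises
"genes common to the members" to any member count. Accretion admits the
remaining program with the largest overlap (≥ 10 genes) against the
*current* MP genes and recomputes the MP after every admission; accretion
never steals members from earlier clusters (member sets are disjoint, and
the audit trail records the overlap at each admission). Leftover programs
are reported unassigned, never forced in. All tie-breaks fall back to
(sample id, K, factor index) so clustering is order-independent.

## 6. Cell scoring and assignment (`mpith.assign`)

One parameterised bin-matched control score covers both scoring uses:
genes are ranked by average log-normalised expression and split into
`n_bins` equal-size bins (ties on gene id, making the binning permutation
invariant); each signature gene contributes its centred expression minus
the mean centred expression of `n_ctrl` control genes drawn without
replacement from its bin (the full bin, deterministically, when the bin is
no larger than `n_ctrl` — hence an all-gene signature with all-gene
controls cancels to exactly zero). Defaults: 30 bins / 100 controls for
assignment scores, 24 bins for the continuous module scores used in
correlations. Control draws are seeded and iterate signature genes in
sorted order, so scores are reproducible and invariant to gene and cell
order.

Assignment: arg-max per cell (ties → first MP in input order); an MP is
scored only with ≥ 25/50 genes present; MPs topping < 5 % of cells (the
boundary is inclusive) are dropped in a single pass and their cells
labelled `unresolved` — not reassigned to the runner-up, and not iterated
to a fixpoint, since dropping never changes the labels of retained MPs;
post-drop prevalence is recorded for auditing.

## 7. Spatial statistics (`mpith.spatial`)

The neighbourhood of a spot is the 8 Moore-adjacent lattice positions that
exist (truncated at edges/corners: 5/3 neighbours; no renormalisation —
the score is a plain sum of available neighbour weights). The
neighbourhood score of any column (cell-type weight or per-spot signature
score) at a tumour spot is the sum over its neighbourhood. MP–TME
correlation pools (MP score, neighbourhood score) pairs across all tumour
spots of all slides without per-slide standardisation; per-slide matrices
are emitted alongside so robustness across slides can be checked.
Zero-variance series produce NaN with a warning, never a silent zero.

## 8. Orchestration (`mpith.pipeline`, `mpith.cli`)

`run_pipeline` executes the stages in order from a single `RunConfig`
(defaults = the reference parameters: K 4–9, 50-gene programs,
35/10/15-gene overlap thresholds, founder 8/>5, accretion 10, 25-gene
conservation, 5 % prevalence), deriving per-stage seeds from the master
seed via `SeedSequence` spawn keys, and writes line-delimited JSON logs
plus a manifest with SHA-256 hashes of every artifact; reruns with the
same config reproduce identical hashes.

## Known limitations

- The generator's flat baseline means leave the expression bins nearly
  degenerate; bin-matching is structurally exercised but not stressed.
- With two planted spatial MPs, their signature scores are strongly
  anti-correlated by construction (what one module gains, the other's
  controls absorb), so a null-association MP on an association slide
  inherits a mirrored correlation; null behaviour is therefore asserted on
  slides generated with all slopes zero.
- The founder rule is strict (> 5 supporters): program families with ≤ 6
  robust copies cannot found a meta-program, so small cohorts (< 7 samples
  carrying a state) will not recover it.
- Gene identifiers are compared as exact strings; no synonym or ortholog
  handling.
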