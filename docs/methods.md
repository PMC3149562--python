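# Methods

This note records the models, conventions and numerical choices behind
h1yinyang, and what the synthetic benchmarks do and do not demonstrate.

## Numbering convention

All reported positions are 1-based on the *met-cleaved* scale by
default: the initiator methionine is removed (as it is on the mature
protein) and the first retained residue is position 1, one below the
database canonical coordinate. `ProteinRecord.numbering_offset` records
the offset to the canonical scale (0 raw, −1 met-cleaved), and `raw`
numbering is selectable per record. The published per-subtype site maps
this package emulates are written on the met-cleaved scale (e.g. the
mitotic H1.2 phosphosite appears as Ser-172 where the canonical UniProt
coordinate is 173), which is why met-cleaved is the default. Unknown
residues map to X and are never S/T candidates.

## Motif scanning

The scanner matches the proline-directed kinase consensus (S/T)PXZ and
(S/T)PXK at every position, reporting the hit at the S/T residue (how
single-position site maps list motifs). Z defaults to the basic set
{K,R,H} and may be restricted to {K,R}. A tetramer ending in K
satisfies both classes and is reported once per class; a dedupe flag
collapses to one hit per position, keeping the more specific STPXK.
Overlapping motifs are all reported — no greedy consumption. The scan
is O(L) and position-shift equivariant; tests verify exact set equality
with an independently coded regex oracle.

## Conservation model

Conservation is computed from a *consumed* alignment (any aligner
producing Clustal or aligned FASTA); the package deliberately contains
no alignment algorithm, which keeps it self-contained and testable.
For each reference S/T column, with the reference row excluded:

- `conserved` — every counted cell equals the reference residue;
- `conserved_substituted` — every counted cell is inside the
  substitution group (fixed to {S,T} for this analysis: both are
  hydroxyl acceptors for kinases and OGT) and at least one differs;
- `not_conserved` — otherwise.

Strict agreement (all rows) is the default, matching an analysis based
on 4–5 orthologs with full agreement; `min_support` relaxes it to a
fraction. Gap cells break conservation by default (`gap_policy=ignore`
drops them from the count instead). `support` is the fraction of
counted cells inside the substitution group, so conserved and
conserved-substituted columns always carry support 1 and, strictly, any
support < 1 is not conserved. Cross-species experimental sites whose
column maps to a conserved or conserved-substituted reference S/T are
transferred as `by_similarity` evidence, never duplicating existing
reference evidence.

## Window scorer

The built-in predictor encodes a window (default 9 residues, centre ±4)
as one-hot blocks of 21 bits — 20 amino acids plus one shared
pad/unknown symbol used beyond the termini — and feeds them to a
single-hidden-layer network (default 4 logistic units, logistic
output). Training is scikit-learn's MLP (adam, learning rate 0.01,
epoch cap 400, stopping on a training-loss plateau); held-out accuracy
is estimated by stratified k-fold cross-validation (default 5) with a
fresh network per fold, after which the final network is refit on all
examples. We stop on the loss plateau rather than a held-out validation
split because at the data sizes involved a 10% split is small enough
for score-based early stopping to trigger at chance level while the
optimiser is still on the initial plateau of the logistic units.

Scoring is a plain numpy forward pass over the stored weights, and the
model serialises to JSON, so a saved model reproduces its scores
bit-identically. The decision threshold is fixed at 0.5 for both the
phospho and glyco arms; predictors that publish a per-residue varying
threshold are approximated by this constant (a recorded limitation —
imported score tables may carry their own per-row thresholds, which are
honoured). Tyr residues are scored by phospho models only; O-GlcNAc
does not occur on Tyr. This scorer is a generic member of the
window-classifier family used by public phosphorylation/O-GlcNAc
servers and is not claimed to replicate any particular trained server;
external exports are imported as score tables instead.

## Interplay calling

Per scored S/T site, with phospho threshold θp, glyco threshold θg and
FN margin δ:

- phospho arm positive: score ≥ θp **or** the site is experimentally
  known to be phosphorylated. The disjunction is a documented choice:
  published proposed-site tables anchor several sites on experimental
  evidence the de novo predictor misses.
- `yin_yang`: phospho arm positive and glyco score ≥ θg.
- `fn_yin_yang`: phospho arm positive and θg − δ ≤ glyco score < θg.
- `phospho_only` / `glyco_only` / `negative`: the remainder — the five
  classes are mutually exclusive and exhaustive.

Ties at a threshold count as positive (≥ rule), so the FN band is
half-open below the threshold. δ defaults to 0.1: "very close to
threshold" is quantified nowhere in the source analyses, so the margin
is an explicit, tunable parameter. The proposed-site report keeps
conserved / conserved-substituted sites only (switchable), partitioned
into Ser and Thr lists. Raising δ can only grow the FN list; raising θg
can only shrink the Yin-Yang list (tested monotonicities).

## Synthetic families

`synthetic_data.generate_family` draws a reference from an H1-like
composition (K 0.22, A 0.22, P 0.09, S 0.06, T 0.04, remainder spread
over the other residues — linker histones are strongly Lys/Ala/Pro
rich), plants non-overlapping (S/T)PXK tetramers at random positions
(default 10 in 220 residues, the order of magnitude seen on real H1
tails), freezes a random column subset (default probability 0.5) plus
all motif columns, and mutates non-frozen columns in each of the
orthologs (default 4, substitution probability 0.3/column). Truth
labels on reference S/T are Bernoulli draws from an explicit logistic
model over window cells (intercept −4; +8 for P at +1; +2.5/+1.5 for
K/R at +3), giving a background acceptor probability of ~2% and
near-certain labels on motif sites; the glyco truth copies the phospho
truth with probability `dual_site_corr` (default 1 — the simplest model
of competing-site structure) and draws from its own logistic model
otherwise; `noise_rate` flips labels (default 0). Emitted score tables
carry the label-model probabilities, standing in for external predictor
exports. Families are gap-free by default so the column↔position map is
trivially checkable; `n_indels` plants 3-column gap blocks to exercise
gap handling. One `numpy` generator seeded from the single config seed
drives every draw.

What passing the synthetic benchmarks shows: the scanning, conservation,
propagation, scoring and calling machinery is correct against
independent oracles and recovers planted structure. What it does not
show: performance on real proteins — real predictor scores are not
logistic functions of a 4-cell pattern, real conservation is
phylogenetically structured rather than i.i.d. per column, and real
dual-modification correlation is unknown. The bundled nine-subtype
records are likewise synthetic stand-ins constructed to carry the
curated annotation positions; results on them demonstrate coordinate
bookkeeping, not biology.

## Problem sizes and benchmarks

The shipped test suite and `scripts/acceptance.py` use: 1000 random
sequences (length ≤ 500) for scanner/oracle equality; 100 families of
length 120 for the conservation recount; 2000 windows (5-fold CV) for
predictor accuracy and its permuted-label null, with ROC measured on
1000 fresh windows; one default family (length 220, 10 motifs) for the
end-to-end recovery plus a byte-identity rerun. These sizes give stable
pass/fail behaviour across seeds while keeping a full run in seconds.

## Curated annotations and their conflicts

`annotations.py` carries the published per-subtype site map
(experimental, predictor-positive, motif, conservation and proposed
columns) as met-cleaved position lists; it is an *input*, never
recomputed. A few printed positions are mutually inconsistent on one
sequence (a position claimed S in one column and T in another, or
falling on an obligatory P/K slot of a printed motif). The fixture
builder resolves these by priority (motif > experimental > phospho
predictor > glyco predictor > conserved > conserved-substituted >
proposed/FN) and drops losing rows. The ortholog sets behind the
published conservation classes are not public, so those classes ship as
annotations rather than being recomputed from an alignment.

## Known limitations

- Constant 0.5 thresholds approximate predictors with wavy per-residue
  thresholds.
- Strict conservation ignores phylogeny (each ortholog counts equally).
- The built-in scorer shares no weights with the public servers whose
  exports it can import; per-kinase prediction is import-only.
- The FN margin, the experimental-OR-predicted phospho arm, and the
  conservation filter are explicit parameters; published proposed-site
  lists mix precedence rules that are not fully specified, so exact
  list reproduction is not a goal.
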