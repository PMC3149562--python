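# h1yinyang

Proposing phosphorylation / *O*-β-GlcNAc interplay ("Yin-Yang") sites on
human linker histone H1 subtypes, as a reusable, tested pipeline.

## The problem

Linker histone H1 sits on the DNA between nucleosomes and its
post-translational state helps decide whether chromatin condenses or
opens. Two modifications compete for the same Ser/Thr hydroxyl:
phosphorylation by proline-directed kinases (CDK2 and relatives, which
recognise the consensus **(S/T)PXZ** / **(S/T)PXK**, X any residue, Z
basic) and *O*-β-GlcNAc added by OGT. A residue where the two can
alternate is a **Yin-Yang site**; a residue whose O-GlcNAc potential
lands just *below* the predictor threshold while the phospho arm is
positive and the position is conserved is a **false-negative (FN)
Yin-Yang site**. This package implements the in-silico procedure for
proposing such sites on the nine human H1 subtypes (H1.1–H1.5, H1.0,
H1t, H1oo, H1x), for computational biologists who want the calling
logic to be reproducible and testable rather than buried in manual
web-server runs.

## What it computes

Per S/T residue *i* of a subtype (positions in met-cleaved numbering,
i.e. one below the database canonical position):

- **motif scan** — hits of (S/T)PXZ ∪ (S/T)PXK, reported at the S/T;
- **conservation** — from a consumed multiple alignment, each reference
  S/T column is `conserved` (all counted rows identical),
  `conserved_substituted` (all rows within {S,T}, at least one differs)
  or `not_conserved`; cross-species experimental sites on conserved
  columns propagate to the reference as "by similarity" evidence;
- **modification potential** — a score in [0,1] per residue, either
  imported from external predictor exports (NetPhos/YinOYang-style
  TSVs) or produced by the built-in sliding-window scorer: windows of
  21-bit one-hot blocks feeding one logistic hidden layer, trained with
  stratified k-fold cross-validation; positive ⇔ score ≥ threshold
  (default 0.5);
- **interplay call** — with phospho arm `P = (s_p ≥ θ_p) ∨ experimental`
  and glyco score `s_g`:
  `yin_yang` iff `P ∧ s_g ≥ θ_g`;
  `fn_yin_yang` iff `P ∧ θ_g − δ ≤ s_g < θ_g` (FN margin δ = 0.1);
  remaining classes `phospho_only`, `glyco_only`, `negative`.
  Proposed-site reports keep only conserved / conserved-substituted
  positions, partitioned by Ser vs Thr.

A synthetic-data module generates H1-like ortholog families with
planted motifs, frozen columns and correlated phospho/glyco truth, so
every stage is testable offline. The bundled nine "H1" records are
**synthetic stand-ins** (built so the curated annotation positions hold
on them), not the SWISS-PROT sequences.

## Worked example

```
$ h1yinyang fixture-bundle --outdir bundle
$ h1yinyang scan --fasta bundle/h1_synthetic.fasta --numbering met_cleaved --out hits.tsv
28 motif hits -> hits.tsv
$ awk -F'\t' 'NR==1 || $1=="P16403"' hits.tsv
seq_id  position  residue  motif_class  tetramer
P16403  30        T        STPXK        TPAK
P16403  145       T        STPXK        TPAK
P16403  153       T        STPXK        TPAK
P16403  172       S        STPXK        SPAK
```

H1.2 (P16403) shows the CDK consensus at Thr-30/145/153 and at Ser-172,
the site phosphorylated during mitosis. Running the full caller on the
bundled tables:

```
$ h1yinyang run --fasta bundle/h1_synthetic.fasta \
    --phospho-scores bundle/phospho_scores.tsv \
    --glyco-scores bundle/glyco_scores.tsv \
    --evidence bundle/evidence.tsv \
    --conservation-table bundle/conservation.tsv \
    --outdir out
pipeline complete; outputs: ['calls', 'conservation', 'evidence', 'glyco_scores',
'hits', 'phospho_scores', 'proposed_sites', 'site_map']
$ awk -F'\t' '$1=="P16402"' out/proposed_sites.tsv
P16402  yin_yang     S  51
P16402  yin_yang     S  188
P16402  fn_yin_yang  S  104
P16402  fn_yin_yang  T  92
P16402  fn_yin_yang  T  154
```

For H1.3 (P16402), Ser-188 — experimentally phosphorylated and
O-GlcNAc-positive in the imported table — is proposed as a Yin-Yang
site, while Ser-104 and Thr-92/154 score just under the O-GlcNAc
threshold on conserved positions and come out as FN-Yin-Yang. The same
`run` command accepts `--alignment` to compute conservation from a
Clustal/aligned-FASTA file instead of a precomputed table, and
`simulate` emits a fully synthetic family to play with.

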