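# motifdms

Deep mutational scanning (DMS) of short protein interaction motifs, built
around the saturation-mutagenesis screen of the Rad54 Rad51-interaction
motif in *S. cerevisiae* (residues T101–L144, carrying the FxxP
recombinase-docking motif at F131–P134).

In such a screen, every 3-codon window of the motif is randomized to NNN
(each base an equal mix of A/C/G/T), yielding 20 amino acids × 44 positions
= 880 single-amino-acid variants. A yeast library carrying the variants is
plated on methyl methanesulfonate (MMS), survivors are deep-sequenced, and
each variant's fitness is read off the change in pool composition.

The package provides:

- **Library design** (`motifdms.motif`): motif/window/variant-space
  definitions, residue-number arithmetic, motif scanning, window translation
  and variant classification (wild-type / single / multi / stop).
- **Read processing** (`motifdms.read_processing`): amplicon filtering —
  a read is kept only if it carries the exact 20-bp constant sequence
  upstream *and* downstream of a 9-bp window — window extraction, counting
  and an exactly conserved rejection ledger.
- **Enrichment scoring** (`motifdms.enrichment`): for each amino-acid
  variant *v* at a window, the fold-enrichment

  *FE(v) = f_selected(v) / f_input(v)*

  of pseudocounted normalized frequencies, wild-type-normalized per
  position and log-transformed:

  *score(v) = log10( FE(v) / FE(wt) )*

  so wild-type scores 0, −0.7 ≈ 5-fold depleted, −2 = 100-fold depleted
  (the heat map's green/white/red anchors). Low-input variants are flagged
  `omitted_low_input` rather than scored.
- **Conservation** (`motifdms.conservation`): alignment-column profiles,
  information content, 5-residue moving-average conservation tracks, and
  natural-vs-screen sequence-logo comparison.
- **Structure contacts** (`motifdms.structure`): polar contacts (donor–
  acceptor < 4 Å, 110–180° angle at the donor heavy atom), hydrophobic
  carbon–carbon contacts (< 4.5 Å), Shrake–Rupley SASA (probe 1.4 Å, 960
  points, pinned Bondi-style radii) and buried surface area
  *BSA = SASA(A) + SASA(B) − SASA(A∪B)* between a peptide and a protomer
  pair, plus 5′/3′-facing protomer labeling along the ssDNA.
- **Synthetic screens** (`motifdms.simulate`): NNN library sampling,
  multinomial selection with per-variant fitness, FASTQ emission with
  per-base sequencing error — byte-identical under a fixed seed — so every
  stage is testable against known truth.

## Worked example

Simulate one 3-codon window screen (wild-type `TKR` at residues 101–103,
100,000 reads per pool, planted deleterious residue 101), then count and
score it:

```bash
motifdms simulate --spec window1.cfg --reads 100000 --seed 7 --outdir screen7
motifdms count --spec window1.cfg --input screen7/input.fastq    --label input    --out in_counts.tsv
motifdms count --spec window1.cfg --input screen7/selected.fastq --label selected --out sel_counts.tsv
# concatenate the two TSVs into counts.tsv, then:
motifdms score --spec window1.cfg --counts counts.tsv --out landscape.tsv --controls controls.json
```

which prints

```
100000 reads, 96011 matched -> in_counts.tsv
100000 reads, 95973 matched -> sel_counts.tsv
landscape (3 positions) -> landscape.tsv
```

96% of reads pass the flank filter — exactly (1−ε)⁴⁰ for the ε = 10⁻³
per-base error rate acting on 40 flank bases. The controls report shows the
internal positive and negative controls behaving as in a real screen:
wild-type enriched (FE ≈ 19.6), stop-codon class depleted
(FE ≈ 0.0013):

```
{'wildtype_fold_enrichment': {'0': 19.59}, 'stop_fold_enrichment': 0.0013, 'stop_depleted': True, 'n_scored': 36}
```

and the most depleted cells in `landscape.tsv` are the substitutions at the
planted deleterious position 101, with scores near −2, i.e. the planted
100-fold fitness deficit read back off the landscape:

```
 position wildtype_aa amino_acid  input_count  selected_count  log10_score flag
      101           T          V           21               1     -2.45     ok
      101           T          I           11               1     -2.18     ok
      101           T          R           24               4     -2.03     ok
```

The same machinery applied with the packaged 44-residue Rad54 motif
(`motifdms design`) enumerates the 880-variant library and locates the FxxP
phenylalanine at residue 131.

## Notes

- The DNA reference codons and constant flanks packaged for the Rad54 motif
  are synthetic stand-ins (the screen's plasmid sequence is not
  distributed); peptide sequences and residue numbering are the real ones.
- Buried-surface-area values for the peptide–protomer interfaces
  (1651.4 Å² for the Rad54 peptide, 1,494.4 Å² for the Hed1 peptide) were
  reported from PISA on the deposited models. Given those models, the same
  quantity can be recomputed here (`motifdms contacts --complex model.cif
  --unit-a C --unit-b A,B --bsa-report bsa.json`) and is expected to agree
  to within ~10%, the spread typical between SASA engines and radii sets.
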