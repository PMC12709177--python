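# dhhkit

Analysis toolkit for **standalone DHH–DHHA1 exoribonuclease families**
(NrnB-like nanoRNases): motif-anchored domain segmentation, redundancy
clustering, progressive alignment, distance phylogenetics, clade-diagnostic
feature extraction with a rule-based A/B/C classifier, exonuclease-polarity
assay models, and a synthetic family generator so the whole pipeline is
testable offline.

## Pipeline stages

| module | purpose |
| --- | --- |
| `dhhkit.sequences` | FASTA I/O, exact `DHH`/`GGGH` motif scanning, offset-based domain segmentation (DHH region / linker / DHHA1 region / C-terminal tail), standalone DHH–DHHA1 inclusion filter |
| `dhhkit.clustering` | greedy incremental identity clustering (CD-HIT-style; identity = identical aligned pairs / shorter length; prokaryote 0.70 / eukaryote 0.90 profiles) |
| `dhhkit.alignment` | affine-gap global alignment (BLOSUM62), UPGMA guide tree, profile–profile progressive MSA, >95 %-gap column filter, aligned-FASTA import/export |
| `dhhkit.phylogeny` | p / Poisson distance matrices (pairwise deletion), neighbor joining, midpoint rooting, seeded bootstrap supports, major-clade extraction, Newick I/O |
| `dhhkit.features` | reference-anchored numbering (e.g. position 285), linker/C-terminal features, per-column entropy & logo matrices, rule-based clade classifier |
| `dhhkit.assays` | degradation-ladder simulation with blocked (phosphorothioate) linkages, exonuclease polarity inference, depletion-trace normalization, malachite-green standard curves, c-di-AMP phosphate stoichiometry |
| `dhhkit.synthetic_data` | three clade archetypes evolved along Yule trees with truth labels + true tree, synthetic assay tables |
| `dhhkit.workflow` | end-to-end composition: scan → cluster → align → filter → NJ → midpoint root → clades → classify |

Coordinates are 1-based with closed intervals throughout.

## CLI

One subcommand per stage (`dhhkit --help` for full options):

```bash
dhhkit simulate --seed 1234 --n-per-clade 20 --out-dir data/
dhhkit scan     --fasta data/dataset.fasta --out segm.tsv
dhhkit cluster  --fasta data/dataset.fasta --profile prokaryote --out clusters.tsv
dhhkit align    --fasta data/dataset.fasta --out aln.fasta
dhhkit tree     --alignment aln.fasta --bootstrap 1000 --seed 1 \
                --out-newick tree.nwk --out-annotations annot.tsv
dhhkit classify --alignment aln.fasta --reference-id A_01 \
                --signature-position 100 --out calls.tsv
dhhkit entropy  --alignment aln.fasta --out entropy.tsv
dhhkit assay    --mode ladder --substrate AUGAGCAAAGGUGAAGAACU --blocks 10 \
                --polarity three_to_five --out ladder.json
```

## Notes

* The aligner and the NJ/bootstrap machinery are self-contained substitutes
  for external MSA/ML tools so that no subprocess dependencies are needed;
  externally produced alignments can be imported with
  `dhhkit align --import-alignment`.
* Synthetic truth labels live only in record labels and the sidecar
  `labels.tsv`; the analysis pipeline never reads them outside tests.
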