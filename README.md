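# synlab

Simulation and interpretation toolkit for base-resolution, multi-task TF
binding profiles governed by a known regulatory grammar.

The package builds a fully controlled synthetic world — planted motif
instances with affinity scaling, strictly spaced cooperative double motifs,
distance-dependent ("soft syntax") cooperativity between a cell-type factor
and a signaling factor, an indirect task tracking a direct binder, and
ChIP-nexus-like stranded footprints with count noise — and then runs the
full interpretation stack against it:

* **`synlab.sim`** — grammar configuration, synthetic genome/profile
  simulation, and an analytic oracle `BindingPredictor` implementing the
  same grammar (noise-free ground truth for every downstream stage).
* **`synlab.model`** — a small dilated-convolution sequence-to-profile
  network (multinomial profile loss + log-counts head) written in pure
  NumPy with hand-verified backprop, plus evaluation metrics (counts
  Spearman, profile Jensen-Shannon distance, binned auPRC).
* **`synlab.attribution`** — per-base contribution scores for any predictor
  (gradient x input vs dinucleotide-shuffled references, or the oracle's
  exact marginals), seqlet extraction, and greedy CWM/PWM motif discovery.
* **`synlab.mapping`** — motif instance calling by CWM scanning
  (continuous-Jaccard similarity + contribution filters) and PWM log-odds
  scanning, reciprocal-overlap dedup, footprint validation, and a scanner
  benchmark.
* **`synlab.insilico`** — motif injection into randomized backgrounds, the
  binding-enhancement statistic `log2((hAB - (hB - h0)) / hA)`, distance
  sweeps, whole-vs-half double-motif cooperativity, spacing edits, and
  minimal-mutation / motif-moving enhancer design.
* **`synlab.syntax`** — contribution-vs-distance statistics, motif islands
  (merged 500 bp windows), IUPAC double-motif spacing scans, and
  motif-variant frequency analysis.
* **`synlab.io_cli`** — FASTA/BED/bedGraph/MEME I/O, YAML run configs, the
  `synlab` CLI, and the end-to-end pipeline.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
scaled-down end-to-end run (simulate a 2 Mb three-task genome, train the
model, recover the planted grammar) that takes several minutes on one CPU.
Everything else completes in ~2 minutes.

## CLI

```bash
synlab run --out runs/demo                 # full pipeline, oracle predictor
synlab run --predictor trained --out runs/t  # with model training
synlab simulate --out runs/sim             # genome + truth + bedGraph profiles
synlab train --run runs/sim                # train on a simulated run dir
synlab sweep --motif-a ACATTCCTG --motif-b CCCTCAGGC --task tead4 \
             --out curve.tsv               # enhancement vs distance
synlab coop --double-sequence ACATTCCTGGCACATTCCTG --split 11 \
            --task tead4 --out coop.json   # whole vs summed half-sites
synlab doublescan --fasta genome.fa --out spacings.tsv
synlab scan-pwm --fasta genome.fa --motif tead=ACATTCCTG --out hits.bed
```

Every command takes `--config` (YAML overriding documented defaults, see
`synlab.io_cli.config.DEFAULTS`) and `--seed`. Run directories carry a
`manifest.json` with config hash, seeds, and per-stage timing; all outputs
declare 0-based half-open coordinates.

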