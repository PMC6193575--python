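# gpsuc

Prediction of lysine succinylation sites from protein sequence.

Succinylation flips the charge of a lysine side chain from +1 to −1 and
is involved in metabolic regulation across bacteria, fungi, plants and
mammals. Experimentally mapped sites are scarce, so candidate lysines
are ranked computationally. `gpsuc` is a library and command-line tool
for researchers who want to train, inspect and apply such a predictor
on their own data — fully offline, with every stage testable.

## The method

Each candidate lysine is represented by a 41-residue window (±20 flank,
`-`-padded at termini) and, optionally, a PSI-BLAST PSSM profile slice.
Five feature blocks are computed per site:

* **AAC** (20): residue frequencies in the window, centre excluded;
* **BE** (820): one-hot encoding of each window position;
* **AAindex** (492): per-position values of 12 physicochemical scales;
* **PSSM** (820): the flattened 41×20 profile window;
* **pCKSAAP** (2000): profile-based k-spaced pair composition,
  S_ab(k) = Σ_r max(min(P[r,a], P[r+k+1,b]), 0) / (L−k−1), k = 0..4.

Features are screened per block by a two-sample Wilcoxon rank-sum test
(exact permutation p-values where feasible, tie-corrected normal
approximation otherwise) and the pCKSAAP/AAindex blocks are cut to a
top-N (generic preset 390/250; nine species presets included). Each
block feeds its own random forest; the five channel scores S_n are
fused by a zero-intercept logistic regression

    log(P/(1−P)) = Σ β_n S_n,

fitted on out-of-fold channel scores under a β ≥ 0 constraint. A site
is called succinylated when P reaches a cutoff chosen for 90%
specificity. Published per-species coefficient sets are available as
presets (e.g. `FusionModel.from_preset("h_sapiens")`). Compositional
diagnostics (positional amino-acid frequencies, mean PSSM and property
values, Kruskal-Wallis and chi-square tests with Bonferroni correction)
are provided alongside the predictor. See `docs/methods.md` for the
full model description and design rationale.

When no PSI-BLAST profiles are available, a deterministic BLOSUM62
pseudo-profile stands in, so the entire pipeline runs from sequence
alone.

## Worked example

Simulate a motif-enriched dataset, train, predict and evaluate — all
through the CLI:

```sh
gpsuc simulate --seed 1 --out-dir data --n-proteins 60 --effect-size 1.0
gpsuc train   --fasta data/proteins.fasta --sites data/sites.tsv \
              --pssm-dir data/pssm --model model --seed 1 \
              --n-trees 100 --folds 5 --ratio \
              --top-n pCKSAAP 150 --top-n AAindex 80
gpsuc predict --fasta data/proteins.fasta --pssm-dir data/pssm \
              --model model --out predictions.tsv
gpsuc evaluate --predictions predictions.tsv --sites data/sites.tsv \
               --cutoff 0.66 --out metrics.json
```

Training chose a specificity-targeted decision cutoff of 0.664 (stored
in `model/fusion.json`), so the evaluation threshold is set to 0.66.
The evaluate step prints (numbers from this exact run):

```json
{
 "Ac": 0.9448584202682563,
 "Sp": 0.9348591549295775,
 "Sn": 1.0,
 "MCC": 0.8293305947645213,
 "AUC": 0.9976240940790374,
 "cutoff": 0.66,
 "counts": {
  "nTP": 103,
  "nTN": 531,
  "nFP": 37,
  "nFN": 0
 }
}
```

`AUC` is the threshold-free ranking quality over all lysines of the
input (0.998: nearly every true site ranks above every background
lysine — expected here, since the model is evaluated on its own
training proteins and the simulated motif is strong). `Ac`, `Sp`, `Sn`
and `MCC` are confusion-matrix metrics at the chosen cutoff: every true
site is recovered while 37 of 568 background lysines are mislabelled.
The same steps are available as library calls
(`gpsuc.synthetic`, `gpsuc.model.train_gpsuc`, `gpsuc.model.predict`,
`gpsuc.evaluate`).

To use real data, provide your own FASTA, a tab-separated site table
(`protein_id  position  label`, 1-based positions, labels
`positive|negative|+1|-1`) and optionally a directory of
`<protein_id>.pssm` files from PSI-BLAST `-out_ascii_pssm`.

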