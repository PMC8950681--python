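# idrpred

Per-residue prediction of intrinsically disordered protein regions (IDPRs)
from sequence-derived features, for bioinformaticians studying protein
disorder and for method developers who need a transparent, fully
reproducible disorder-prediction pipeline.

Disordered regions — stretches of a protein that lack a stable tertiary
structure — drive molecular recognition, signalling and regulation, and
are expensive to map experimentally. `idrpred` classifies every residue
of a protein as ordered or disordered from a `35 × L` feature matrix
combining:

* **20 evolutionary channels** — the log-odds columns of a PSI-BLAST PSSM
  (supplied by the user; a BLOSUM62 pseudo-profile is available for
  profile-free runs), window-averaged;
* **7 physicochemical scales** and **3 disorder propensities**,
  window-averaged;
* **Shannon entropy** and **topological (subword-complexity) entropy** of
  the residue window;
* **persistent entropy**: each window is embedded on a cylinder in R³
  (residue identity → angle, position → height), the Vietoris–Rips
  persistence diagram of the point cloud is computed, and its bar-length
  entropy `E = −Σ pᵢ log₂ pᵢ` becomes the feature;
* **PCAA2 / PCAA3**: corpus-wide dipeptide/tripeptide probabilities,
  min–max scaled and positionally averaged.

The classifier is an MLP → VGG19-style convolutional backbone → MLP with
a skip connection, trained per-residue with binary cross-entropy and SGD
on "packages" of 128 residues. It is implemented from scratch in numpy
(hand-written backprop); predictions in eval mode are exactly
reproducible. Evaluation reports Sens, Spec, BACC and MCC over pooled
residues, with protein-level cross-validation.

## Worked example

Everything below runs offline; the synthetic generator plants a known
order/disorder signal and fabricates PSI-BLAST-style profiles.

```bash
idrpred simulate --out-dir demo --n-proteins 20 --seed 7
idrpred build-kmer-table --sequences demo/sequences.fasta --k 2 --out demo/k2.tsv
idrpred build-kmer-table --sequences demo/sequences.fasta --k 3 --out demo/k3.tsv
idrpred train --sequences demo/sequences.fasta --labels demo/labels.txt \
    --pssm-dir demo/pssm --kmer-table-2 demo/k2.tsv --kmer-table-3 demo/k3.tsv \
    --scale small --epochs 3 --lr 0.01 --seed 7 --model-out demo/model.npz
idrpred evaluate --sequences demo/sequences.fasta --labels demo/labels.txt \
    --pssm-dir demo/pssm --kmer-table-2 demo/k2.tsv --kmer-table-3 demo/k3.tsv \
    --model demo/model.npz
```

The evaluate step prints the pooled per-residue metrics, e.g.

```
                     Sens     Spec     BACC      MCC
pooled             0.9292   0.9793   0.9542   0.8923
```

Sens is the fraction of truly disordered residues recovered, Spec the
fraction of ordered residues kept, BACC their mean, and MCC the Matthews
correlation of the 2×2 confusion table (1 = perfect, 0 = chance). Here
the model was evaluated on its own small training corpus, so the numbers
mainly confirm the pipeline learns the planted signal; held-out behaviour
is what `scripts/acceptance.py` measures.

In Python, the same pipeline is three calls:

```python
from idrpred.pipeline import planted_recovery_experiment
out = planted_recovery_experiment(seed=1)
print(out["report"].table_row("held-out"))
```

Other subcommands: `featurize` (write the 35×L matrices as TSV),
`predict` (per-residue probability TSV for unlabelled sequences), `cv`
(protein-level k-fold cross-validation, with `--sweep` over window
sizes). Feature extraction is library-accessible per module:
`idrpred.tda.persistent_entropy_track`, `idrpred.kmers.pcaa_track`,
`idrpred.profiles.assemble_feature_matrix`, etc.

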