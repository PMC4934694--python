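# rnaiface

Per-residue prediction of protein–RNA interface residues from evolutionary
profile features, together with the machinery around it: structure-based
interface labeling, PSSM generation and comparison, and uniform subsampling
of the reference database that makes profile generation fast.

## The problem

Many proteins bind RNA through a small set of surface residues. Given only a
protein sequence, the task is to label each residue as *interface* (within
5 Å of any atom of a bound RNA, measured on a solved complex structure) or
*non-interface*. The standard feature representation is the PSI-BLAST
position-specific scoring matrix (PSSM): an L×20 matrix of log-odds
conservation scores obtained by iterative search against a large protein
database. Building those profiles against a 50-million-sequence database is
the computational bottleneck of every server in this family — and, as it
turns out, unnecessary: profiles built against a small *uniform random
sample* of the database are nearly as informative (and sometimes more so)
at a fraction of the cost.

## The method

1. **Labeling.** Parse protein–RNA complexes (PDB), mark residue *i* as
   interface iff min over atom pairs ‖a − r‖ ≤ 5 Å for any RNA atom r.
   Benchmark admission criteria: resolution < 3.5 Å, protein length ≥ 40,
   an RNA chain of ≥ 5 nt, ≥ 3 interface residues, ≤ 30 % mutual sequence
   identity.
2. **Features.** Run PSI-BLAST (3 iterations, e-value 0.001) to get a PSSM;
   squash each score x through the logistic f(x) = 1/(1+e⁻ˣ); encode each
   residue by the 25-residue window centred on it → 25 × 20 = 500 features
   in (0,1), with 0.5 padding past the termini.
3. **Classifier.** Gaussian naive Bayes (NB), 100-tree random forest
   (RF100), linear and RBF-kernel SVMs (SVML, SVMRBF), and the **consensus**
   — the elementwise mean of the SVMRBF and RF100 interface probabilities,
   p = (p_SVMRBF + p_RF100)/2 — which tolerates the noisier profiles from a
   1 % database sample.
4. **Evaluation.** ACC, Sn, Sp, MCC at a probability threshold (default
   0.5, ties positive) and ROC AUC, under chain-level 5-fold
   cross-validation (whole chains, balanced on residue counts, never split
   across train and test).
5. **Database subsampling.** A k % sample keeps ceil(n·k/100) records drawn
   uniformly without replacement (reservoir sampling, order-preserving,
   seed-reproducible). Profile drift between databases is measured by NSSD
   (mean squared entry difference) and symmetrized, normalized KL
   divergence (NKL) between same-query profiles.

## Worked example

Synthetic planted-signal data stands in for a curated benchmark: interface
labels are drawn at 15 % per residue, and interface residues receive a mean
shift of `effect_size` (raw-score units) in five profile columns.

```python
from rnaiface import (SignalSpec, synth_profile_dataset, encode_chain,
                      make_folds, cross_validate, ModelSpec)

profiles, annotations = synth_profile_dataset(
    n_chains=20, chain_len=100, spec=SignalSpec(effect_size=1.0, seed=7))
by_chain = {a.chain_id: encode_chain(p, a)
            for p, a in zip(profiles, annotations)}
folds = make_folds([(c, len(d)) for c, d in by_chain.items()], k=5, seed=7)
result = cross_validate(by_chain, ModelSpec(algorithm="CONSENSUS", seed=7), folds)
print(f"pooled AUC = {result.pooled.auc:.3f}")
print(f"pooled MCC = {result.pooled.mcc:.3f}")
```

prints

```
pooled AUC = 0.887
pooled MCC = 0.477
```

AUC 0.887 means a randomly chosen interface residue outranks a randomly
chosen non-interface residue 88.7 % of the time, while MCC 0.477 reflects a
conservative default threshold on imbalanced data (sensitivity 0.305 at
specificity 0.992 here). At the generator's default `effect_size=3.0` the
signal is fully separable and both reach 1.0; at `effect_size=0.0` the
pooled AUC sits at chance (≈ 0.5).

The same pipeline is scriptable from the shell:

```sh
rnaiface synth profiles --n-chains 20 --chain-len 100 --seed 7 --out work/
rnaiface encode --labels work/labels.txt --pssm-dir work/ --out work/data.npz
rnaiface cv --dataset work/data.npz --algorithm CONSENSUS --out report.json
rnaiface sample-db --mode fraction --k 1 --seed 42 big.fasta small.fasta
```

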