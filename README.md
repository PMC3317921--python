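# barcodeval

Evaluation toolkit for multi-locus DNA-barcoding species identification.

DNA barcoding assigns specimens to species by comparing a short
standardized marker (the mitochondrial COI 5' fragment for animals, often
supplemented by the nuclear ribosomal spacers ITS1/ITS2) against a
reference library. For *closely related* species — sibling species still
undergoing incomplete lineage sorting — identification is hard: within-
and between-species genetic variation overlap, haplotypes are shared
across species boundaries, and nuclear markers frequently fail to
sequence at all. This package provides the full evaluation machinery a
study of such a system needs, for anyone comparing barcode markers or
assignment methods:

- **K2P distances and the barcoding gap.** Pairwise Kimura 2-parameter
  distances with pairwise deletion of gap/N columns,
  `d = -½·ln(1−2P−Q) − ¼·ln(1−2Q)` with P/Q the transition/transversion
  proportions; intra- vs inter-specific distance partitions, shared-axis
  histograms, and per-species gaps `min(inter) − max(intra)`.
- **Three assignment methods.** Minimum distance (MD: nearest reference's
  species), best close match (BCM: nearest reference, but *unidentified*
  beyond the 95th percentile of intraspecific distances), and a
  backpropagation neural network (BP: one hidden layer over one-hot
  encoded alignment columns; learning rate 0.2, momentum 0.5, MSE goal
  1e-5).
- **Resampling evaluation.** Leave-one-out (500 replicates) and random
  reference:query splits (9:1, 1:1); success rate `p̂ = N_hit / N_query`
  with a Wilson score confidence interval; and the sequencing-corrected
  **overall success rate** `p̂ × n_sequenced / N_submitted`, which
  multiplies assignment success by the fraction of specimens that
  actually sequenced at every locus of the barcode.
- **Haplotype networks.** Collapse alignments to haplotypes under
  "missing" or "5th-state" gap handling, flag haplotypes shared between
  species, and build the minimum-spanning network of mutation steps.
- **Synthetic data generator.** A seed-deterministic generator emulating
  a six-species design — three well-separated species and a sibling trio
  with ILS haplotype sharing — with three loci (652/804/656 aligned
  columns), ITS-like indels, and per-locus sequencing dropout, plus a
  truth table for parameter-recovery testing.

## Worked example

```python
from barcodeval import evaluate_barcode, generate, paper_preset

dataset, truth = generate(paper_preset())   # 140 specimens, 6 species, 3 loci
rep = evaluate_barcode(dataset, ["coi", "its1", "its2"],
                       method="md", design="loo", n_reps=500, seed=11)
print(f"assignment success {rep.p_hat:.1%} "
      f"(95% CI {rep.ci_low:.1%}-{rep.ci_high:.1%}), "
      f"sequencing {rep.seq_success:.1%}, overall {rep.overall:.1%}")
```

```
assignment success 97.2% (95% CI 95.4%-98.3%), sequencing 32.1%, overall 31.2%
```

The three-gene barcode assigns 97% of queries correctly *among specimens
that sequenced at all three loci* — but only 32% of specimens did, so the
overall identification rate a user would actually experience is 31%.
Single-locus runs (`examples/success_rates.py`) show the flip side: the
COI-like locus sequences for every specimen, so its assignment rate *is*
its overall rate. The `examples/` directory has one short script per
capability (simulation, gap analysis, classification, success rates,
haplotype networks), each printing the numbers it computes and what they
mean.

A thin CLI wraps the same calls:

```bash
barcode-eval simulate --preset paper --out scratch/data
barcode-eval evaluate --data scratch/data --method md --loci coi --design loo --seed 1
```

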