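"""Success rates with confidence intervals and sequencing correction.

Runs the leave-one-out design (500 replicates) for the single-locus and
three-locus barcodes, printing the assignment success rate, its 95%
Wilson interval, and the overall rate after multiplying by the fraction
of specimens that sequenced at every locus of the barcode — the number
that matters when a marker often fails to sequence.
"""

from barcodeval import evaluate_barcode, generate, paper_preset

dataset, _ = generate(paper_preset())

print(f"{'barcode':<16} {'success':>8} {'95% CI':>17} {'seq.':>7} {'overall':>8}")
for loci in (["coi"], ["its1"], ["its2"], ["coi", "its1", "its2"]):
    rep = evaluate_barcode(dataset, loci, method="md", design="loo",
                           n_reps=500, seed=11)
    name = "+".join(loci)
    print(f"{name:<16} {rep.p_hat * 100:7.1f}% "
          f"({rep.ci_low * 100:5.2f}-{rep.ci_high * 100:5.2f}%) "
          f"{rep.seq_success * 100:6.1f}% {rep.overall * 100:7.1f}%")
print("\nA multi-locus barcode can assign perfectly yet score poorly "
      "overall when one locus rarely sequences.")
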