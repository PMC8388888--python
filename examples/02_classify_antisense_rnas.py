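"""Classify non-coding transcripts into sRNA / asRNA I and detect II/III pairs.

sRNAs are trans-encoded (no opposite-strand overlap); asRNAs I overlap an
annotated feature antisense; asRNAs II arise from divergent (5'-overlap)
and asRNAs III — cutoRNAs — from convergent (3'-overlap) transcription.
"""

from astrx import antisense, evaluate, reannotation, simulate

truth = simulate.generate_truth(seed=2)
predictions = [
    simulate.split_prediction(
        simulate.fragment_predictions(truth, timepoint=tp, seed=2)
    )
    for tp in (48, 72, 96, 120)
]
coverage = simulate.emit_coverage(truth, seed=2)
result = reannotation.reannotate(
    predictions, truth.genes, coverage=coverage, repeats=truth.repeat_regions
)

catalog, divergent, convergent = evaluate.classify_result(result)
summary = antisense.summarize_classes(catalog, divergent + convergent)

print(f"{'class':10s} {'count':>5s} {'median len':>10s} {'median overlap':>14s}")
for name in ("sRNA", "asRNA_I", "asRNA_II", "asRNA_III"):
    row = summary[name]
    med_len = row.get("median_length")
    med_ov = row.get("median_overlap_length")
    print(
        f"{name:10s} {row['count']:5d} "
        f"{med_len if med_len is not None else '-':>10} "
        f"{med_ov if med_ov is not None else '-':>14}"
    )

flagged = [r for r in catalog if antisense.below_containment_threshold(r)]
print(
    f"\n{len(flagged)} asRNA(s) cover < 90% of their length on their targets "
    "(partial antisense overlap)"
)
for rec in flagged[:3]:
    print(
        f"  {rec.id}: [{rec.start}, {rec.end}] {rec.strand} "
        f"containment {rec.containment_frac:.2f} targets {rec.targets}"
    )
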