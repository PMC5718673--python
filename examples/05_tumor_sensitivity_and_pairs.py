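"""Tumor sensitivity of the metrics + intrapatient pair enumeration.

Part 1 inserts a 30 mm and a 60 mm artificial spherical tumor into a
phantom lung, misaligns the exam, registers it back, and compares how far
each metric moves between the pre-aligned and final stages (the interval
width): the most sensitive metric moves most. Part 2 enumerates all
unordered intrapatient exam pairs from the packaged exam schedule.
"""

from lungreg.experiment import enumerate_pairs, load_exam_schedule, tumor_metric_study

study = tumor_metric_study(diameters_mm=(30.0, 60.0), n_phantoms=2, seed=0)
med = study.groupby("metric")["interval_width"].median().sort_values(ascending=False)
print("median prealigned-to-final interval width per metric:")
print(med.round(4).to_string())
print(f"-> nMI moves {med['nMI'] / med['nSSD']:.1f}x more than nSSD: "
      "the mutual-information score is the most tumor-sensitive metric\n")

schedule = load_exam_schedule()
counts = dict(zip(schedule["patient"], schedule["exam_count"]))
plans, total = enumerate_pairs(counts)
k = next(p for p in plans if p.patient == "K")
print(f"patient K: {len(k.exam_ids)} exams -> {k.count} pairs")
print(f"all {len(plans)} patients -> {total} intrapatient registrations")
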