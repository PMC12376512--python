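"""Assay-trace metrics: glucose-curve AUC and mito-stress respiration.

Builds a glucose-tolerance curve and a phase-labelled oxygen-consumption
trace, then computes the total trapezoidal AUC and the standard
respiration metrics.
"""

from lipsmr import AssayParams, auc_trapezoid, generate_assay_traces, respiration_metrics

times = (0, 15, 30, 60, 120)
glucose = (5, 15, 12, 9, 6)  # mmol/L over 2 h
print("GTT AUC (mmol/L x min):", auc_trapezoid(times, glucose))
print(
    "incremental AUC:",
    auc_trapezoid(times, glucose, baseline_subtract=True),
)

trace = generate_assay_traces("ocr", AssayParams(noise_sd=2.0), seed=1)
m = respiration_metrics(trace)
print("\nOCR trace (pmol O2/min), phases baseline->oligomycin->FCCP->rot/AA")
print(f"  non-mitochondrial : {m.non_mito:7.2f}")
print(f"  basal             : {m.basal:7.2f}")
print(f"  ATP-linked        : {m.atp_linked:7.2f}")
print(f"  maximal           : {m.maximal:7.2f}")
print(f"  spare capacity    : {m.spare:7.2f}  (= maximal - basal)")
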