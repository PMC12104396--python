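"""Audit a published per-drug summary table without raw plate data.

Replay mode feeds reported total IC50s (µM) straight into the
extrapolation chain: unbound IC50 (fu_inc = 0.02), Ki,u by the regulatory
/2 shortcut, unbound Cmax (fu = 0.01) in both units, and the static-model
Cmax,u/Ki,u ratio against the inclusive 0.02 cutoff.  The printed ratio
column of the source table is also passed in so the report shows where the
computed ratios disagree with it.
"""

from cypscreen import builtin_profiles, flag_printed_ratios, render_report, replay_ic50s

reported_ic50_um = {
    "Omeprazole": 1.41, "Lansoprazole": 1.65, "Pantoprazole": 3.52,
    "Rabeprazole": 6.43, "Ilaprazole": 6.62,
}
printed_ratios = {
    "Omeprazole": 0.0288, "Lansoprazole": 0.00332, "Pantoprazole": 0.00124,
    "Rabeprazole": 0.000635, "Ilaprazole": 0.00224,
}

result = replay_ic50s(reported_ic50_um, builtin_profiles())
print(render_report(result.assessments, printed_ratios=printed_ratios,
                    provenance=result.provenance))

flags = flag_printed_ratios(printed_ratios, threshold=0.02)
print("Threshold calls on the printed ratios themselves:", flags)
print("\nOnly omeprazole reaches the 0.02 cutoff on the printed ratios; the "
      "ratios recomputed from the table's own Cmax,u and Ki,u columns are "
      "all below it (see the discrepancy section above).")
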