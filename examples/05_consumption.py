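"""Continuous vs segmented sample-consumption accounting.

Reproduces the campaign bookkeeping: hits per microlitre of crystal
suspension, the fold-change of segmented over continuous injection, and the
percent volume reduction at matched duration.
"""

from dropjet import consumption_report, continuous_waste_fraction, EUXFEL, hit_rate_percent

report = consumption_report(
    [
        ("continuous", 26.0, 260.0, 577),
        ("segmented-subset", 26.0, 110.0, 735),
        ("segmented-all", 134.0, 962.0, 5770),
    ],
    reference_label="continuous",
)

cols = ["minutes", "volume_ul", "hits", "hits_per_ul", "fold_change", "percent_reduction"]
print(report.table[cols].round(1).to_string())
print()
print(f"average Q_aq of the segmented subset: "
      f"{report.table.loc['segmented-subset', 'q_aq_ul_min']:.1f} uL/min")
print(f"campaign hit rate: {hit_rate_percent(37_000, 4_100_000):.1f}% of images")
print(f"jet time never probed by any pulse (continuous injection): "
      f"{100 * continuous_waste_fraction(EUXFEL.schedule):.2f}%")
# Segmented injection collected ~3x more hits per microlitre than the
# continuous jet at matched duration, cutting suspension use by ~60%,
# while a continuous jet runs unprobed >99% of the time between trains.
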