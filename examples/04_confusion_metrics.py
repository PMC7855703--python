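"""Confusion-matrix metrics on the packaged reference cohort tables.

Metric names are orientation-explicit: row ratios normalize the diagonal by
row totals, column ratios by column totals — which of these is "precision"
vs "recall" depends on whether rows hold truth or predictions.
"""

import histomap as hm

for name in ("melanoma", "tnbc", "neuroblastoma"):
    cm = hm.load_reference_table(name)
    print(f"{name}: {cm.total} superpixels, {len(cm.class_names)} classes")
    print(f"  overall accuracy  {hm.overall_accuracy(cm):5.1f} %")
    print(f"  macro row ratio   {hm.macro_row_ratio(cm):5.1f} %")
    print(f"  macro col ratio   {hm.macro_col_ratio(cm):5.1f} %")

cm = hm.load_reference_table("tnbc")
print("\nnecrosis vs stroma in the breast-cancer table "
      "(the clinically hard distinction):")
print(f"  necrosis row ratio {hm.class_row_ratio(cm, 'necrosis'):.1f} %  "
      f"col ratio {hm.class_col_ratio(cm, 'necrosis'):.1f} %")
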