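# Reference confusion matrices

Three confusion matrices transcribed from a published evaluation of
superpixel tissue classification on three cohorts, used here to validate the
metric arithmetic in `histomap.evaluation`:

- `table4_melanoma.csv` — 6 classes, 14,092 test superpixels (melanoma).
- `table5_tnbc.csv` — 6 classes, 10,349 test superpixels (triple-negative
  breast cancer).
- `table6_neuroblastoma.csv` — 8 classes, 9,868 test superpixels (mouse
  neuroblastoma).

Format: CSV with a header row and index column of class names; entry (i, j)
counts items labeled class_i by the first stream and class_j by the second.

## Documented inconsistencies in the printed summary figures

Two summary figures printed alongside the original tables do not recompute
from the tables' own entries and are therefore excluded from exact checks:

- Melanoma table: the printed "average recall = 98.5%" does not match any
  single consistent normalization of the table (the column-normalized macro
  ratio computes to 98.8).
- Neuroblastoma table: the printed "overall accuracy = 98.3%" recomputes to
  98.2 from the table entries (trace 9,695 / total 9,868 = 98.25%); treated
  as a printing/rounding inconsistency.

All other printed summary figures for these tables (overall accuracies,
macro row/column ratios, and the per-class necrosis and differentiation
ratios) recompute exactly after half-up rounding to one decimal.
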