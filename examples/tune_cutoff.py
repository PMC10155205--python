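"""Select a high-precision decision threshold from the packaged sweep table.

The packaged table records, for a 10-fold cross-validated classifier on a
98-compound training split (67 highly / 31 poorly permeable), the precision
and true/false-positive counts at each probability cutoff. Raising the
cutoff trades recall for precision; the default rule picks the smallest
cutoff leaving at most one false positive.
"""

from hiascreen import select_cutoff
from hiascreen.metrics import ConfusionMatrix, precision
from hiascreen.tuning import RULE_MAX_PRECISION, reference_sweep_table

table = reference_sweep_table()
print("threshold  precision  TP  FP   TPR")
for row in table.rows:
    print(f"  {row.threshold:6.4f}    {row.precision:5.3f}  {row.tp:3d} {row.fp:3d}  {row.tpr:.3f}")

for fp_max in (1, 0):
    sel = select_cutoff(table, fp_max=fp_max)
    row = next(r for r in table.rows if r.threshold == sel.threshold)
    cm = ConfusionMatrix(tp=row.tp, tn=0, fp=row.fp, fn=0)
    print(f"fp_max={fp_max}: threshold {sel.threshold} "
          f"(precision {precision(cm):.3f}, keeps {row.tp} true positives)")

sel = select_cutoff(table, rule=RULE_MAX_PRECISION)
print(f"literal max-precision rule: threshold {sel.threshold}")
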