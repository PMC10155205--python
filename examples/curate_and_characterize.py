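"""Curate a small SMILES+HIA table and characterize its diversity.

Builds a six-molecule table with a deliberate duplicate (two spellings of
ethanol with disagreeing HIA), deduplicates it, labels each compound at the
85% absorption boundary, and summarizes pairwise Tanimoto similarity and
molecular weight — the three features used to judge a screening dataset's
applicability domain.
"""

from hiascreen import (
    assign_class,
    deduplicate,
    make_record,
    similarity_summary,
    weight_summary,
)

raw = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 100.0),
    ("serotonin", "NCCc1c[nH]c2ccccc12", 75.0),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 88.0),
    ("sulpiride", "CCN1CCCC1CNC(=O)c1cc(S(N)(=O)=O)ccc1OC", 36.0),
    ("ethanol", "CCO", 100.0),
    ("ethanol-dup", "OCC", 90.0),  # same structure, conflicting HIA
]

records = [make_record(name, smiles, hia) for name, smiles, hia in raw]
dataset = deduplicate(records)

print(f"{dataset.n_raw} rows -> {dataset.n_unique} unique molecules")
for rec in dataset.records:
    label = assign_class(rec.hia_percent)
    kind = "highly" if label == 1 else "poorly"
    print(f"  {rec.id:12s} HIA {rec.hia_percent:5.1f}%  -> class {label} ({kind} permeable)")

sim = similarity_summary(dataset)
wt = weight_summary(dataset)
print(f"tanimoto ({sim.fingerprint_spec}): "
      f"min {sim.min:.3f} median {sim.median:.3f} max {sim.max:.3f}")
print(f"mol weight g/mol: min {wt.min:.2f} median {wt.median:.2f} max {wt.max:.2f}")
print("low median similarity + wide weight range = broad applicability domain")
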