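"""Sevenfold augmentation and the 7:2:1 stratified split.

Expands a manifest of 1088 crops (the six transforms plus the original
per crop gives 7616 rows), then splits per class with the leakage guard
so all seven variants of one original land in the same subset. Also
prints the per-variety split table that follows from the seven
published per-variety totals under the floor / round-half-up /
remainder rule.
"""

import pandas as pd

from hyperseed import AugmentationParams, SplitSpec, assign_split, expand_dataset, split_counts

manifest = pd.DataFrame(
    {"path": [f"seed{i:04d}.png" for i in range(1088)],
     "label": [f"H{i % 7 + 1}" for i in range(1088)]}
)
expanded = expand_dataset(manifest, AugmentationParams())
print(f"{len(manifest)} crops -> {len(expanded)} rows after sevenfold expansion")

split = assign_split(expanded, SplitSpec(rng_seed=0))
counts = split.groupby("split").size()
print(f"grouped split sizes: {dict(counts)}")
families = split.groupby("origin")["split"].nunique()
print(f"augmentation families straddling splits: {(families > 1).sum()}")

print("\nper-variety 7:2:1 table from the published totals:")
print(f"{'variety':>8} {'total':>6} {'train':>6} {'val':>5} {'test':>5}")
for name, n in [("H1", 1085), ("H2", 1085), ("H3", 1099), ("H4", 1085),
                ("H5", 1064), ("H6", 1120), ("H7", 1078)]:
    tr, va, te = split_counts(n)
    print(f"{name:>8} {n:>6} {tr:>6} {va:>5} {te:>5}")
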