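"""Generate a synthetic payment universe and look at its shape.

Builds the default-calibration bundle — 34 donor companies, 7,500 practices,
one dominant donor — and prints the quartiles of the single-payment value
distribution next to their calibration targets (£170 / £320 / £869).
"""

import numpy as np

from payline import generate_bundle, normalize_vat

bundle = generate_bundle(seed=42)
payments = normalize_vat(bundle.payments)  # analysis happens VAT-exclusive

print(f"payments: {len(payments)}, practices in registry: {len(bundle.registry)}")
q1, med, q3 = np.quantile(payments["amount_gbp"], [0.25, 0.5, 0.75])
print(f"single-payment value quartiles: £{q1:,.2f} / £{med:,.2f} / £{q3:,.2f}")
print("calibration targets:            £170.00 / £320.00 / £869.00")

by_company = payments["company"].value_counts()
print(f"\ndominant donor: {by_company.idxmax()} with {by_company.max()} payments"
      f" (next largest: {by_company.iloc[1]})")

counts = bundle.truth.groupby("practice_code").size()
print(f"practices receiving payments: {len(counts)}; "
      f"share receiving at most two: {(counts <= 2).mean():.1%}")
# Most practices see one or two payments while a popular few accumulate many —
# the concentration pattern the downstream analyses quantify.
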