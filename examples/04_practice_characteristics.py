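"""Do bigger, older-population, or less deprived practices receive more?

Joins practice characteristics onto the linked payments, forms quartile
strata, and compares each stratum's per-practice total payment value against
the reference stratum (London for regions, quartile 1 elsewhere) with a
two-sided Wilcoxon rank-sum test at alpha = 0.05.
"""

from payline import (
    generate_bundle,
    link_payments,
    normalize_vat,
    profile_practices,
    stratified_comparison,
)

bundle = generate_bundle(seed=42)
linked, _ = link_payments(normalize_vat(bundle.payments), bundle.registry)
profiles = profile_practices(linked, bundle.registry)

for grouping in ("region", "size_quartile", "imd_quartile"):
    out = stratified_comparison(profiles, grouping)
    print(f"\n=== {grouping} (reference: "
          f"{out.loc[out['is_reference'], 'stratum'].item()}) ===")
    for row in out.itertuples():
        p = "ref" if row.is_reference else f"p={row.p_value:.3f}"
        flag = " *" if row.significant else ""
        print(f"  {row.stratum!s:28} n={row.n_practices:5d} "
              f"median £{row.median:8,.2f} [{row.q1:,.2f}–{row.q3:,.2f}]  {p}{flag}")

# The generator draws payment values independently of practice characteristics,
# so differences here reflect sampling noise: expect few starred strata.
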