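# payline

Analysis pipeline for **drug-company payments to general practices in
England**, as disclosed at the healthcare-organisation level in industry
transparency data (one row per transfer of value: donor company, free-text
recipient, category, GBP amount, VAT-reporting basis).

It is written for health-services researchers who want to go from a raw
payments extract plus a practice registry to:

1. **Record linkage** — matching free-text recipient names/addresses to
   unique practice codes (exact-normalized, then postcode-district-gated
   token-set fuzzy matching), with a full exclusion report accounting for
   unlinkable payments by count, value and distinct recipient identity;
2. **VAT normalisation** — bringing amounts reported VAT-inclusive onto the
   exclusive basis (divide by 1 + rate, half-up pence rounding);
3. **Concentration descriptives** — median/IQR summaries at every level of
   analysis, per-company and per-practice concentration tables, top-*k*
   donor/recipient shares, and value shares per payment category;
4. **Stratified comparison** — two-sided Wilcoxon rank-sum tests of the
   per-practice total payment value across regions and quartiles of practice
   size, elderly-patient share, and deprivation, each against a reference
   stratum (London; first quartiles), α = 0.05, no multiplicity adjustment;
5. **Valued company networks** — company × practice incidences under payment
   thresholds, projected one-mode so that the weight *w<sub>ij</sub>* counts
   practices companies *i* and *j* both pay, with valued density
   Σ<sub>i&lt;j</sub> w<sub>ij</sub> / (n(n−1)/2), node strength
   Σ<sub>j</sub> w<sub>ij</sub> and degree, and centralization
   Σ<sub>i</sub>(c<sub>max</sub> − c<sub>i</sub>) / ((n−1)(n−2)·w<sub>max</sub>)
   (Freeman degree centralization on binary graphs).

A calibrated **synthetic-data generator** stands in for the proprietary
extract: 34 companies and 7,500 practices by default, heavy-tailed payment
values hitting the published quartiles (£170 / £320 / £869), one dominant
donor making ~1,000 small payments to ~780 practices, and configurable
recipient-name corruption with a ground-truth table so linkage can be scored
exactly.

## Worked example

```python
from payline import (generate_bundle, normalize_vat, link_payments,
                     concentration, top_k_share)

bundle = generate_bundle(seed=42)
linked, report = link_payments(normalize_vat(bundle.payments), bundle.registry)
print(report.to_dict())
by_company = concentration(linked, "company")
print(f"top-10 donors: {top_k_share(by_company, 10, 'value'):.1%} of value")
```

prints (seed 42):

```
payments:  2509 total, 173 excluded (6.9%)
value:     £2,441,629.20 total, £230,291.59 excluded (9.4%)
final sample: 2336 payments worth £2,211,337.61
top-10 donors: 87.4% of value
```

i.e. ~7% of synthetic payments carry recipients corrupted beyond linkage
(the configured unmatchable rate), and the ten biggest donors account for
almost nine-tenths of all money — the concentration pattern this kind of
disclosure data shows.  Every match is scored against the bundle's truth
table; with only light name noise, recall is 100%.

The `examples/` directory has one narrative script per capability
(simulation, linkage, concentration, stratified comparison, networks, full
pipeline); each prints the numbers it computes and a line on what they mean.
`payline run --config config.yaml` runs the whole pipeline from a YAML
config and writes delimited tables, GraphML networks, and a
machine-readable `results.json`.

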