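# Methods

## Setting and data model

The package analyses one year of organisational-level transfer-of-value
disclosures from pharmaceutical companies to general practices in England.
A payments table has one row per transfer: donor company, two free-text
recipient fields (institution name and institution location), a category
(donations/grants, contributions to event costs, fees for service and
consultancy), a GBP amount, and the VAT basis the company reported on.  A
practice registry supplies clean names, addresses, postcodes, region,
registered-patient and over-65 counts, and a deprivation decile (1 = most
deprived) per unique practice code.

## Synthetic generator

The generator emulates the *statistical* structure of the real extract so
every downstream stage can be exercised and scored; it does not attempt to
model marketing behaviour, products, or time.

**Single-payment values.** Two-piece lognormal: log-value is Gaussian with
scale σ_low = ln(320/170)/z₀.₇₅ below the median and
σ_high = ln(869/320)/z₀.₇₅ above it (z₀.₇₅ ≈ 0.6745), median £320.  This
hits the calibration quartiles (£170, £320, £869) exactly in distribution;
a single-scale lognormal cannot, because £320 is not the geometric mean of
£170 and £869.  Values are rounded to pence and floored at £8 (the smallest
disclosed payment).  A scalar sigma reproduces the classic lognormal if
wanted.

**Donors.** 34 companies.  Company 0 is the *dominant donor*: 1,000
payments over 780 distinct practices, chosen without replacement under the
same popularity law as everyone else, so it shares recipients widely — this
is what makes it the strength-maximal node of the projected company network.
Ordinary companies draw payment counts from a discrete lognormal
(median 14.5, σ = 1.6, truncated to [1, n_dominant/3]); the truncation keeps
any ordinary donor well below the dominant one, mirroring the observed gap
between the largest (≈1,000 payments) and second-largest (≈260) donors.

**Practice selection.** A Zipf-like popularity law over a random permutation
of practices, weight ∝ rank^(−α), α = 1.3 by default.  Under the default
calibration roughly 60–65% of payment-receiving practices get exactly one
payment and the 75th percentile of payments per receiving practice is 2, the
published upper quartile.  The head of the popularity law is heavier than
the real maximum (hundreds of payments to the single most popular practice
versus 132 observed); quartile-level calibration, not extreme-order
statistics, is the generator's contract.

**Categories and VAT.** Categories are drawn i.i.d. with probabilities
(0.7636, 0.2250, 0.0114) — the published value shares renormalised to an
exact simplex (the printed percentages sum to 100.01 after rounding).
Amounts are generated on the VAT-exclusive scale; a configurable fraction of
companies (default 20%) is flagged as reporting VAT-inclusive and has
recorded amounts multiplied by 1.2, which `normalize_vat` inverts.
Calibration checks therefore measure VAT-normalised values.

**Recipient strings and ground truth.** Names and addresses are rendered
from the registry.  *Light* noise (default 30% of payments) applies only
transformations the linkage normalizer provably undoes: case changes,
punctuation insertion, whitespace, and abbreviation swaps drawn from the
normalizer's own table.  *Heavy* corruption (default 6.7%, the published
exclusion rate) replaces the name with a token string absent from the
registry and drops the postcode, so such rows cannot be linked.  A small
fraction (5%) carry the practice name in the location field instead of the
name field, exercising the either-field candidate logic.  The truth table
records the generating practice for every payment, including corrupted ones.

**Registry.** Regions follow weights back-derived from published regional
practice counts; registered patients are lognormal (median ≈ 6,500, floor
500); the over-65 share is Beta(6, 27) (mean ≈ 0.18, matching the national
age structure); deprivation deciles are uniform on 1..10.  Synthetic
postcode areas are one letter per region so a postcode district identifies
its region.

**What passing tests do and do not show.** The generator reproduces
marginal distributions and the dominant-donor topology, not real
correlations between practice characteristics and payment values (values
are drawn independently of size, age structure and deprivation).  Stratified
comparisons on synthetic data therefore test calibration under the null,
power under injected shifts, and plumbing — not substantive findings about
real practices.  Likewise, heavy corruption is i.i.d. per payment, so the
share of *distinct recipient identities* excluded runs higher than the
share of payments excluded; on real data multiple payments can share one
unlinkable recipient.

## VAT normalisation

UK standard rate 20% by default.  Inclusive amounts are divided by
(1 + rate) and rounded half-up to the penny (decimal arithmetic, not float);
exclusive amounts pass unchanged; every output row is marked exclusive.
Basis resolution is row-first (a row's own stated basis wins), then a
per-company map, then the unknown-basis policy (default: assume exclusive,
i.e. leave unaltered).  Row-first precedence makes the operation idempotent.
Division rather than subtraction keeps the adjustment invertible.

## Linkage

Deterministic two-stage matching with a full audit trail (method,
similarity, matched field per payment):

1. **Exact-normalized.** Candidates (institution name first, then location)
   are normalised — casefold, punctuation → space, whitespace collapsed,
   fixed abbreviation table expanded (rd→road, st→street — resolved to
   street, not saint — surg→surgery, dr→doctor, hc→health centre,
   med→medical, ave/ln/ctr) — and looked up against registry name,
   name+postcode, and address+postcode keys.  Keys that collide across
   practices are poisoned and never matched on.
2. **Fuzzy.** Token-set similarity (the classic token-set ratio over
   difflib sequence ratios, made symmetric) of the name-bearing candidate
   against registry names *in the same postcode district*; accept at
   ≥ 0.90, highest similarity wins, ties to the lexicographically smallest
   code.  Candidates with no parsable postcode are not fuzzy-matched: an
   ungated fuzzy pass over 7,500 registry names would trade auditability
   for recall on rows that are, by construction of the data, unlinkable.

The exclusion report counts unmatched payments, their pence-exact value,
and distinct unmatched recipient identities (deduplicated by normalized
string); percentage precision is 2 dp for counts and 1 dp for value,
matching disclosure-analysis reporting conventions.

## Quartiles and summaries

All quantiles are type-7 (linear interpolation, numpy default).  Quartile
labels use cut points at the 0.25/0.50/0.75 quantiles with ties assigned to
the lower quartile, computed over payment-receiving practices only — the
analysis population.  Deprivation quartiles derive from the decile scores;
quartile 1 is the most deprived.  With heavily tied inputs whole quartiles
can collapse (an all-equal vector is labelled 1 throughout); this is the
documented tie rule, not an error.

## Rank-sum comparison

Unit of analysis: per-practice total payment value within stratum (a
per-payment variant is available via `unit="payment"`).  The test is the
two-sided Wilcoxon rank-sum / Mann–Whitney U with midranks, computed by
scipy: exact enumeration when both samples pool to ≤ 20 untied
observations (exact mode refuses tied data and points to the normal
approximation), otherwise the tie-corrected normal approximation with a
0.5 continuity correction.  Raw p-values are reported per stratum with no
multiple-testing adjustment — one comparison per stratum against its fixed
reference (London; first quartiles), α = 0.05.  Test properties verified in
the suite: agreement of exact and approximate p within 0.02 for untied
n = 10–12, and type-I error 0.05 ± 0.02 under a simulated null.

## Networks

The company × practice incidence marks a pair active under one of three
threshold bases: at least one individual payment ≥ cutoff (the default
reading of value-thresholded networks), pair total ≥ cutoff, or pair
payment count ≥ cutoff.  Projection gives w_ij = |{p : active(i,p) ∧
active(j,p)}|, symmetric, zero diagonal; nodes are companies with ≥ 1
active pair, isolates retained and counted separately.

Valued density is Σ_{i<j} w_ij / (n(n−1)/2) — mean tie strength per
possible pair, unbounded above.  Valued centralization is
Σ_i (c_max − c_i) / ((n−1)(n−2)·w_max) with c = strength and w_max the
largest observed edge weight.  This normalisation is chosen because it
reduces exactly to Freeman degree centralization when weights are 0/1, is
attained (= 1) by a uniform-weight star, and vanishes on complete
equal-weight graphs; there is no single established convention for valued
centralization, so both the valued and the binary (dichotomized Freeman)
figure are always reported side by side, as are strength and degree.
Stratified networks filter practices to a stratum *before* incidence
construction, so active pairs partition exactly across strata.

## Problem sizes and determinism

Default scale — 34 companies, 7,500 practices, ~2,500 payments per bundle —
runs the full pipeline in about a second.  Calibration checks pool ~20
bundles (≥ 50,000 payments) for value quartiles and use 10 seeds for the
payments-per-practice quartile.  Every random draw flows from a single
integer seed through numpy's `default_rng`; identical configs produce
byte-identical tables.

## Known limitations

- Single-year cross-section; no products, no prescribing, no temporal
  dynamics.
- Linkage is deterministic; no probabilistic (Fellegi–Sunter) model and no
  geocoding.  Recall guarantees hold for the noise classes the generator
  defines, not for arbitrary real-world spelling variation.
- The valued-centralization normalisation is one defensible convention
  among several; cross-tool comparisons should use the exported edge lists
  rather than the scalar summaries.
- Synthetic strata are exchangeable by construction, so the stratified
  comparison on default synthetic data tests the null, not real effects.
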