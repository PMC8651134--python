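"""Synthetic Disclosure-style payment data.

Generates a payments table, a practice registry, and a ground-truth linkage
table with the statistical structure of industry transfer-of-value disclosures
to English general practices in a single year: a few dozen donor companies, a
heavily right-skewed single-payment value distribution, one dominant donor
spreading ~1,000 small payments across ~780 practices, and a long tail of
practices receiving one or two payments each.

The default calibration targets the published summary quartiles of the 2015
disclosure data: single-payment values with quartiles (£170, £320, £869),
payment counts per ordinary company with median ~14.5 and upper quartile ~81,
and three quarters of payment-receiving practices receiving at most two
payments.  Single-payment values follow a two-piece lognormal: log-value is
Gaussian with a different scale below and above the median, so all three
quartile targets are matched exactly in distribution (a one-scale lognormal
cannot match them, because £320 is not the geometric mean of £170 and £869).

Recipient strings are rendered from the registry with configurable corruption:
*light* noise (case, punctuation, whitespace, standard abbreviations) that a
linkage normalizer recovers exactly, and *heavy* corruption (name replaced by
a string absent from the registry, no postcode) that models recipients that
cannot be linked to a practice code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "CATEGORIES",
    "DominantDonor",
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_registry",
    "generate_payments",
    "generate_bundle",
]

#: The nine English regions (former Government Office Regions / NUTS1).
REGIONS = (
    "East Midlands",
    "East of England",
    "London",
    "North East England",
    "North West England",
    "South East England",
    "South West England",
    "West Midlands",
    "Yorkshire and the Humber",
)

#: Transfer-of-value categories used in organisational-level disclosures.
CATEGORIES = ("donation_grant", "event_contribution", "service_consultancy")

# Share of England's practices per region, back-derived from published
# regional counts of payment-receiving practices and their share of all
# practices in each region.
_DEFAULT_REGION_WEIGHTS = {
    "East Midlands": 0.087,
    "East of England": 0.082,
    "London": 0.185,
    "North East England": 0.085,
    "North West England": 0.157,
    "South East England": 0.109,
    "South West England": 0.082,
    "West Midlands": 0.108,
    "Yorkshire and the Humber": 0.105,
}

# Postcode area letter per region (synthetic, one letter each so that a
# postcode district uniquely identifies a region).
_REGION_AREA = {
    "East Midlands": "D",
    "East of England": "C",
    "London": "E",
    "North East England": "N",
    "North West England": "M",
    "South East England": "G",
    "South West England": "B",
    "West Midlands": "W",
    "Yorkshire and the Humber": "L",
}

_Z75 = 0.6744897501960817  # 75th-percentile of the standard normal

#: Published single-payment value quartiles (GBP) the default calibration hits.
VALUE_Q1, VALUE_MEDIAN, VALUE_Q3 = 170.0, 320.0, 869.0

_DEFAULT_MU = math.log(VALUE_MEDIAN)
_DEFAULT_SIGMA = (
    math.log(VALUE_MEDIAN / VALUE_Q1) / _Z75,   # scale below the median
    math.log(VALUE_Q3 / VALUE_MEDIAN) / _Z75,   # scale above the median
)

# --------------------------------------------------------------------------
# name pools (synthetic; products of these parts are unique by construction)

_NAME_PREFIXES = (
    "OAK", "ASH", "ELM", "BIRCH", "WILLOW", "MAPLE", "CEDAR", "HOLLY",
    "HAWTHORN", "ROWAN", "ALDER", "BEECH", "POPLAR", "LAUREL", "IVY",
    "FERN", "HEATHER", "BRAMBLE", "CLOVER", "THORN", "MOSS", "REED",
    "MARSH", "FELL", "MOOR", "DALE", "GLEN", "COMBE", "HURST", "WYKE",
    "STAN", "WIN", "NOR", "SUD", "EAST", "WEST", "UP", "NETHER", "KIRK",
    "CHURCH", "MILL", "BRIDGE", "CASTLE", "ABBEY", "PRIORY", "GRANGE",
    "MANOR", "PARK", "SPRING", "SUMMER", "WINTER", "HIGH", "LOW", "NEW",
    "OLD", "GREAT", "LITTLE", "BROAD", "LONG", "SHORT",
)

_NAME_SUFFIXES = (
    "WOOD", "FIELD", "GATE", "BROOK", "SIDE", "VIEW", "LEIGH", "WORTH",
    "BOURNE", "FORD", "HILL", "VALE", "CROFT", "DENE", "HOLME", "LEA",
    "MEAD", "RIDGE", "STONE", "WELL", "WICK", "THORPE", "STEAD", "MERE",
    "HAVEN", "COURT", "GREEN", "LANDS", "ROW", "BANK",
)

_PRACTICE_TYPES = (
    "SURGERY",
    "MEDICAL CENTRE",
    "MEDICAL PRACTICE",
    "HEALTH CENTRE",
    "FAMILY PRACTICE",
    "GROUP PRACTICE",
)

_STREET_TYPES = ("ROAD", "STREET", "LANE", "AVENUE", "CLOSE", "DRIVE")

_TOWN_SUFFIXES = ("TON", "FORD", "BURY", "HAM", "WICK", "FIELD")

_COMPANY_STEMS = (
    "Altara", "Benvex", "Corvida", "Dunmore", "Eltrix", "Farleigh",
    "Gravand", "Helixor", "Ivermont", "Jurand", "Kelvane", "Lorimer",
    "Marvex", "Norbrook", "Orlane", "Pellard", "Quorven", "Rostram",
    "Selvine", "Tarquin", "Umbral", "Vantor", "Wexford", "Yelvane",
    "Zorvan", "Ardleigh", "Bextram", "Calvert", "Dorvane", "Elmsworth",
    "Fenwick", "Garlane", "Hollis", "Ingram", "Jesmond", "Kirwan",
    "Lambourn", "Morvern", "Nethervale", "Oswin",
)

_COMPANY_FORMS = ("Pharmaceuticals", "Pharma", "Biosciences", "Healthcare", "Therapeutics")

# Reverse of the linkage normalizer's abbreviation table: light noise applies
# these, the normalizer undoes them.
_LIGHT_ABBREV = {
    "ROAD": "RD",
    "STREET": "ST",
    "SURGERY": "SURG",
    "DOCTOR": "DR",
    "MEDICAL": "MED",
    "HEALTH CENTRE": "HC",
}


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DominantDonor:
    """Blanket-strategy donor: many small payments to many practices."""

    n_payments: int = 1000
    n_practices: int = 780


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic payment universe.

    ``lognormal_sigma`` may be a single scale (classic lognormal) or a
    ``(low, high)`` pair for the two-piece lognormal used by default.
    ``ordinary_donor_payments`` is the ``(mu, sigma)`` of a discrete lognormal
    (rounded, clipped to >= 1) for payment counts of non-dominant companies.
    """

    n_companies: int = 34
    n_practices: int = 7500
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_WEIGHTS)
    )
    lognormal_mu: float = _DEFAULT_MU
    lognormal_sigma: float | tuple[float, float] = _DEFAULT_SIGMA
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            # published value shares 76.36/22.51/1.14 sum to 100.01 after
            # rounding; renormalised to an exact unit simplex
            "donation_grant": 0.7636,
            "event_contribution": 0.2250,
            "service_consultancy": 0.0114,
        }
    )
    dominant_donor: DominantDonor = field(default_factory=DominantDonor)
    ordinary_donor_payments: tuple[float, float] = (math.log(14.5), 1.6)
    practice_popularity_alpha: float = 1.3
    unmatchable_rate: float = 0.067
    name_noise_rate: float = 0.30
    location_name_rate: float = 0.05
    vat_inclusive_fraction: float = 0.20
    value_floor_gbp: float = 8.0
    over65_beta_params: tuple[float, float] = (6.0, 27.0)
    patients_lognormal: tuple[float, float] = (math.log(6500.0), 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_companies < 1 or self.n_practices < 1:
            raise ValueError("n_companies and n_practices must be positive")
        for label, probs in (
            ("region_weights", self.region_weights),
            ("category_mix", self.category_mix),
        ):
            vals = list(probs.values())
            if any(v < 0 for v in vals):
                raise ValueError(f"{label}: probabilities must be nonnegative")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{label}: probabilities must sum to 1")
        if set(self.region_weights) != set(REGIONS):
            raise ValueError("region_weights must cover exactly the 9 English regions")
        if set(self.category_mix) != set(CATEGORIES):
            raise ValueError(f"category_mix must cover exactly {CATEGORIES}")
        for label, rate in (
            ("unmatchable_rate", self.unmatchable_rate),
            ("name_noise_rate", self.name_noise_rate),
            ("location_name_rate", self.location_name_rate),
            ("vat_inclusive_fraction", self.vat_inclusive_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.dominant_donor.n_payments < self.dominant_donor.n_practices:
            raise ValueError("dominant donor cannot pay fewer payments than practices")
        sig = self.lognormal_sigma
        sigmas = (sig, sig) if np.isscalar(sig) else tuple(sig)
        if len(sigmas) != 2 or any(s <= 0 for s in sigmas):
            raise ValueError("lognormal_sigma must be positive (scalar or pair)")

    @property
    def sigma_pair(self) -> tuple[float, float]:
        sig = self.lognormal_sigma
        return (float(sig), float(sig)) if np.isscalar(sig) else (float(sig[0]), float(sig[1]))


@dataclass
class SyntheticBundle:
    """Payments + registry + ground truth from one generator run."""

    payments: pd.DataFrame
    registry: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write payments.csv / registry.csv / truth.csv (UTF-8, headers)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("payments", self.payments),
            ("registry", self.registry),
            ("truth", self.truth),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.2f")
            paths[name] = p
        return paths


# --------------------------------------------------------------------------
# registry


def generate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic practice registry.

    One row per practice: unique code (letter + 5 digits), name, address,
    postcode, region, registered-patient count, over-65 patient count, and
    deprivation decile (1 = most deprived), uniform over 1..10.
    """
    rng = np.random.default_rng([config.seed, 0xA11CE])
    n = config.n_practices

    regions = rng.choice(
        REGIONS, size=n, p=[config.region_weights[r] for r in REGIONS]
    )

    # unique practice names: permuted (prefix+suffix) x type combinations,
    # cycled with a roman-free numeric disambiguator beyond the pool size
    roots = [p + s for p in _NAME_PREFIXES for s in _NAME_SUFFIXES]
    combos = len(roots) * len(_PRACTICE_TYPES)
    perm = rng.permutation(combos)
    names = []
    for i in range(n):
        k = perm[i % combos]
        base = f"{roots[k % len(roots)]} {_PRACTICE_TYPES[k // len(roots)]}"
        names.append(base if i < combos else f"{base} {i // combos + 1}")

    towns = [
        p + s for p in _NAME_PREFIXES[:30] for s in _TOWN_SUFFIXES
    ]
    street_roots = rng.choice(len(roots), size=n)
    street_types = rng.choice(_STREET_TYPES, size=n)
    house_no = rng.integers(1, 200, size=n)
    town_idx = rng.choice(len(towns), size=n)
    addresses = [
        f"{house_no[i]} {roots[street_roots[i]]} {street_types[i]}, {towns[town_idx[i]]}"
        for i in range(n)
    ]

    district = rng.integers(1, 43, size=n)
    sector = rng.integers(1, 10, size=n)
    unit_letters = rng.integers(0, 26, size=(n, 2))
    postcodes = [
        f"{_REGION_AREA[regions[i]]}{district[i]} "
        f"{sector[i]}{chr(65 + unit_letters[i, 0])}{chr(65 + unit_letters[i, 1])}"
        for i in range(n)
    ]

    codes = [f"{_REGION_AREA[regions[i]]}{i:05d}" for i in range(n)]

    mu, sig = config.patients_lognormal
    n_registered = np.maximum(
        500, np.rint(rng.lognormal(mu, sig, size=n))
    ).astype(int)
    a, b = config.over65_beta_params
    share65 = rng.beta(a, b, size=n)
    n_over65 = np.rint(share65 * n_registered).astype(int)
    imd = rng.integers(1, 11, size=n)

    return pd.DataFrame(
        {
            "practice_code": codes,
            "name": names,
            "address": addresses,
            "postcode": postcodes,
            "region": regions,
            "n_registered": n_registered,
            "n_over65": n_over65,
            "imd_decile": imd,
        }
    )


# --------------------------------------------------------------------------
# payments


def _sample_values(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    """Two-piece lognormal single-payment values, floored and rounded to pence."""
    lo, hi = config.sigma_pair
    z = rng.standard_normal(n)
    sig = np.where(z < 0, lo, hi)
    v = np.exp(config.lognormal_mu + sig * z)
    return np.maximum(config.value_floor_gbp, np.round(v, 2))


def _light_noise(name: str, rng: np.random.Generator) -> str:
    """Recoverable corruption: case, punctuation, whitespace, abbreviations."""
    s = name
    if rng.random() < 0.5:
        for full, abbr in _LIGHT_ABBREV.items():
            if full in s and rng.random() < 0.6:
                s = s.replace(full, abbr + ("." if rng.random() < 0.5 else ""))
    style = rng.integers(0, 3)
    if style == 1:
        s = s.title()
    elif style == 2:
        s = s.lower()
    if rng.random() < 0.4:
        toks = s.split(" ")
        if len(toks) > 1:
            j = int(rng.integers(0, len(toks) - 1))
            sep = "-" if rng.random() < 0.5 else ",  "
            toks[j] = toks[j] + sep
            s = " ".join(toks).replace("- ", "-")
    return s


def _heavy_token(rng: np.random.Generator) -> str:
    return "".join(chr(65 + int(c)) for c in rng.integers(0, 26, size=6))


def generate_payments(
    registry: pd.DataFrame, config: GeneratorConfig
) -> SyntheticBundle:
    """Draw a payments table against ``registry`` and return the full bundle.

    Company 0 is the dominant donor: ``dominant_donor.n_payments`` payments
    spread over ``dominant_donor.n_practices`` distinct practices (chosen
    uniformly — a blanket strategy).  Ordinary companies draw a payment count
    from the configured discrete lognormal and pick practices by a Zipf-like
    popularity law with exponent ``practice_popularity_alpha``, so a handful
    of popular practices accumulate many payments while most receive one or
    two.  Amounts are generated VAT-exclusive; companies flagged as reporting
    VAT-inclusive have their recorded amounts multiplied by 1.2.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if config.dominant_donor.n_practices > len(registry):
        raise ValueError("dominant_donor.n_practices exceeds registry size")

    rng = np.random.default_rng([config.seed, 0x9A7])
    n_pr = len(registry)

    stems = list(_COMPANY_STEMS)
    if config.n_companies > len(stems) * len(_COMPANY_FORMS):
        raise ValueError("too many companies for the name pool")
    forms = rng.choice(_COMPANY_FORMS, size=config.n_companies)
    companies = [f"{stems[i % len(stems)]} {forms[i]}" for i in range(config.n_companies)]
    basis = np.where(
        rng.random(config.n_companies) < config.vat_inclusive_fraction,
        "inclusive",
        "exclusive",
    )

    # shared popularity law: a Zipf-like weight over a random practice ranking
    ranks = rng.permutation(n_pr) + 1
    weights = ranks.astype(float) ** -config.practice_popularity_alpha
    weights /= weights.sum()

    # dominant donor: distinct practices popularity-weighted (so it shares
    # the attractive practices every other donor also targets), extras
    # re-spread uniformly over its own practice set
    dom = config.dominant_donor
    dom_practices = rng.choice(n_pr, size=dom.n_practices, replace=False, p=weights)
    extra = rng.choice(dom_practices, size=dom.n_payments - dom.n_practices)
    dom_targets = np.concatenate([dom_practices, extra])

    # ordinary donors: truncated lognormal counts (no ordinary donor rivals
    # the dominant one; the cap mirrors the observed second-largest donor's
    # scale), popularity-weighted practice choice
    mu_c, sig_c = config.ordinary_donor_payments
    cap = max(1, dom.n_payments // 3)
    counts = np.clip(
        np.rint(rng.lognormal(mu_c, sig_c, size=config.n_companies - 1)), 1, cap
    ).astype(int)
    ord_targets = rng.choice(n_pr, size=int(counts.sum()), p=weights)

    company_idx = np.concatenate(
        [np.zeros(dom.n_payments, dtype=int), np.repeat(np.arange(1, config.n_companies), counts)]
    )
    practice_idx = np.concatenate([dom_targets, ord_targets])
    n_pay = len(company_idx)

    values = _sample_values(rng, n_pay, config)
    cats = rng.choice(
        CATEGORIES, size=n_pay, p=[config.category_mix[c] for c in CATEGORIES]
    )

    u = rng.random(n_pay)
    corruption = np.where(
        u < config.unmatchable_rate,
        "heavy",
        np.where(u < config.unmatchable_rate + config.name_noise_rate, "light", "none"),
    )
    in_location = rng.random(n_pay) < config.location_name_rate

    reg_name = registry["name"].to_numpy()
    reg_addr = registry["address"].to_numpy()
    reg_pc = registry["postcode"].to_numpy()

    inst_name = np.empty(n_pay, dtype=object)
    inst_loc = np.empty(n_pay, dtype=object)
    towns_pool = [p + s for p in _NAME_PREFIXES[:30] for s in _TOWN_SUFFIXES]
    for i in range(n_pay):
        p = practice_idx[i]
        if corruption[i] == "heavy":
            inst_name[i] = f"HEALTH CENTRE {_heavy_token(rng)}"
            inst_loc[i] = f"{_heavy_token(rng)} HOUSE, {towns_pool[int(rng.integers(0, len(towns_pool)))]}"
            continue
        name = reg_name[p]
        loc = f"{reg_addr[p]}, {reg_pc[p]}"
        if corruption[i] == "light":
            name = _light_noise(name, rng)
            loc = _light_noise(loc, rng)
        if in_location[i]:
            inst_name[i] = ""
            inst_loc[i] = f"{name}, {reg_pc[p]}"
        else:
            inst_name[i] = name
            inst_loc[i] = loc

    amounts = values.copy()
    inclusive = basis[company_idx] == "inclusive"
    amounts[inclusive] = np.round(amounts[inclusive] * 1.2, 2)

    order = rng.permutation(n_pay)
    payments = pd.DataFrame(
        {
            "company": np.array(companies, dtype=object)[company_idx],
            "institution_name": inst_name,
            "institution_location": inst_loc,
            "category": cats,
            "amount_gbp": amounts,
            "vat_basis": basis[company_idx],
        }
    ).iloc[order].reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "payment_id": np.arange(n_pay),
            "practice_code": registry["practice_code"].to_numpy()[practice_idx][order],
            "corruption": corruption[order],
        }
    )
    return SyntheticBundle(payments=payments, registry=registry, truth=truth, config=config)


def generate_bundle(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Convenience: registry + payments from one config (optionally reseeded)."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    return generate_payments(generate_registry(config), config)
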