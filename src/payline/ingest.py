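"""Reading and validating payment tables; VAT normalisation.

Disclosure-style extracts report amounts on whichever VAT basis each company
chose; comparing values across companies requires bringing everything onto a
common (exclusive) basis.  Stripping VAT is a division by ``1 + rate`` with
half-up rounding to pence, so the adjustment is invertible and idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "PAYMENT_COLUMNS",
    "SchemaError",
    "PaymentValidationError",
    "VatPolicy",
    "read_payments",
    "read_registry",
    "normalize_vat",
    "recipient_strings",
]

PAYMENT_COLUMNS = (
    "company",
    "institution_name",
    "institution_location",
    "category",
    "amount_gbp",
    "vat_basis",
)

REGISTRY_COLUMNS = (
    "practice_code",
    "name",
    "address",
    "postcode",
    "region",
    "n_registered",
    "n_over65",
    "imd_decile",
)

_CATEGORIES = {"donation_grant", "event_contribution", "service_consultancy"}
_BASES = {"inclusive", "exclusive", "unknown"}


class SchemaError(ValueError):
    """The file's header does not match the expected schema."""


class PaymentValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists (row, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}: {m}" for r, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid payment row(s): {lines}{more}")


def read_payments(path: str | Path) -> pd.DataFrame:
    """Read and validate a payments CSV.

    Unknown extra columns are ignored with a warning (tolerant reader).
    Invalid rows are collected and raised together as
    :class:`PaymentValidationError` naming 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PAYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in PAYMENT_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)
        df = df[list(PAYMENT_COLUMNS)]

    errors: list[tuple[int, str]] = []
    amounts = pd.to_numeric(df["amount_gbp"], errors="coerce")
    for i in df.index:
        row = i + 1  # 1-based data row (header not counted)
        if pd.isna(amounts[i]):
            errors.append((row, f"non-numeric amount {df.at[i, 'amount_gbp']!r}"))
        elif amounts[i] <= 0:
            errors.append((row, f"non-positive amount {amounts[i]}"))
        if df.at[i, "category"] not in _CATEGORIES:
            errors.append((row, f"unknown category {df.at[i, 'category']!r}"))
        if df.at[i, "vat_basis"] not in _BASES:
            errors.append((row, f"unknown vat_basis {df.at[i, 'vat_basis']!r}"))
        if not df.at[i, "company"]:
            errors.append((row, "blank company"))
    if errors:
        raise PaymentValidationError(errors)

    out = df.copy()
    out["amount_gbp"] = amounts.round(2)
    return out


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a practice registry CSV and check basic integrity."""
    df = pd.read_csv(path, dtype={"practice_code": str, "postcode": str})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["practice_code"].duplicated().any():
        dups = df.loc[df["practice_code"].duplicated(), "practice_code"].tolist()
        raise SchemaError(f"{path}: duplicate practice codes {dups[:5]}")
    return df


@dataclass(frozen=True)
class VatPolicy:
    """How to resolve each payment onto the VAT-exclusive basis.

    Resolution order per row: the row's own ``vat_basis`` if known, else the
    ``per_company_basis`` map, else ``unknown_policy``.  Row-first precedence
    makes :func:`normalize_vat` idempotent: after one pass every row is
    exclusive and a second pass changes nothing.
    """

    rate: float = 0.20
    per_company_basis: dict[str, str] = field(default_factory=dict)
    unknown_policy: str = "assume_exclusive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        if self.unknown_policy not in {"assume_exclusive", "assume_inclusive", "reject"}:
            raise ValueError(f"bad unknown_policy {self.unknown_policy!r}")
        bad = {c: b for c, b in self.per_company_basis.items() if b not in {"inclusive", "exclusive"}}
        if bad:
            raise ValueError(f"per_company_basis values must be inclusive/exclusive: {bad}")


def _strip_vat(amount: float, rate: float) -> float:
    q = (Decimal(f"{amount:.2f}") / (1 + Decimal(str(rate)))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def normalize_vat(payments: pd.DataFrame, policy: VatPolicy | None = None) -> pd.DataFrame:
    """Return a copy with every amount on the VAT-exclusive basis.

    Inclusive amounts are divided by ``1 + rate`` and rounded half-up to
    pence; exclusive amounts pass through unchanged; ``vat_basis`` is set to
    ``exclusive`` on all rows.  The adjusted total never exceeds the input
    total.
    """
    policy = policy or VatPolicy()
    basis = payments["vat_basis"].copy()
    unknown = ~basis.isin(["inclusive", "exclusive"])
    if unknown.any():
        mapped = payments.loc[unknown, "company"].map(policy.per_company_basis)
        basis.loc[unknown] = mapped
        still = basis.isna() | ~basis.isin(["inclusive", "exclusive"])
        if still.any():
            if policy.unknown_policy == "reject":
                names = sorted(payments.loc[still, "company"].unique())
                raise ValueError(f"VAT basis unresolved for companies: {names}")
            basis.loc[still] = (
                "exclusive" if policy.unknown_policy == "assume_exclusive" else "inclusive"
            )

    out = payments.copy()
    inc = basis == "inclusive"
    out.loc[inc, "amount_gbp"] = [
        _strip_vat(a, policy.rate) for a in out.loc[inc, "amount_gbp"]
    ]
    out["vat_basis"] = "exclusive"
    return out


def recipient_strings(institution_name: str, institution_location: str) -> list[str]:
    """Ordered candidate recipient strings for linkage.

    The institution-name field comes first, then the location field; blanks
    are dropped.  An empty list marks the record unlinkable at source.
    """
    return [
        s.strip()
        for s in (institution_name, institution_location)
        if s is not None and str(s).strip()
    ]
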