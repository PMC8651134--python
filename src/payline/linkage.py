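"""Linking free-text payment recipients to practice codes.

Disclosure extracts name recipients as free text in the institution-name and
institution-location fields; the registry carries clean names, addresses and
postcodes keyed by practice code.  Linkage is deterministic and two-stage:

1. *exact-normalized* — any candidate string, after canonical normalisation
   (casefold, punctuation stripped, whitespace collapsed, standard
   abbreviations expanded), equals a registry name, name + postcode, or
   address + postcode;
2. *fuzzy* — token-set similarity of the best candidate against registry
   names within the same postcode district, accepted at or above a threshold
   (default 0.90), best similarity wins, ties broken by the lexicographically
   smallest practice code.  Candidates with no parsable postcode are not
   fuzzy-matched.

Everything else is unmatched and flows into the exclusion report, which
accounts for dropped payments by count, value and distinct recipient
identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from difflib import SequenceMatcher

import numpy as np
import pandas as pd

__all__ = [
    "normalize_text",
    "normalize_postcode",
    "token_set_similarity",
    "MatchResult",
    "ExclusionReport",
    "link_payments",
]

#: Fixed abbreviation-expansion table; "st" resolves to street, not saint.
ABBREVIATIONS = {
    "rd": "road",
    "st": "street",
    "surg": "surgery",
    "dr": "doctor",
    "hc": "health centre",
    "med": "medical",
    "ave": "avenue",
    "ln": "lane",
    "ctr": "centre",
}

_PUNCT = re.compile(r"[^\w\s]")
_POSTCODE = re.compile(r"\b([A-Z]{1,2}\d{1,2}[A-Z]?)\s*(\d[A-Z]{2})\b", re.IGNORECASE)


def normalize_text(raw: str) -> str:
    """Canonical form of a free-text name/address string.

    Casefolds, maps punctuation to spaces, collapses whitespace and expands
    the fixed abbreviation table.  Idempotent: expansions are never
    abbreviations themselves.
    """
    if raw is None:
        return ""
    s = _PUNCT.sub(" ", str(raw).casefold())
    return " ".join(ABBREVIATIONS.get(t, t) for t in s.split())


def normalize_postcode(raw: str) -> str:
    """Uppercase a UK-style postcode with a single internal space."""
    m = _POSTCODE.search(str(raw))
    if not m:
        return ""
    return f"{m.group(1).upper()} {m.group(2).upper()}"


def _extract_postcode(raw: str) -> tuple[str, str]:
    """(normalized postcode, remainder of the string) — both may be empty."""
    m = _POSTCODE.search(str(raw))
    if not m:
        return "", str(raw)
    pc = f"{m.group(1).upper()} {m.group(2).upper()}"
    rest = (str(raw)[: m.start()] + " " + str(raw)[m.end():]).strip()
    return pc, rest


def token_set_similarity(a: str, b: str) -> float:
    """Token-set ratio in [0, 1].

    Order-insensitive: compares the sorted common-token core against each
    side's full sorted token string and returns the best sequence ratio, so
    a string that is a token-subset of the other scores 1.0.
    """
    ta, tb = set(a.split()), set(b.split())
    if not ta or not tb:
        return 1.0 if ta == tb else 0.0
    inter = " ".join(sorted(ta & tb))
    sa = (inter + " " + " ".join(sorted(ta - tb))).strip()
    sb = (inter + " " + " ".join(sorted(tb - ta))).strip()
    best = 0.0
    for x, y in ((inter, sa), (inter, sb), (sa, sb)):
        if x == y:
            return 1.0 if x else 0.0
        # SequenceMatcher is direction-sensitive; fix the orientation so the
        # similarity is symmetric in its arguments
        x, y = min(x, y), max(x, y)
        best = max(best, SequenceMatcher(None, x, y).ratio())
    return best


@dataclass(frozen=True)
class MatchResult:
    payment_id: int
    practice_code: str | None
    method: str  # exact_normalized | fuzzy | unmatched
    similarity: float
    matched_on: str | None


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of payments dropped because recipients could not be linked.

    Percentages follow the reporting precision convention of published
    disclosure analyses: two decimals for payment and practice counts, one
    decimal for value.
    """

    n_payments_total: int
    n_excluded: int
    value_total_gbp: float
    value_excluded_gbp: float
    n_recipient_practices_total: int
    n_practices_excluded: int

    @property
    def pct_excluded(self) -> float:
        return round(100.0 * self.n_excluded / self.n_payments_total, 2)

    @property
    def pct_value_excluded(self) -> float:
        return round(100.0 * self.value_excluded_gbp / self.value_total_gbp, 1)

    @property
    def pct_practices_excluded(self) -> float:
        return round(
            100.0 * self.n_practices_excluded / self.n_recipient_practices_total, 2
        )

    @property
    def n_payments_final(self) -> int:
        return self.n_payments_total - self.n_excluded

    @property
    def value_final_gbp(self) -> float:
        # pence-exact subtraction
        return (
            round(self.value_total_gbp * 100) - round(self.value_excluded_gbp * 100)
        ) / 100.0

    @property
    def n_recipient_practices_final(self) -> int:
        return self.n_recipient_practices_total - self.n_practices_excluded

    def __post_init__(self) -> None:
        if self.n_excluded > self.n_payments_total:
            raise ValueError("excluded payments exceed total")
        if self.n_practices_excluded > self.n_recipient_practices_total:
            raise ValueError("excluded practices exceed total")
        if round(self.value_excluded_gbp, 2) > round(self.value_total_gbp, 2):
            raise ValueError("excluded value exceeds total")

    def to_dict(self) -> dict:
        return {
            "n_payments_total": self.n_payments_total,
            "n_excluded": self.n_excluded,
            "pct_excluded": self.pct_excluded,
            "value_total_gbp": round(self.value_total_gbp, 2),
            "value_excluded_gbp": round(self.value_excluded_gbp, 2),
            "pct_value_excluded": self.pct_value_excluded,
            "n_recipient_practices_total": self.n_recipient_practices_total,
            "n_practices_excluded": self.n_practices_excluded,
            "pct_practices_excluded": self.pct_practices_excluded,
            "n_payments_final": self.n_payments_final,
            "value_final_gbp": self.value_final_gbp,
            "n_recipient_practices_final": self.n_recipient_practices_final,
        }


def _registry_maps(registry: pd.DataFrame):
    """Lookup structures for exact and fuzzy matching."""
    if registry["practice_code"].duplicated().any():
        raise ValueError("registry practice codes must be unique")

    name_map: dict[str, str | None] = {}
    name_pc_map: dict[str, str] = {}
    addr_map: dict[str, str | None] = {}
    district_names: dict[str, list[tuple[str, str]]] = {}

    for code, name, addr, pc in registry[
        ["practice_code", "name", "address", "postcode"]
    ].itertuples(index=False):
        nname = normalize_text(name)
        npc = normalize_postcode(pc)
        # ambiguous keys are poisoned with None and never matched on
        name_map[nname] = None if nname in name_map else code
        key = f"{nname}|{npc}"
        name_pc_map[key] = None if key in name_pc_map else code
        naddr = normalize_text(f"{addr} {pc}")
        addr_map[naddr] = None if naddr in addr_map else code
        district = npc.split(" ")[0] if npc else ""
        if district:
            district_names.setdefault(district, []).append((nname, code))
    return name_map, name_pc_map, addr_map, district_names


def link_payments(
    payments: pd.DataFrame,
    registry: pd.DataFrame,
    fuzzy_threshold: float = 0.90,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Resolve each payment to a practice code or mark it unmatched.

    Returns the linked table (input columns plus ``practice_code``,
    ``method``, ``similarity``, ``matched_on``) and the exclusion report.
    Distinct recipient identities are counted as matched codes plus distinct
    normalized strings among the unmatched.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    name_map, name_pc_map, addr_map, district_names = _registry_maps(registry)

    results: list[MatchResult] = []
    for row in payments.itertuples():
        pid = row.Index
        candidates = [
            s for s in (row.institution_name, row.institution_location)
            if s is not None and str(s).strip()
        ]
        match: MatchResult | None = None
        parsed = []
        for cand in candidates:
            pc, rest = _extract_postcode(cand)
            parsed.append((cand, pc, normalize_text(cand), normalize_text(rest)))
        # stage 1: exact on normalized name / name+postcode / address
        for cand, pc, nfull, nrest in parsed:
            for key, table in (
                (nfull, name_map),
                (nfull, addr_map),
                (f"{nrest}|{pc}", name_pc_map) if pc else (None, None),
                (nrest, name_map) if pc else (None, None),
            ):
                code = table.get(key) if table else None
                if code is not None:
                    match = MatchResult(pid, code, "exact_normalized", 1.0, cand)
                    break
            if match:
                break
        # stage 2: postcode-district-gated fuzzy against registry names; the
        # district may come from either field, the probe from any candidate
        # with name content left once its postcode is stripped
        if match is None:
            district = next((pc.split(" ")[0] for _, pc, _, _ in parsed if pc), None)
            best_sim, best_code, best_cand = 0.0, None, None
            if district is not None:
                for cand, pc, nfull, nrest in parsed:
                    probe = nrest if pc else nfull
                    if not probe:
                        continue
                    for nname, code in district_names.get(district, ()):
                        sim = token_set_similarity(probe, nname)
                        if sim > best_sim or (
                            sim == best_sim and code < (best_code or "￿")
                        ):
                            best_sim, best_code, best_cand = sim, code, cand
            if best_code is not None and best_sim >= fuzzy_threshold:
                match = MatchResult(pid, best_code, "fuzzy", best_sim, best_cand)
        if match is None:
            match = MatchResult(pid, None, "unmatched", 0.0, None)
        results.append(match)

    res = pd.DataFrame(results)
    linked = payments.copy()
    linked["practice_code"] = res["practice_code"].to_numpy()
    linked["method"] = res["method"].to_numpy()
    linked["similarity"] = res["similarity"].to_numpy()
    linked["matched_on"] = res["matched_on"].to_numpy()

    pence = np.rint(linked["amount_gbp"].to_numpy() * 100).astype(np.int64)
    unmatched = linked["method"] == "unmatched"
    # distinct unmatched recipient identities, deduplicated by normalized text
    unmatched_ids = {
        normalize_text(f"{n} {l}")
        for n, l in zip(
            linked.loc[unmatched, "institution_name"],
            linked.loc[unmatched, "institution_location"],
        )
    }
    report = ExclusionReport(
        n_payments_total=int(len(linked)),
        n_excluded=int(unmatched.sum()),
        value_total_gbp=int(pence.sum()) / 100.0,
        value_excluded_gbp=int(pence[unmatched.to_numpy()].sum()) / 100.0,
        n_recipient_practices_total=int(
            linked.loc[~unmatched, "practice_code"].nunique() + len(unmatched_ids)
        ),
        n_practices_excluded=len(unmatched_ids),
    )
    return linked, report
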