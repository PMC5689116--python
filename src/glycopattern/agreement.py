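"""Inter-rater agreement statistics for validating automated detection.

The validation design compares binary present/absent calls of a panel of
clinician raters against the automated dashboard (the reference rater).
Three statistics summarize concordance:

* **percent agreement** p_o — matching pairs over compared pairs;
* **Cohen's kappa** κ = (p_o − p_e)/(1 − p_e), the chance-corrected
  agreement, with p_e from the two raters' marginal frequencies; its 95 %
  CI uses the large-sample (Fleiss–Cohen–Everitt) asymptotic variance,
  truncated to [−1, 1];
* **pooled agreement** — the n-weighted mean of per-case agreement
  fractions, Σ fᵢ·nᵢ / Σ nᵢ, i.e. total matching evaluations over total
  evaluations (equivalent to percent agreement on the concatenation).

Interpretation bands for κ: no agreement (κ < 0), not significant
(0 ≤ κ ≤ 0.20), medium (0.21–0.40), moderate (0.41–0.60), substantial
(0.61–0.80), almost perfect (κ > 0.80).

When one rater is constant and the other is not, p_e equals p_o and κ is
identically 0; when both raters are constant and identical, κ is
undefined (reported as ``None`` with p_o attached) rather than forced to
a value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "RatingTable",
    "percent_agreement",
    "cohens_kappa",
    "kappa_from_ratings",
    "pooled_agreement",
    "interpret_kappa",
    "read_rating_table",
    "evaluate_rating_table",
]

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between one rater pair on binary items."""

    p_o: float
    p_e: float
    kappa: Optional[float]
    se: Optional[float]
    ci95: Optional[tuple[float, float]]
    n: int
    interpretation: str

    def to_dict(self) -> dict:
        return {
            "p_o": self.p_o, "p_e": self.p_e, "kappa": self.kappa,
            "se": self.se, "ci95": list(self.ci95) if self.ci95 else None,
            "n": self.n, "interpretation": self.interpretation,
        }


def percent_agreement(
    reference: Sequence, rater: Sequence
) -> tuple[Optional[float], int]:
    """Fraction of matching pairs, dropping pairs with a missing rating.

    Returns ``(fraction, n_compared)``; the fraction is ``None`` when no
    pair could be compared.
    """
    if len(reference) != len(rater):
        raise ValueError("rating vectors must have equal length")
    matches = 0
    compared = 0
    for ref, rat in zip(reference, rater):
        if _is_missing(ref) or _is_missing(rat):
            continue
        compared += 1
        matches += bool(ref) == bool(rat)
    if compared == 0:
        return None, 0
    return matches / compared, compared


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def interpret_kappa(kappa: float) -> str:
    """Map κ to its agreement band (upper edges as printed)."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa < 0:
        return "no agreement"
    if kappa <= 0.20:
        return "not significant"
    if kappa <= 0.40:
        return "medium"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_kappa(a: int, b: int, c: int, d: int) -> AgreementResult:
    """Cohen's kappa from the 2x2 paired-rating table.

    ``a`` = both present, ``b`` = reference present / rater absent,
    ``c`` = reference absent / rater present, ``d`` = both absent.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("cell counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one paired observation is required")
    p = np.array([[a, b], [c, d]], dtype=float) / n
    row = p.sum(axis=1)   # reference marginal
    col = p.sum(axis=0)   # rater marginal
    p_o = p[0, 0] + p[1, 1]
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        # Both raters constant and identical: chance agreement saturates.
        return AgreementResult(p_o=p_o, p_e=p_e, kappa=None, se=None,
                               ci95=None, n=n, interpretation="undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(max(_kappa_variance(p, row, col, p_o, p_e, n), 0.0))
    lo = max(kappa - Z_95 * se, -1.0)
    hi = min(kappa + Z_95 * se, 1.0)
    return AgreementResult(p_o=p_o, p_e=p_e, kappa=kappa, se=se,
                           ci95=(lo, hi), n=n,
                           interpretation=interpret_kappa(kappa))


def _kappa_variance(p, row, col, p_o: float, p_e: float, n: int) -> float:
    # Large-sample variance of kappa-hat (Fleiss, Cohen & Everitt 1969).
    term_a = sum(
        p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2
        for i in range(2))
    term_b = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j)
    term_c = (p_o * p_e - 2 * p_e + p_o) ** 2
    return (term_a + term_b - term_c) / (n * (1 - p_e) ** 4)


def kappa_from_ratings(reference: Sequence, rater: Sequence) -> AgreementResult:
    """Kappa from two binary vectors (missing ratings dropped pairwise)."""
    if len(reference) != len(rater):
        raise ValueError("rating vectors must have equal length")
    a = b = c = d = 0
    for ref, rat in zip(reference, rater):
        if _is_missing(ref) or _is_missing(rat):
            continue
        ref, rat = bool(ref), bool(rat)
        if ref and rat:
            a += 1
        elif ref and not rat:
            b += 1
        elif not ref and rat:
            c += 1
        else:
            d += 1
    return cohens_kappa(a, b, c, d)


def pooled_agreement(per_case: Sequence[tuple[float, int]]) -> float:
    """n-weighted pooling: total matching evaluations / total evaluations."""
    if not per_case:
        raise ValueError("cannot pool an empty list")
    total_n = 0
    total_matches = 0.0
    for fraction, n in per_case:
        if n <= 0:
            raise ValueError(f"evaluation count must be positive, got {n}")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"agreement fraction must be in [0, 1], got {fraction}")
        total_matches += fraction * n
        total_n += n
    return total_matches / total_n


# ---------------------------------------------------------------------------
# Rating tables

@dataclass
class RatingTable:
    """Binary panel ratings: items x raters against a fixed reference.

    ``ratings[j, i]`` is rater j's call on item i (1 present, 0 absent,
    NaN missing).
    """

    items: list[str]
    reference: np.ndarray           # bool, shape (n_items,)
    ratings: np.ndarray             # float, shape (n_raters, n_items)
    rater_ids: list[str]

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=bool)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if len(self.items) < 1 or len(self.rater_ids) < 1:
            raise ValueError("rating table needs >= 1 item and >= 1 rater")
        if self.reference.shape != (len(self.items),):
            raise ValueError("reference length must match items")
        if self.ratings.shape != (len(self.rater_ids), len(self.items)):
            raise ValueError("ratings must be raters x items")


_TOKENS = {"present": 1.0, "absent": 0.0, "1": 1.0, "0": 0.0, "": math.nan}


def read_rating_table(path: Union[str, Path]) -> RatingTable:
    """Read a ratings CSV: ``item_id, reference, rater_id, rating``."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["item_id", "reference", "rater_id", "rating"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    items: list[str] = []
    reference: dict[str, float] = {}
    for _, row in frame.iterrows():
        item = row["item_id"]
        token = row["reference"].strip().lower()
        if token not in _TOKENS or math.isnan(_TOKENS[token]):
            raise ValueError(f"bad reference token {row['reference']!r} for {item!r}")
        value = _TOKENS[token]
        if item in reference:
            if reference[item] != value:
                raise ValueError(f"conflicting reference for item {item!r}")
        else:
            reference[item] = value
            items.append(item)
    raters = list(dict.fromkeys(frame["rater_id"]))
    item_index = {it: i for i, it in enumerate(items)}
    ratings = np.full((len(raters), len(items)), math.nan)
    rater_index = {r: j for j, r in enumerate(raters)}
    for _, row in frame.iterrows():
        token = row["rating"].strip().lower()
        if token not in _TOKENS:
            raise ValueError(f"bad rating token {row['rating']!r}")
        ratings[rater_index[row["rater_id"]], item_index[row["item_id"]]] = _TOKENS[token]
    return RatingTable(items=items,
                       reference=np.array([reference[i] for i in items], dtype=bool),
                       ratings=ratings, rater_ids=raters)


def evaluate_rating_table(table: RatingTable) -> dict:
    """Per-rater agreement against the reference, plus the pooled summary."""
    per_rater = {}
    pooled_input = []
    for j, rater_id in enumerate(table.rater_ids):
        fraction, n = percent_agreement(table.reference, table.ratings[j])
        entry: dict = {"percent_agreement": fraction, "n": n}
        if n >= 1:
            entry["kappa"] = kappa_from_ratings(
                table.reference, table.ratings[j]).to_dict()
            pooled_input.append((fraction, n))
        per_rater[rater_id] = entry
    out = {"per_rater": per_rater}
    if pooled_input:
        out["pooled_agreement"] = pooled_agreement(pooled_input)
        out["n_total"] = sum(n for _, n in pooled_input)
    return out
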