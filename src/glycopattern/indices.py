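"""Summary statistics and blood-glucose risk indices.

The variability block of the dashboard rests on four quantities computed
from the glucose series of the analysis window:

* the sample standard deviation SD (mg/dL, n-1 denominator — the clinical
  convention for SMBG variability);
* the percentage coefficient of variation, %CV = 100 * SD / mean;
* the Low and High Blood Glucose Indices (LBGI / HBGI), the canonical
  risk indices built on the symmetrizing log-power transform of glucose

      f(bg) = 1.509 * ((ln bg)^1.084 - 5.381),   bg in mg/dL,

  with squared risk r(bg) = 10 * f(bg)^2.  LBGI is the mean of r over
  readings on the hypoglycemic side (f < 0), HBGI the mean over the
  hyperglycemic side (f > 0); both are means over *all* n readings, so
  each index is zero when no reading lies on its side.

f is strictly increasing and crosses zero at the risk-neutral glucose
(~112.5 mg/dL), where both indices vanish.  Risk categories (minimal /
low / moderate / high) follow the standard published band edges; the
dashboard flags an index when its category is moderate or high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "RISK_COEF",
    "RISK_EXPONENT",
    "RISK_OFFSET",
    "LBGI_EDGES",
    "HBGI_EDGES",
    "GlucoseSummary",
    "risk_transform",
    "risk_neutral_glucose",
    "compute_risk_indices",
    "classify_risk",
    "glucose_summary",
]

# Coefficients of the symmetrizing transform (glucose in mg/dL).
RISK_COEF = 1.509
RISK_EXPONENT = 1.084
RISK_OFFSET = 5.381

#: Default band edges, lower edge inclusive.  LBGI: minimal < 1.1 <= low
#: < 2.5 <= moderate < 5.0 <= high.  HBGI: low < 4.5 <= moderate < 9.0 <= high.
LBGI_EDGES = (1.1, 2.5, 5.0)
HBGI_EDGES = (4.5, 9.0)

_LBGI_LABELS = ("minimal", "low", "moderate", "high")
_HBGI_LABELS = ("low", "moderate", "high")


def risk_transform(bg: float) -> tuple[float, float]:
    """Return ``(f, r)`` for one glucose value: signed risk and r = 10 f^2."""
    if bg <= 0:
        raise ValueError(f"glucose must be positive, got {bg}")
    f = RISK_COEF * (math.log(bg) ** RISK_EXPONENT - RISK_OFFSET)
    return f, 10.0 * f * f


def risk_neutral_glucose() -> float:
    """The glucose at which f = 0 (closed form: exp(5.381^(1/1.084)))."""
    return math.exp(RISK_OFFSET ** (1.0 / RISK_EXPONENT))


def compute_risk_indices(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    """LBGI and HBGI as one-sided means of r(bg) over all readings.

    Returns ``(None, None)`` for an empty series.
    """
    if not values:
        return None, None
    low_total = 0.0
    high_total = 0.0
    for bg in values:
        f, r = risk_transform(bg)
        if f < 0:
            low_total += r
        elif f > 0:
            high_total += r
    n = len(values)
    return low_total / n, high_total / n


def classify_risk(
    value: float,
    side: str,
    edges: Optional[Sequence[float]] = None,
) -> str:
    """Map a nonnegative index to its category; lower band edge inclusive."""
    if value < 0:
        raise ValueError(f"risk index must be >= 0, got {value}")
    if side == "low":
        edges = LBGI_EDGES if edges is None else tuple(edges)
        labels = _LBGI_LABELS if len(edges) == 3 else _labels_for(edges)
    elif side == "high":
        edges = HBGI_EDGES if edges is None else tuple(edges)
        labels = _HBGI_LABELS if len(edges) == 2 else _labels_for(edges)
    else:
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    for edge, label in zip(reversed(edges), reversed(labels[1:])):
        if value >= edge:
            return label
    return labels[0]


def _labels_for(edges: Sequence[float]) -> tuple[str, ...]:
    # Custom edge counts fall back to the generic ladder, truncated from the top.
    ladder = ("minimal", "low", "moderate", "high")
    return ladder[-(len(edges) + 1):]


@dataclass(frozen=True)
class GlucoseSummary:
    """Window-level summary of a glucose series.

    ``sd`` and ``cv_percent`` are ``None`` (undefined, never 0) when fewer
    than two readings are available.
    """

    n: int
    mean: float
    sd: Optional[float]
    cv_percent: Optional[float]
    lbgi: float
    hbgi: float
    lbgi_category: str
    hbgi_category: str


def glucose_summary(
    values: Sequence[float],
    lbgi_edges: Optional[Sequence[float]] = None,
    hbgi_edges: Optional[Sequence[float]] = None,
) -> GlucoseSummary:
    """Summarize a glucose series (mg/dL); requires at least one reading."""
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty glucose series")
    mean = sum(values) / n
    if n >= 2:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sd: Optional[float] = math.sqrt(var)
        cv: Optional[float] = 100.0 * sd / mean if mean > 0 else None
    else:
        sd = None
        cv = None
    lbgi, hbgi = compute_risk_indices(values)
    assert lbgi is not None and hbgi is not None
    return GlucoseSummary(
        n=n, mean=mean, sd=sd, cv_percent=cv, lbgi=lbgi, hbgi=hbgi,
        lbgi_category=classify_risk(lbgi, "low", lbgi_edges),
        hbgi_category=classify_risk(hbgi, "high", hbgi_edges),
    )
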