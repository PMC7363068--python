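"""Extrapolated pollination performance per park type.

Two-step extrapolation from per-unit visitation rates to a park-level
ecosystem-service index:

* total visitations = mean session rate × spatial total, where the spatial
  total is the summed flower-bed surface (m²) or Tilia crown green volume
  (m³) of the park type — the expected number of visits on all beds/trees
  of the park type within 30 minutes;
* pollination estimator = total visitations / park area (m²) — visits per
  m² of park area per 30 minutes, the comparable performance index.

Estimators are reported at one-decimal precision alongside full precision;
extrapolated totals above 10,000 are additionally rounded to the nearest
1,000 for presentation, mirroring the coarse "estimated" character of the
extrapolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survey_data import Dataset
from .visitation import TOTAL, compute_rates, summarize_rates

__all__ = ["total_visitations", "pollination_estimator",
           "performance_report", "round_total", "round_estimator"]

_ELEMENT_SPATIAL = {"public_bed": "flowerbed_area_m2",
                    "tilia_tree": "tilia_green_volume_m3"}


def total_visitations(mean_rate: float, spatial_total: float) -> float:
    """Extrapolated visits per 30 min on all beds/trees of a park type."""
    if mean_rate < 0 or spatial_total < 0:
        raise ValueError("mean rate and spatial total must be >= 0")
    return float(mean_rate) * float(spatial_total)


def pollination_estimator(total_visits: float, park_area_m2: float) -> float:
    """Visits per m² park area per 30 min (full precision)."""
    if park_area_m2 <= 0:
        raise ValueError("park area must be > 0")
    if total_visits < 0:
        raise ValueError("total visitations must be >= 0")
    return float(total_visits) / float(park_area_m2)


def round_estimator(value: float) -> float:
    """Presentation precision of the estimator: one decimal."""
    return float(np.round(value, 1))


def round_total(value: float) -> float:
    """Presentation rounding of extrapolated totals: nearest 1,000 above
    10,000, else nearest integer."""
    if value > 10_000:
        return float(np.round(value / 1000.0) * 1000.0)
    return float(np.round(value))


def performance_report(d: Dataset, pooled_beds: bool = False,
                       n_boot: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per park type × structural element: mean rate, extrapolated total,
    and pollination estimator.

    Bed rows use public-bed session rates by default (``pooled_beds=True``
    pools study and public beds); tree rows use tree sessions. Park types
    without a structural element (no sessions, or zero spatial total) are
    absent from the table, not zero. With ``n_boot`` > 0 a nonparametric
    bootstrap over sessions adds a 95 % interval for the estimator.

    Raises ``ValueError`` if a park type has sessions but its sites carry
    no matching spatial measurements.
    """
    rates = compute_rates(d, level="main_group")
    site_cols = ["park_type", "park_area_m2", "flowerbed_area_m2",
                 "tilia_green_volume_m3"]
    areas = d.sites[site_cols].groupby("park_type").sum()

    rng = np.random.default_rng(seed)
    rows = []
    for element, spatial_col in _ELEMENT_SPATIAL.items():
        kinds = ("study_bed", "public_bed") if (pooled_beds and
                                               element == "public_bed") \
            else (element,)
        sub = rates[(rates["element_kind"].isin(kinds))
                    & (rates["group_key"] == TOTAL)]
        for park, vals in sub.groupby("park_type")["rate"]:
            spatial = float(areas.loc[park, spatial_col])
            park_area = float(areas.loc[park, "park_area_m2"])
            if spatial == 0:
                raise ValueError(
                    f"{park}: {element} sessions present but "
                    f"{spatial_col} is zero in the site table")
            mean_rate = float(vals.mean())
            total = total_visitations(mean_rate, spatial)
            est = pollination_estimator(total, park_area)
            row = {"park_type": park, "element_kind": element,
                   "n_sessions": int(len(vals)), "mean_rate": mean_rate,
                   "spatial_total": spatial, "total_visitations": total,
                   "total_visitations_rounded": round_total(total),
                   "park_area_m2": park_area, "estimator": est,
                   "estimator_rounded": round_estimator(est)}
            if n_boot > 0 and len(vals) > 1:
                v = vals.to_numpy(float)
                boots = [pollination_estimator(
                    total_visitations(rng.choice(v, len(v)).mean(), spatial),
                    park_area) for _ in range(n_boot)]
                row["estimator_ci_low"], row["estimator_ci_high"] = (
                    float(np.percentile(boots, 2.5)),
                    float(np.percentile(boots, 97.5)))
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["element_kind", "park_type"],
                              ignore_index=True)
    return out
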