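"""Domain types, CSV I/O, validation and taxonomy aggregation for
timed pollinator-visitation surveys.

The data model mirrors a standardized urban field protocol: observers watch
one spatial unit — a 1 m² flower bed or 1 m³ of tree crown — for a fixed
session (reference 30 minutes) and count every pollinator entering it,
classified by eye into morphogroups, noting the plant approached and whether
the insect actually visited a blossom (a precondition for pollination) or
only made a reconnaissance flight.

A :class:`Dataset` bundles five tidy tables (sites, sessions, events, plant
catalog, pollinator taxonomy) held as :class:`pandas.DataFrame` objects.
All readers are strict: missing mandatory columns and dangling foreign keys
raise, unknown columns are dropped with a warning, and blank counts are
rejected rather than coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pollinet")

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

PARK_TYPES = (
    "prestigious",
    "recreational",
    "community_garden",
    "cemetery",
    "rural_reference",
)

ELEMENT_KINDS = ("study_bed", "public_bed", "tilia_tree")

#: Pollination syndromes: functional classification of a flower by the
#: pollinator guild its morphology targets.
SYNDROMES = ("generalist", "hymenoptera", "bee", "bumblebee", "butterfly",
             "pollen", "n.d.")

#: The five main pollinator groups used for community-level analyses.
MAIN_GROUPS = ("honeybee", "bumblebee", "hoverfly", "solitary_bee", "other")

INTERACTION_KINDS = ("blossom_visit", "reconnaissance")

AGGREGATION_LEVELS = ("species", "morphogroup", "main_group")

#: Constant plant label carried by tree sessions (linden crowns).
TILIA = "Tilia spp."

#: Reference session length in minutes; rates are normalized to it.
REFERENCE_DURATION_MIN = 30.0

SESSION_COLUMNS = [
    "record_id", "site_id", "element_kind", "unit_id", "date", "start_time",
    "duration_min", "temperature_C", "wind", "cloudiness",
]
EVENT_COLUMNS = [
    "record_id", "plant_species", "pollinator_label", "interaction_kind",
    "count",
]
SITE_COLUMNS = [
    "site_id", "name", "park_type", "latitude", "longitude", "park_area_m2",
    "flowerbed_area_m2", "tilia_green_volume_m3",
]
PLANT_COLUMNS = ["species", "family", "syndrome"]
TAXONOMY_COLUMNS = ["pollinator_label", "morphogroup", "main_group"]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SurveyDataError(Exception):
    """Base class for survey-data failures."""


class SchemaError(SurveyDataError):
    """A mandatory column is missing or a value cannot be parsed."""


class IntegrityError(SurveyDataError):
    """A foreign key does not resolve."""


class UnmappedLabelError(SurveyDataError):
    """A pollinator label is absent from the taxonomy."""

    def __init__(self, labels: Iterable[str]):
        self.labels = sorted(set(labels))
        super().__init__(f"labels missing from taxonomy: {self.labels}")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A validated survey dataset: five tidy tables plus the aggregation
    level the event labels currently live at."""

    sites: pd.DataFrame
    sessions: pd.DataFrame
    events: pd.DataFrame
    plants: pd.DataFrame
    taxonomy: pd.DataFrame
    level: str = "species"

    def copy(self) -> "Dataset":
        return Dataset(self.sites.copy(), self.sessions.copy(),
                       self.events.copy(), self.plants.copy(),
                       self.taxonomy.copy(), self.level)

    @property
    def total_count(self) -> int:
        return int(self.events["count"].sum()) if len(self.events) else 0

    def blossom_total(self) -> int:
        ev = self.events
        if not len(ev):
            return 0
        return int(ev.loc[ev["interaction_kind"] == "blossom_visit",
                          "count"].sum())


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    kind: str          # e.g. "count", "integrity", "vocabulary"
    table: str
    rows: tuple
    message: str


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _read_table(path: Path, mandatory: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], encoding="utf-8")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", name, extra)
        df = df.drop(columns=extra)
    return df[mandatory]


def _to_numeric(df: pd.DataFrame, col: str, name: str,
                integer: bool = False) -> pd.Series:
    raw = df[col]
    if raw.isna().any():
        bad = list(df.index[raw.isna()])
        raise SchemaError(f"{name}.{col}: blank value(s) at rows {bad}; "
                          "blank counts/measures are rejected, not zero")
    out = pd.to_numeric(raw, errors="coerce")
    if out.isna().any():
        bad = list(df.index[out.isna()])
        raise SchemaError(f"{name}.{col}: unparsable value(s) at rows {bad}")
    if integer:
        if not np.allclose(out, np.round(out)):
            bad = list(df.index[~np.isclose(out, np.round(out))])
            raise SchemaError(f"{name}.{col}: non-integer value(s) "
                              f"at rows {bad}")
        out = out.astype(int)
    return out


def read_dataset(directory: str | Path | None = None, *,
                 sites: str | Path | None = None,
                 sessions: str | Path | None = None,
                 events: str | Path | None = None,
                 plants: str | Path | None = None,
                 taxonomy: str | Path | None = None) -> Dataset:
    """Read a dataset from five CSV files.

    Either pass ``directory`` containing ``sites.csv``, ``sessions.csv``,
    ``events.csv``, ``plants.csv`` and ``taxonomy.csv``, or the five paths
    explicitly. Raises :class:`SchemaError` / :class:`IntegrityError` on a
    malformed file; a valid file set yields a referentially intact Dataset.
    """
    if directory is not None:
        directory = Path(directory)
        sites = sites or directory / "sites.csv"
        sessions = sessions or directory / "sessions.csv"
        events = events or directory / "events.csv"
        plants = plants or directory / "plants.csv"
        taxonomy = taxonomy or directory / "taxonomy.csv"
    if None in (sites, sessions, events, plants, taxonomy):
        raise ValueError("pass a directory or all five file paths")

    site_df = _read_table(Path(sites), SITE_COLUMNS, "sites")
    sess_df = _read_table(Path(sessions), SESSION_COLUMNS, "sessions")
    ev_df = _read_table(Path(events), EVENT_COLUMNS, "events")
    plant_df = _read_table(Path(plants), PLANT_COLUMNS, "plants")
    tax_df = _read_table(Path(taxonomy), TAXONOMY_COLUMNS, "taxonomy")

    for col in ("latitude", "longitude", "park_area_m2", "flowerbed_area_m2",
                "tilia_green_volume_m3"):
        site_df[col] = _to_numeric(site_df, col, "sites")
    sess_df["duration_min"] = _to_numeric(sess_df, "duration_min", "sessions")
    if len(ev_df):
        ev_df["count"] = _to_numeric(ev_df, "count", "events", integer=True)
    else:
        ev_df["count"] = ev_df["count"].astype(int)

    ds = Dataset(site_df, sess_df, ev_df, plant_df, tax_df)
    report = validate_dataset(ds)
    hard = [v for v in report if v.kind == "integrity"]
    if hard:
        raise IntegrityError("; ".join(v.message for v in hard))
    soft = [v for v in report if v.kind != "integrity"]
    if soft:
        raise SchemaError("; ".join(v.message for v in soft))
    return ds


def write_dataset(d: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, df in (("sites", d.sites), ("sessions", d.sessions),
                     ("events", d.events), ("plants", d.plants),
                     ("taxonomy", d.taxonomy)):
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, encoding="utf-8")
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(d: Dataset) -> list[Violation]:
    """Check every dataset invariant; a valid dataset yields ``[]``.

    Reported kinds: ``count`` (negative/non-integer counts), ``vocabulary``
    (value outside a closed vocabulary), ``duration``, ``area``,
    ``duplicate`` and ``integrity`` (dangling references).
    """
    out: list[Violation] = []

    def bad(kind, table, mask, message):
        rows = tuple(mask[mask].index) if hasattr(mask, "index") else tuple(mask)
        out.append(Violation(kind, table, rows, f"{message} (rows {list(rows)})"))

    s = d.sites
    if len(s):
        if s["site_id"].duplicated().any():
            bad("duplicate", "sites", s["site_id"].duplicated(),
                "duplicate site_id")
        m = ~s["park_type"].isin(PARK_TYPES)
        if m.any():
            bad("vocabulary", "sites", m, "unknown park_type")
        for col in ("park_area_m2", "flowerbed_area_m2",
                    "tilia_green_volume_m3"):
            m = ~np.isfinite(s[col]) | (s[col] < 0)
            if m.any():
                bad("area", "sites", m, f"negative/non-finite {col}")
        m = s["park_area_m2"] < s["flowerbed_area_m2"]
        if m.any():
            bad("area", "sites", m, "flowerbed_area_m2 exceeds park_area_m2")

    se = d.sessions
    if len(se):
        if se["record_id"].duplicated().any():
            bad("duplicate", "sessions", se["record_id"].duplicated(),
                "duplicate record_id")
        m = ~se["element_kind"].isin(ELEMENT_KINDS)
        if m.any():
            bad("vocabulary", "sessions", m, "unknown element_kind")
        m = se["duration_min"] <= 0
        if m.any():
            bad("duration", "sessions", m, "duration_min must be > 0")
        m = ~se["site_id"].isin(set(d.sites["site_id"]))
        if m.any():
            bad("integrity", "sessions", m, "session references unknown site")

    ev = d.events
    if len(ev):
        m = ev["count"] < 0
        if m.any():
            bad("count", "events", m, "negative count")
        m = ~ev["interaction_kind"].isin(INTERACTION_KINDS)
        if m.any():
            bad("vocabulary", "events", m, "unknown interaction_kind")
        m = ~ev["record_id"].isin(set(se["record_id"]))
        if m.any():
            bad("integrity", "events", m, "event references unknown session")
        known_plants = set(d.plants["species"]) | {TILIA}
        m = ~ev["plant_species"].isin(known_plants)
        if m.any():
            bad("integrity", "events", m,
                "event references plant absent from the catalog")

    p = d.plants
    if len(p):
        m = ~p["syndrome"].isin(SYNDROMES)
        if m.any():
            bad("vocabulary", "plants", m, "unknown pollination syndrome")

    t = d.taxonomy
    if len(t):
        m = ~t["main_group"].isin(MAIN_GROUPS)
        if m.any():
            bad("vocabulary", "taxonomy", m, "unknown main_group")
        # aggregation must be a function morphogroup -> main_group
        amb = t.groupby("morphogroup")["main_group"].nunique()
        if (amb > 1).any():
            rows = tuple(amb[amb > 1].index)
            out.append(Violation("integrity", "taxonomy", rows,
                                 f"morphogroup(s) {list(rows)} map to "
                                 "several main groups"))
    return out


# ---------------------------------------------------------------------------
# Taxonomy aggregation
# ---------------------------------------------------------------------------

def aggregate_labels(d: Dataset, level: str) -> Dataset:
    """Re-key event pollinator labels to ``morphogroup`` or ``main_group``.

    Counts are summed within (session, plant, level key, interaction kind);
    the grand total is conserved. ``species`` is the identity (raw labels).
    Raises :class:`UnmappedLabelError` if the taxonomy does not cover every
    label present in the events.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"level must be one of {AGGREGATION_LEVELS}")
    if level == "species" or d.level == level:
        out = d.copy()
        out.level = level if level != "species" else d.level
        return out
    if d.level == "main_group" and level == "morphogroup":
        raise ValueError("cannot disaggregate main_group back to morphogroup")

    key = {"morphogroup": "morphogroup", "main_group": "main_group"}[level]
    # after aggregation to morphogroup, labels *are* morphogroups
    if d.level == "morphogroup":
        mapping = (d.taxonomy.drop_duplicates("morphogroup")
                   .set_index("morphogroup")[key])
    else:
        mapping = d.taxonomy.set_index("pollinator_label")[key]

    ev = d.events.copy()
    if len(ev):
        unmapped = set(ev["pollinator_label"]) - set(mapping.index)
        if unmapped:
            raise UnmappedLabelError(unmapped)
        ev["pollinator_label"] = ev["pollinator_label"].map(mapping)
        ev = (ev.groupby(["record_id", "plant_species", "pollinator_label",
                          "interaction_kind"], as_index=False, sort=True)
              ["count"].sum())
        ev = ev[EVENT_COLUMNS]
    out = d.copy()
    out.events = ev
    out.level = level
    return out


def filter_events(d: Dataset, interaction_kind: str | None = None,
                  element_kinds: Iterable[str] | None = None) -> Dataset:
    """Restrict events by interaction kind and/or session element kind."""
    out = d.copy()
    ev = out.events
    if interaction_kind is not None:
        if interaction_kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction_kind {interaction_kind!r}")
        ev = ev[ev["interaction_kind"] == interaction_kind]
    if element_kinds is not None:
        keep = set(element_kinds)
        sess = out.sessions
        ids = set(sess.loc[sess["element_kind"].isin(keep), "record_id"])
        ev = ev[ev["record_id"].isin(ids)]
        out.sessions = sess[sess["element_kind"].isin(keep)].reset_index(drop=True)
    out.events = ev.reset_index(drop=True)
    return out
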