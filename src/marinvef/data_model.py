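"""Typed tables, CSV readers/validators, and the scientific-name join.

The model operates on three relational inputs:

* an ecoregion table — the spatial units of the regionalization, each with its
  marine area (land excluded, km²) and centroid latitude;
* a species-by-ecoregion occurrence table, flagging whether the species is
  alien in that particular ecoregion and, for aliens, whether the record is
  coordinate-backed ("sighted") or attributed without coordinates
  ("total_only");
* a per-species threat assessment table carrying the Red List category
  (DD/LC/NT/VU/EN/CR/EW/EX), the set of threat codes recorded for the
  species, and — for data-deficient species — an externally supplied
  probability of being threatened.

``build_dataset`` joins the three on the species' scientific name into an
immutable :class:`StudyDataset` consumed by every downstream stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("marinvef")

THREAT_LEVELS: tuple[str, ...] = ("DD", "LC", "NT", "VU", "EN", "CR", "EW", "EX")
#: Red List categories counted as "threatened" (extinct categories included:
#: the model is retrospective).
THREATENED_LEVELS: frozenset[str] = frozenset({"NT", "VU", "EN", "CR", "EW", "EX"})

PROVENANCES: tuple[str, ...] = ("sighted", "total_only", "not_applicable")

_WS = re.compile(r"\s+")


class SchemaError(ValueError):
    """An input file lacks a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A row violates a table invariant (range, uniqueness, enum membership)."""


class ConfigurationError(ValueError):
    """A configured key (e.g. the invasion threat code) is inconsistent."""


def normalize_name(name: str) -> str:
    """Normalize a scientific name: trim and collapse internal whitespace.

    Matching is exact on this normalized string — no fuzzy or synonym
    resolution.
    """
    return _WS.sub(" ", str(name).strip())


def _require_columns(frame: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Threat-code taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThreatTaxonomy:
    """Mapping from raw threat codes to the canonical codes used as matrix columns.

    ``codes`` is the closed set of canonical codes when known; ``None`` leaves
    the taxonomy open, with membership inferred from the data. The granularity
    at which threats are attributed (top-level categories vs subcategories) is
    a modelling choice, hence configurable.
    """

    name: str
    codes: frozenset | None
    canonicalize: Callable[[str], str] = field(compare=False)

    def canonical(self, code: str) -> str:
        return self.canonicalize(str(code).strip())

    def contains(self, code: str) -> bool:
        return self.codes is None or code in self.codes

    @staticmethod
    def iucn_top_level() -> "ThreatTaxonomy":
        """IUCN top-level categories "1"–"12", with every "8.1"-prefixed code
        (invasive non-native/alien species/diseases) collapsed to the single
        invasion code "8.1"."""

        def canon(code: str) -> str:
            if code == "8.1" or code.startswith("8.1."):
                return "8.1"
            return code.split(".", 1)[0]

        members = frozenset(str(i) for i in range(1, 13)) | {"8.1"}
        return ThreatTaxonomy("iucn_top_level", members, canon)

    @staticmethod
    def identity(codes: Iterable[str] | None = None) -> "ThreatTaxonomy":
        """Codes used verbatim; membership restricted to ``codes`` if given."""
        members = frozenset(str(c) for c in codes) if codes is not None else None
        return ThreatTaxonomy("identity", members, lambda c: c)


DEFAULT_INVASION_CODE = "8.1"


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EcoregionTable:
    """Validated ecoregion table: ``ecoregion_id``, ``name``, ``area_km2``,
    ``centroid_latitude``. Areas are marine area excluding land, precomputed
    externally in an equal-area projection; this package never computes
    geometry."""

    frame: pd.DataFrame

    COLUMNS = ("ecoregion_id", "name", "area_km2", "centroid_latitude")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EcoregionTable":
        _require_columns(frame, cls.COLUMNS, "ecoregion table")
        out = frame.loc[:, list(cls.COLUMNS)].copy()
        out["ecoregion_id"] = out["ecoregion_id"].astype(str)
        out["name"] = out["name"].astype(str)
        out["area_km2"] = pd.to_numeric(out["area_km2"], errors="raise")
        out["centroid_latitude"] = pd.to_numeric(out["centroid_latitude"], errors="raise")
        dup = out["ecoregion_id"].duplicated()
        if dup.any():
            ids = sorted(out.loc[dup, "ecoregion_id"].unique())
            raise ValidationError(f"duplicate ecoregion_id value(s): {ids}")
        bad_area = ~(out["area_km2"] > 0)
        if bad_area.any():
            rows = list(out.index[bad_area])
            raise ValidationError(f"non-positive area_km2 at row index(es) {rows}")
        bad_lat = ~out["centroid_latitude"].between(-90.0, 90.0)
        if bad_lat.any():
            rows = list(out.index[bad_lat])
            raise ValidationError(f"centroid_latitude outside [-90, 90] at row(s) {rows}")
        return cls(out.reset_index(drop=True))

    @property
    def ids(self) -> list[str]:
        return list(self.frame["ecoregion_id"])

    def area_map(self) -> Mapping[str, float]:
        return dict(zip(self.frame["ecoregion_id"], self.frame["area_km2"]))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class OccurrenceTable:
    """Species-by-ecoregion presence with per-ecoregion alien status.

    ``alien_provenance`` is ``sighted`` (coordinate-backed record),
    ``total_only`` (attributed without coordinates) or ``not_applicable``
    (native occurrences — normalized unconditionally)."""

    frame: pd.DataFrame

    COLUMNS = ("species_name", "ecoregion_id", "is_alien", "alien_provenance")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OccurrenceTable":
        _require_columns(frame, cls.COLUMNS, "occurrence table")
        out = frame.loc[:, list(cls.COLUMNS)].copy()
        out["species_name"] = out["species_name"].map(normalize_name)
        out["ecoregion_id"] = out["ecoregion_id"].astype(str)
        out["is_alien"] = _parse_bool(out["is_alien"])
        prov = out["alien_provenance"].astype("object")
        prov = prov.where(~prov.isna(), "").astype(str).str.strip()
        # native rows are normalized to not_applicable regardless of input
        prov[~out["is_alien"]] = "not_applicable"
        bad = out["is_alien"] & ~prov.isin(["sighted", "total_only"])
        if bad.any():
            rows = list(out.index[bad])
            raise ValidationError(
                "alien occurrence with provenance not in {sighted, total_only} "
                f"at row(s) {rows}"
            )
        out["alien_provenance"] = prov
        dup = out.duplicated(subset=["species_name", "ecoregion_id"])
        if dup.any():
            pairs = out.loc[dup, ["species_name", "ecoregion_id"]].values.tolist()
            raise ValidationError(f"duplicate (species, ecoregion) pair(s): {pairs}")
        return cls(out.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["is_alien"] = out["is_alien"].map({True: "true", False: "false"})
        out.to_csv(path, index=False)


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        True: True, False: False, 1: True, 0: False,
    }

    def conv(v):
        key = v.strip().lower() if isinstance(v, str) else v
        if isinstance(key, (bool, np.bool_)):
            return bool(key)
        if key in mapping:
            return mapping[key]
        raise ValidationError(f"unparseable boolean value {v!r} in is_alien")

    return series.map(conv).astype(bool)


@dataclass(frozen=True)
class AssessmentTable:
    """Per-species Red List assessment: category, threat-code set and, for DD
    species, the probability of being threatened (externally predicted,
    consumed here as a plain number)."""

    frame: pd.DataFrame

    COLUMNS = ("species_name", "threat_level", "threat_codes", "dd_threat_probability")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        strict: bool = True,
        dd_default: float = 0.0,
    ) -> "AssessmentTable":
        _require_columns(
            frame, ("species_name", "threat_level", "threat_codes"), "assessment table"
        )
        out = frame.copy()
        if "dd_threat_probability" not in out.columns:
            out["dd_threat_probability"] = np.nan
        out = out.loc[:, list(cls.COLUMNS)]
        out["species_name"] = out["species_name"].map(normalize_name)
        out["threat_level"] = out["threat_level"].astype(str).str.strip()
        bad_level = ~out["threat_level"].isin(THREAT_LEVELS)
        if bad_level.any():
            toks = sorted(out.loc[bad_level, "threat_level"].unique())
            raise ValidationError(f"unknown threat_level token(s): {toks}")
        dup = out["species_name"].duplicated()
        if dup.any():
            names = sorted(out.loc[dup, "species_name"].unique())
            raise ValidationError(f"duplicate species_name value(s): {names}")
        out["threat_codes"] = out["threat_codes"].map(parse_threat_codes)
        out["dd_threat_probability"] = pd.to_numeric(
            out["dd_threat_probability"], errors="raise"
        )

        is_dd = out["threat_level"] == "DD"
        has_p = out["dd_threat_probability"].notna()
        bad_range = has_p & ~out["dd_threat_probability"].between(0.0, 1.0)
        if bad_range.any():
            rows = list(out.index[bad_range])
            raise ValidationError(f"dd_threat_probability outside [0, 1] at row(s) {rows}")
        stray = has_p & ~is_dd
        if stray.any():
            rows = list(out.index[stray])
            if strict:
                raise ValidationError(
                    f"dd_threat_probability given for non-DD species at row(s) {rows}"
                )
            logger.warning(
                "dropping dd_threat_probability on non-DD species at row(s) %s", rows
            )
            out.loc[stray, "dd_threat_probability"] = np.nan
        missing_dd = is_dd & ~has_p
        if missing_dd.any():
            if not 0.0 <= dd_default <= 1.0:
                raise ConfigurationError("dd_default must lie in [0, 1]")
            logger.warning(
                "%d DD species without dd_threat_probability; defaulting to %g",
                int(missing_dd.sum()), dd_default,
            )
            out.loc[missing_dd, "dd_threat_probability"] = dd_default
        return cls(out.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["threat_codes"] = out["threat_codes"].map(format_threat_codes)
        out.to_csv(path, index=False)


def parse_threat_codes(value) -> frozenset:
    """Parse a "|"-delimited in-cell set of threat codes; blank → empty set."""
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(c).strip() for c in value if str(c).strip())
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(c.strip() for c in text.split("|") if c.strip())


def format_threat_codes(codes: frozenset) -> str:
    return "|".join(sorted(codes))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_ecoregions(path: str | Path) -> EcoregionTable:
    """Read and validate an ecoregion CSV (row order preserved)."""
    return EcoregionTable.from_frame(_read_csv(path))


def read_occurrences(path: str | Path) -> OccurrenceTable:
    """Read and validate an occurrence CSV; native rows are normalized to
    ``alien_provenance = not_applicable``."""
    return OccurrenceTable.from_frame(_read_csv(path))


def read_assessments(
    path: str | Path, *, strict: bool = True, dd_default: float = 0.0
) -> AssessmentTable:
    """Read and validate an assessment CSV.

    ``strict`` controls whether a probability on a non-DD species is an error
    or dropped with a warning; ``dd_default`` fills DD species that lack a
    probability (0 treats them as not threatened)."""
    return AssessmentTable.from_frame(_read_csv(path), strict=strict, dd_default=dd_default)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])


# ---------------------------------------------------------------------------
# The joined dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDataset:
    """Immutable bundle of validated, joined study inputs.

    Assessment threat codes are stored canonicalized under ``taxonomy``.
    Occurrence species absent from the assessment table are retained but
    flagged ``unassessed`` and excluded from every assessed/threatened count.
    """

    ecoregions: EcoregionTable
    occurrences: OccurrenceTable
    assessments: AssessmentTable
    invasion_threat_code: str
    taxonomy: ThreatTaxonomy
    unassessed: frozenset
    join_log: dict

    def threat_code_universe(self) -> list[str]:
        """Canonical codes forming the columns of the intensity matrix:
        the taxonomy's closed set if it has one, otherwise the observed codes,
        always including the invasion code."""
        observed: set[str] = set()
        for codes in self.assessments.frame["threat_codes"]:
            observed |= codes
        if self.taxonomy.codes is not None:
            observed |= set(self.taxonomy.codes)
        observed.add(self.invasion_threat_code)
        return sorted(observed)


def build_dataset(
    ecoregions: EcoregionTable,
    occurrences: OccurrenceTable,
    assessments: AssessmentTable,
    invasion_threat_code: str = DEFAULT_INVASION_CODE,
    taxonomy: ThreatTaxonomy | None = None,
) -> StudyDataset:
    """Join the three validated tables on the species' scientific name.

    Referential integrity (occurrence → ecoregion) is enforced; species with
    occurrences but no assessment are flagged, not dropped. The join log
    accounts for every input row: rows in = rows kept + rows flagged.
    """
    if taxonomy is None:
        taxonomy = ThreatTaxonomy.iucn_top_level()
    invasion_threat_code = str(invasion_threat_code).strip()
    if not taxonomy.contains(invasion_threat_code):
        raise ConfigurationError(
            f"invasion threat code {invasion_threat_code!r} is not a member of "
            f"the {taxonomy.name!r} threat taxonomy"
        )

    occ = occurrences.frame
    known = set(ecoregions.frame["ecoregion_id"])
    unknown = set(occ["ecoregion_id"]) - known
    if unknown:
        raise ValidationError(
            f"occurrence(s) reference unknown ecoregion_id(s): {sorted(unknown)}"
        )

    assessed_names = set(assessments.frame["species_name"])
    occ_names = set(occ["species_name"])
    if not (occ_names & assessed_names):
        raise ValidationError(
            "empty join: no species in common between occurrences and assessments"
        )
    unassessed = frozenset(occ_names - assessed_names)

    canon = assessments.frame.copy()
    canon["threat_codes"] = canon["threat_codes"].map(
        lambda codes: frozenset(taxonomy.canonical(c) for c in codes)
    )

    flagged_rows = int(occ["species_name"].isin(unassessed).sum())
    join_log = {
        "occurrence_rows_in": int(len(occ)),
        "occurrence_rows_kept": int(len(occ)) - flagged_rows,
        "occurrence_rows_flagged_unassessed": flagged_rows,
        "unassessed_species": sorted(unassessed),
        "assessed_species_without_occurrence": sorted(assessed_names - occ_names),
    }
    if unassessed:
        logger.info(
            "join: %d occurrence rows (%d species) flagged unassessed",
            flagged_rows, len(unassessed),
        )
    return StudyDataset(
        ecoregions=ecoregions,
        occurrences=occurrences,
        assessments=AssessmentTable(canon),
        invasion_threat_code=invasion_threat_code,
        taxonomy=taxonomy,
        unassessed=unassessed,
        join_log=join_log,
    )
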