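"""Habitat ranges, the ecoregion-by-threat intensity matrix, and Φ_inv.

The relative invasion-threat frequency of an ecoregion is built in three
steps:

1. Each species' potential habitat range is the summed marine area of every
   ecoregion where any occurrence of that species exists (native or alien —
   presence is presence). Species are assumed uniformly distributed within an
   ecoregion's area.
2. The threat intensity of threat *t* in ecoregion *r* is the ecoregion's
   area divided by the summed habitat ranges of the native species that are
   extant in *r*, carry a threatened Red List category (NT–EX), and list *t*
   among their threat codes. An (r, t) pair with no qualifying species has
   intensity 0 — it carries no threat signal.
3. Within each ecoregion the intensities are normalized to sum to 1; Φ_inv is
   the normalized entry of the invasion threat column. All-zero rows stay
   zero, so Φ_inv = 0 where no coded threat to natives is recorded.

Data-deficient species do not enter this computation; their probability mass
is handled downstream in the threatened-species count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import THREATENED_LEVELS, ConfigurationError, StudyDataset


@dataclass(frozen=True)
class HabitatRangeVector:
    """Per-species habitat range in km² (Series indexed by species_name)."""

    ranges: pd.Series

    def __getitem__(self, species_name: str) -> float:
        return float(self.ranges[species_name])

    def as_dict(self) -> Mapping[str, float]:
        return self.ranges.to_dict()


@dataclass(frozen=True)
class ThreatIntensityMatrix:
    """Ecoregion × threat intensity; rows in input ecoregion order, columns
    sorted threat codes. Entries are nonnegative; 0 exactly where no native,
    threatened species carries the threat."""

    values: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="ecoregion_id")


@dataclass(frozen=True)
class ThreatFrequencyResult:
    """Intensity matrix, its row-normalization, and the Φ_inv vector."""

    intensity: ThreatIntensityMatrix
    phi: pd.DataFrame
    phi_inv: pd.Series

    def to_csv(self, path: str | Path) -> None:
        self.phi.to_csv(path, index_label="ecoregion_id")


def habitat_ranges(dataset: StudyDataset) -> HabitatRangeVector:
    """Sum ecoregion areas over all occurrences (native and alien) per species."""
    occ = dataset.occurrences.frame
    merged = occ.merge(
        dataset.ecoregions.frame[["ecoregion_id", "area_km2"]],
        on="ecoregion_id",
        how="left",
    )
    ranges = merged.groupby("species_name", sort=True)["area_km2"].sum()
    ranges.name = "range_km2"
    return HabitatRangeVector(ranges)


def threat_intensity(
    dataset: StudyDataset, ranges: HabitatRangeVector | None = None
) -> ThreatIntensityMatrix:
    """Build the intensity matrix area(r) / Σ ranges of qualifying species.

    Qualifying for (r, t): native occurrence in r, threatened category, and t
    in the species' canonical threat codes. Alien-only presence in r never
    qualifies for row r, though it still counts toward the species' range.
    """
    if ranges is None:
        ranges = habitat_ranges(dataset)
    eco = dataset.ecoregions.frame
    region_ids = list(eco["ecoregion_id"])
    columns = dataset.threat_code_universe()

    assess = dataset.assessments.frame
    threatened = assess[assess["threat_level"].isin(THREATENED_LEVELS)]
    # species -> exploded (species, threat code) rows
    exploded = (
        threatened[["species_name", "threat_codes"]]
        .assign(threat_code=lambda df: df["threat_codes"].map(sorted))
        .explode("threat_code")
        .dropna(subset=["threat_code"])
        .loc[:, ["species_name", "threat_code"]]
    )

    occ = dataset.occurrences.frame
    native = occ.loc[~occ["is_alien"], ["species_name", "ecoregion_id"]]
    pairs = native.merge(exploded, on="species_name")
    pairs = pairs.assign(range_km2=pairs["species_name"].map(ranges.ranges))

    denom = (
        pairs.groupby(["ecoregion_id", "threat_code"])["range_km2"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=region_ids, columns=columns, fill_value=0.0)
    )
    area = eco.set_index("ecoregion_id")["area_km2"].reindex(region_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = area.values[:, None] / denom.values
    intensity = np.where(denom.values > 0, intensity, 0.0)
    frame = pd.DataFrame(intensity, index=pd.Index(region_ids, name="ecoregion_id"),
                         columns=columns)
    return ThreatIntensityMatrix(frame)


def relative_frequencies(
    intensity: ThreatIntensityMatrix, invasion_threat_code: str
) -> ThreatFrequencyResult:
    """Row-normalize the intensity matrix and extract Φ_inv.

    Rows with no threat signal stay all-zero (Φ_inv = 0 there). Row sums use
    numpy's pairwise summation for stability.
    """
    values = intensity.values
    if invasion_threat_code not in values.columns:
        raise ConfigurationError(
            f"invasion threat code {invasion_threat_code!r} absent from the "
            "intensity matrix columns"
        )
    totals = values.to_numpy().sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = values.to_numpy() / totals[:, None]
    phi = np.where(totals[:, None] > 0, phi, 0.0)
    phi_frame = pd.DataFrame(phi, index=values.index, columns=values.columns)
    phi_inv = phi_frame[invasion_threat_code].copy()
    phi_inv.name = "phi_inv"
    return ThreatFrequencyResult(intensity=intensity, phi=phi_frame, phi_inv=phi_inv)


def compute_threat_frequencies(dataset: StudyDataset) -> ThreatFrequencyResult:
    """Convenience: ranges → intensity → normalized frequencies in one call."""
    ranges = habitat_ranges(dataset)
    intensity = threat_intensity(dataset, ranges)
    return relative_frequencies(intensity, dataset.invasion_threat_code)
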