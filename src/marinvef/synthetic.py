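"""Seeded synthetic study generator with planted ground truth.

Emulates the shape of a harmonized occurrence/assessment join for marine
coastal ecoregions: a configurable number of ecoregions with areas and
centroid latitudes, species scattered over them by an occupancy probability,
a fraction of occurrences marked alien (coordinate-backed or not), Red List
categories drawn from a weight vector, threat-code sets for threatened
species, and probability-of-being-threatened values for data-deficient
species.

Default parameters describe a desk-scale study: a few dozen ecoregions and a
few hundred species, with category weights shaped like the marine Red List
(LC-dominated, a substantial DD share, few extinct), a mean of 2.5 threats
per threatened species, and a ~8% alien occurrence share of which most are
coordinate-backed. What the generator does not emulate — spatial
autocorrelation, taxonomic structure, observer bias — is documented in the
methods note.

Ground truth (per-ecoregion Φ_inv, PDF, EF) is computed by the bundled
triple-loop oracle, never by the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _oracle
from .data_model import (
    AssessmentTable,
    EcoregionTable,
    OccurrenceTable,
    StudyDataset,
    ThreatTaxonomy,
    build_dataset,
)

INVASION_CODE = "invasion"

_DEFAULT_LEVEL_WEIGHTS = {
    "DD": 0.15, "LC": 0.60, "NT": 0.06, "VU": 0.09,
    "EN": 0.05, "CR": 0.03, "EW": 0.005, "EX": 0.015,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    n_ecoregions: int = 30
    n_species: int = 300
    n_threats: int = 12
    area_range: tuple[float, float] = (5e3, 1.5e6)  # km²
    occupancy: float = 0.08
    alien_fraction: float = 0.08
    sighted_fraction: float = 0.8
    level_weights: dict = field(default_factory=lambda: dict(_DEFAULT_LEVEL_WEIGHTS))
    threat_rate: float = 2.5  # mean threats per threatened species
    dd_probability_range: tuple[float, float] = (0.1, 0.9)
    latitude_gradient: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ecoregions, self.n_species, self.n_threats) < 1:
            raise ValueError("n_ecoregions, n_species and n_threats must be >= 1")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1] (0 is infeasible)")
        for name in ("alien_fraction", "sighted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.area_range
        if not 0 < lo <= hi:
            raise ValueError("area_range must be a positive interval")
        lo, hi = self.dd_probability_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("dd_probability_range must lie within [0, 1]")
        w = self.level_weights
        if set(w) - set(_DEFAULT_LEVEL_WEIGHTS) or min(w.values(), default=-1) < 0:
            raise ValueError("level_weights must be nonnegative over the eight categories")
        if sum(w.values()) <= 0:
            raise ValueError("level_weights must have positive total mass")
        if self.threat_rate < 1.0:
            raise ValueError("threat_rate must be >= 1 (a threatened species has a threat)")


def threat_codes_for(config: GeneratorConfig) -> list[str]:
    return [INVASION_CODE] + [f"T{i:02d}" for i in range(2, config.n_threats + 1)]


def generate_dataset(config: GeneratorConfig) -> tuple[StudyDataset, pd.DataFrame]:
    """Draw one synthetic study; returns the dataset and its planted truth.

    Deterministic for a fixed config (single seeded RNG stream); species and
    ecoregion identifiers are deterministic ("S0001", "ER01").
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_r, n_s = config.n_ecoregions, config.n_species

    rid_width = max(2, len(str(n_r)))
    sid_width = max(4, len(str(n_s)))
    region_ids = [f"ER{i + 1:0{rid_width}d}" for i in range(n_r)]
    species = [f"S{i + 1:0{sid_width}d}" for i in range(n_s)]
    codes = threat_codes_for(config)

    areas = rng.uniform(*config.area_range, size=n_r)
    lats = rng.uniform(-90.0, 90.0, size=n_r)
    eco = pd.DataFrame(
        {
            "ecoregion_id": region_ids,
            "name": [f"Synthetic ecoregion {rid}" for rid in region_ids],
            "area_km2": np.round(areas, 1),
            "centroid_latitude": np.round(lats, 3),
        }
    )

    # occupancy: resample any species with no occurrence until nonempty
    present = rng.random((n_s, n_r)) < config.occupancy
    for i in range(n_s):
        while not present[i].any():
            present[i] = rng.random(n_r) < config.occupancy

    occ_rows = []
    native_regions: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        where = np.flatnonzero(present[i])
        alien = rng.random(where.size) < config.alien_fraction
        sighted = rng.random(where.size) < config.sighted_fraction
        native_regions[sp] = [int(j) for j, a in zip(where, alien) if not a]
        for j, a, s in zip(where, alien, sighted):
            occ_rows.append(
                {
                    "species_name": sp,
                    "ecoregion_id": region_ids[j],
                    "is_alien": bool(a),
                    "alien_provenance": ("sighted" if s else "total_only")
                    if a
                    else "not_applicable",
                }
            )
    occ = pd.DataFrame(occ_rows)

    level_names = list(_DEFAULT_LEVEL_WEIGHTS)
    weights = np.array([config.level_weights.get(l, 0.0) for l in level_names])
    weights = weights / weights.sum()
    levels = rng.choice(level_names, size=n_s, p=weights)

    threatened = {"NT", "VU", "EN", "CR", "EW", "EX"}
    abs_lat = np.abs(lats)
    assess_rows = []
    for sp, level in zip(species, levels):
        threat_set: list[str] = []
        prob = np.nan
        if level in threatened:
            k = int(min(1 + rng.poisson(config.threat_rate - 1.0), len(codes)))
            if config.latitude_gradient:
                # plant invasion threat preferentially on high-|latitude| natives
                nat = native_regions[sp]
                mean_lat = float(abs_lat[nat].mean()) if nat else 45.0
                p_inv = 0.15 + 0.75 * mean_lat / 90.0
                if rng.random() < p_inv:
                    rest = rng.choice(codes[1:], size=min(k - 1, len(codes) - 1),
                                      replace=False)
                    threat_set = [INVASION_CODE, *rest]
                else:
                    threat_set = list(
                        rng.choice(codes[1:], size=min(k, len(codes) - 1), replace=False)
                    )
            else:
                threat_set = list(rng.choice(codes, size=k, replace=False))
        elif level == "LC" and rng.random() < 0.2:
            # LC species can carry threat listings too; they must never count
            k = int(rng.integers(1, 3))
            threat_set = list(rng.choice(codes, size=k, replace=False))
        elif level == "DD":
            prob = float(np.round(rng.uniform(*config.dd_probability_range), 4))
        assess_rows.append(
            {
                "species_name": sp,
                "threat_level": level,
                "threat_codes": "|".join(sorted(threat_set)),
                "dd_threat_probability": prob,
            }
        )
    assess = pd.DataFrame(assess_rows)

    dataset = build_dataset(
        EcoregionTable.from_frame(eco),
        OccurrenceTable.from_frame(occ),
        AssessmentTable.from_frame(assess),
        invasion_threat_code=INVASION_CODE,
        taxonomy=ThreatTaxonomy.identity(codes),
    )
    truth = planted_truth(dataset)
    return dataset, truth


def varied_config(
    seed: int,
    *,
    max_ecoregions: int = 10,
    max_species: int = 50,
    max_threats: int = 12,
) -> GeneratorConfig:
    """Draw a small randomized configuration (sizes and rates included) for
    property checks over many independent study conditions."""
    rng = np.random.default_rng(seed)
    return GeneratorConfig(
        n_ecoregions=int(rng.integers(2, max_ecoregions + 1)),
        n_species=int(rng.integers(10, max_species + 1)),
        n_threats=int(rng.integers(2, max_threats + 1)),
        occupancy=float(rng.uniform(0.1, 0.4)),
        alien_fraction=float(rng.uniform(0.05, 0.3)),
        sighted_fraction=float(rng.uniform(0.5, 1.0)),
        threat_rate=float(rng.uniform(1.0, 4.0)),
        dd_probability_range=(0.05, 0.95),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def planted_truth(dataset: StudyDataset) -> pd.DataFrame:
    """Per-ecoregion phi_inv/pdf/ef/status via the independent loop oracle."""
    ef = _oracle.oracle_effect_factors(dataset, alien_mode="sighted", include_dd=True)
    rows = [
        {"ecoregion_id": rid, **vals}
        for rid, vals in ef.items()
    ]
    return pd.DataFrame(rows, columns=["ecoregion_id", "phi_inv", "pdf", "ef", "status"])


def generate(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write the three study CSVs plus planted_truth.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(config)
    paths = {
        "ecoregions": out / "ecoregions.csv",
        "occurrences": out / "occurrences.csv",
        "assessments": out / "assessments.csv",
        "planted_truth": out / "planted_truth.csv",
    }
    dataset.ecoregions.to_csv(paths["ecoregions"])
    dataset.occurrences.to_csv(paths["occurrences"])
    # write raw (identity-taxonomy) codes as generated
    dataset.assessments.to_csv(paths["assessments"])
    truth.to_csv(paths["planted_truth"], index=False, na_rep="")
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Hand-built scenarios with closed-form expectations
# ---------------------------------------------------------------------------


def _toy(eco_rows, occ_rows, assess_rows, codes) -> StudyDataset:
    eco = EcoregionTable.from_frame(
        pd.DataFrame(eco_rows, columns=["ecoregion_id", "name", "area_km2",
                                        "centroid_latitude"])
    )
    occ = OccurrenceTable.from_frame(
        pd.DataFrame(occ_rows, columns=["species_name", "ecoregion_id", "is_alien",
                                        "alien_provenance"])
    )
    assess = AssessmentTable.from_frame(
        pd.DataFrame(assess_rows, columns=["species_name", "threat_level",
                                           "threat_codes", "dd_threat_probability"])
    )
    return build_dataset(eco, occ, assess, invasion_threat_code=INVASION_CODE,
                         taxonomy=ThreatTaxonomy.identity(codes))


def endemic_k_threats(k: int) -> StudyDataset:
    """One ecoregion, one endemic VU species carrying k distinct threats
    (invasion among them), one sighted alien. Φ_inv = 1/k and EF = 1/k.

    The alien carries no assessment, so the endemic is the sole assessed
    species — the EF identity case."""
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    codes = [INVASION_CODE] + [f"T{i:02d}" for i in range(2, 7)]
    threats = "|".join(sorted([INVASION_CODE] + codes[1:k]))
    return _toy(
        [("ER1", "Endemic island", 100.0, -10.0)],
        [
            ("Endemica unica", "ER1", "false", ""),
            ("Peregrina advena", "ER1", "true", "sighted"),
        ],
        [("Endemica unica", "VU", threats, np.nan)],
        codes,
    )


def two_region_shared_species() -> StudyDataset:
    """Two ecoregions (areas 4 and 6); one VU species native to both with
    threats {invasion, pollution}; one EN species native to the small region
    with {pollution} only. Φ_inv of the small region is 7/12."""
    codes = [INVASION_CODE, "pollution"]
    return _toy(
        [("ER1", "Small basin", 4.0, 15.0), ("ER2", "Large basin", 6.0, -40.0)],
        [
            ("Vulnerabilis communis", "ER1", "false", ""),
            ("Vulnerabilis communis", "ER2", "false", ""),
            ("Endangerata localis", "ER1", "false", ""),
        ],
        [
            ("Vulnerabilis communis", "VU", f"{INVASION_CODE}|pollution", np.nan),
            ("Endangerata localis", "EN", "pollution", np.nan),
        ],
        codes,
    )


def zero_alien_region() -> StudyDataset:
    """Invasion-threatened native present but no alien records: EF undefined
    (division by zero aliens)."""
    codes = [INVASION_CODE, "pollution"]
    return _toy(
        [("ER1", "Pristine shelf", 50.0, -65.0)],
        [("Threata nativa", "ER1", "false", "")],
        [("Threata nativa", "CR", INVASION_CODE, np.nan)],
        codes,
    )


def zero_phi_region() -> StudyDataset:
    """Aliens present but the only threatened native carries no invasion
    threat: Φ_inv = 0 hence EF = 0."""
    codes = [INVASION_CODE, "pollution"]
    return _toy(
        [("ER1", "Polluted gulf", 80.0, 40.0)],
        [
            ("Pressa polluta", "ER1", "false", ""),
            ("Peregrina advena", "ER1", "true", "sighted"),
        ],
        [
            ("Pressa polluta", "EN", "pollution", np.nan),
            ("Peregrina advena", "LC", "", np.nan),
        ],
        codes,
    )


def dd_mix() -> StudyDataset:
    """One invasion-threatened VU native plus two DD natives with threat
    probabilities 0.8 and 0.3, and two aliens (one sighted, one coordinate-
    free): exercises T_DD augmentation and both alien modes."""
    codes = [INVASION_CODE, "pollution"]
    return _toy(
        [("ER1", "Mixed coast", 200.0, 5.0)],
        [
            ("Vulnerabilis sola", "ER1", "false", ""),
            ("Incognita prima", "ER1", "false", ""),
            ("Incognita secunda", "ER1", "false", ""),
            ("Peregrina visa", "ER1", "true", "sighted"),
            ("Peregrina relata", "ER1", "true", "total_only"),
        ],
        [
            ("Vulnerabilis sola", "VU", INVASION_CODE, np.nan),
            ("Incognita prima", "DD", "", 0.8),
            ("Incognita secunda", "DD", "", 0.3),
            ("Peregrina visa", "LC", "", np.nan),
            ("Peregrina relata", "LC", "", np.nan),
        ],
        codes,
    )


def scenario_library() -> dict:
    """Named hand-built datasets with known closed-form behaviour."""
    lib = {f"endemic_{k}_threats": endemic_k_threats(k) for k in range(1, 7)}
    lib["two_region_shared_species"] = two_region_shared_species()
    lib["zero_alien_region"] = zero_alien_region()
    lib["zero_phi_region"] = zero_phi_region()
    lib["dd_mix"] = dd_mix()
    return lib
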