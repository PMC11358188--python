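"""Latitude-band summaries, output writers, and pipeline orchestration.

Distributions of EF and Φ_inv are summarized within the six 30°-wide
latitude bands from 90°N to 90°S. A boundary latitude belongs to the
poleward band: band intervals are closed on the equator side and open on the
poleward side, except the two polar bands which are closed at ±90. The
equator itself (exactly 0°) is assigned to the northern 0–30 band by
convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    ConfigurationError,
    ThreatTaxonomy,
    build_dataset,
    read_assessments,
    read_ecoregions,
    read_occurrences,
)
from .effect_factors import EffectFactorTable, compare_variants, compute_ef_table
from .synthetic import GeneratorConfig, generate_dataset, planted_truth
from .threat_frequency import compute_threat_frequencies

#: Band labels ordered from the north pole to the south pole.
BAND_LABELS = ("60..90", "30..60", "0..30", "-30..0", "-60..-30", "-90..-60")


def band_of(latitude: float) -> str:
    """Assign a latitude to its 30° band (boundaries go poleward)."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    idx = min(int(abs(latitude) // 30), 2)
    if latitude >= 0:
        return BAND_LABELS[2 - idx]
    return BAND_LABELS[3 + idx]


def latitude_summary(ef_table: EffectFactorTable) -> pd.DataFrame:
    """Per-band counts and min/median/mean/max of EF and Φ_inv.

    n/a effect factors are excluded from the EF statistics but tallied in
    ``n_ef_na``; zero values are included. All six bands are always emitted,
    empty ones with NaN statistics.
    """
    frame = ef_table.frame
    bands = frame["centroid_latitude"].map(band_of)
    rows = []
    for label in BAND_LABELS:
        sub = frame[bands == label]
        ef = sub["ef"].dropna()
        phi = sub["phi_inv"].dropna()
        row = {
            "band": label,
            "n_ecoregions": int(len(sub)),
            "n_ef_defined": int(len(ef)),
            "n_ef_na": int(sub["ef"].isna().sum()),
        }
        for prefix, values in (("ef", ef), ("phi_inv", phi)):
            row[f"{prefix}_min"] = float(values.min()) if len(values) else np.nan
            row[f"{prefix}_median"] = float(values.median()) if len(values) else np.nan
            row[f"{prefix}_mean"] = float(values.mean()) if len(values) else np.nan
            row[f"{prefix}_max"] = float(values.max()) if len(values) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Key-value run configuration (loadable from a YAML file).

    Either the three input paths are set, or ``generator`` requests a
    synthetic study drawn at run time.
    """

    ecoregions: str | None = None
    occurrences: str | None = None
    assessments: str | None = None
    generator: dict | None = None
    invasion_threat_code: str | None = None
    taxonomy: str = "iucn_top_level"  # or "identity"
    taxonomy_codes: list | None = None
    alien_mode: str = "sighted"
    include_dd: bool = True
    strict: bool = True
    dd_default: float = 0.0
    seed: int | None = None
    out_dir: str = "marinvef_out"
    geojson: str | None = None  # optional geometry file to decorate

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def resolve_taxonomy(self) -> ThreatTaxonomy:
        if self.taxonomy == "iucn_top_level":
            return ThreatTaxonomy.iucn_top_level()
        if self.taxonomy == "identity":
            return ThreatTaxonomy.identity(self.taxonomy_codes)
        raise ConfigurationError(f"unknown taxonomy {self.taxonomy!r}")


def load_dataset(config: PipelineConfig):
    """Materialize the study dataset named by the config (files or generator)."""
    if config.generator is not None:
        gen_kwargs = dict(config.generator)
        if config.seed is not None:
            gen_kwargs.setdefault("seed", config.seed)
        gen = GeneratorConfig(**gen_kwargs)
        dataset, _ = generate_dataset(gen)
        return dataset
    missing = [
        name
        for name in ("ecoregions", "occurrences", "assessments")
        if getattr(config, name) is None
    ]
    if missing:
        raise ConfigurationError(
            f"config must set input path(s) {missing} or a generator section"
        )
    eco = read_ecoregions(config.ecoregions)
    occ = read_occurrences(config.occurrences)
    assess = read_assessments(
        config.assessments, strict=config.strict, dd_default=config.dd_default
    )
    taxonomy = config.resolve_taxonomy()
    invasion = config.invasion_threat_code
    if invasion is None:
        invasion = "8.1" if config.taxonomy == "iucn_top_level" else "invasion"
    return build_dataset(eco, occ, assess, invasion_threat_code=invasion,
                         taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_geojson(ef_table: EffectFactorTable, geometry_path: str | Path,
                  out_path: str | Path) -> None:
    """Merge ef/phi_inv as feature properties into a user-supplied GeoJSON
    keyed by ``ecoregion_id``; geometry is never required or computed here."""
    doc = json.loads(Path(geometry_path).read_text())
    by_id = ef_table.frame.set_index("ecoregion_id")
    for feature in doc.get("features", []):
        rid = feature.get("properties", {}).get("ecoregion_id")
        if rid in by_id.index:
            row = by_id.loc[rid]
            feature["properties"].update(
                ef=None if pd.isna(row["ef"]) else float(row["ef"]),
                phi_inv=float(row["phi_inv"]),
                status=row["status"],
            )
    Path(out_path).write_text(json.dumps(doc, sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run all stages and write the output bundle; returns the output directory.

    Outputs: effect_factors.csv, phi_matrix.csv, intensity_matrix.csv,
    variants.csv, latitude_summary.csv, join_log.json, and manifest.json with
    a config echo, package version, seed and per-file SHA-256 checksums.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = load_dataset(config)
    tfr = compute_threat_frequencies(dataset)
    ef_table = compute_ef_table(
        dataset, tfr, alien_mode=config.alien_mode, include_dd=config.include_dd
    )
    variants = compare_variants(dataset, tfr)
    summary = latitude_summary(ef_table)

    paths = {
        "effect_factors.csv": lambda p: ef_table.to_csv(p),
        "phi_matrix.csv": lambda p: tfr.to_csv(p),
        "intensity_matrix.csv": lambda p: tfr.intensity.to_csv(p),
        "variants.csv": lambda p: variants.to_csv(p),
        "latitude_summary.csv": lambda p: summary.to_csv(p, index=False, na_rep=""),
        "join_log.json": lambda p: p.write_text(
            json.dumps(dataset.join_log, indent=2, sort_keys=True)
        ),
    }
    if config.generator is not None:
        truth = planted_truth(dataset)
        paths["planted_truth.csv"] = lambda p: truth.to_csv(p, index=False, na_rep="")
    if config.geojson is not None:
        paths["effect_factors.geojson"] = lambda p: write_geojson(
            ef_table, config.geojson, p
        )
    for name, writer in paths.items():
        writer(out / name)

    manifest = {
        "package": "marinvef",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "variant_summary": {
            "mean_sighted_total_difference": None
            if pd.isna(variants.mean_difference) else variants.mean_difference,
            "max_sighted_total_gap": None
            if pd.isna(variants.max_gap) else variants.max_gap,
        },
        "outputs": {name: _sha256(out / name) for name in paths},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
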