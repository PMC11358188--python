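"""Per-ecoregion species counts and the effect factor (PDF per alien introduction).

The effect factor of ecoregion r is

    EF_r = PDF_r / N_Alien_r = (N_Threatened_r * Phi_inv_r) / N_Assessed_r / N_Alien_r

with N_Threatened = (invasion-threatened natives with a listed NT–EX
category) + T_DD, where T_DD sums the probability-of-being-threatened over
the data-deficient species natively occurring in r. N_Assessed counts every
assessed species with any occurrence in r (the denominator mirrors the
per-ecoregion species lists the occurrences came from); N_Alien counts alien
occurrences, either coordinate-backed only ("sighted") or including
coordinate-free attributions ("total").

Degenerate ecoregions keep their semantics distinct: EF = 0 means the threat
signal or invasion share is genuinely zero; an n/a status means the quotient
is undefined (no assessed species, or division by zero aliens) and is never
encoded as a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import THREATENED_LEVELS, StudyDataset, ValidationError
from .threat_frequency import ThreatFrequencyResult

STATUS_OK = "ok"
STATUS_ZERO_PHI = "zero_phi"
STATUS_ZERO_ALIEN = "zero_alien_na"
STATUS_ZERO_ASSESSED = "zero_assessed_na"

ALIEN_MODES = ("sighted", "total")


@dataclass(frozen=True)
class EffectFactorTable:
    """One row per ecoregion: counts, Φ_inv, PDF, EF and a status flag.

    ``pdf``/``ef`` are NaN exactly when the corresponding status is an n/a
    status; NaN is representation only — the status column is normative."""

    frame: pd.DataFrame

    COLUMNS = (
        "ecoregion_id", "name", "centroid_latitude", "n_assessed",
        "n_alien_sighted", "n_alien_total", "n_alien", "n_threatened_listed",
        "t_dd", "n_threatened", "phi_inv", "pdf", "ef", "status",
    )

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.loc[:, list(self.COLUMNS)].copy()
        out.to_csv(path, index=False, na_rep="")


@dataclass(frozen=True)
class VariantComparison:
    """Per-ecoregion EF under the three reporting variants plus gap summaries
    over ecoregions where both compared variants are defined."""

    frame: pd.DataFrame  # ecoregion_id, ef_sighted, ef_total, ef_no_dd
    mean_difference: float  # mean of (ef_sighted - ef_total)
    max_gap: float

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, na_rep="")


def _check_ecoregion(dataset: StudyDataset, ecoregion_id: str) -> None:
    if ecoregion_id not in set(dataset.ecoregions.frame["ecoregion_id"]):
        raise ValidationError(f"unknown ecoregion_id {ecoregion_id!r}")


def count_assessed(dataset: StudyDataset, ecoregion_id: str) -> int:
    """Distinct assessed species (any category, DD and LC included) with any
    occurrence — native or alien — in the ecoregion."""
    _check_ecoregion(dataset, ecoregion_id)
    occ = dataset.occurrences.frame
    here = occ.loc[occ["ecoregion_id"] == ecoregion_id, "species_name"]
    assessed = set(dataset.assessments.frame["species_name"])
    return len(set(here) & assessed)


def count_aliens(dataset: StudyDataset, ecoregion_id: str, mode: str = "sighted") -> int:
    """Alien occurrences in the ecoregion; ``total`` adds coordinate-free records."""
    _check_ecoregion(dataset, ecoregion_id)
    if mode not in ALIEN_MODES:
        raise ValueError(f"alien mode must be one of {ALIEN_MODES}, got {mode!r}")
    occ = dataset.occurrences.frame
    here = occ[(occ["ecoregion_id"] == ecoregion_id) & occ["is_alien"]]
    if mode == "sighted":
        here = here[here["alien_provenance"] == "sighted"]
    return int(here["species_name"].nunique())


def threatened_mass(
    dataset: StudyDataset, ecoregion_id: str, include_dd: bool = True
) -> tuple[int, float]:
    """Invasion-threatened natives of the ecoregion: listed count and T_DD.

    The listed count takes distinct native species with the invasion threat
    code and a category in NT–EX. T_DD sums dd_threat_probability over all
    DD species natively occurring in the ecoregion (no threat-code filter:
    DD species typically lack threat listings, and Φ_inv already rescales
    total threat to the invasion share)."""
    _check_ecoregion(dataset, ecoregion_id)
    occ = dataset.occurrences.frame
    natives = set(
        occ.loc[(occ["ecoregion_id"] == ecoregion_id) & ~occ["is_alien"], "species_name"]
    )
    assess = dataset.assessments.frame
    local = assess[assess["species_name"].isin(natives)]
    inv = dataset.invasion_threat_code
    listed = local[
        local["threat_level"].isin(THREATENED_LEVELS)
        & local["threat_codes"].map(lambda codes: inv in codes)
    ]
    n_listed = int(listed["species_name"].nunique())
    t_dd = 0.0
    if include_dd:
        dd = local[local["threat_level"] == "DD"]
        t_dd = float(dd["dd_threat_probability"].fillna(0.0).sum())
    return n_listed, t_dd


def effect_factor(
    n_threatened: float, phi_inv: float, n_assessed: int, n_alien: int
) -> tuple[float, float, str]:
    """Evaluate one ecoregion's PDF and EF with explicit degenerate statuses.

    Returns ``(pdf, ef, status)``; pdf/ef are NaN under their n/a statuses.
    """
    if min(n_threatened, phi_inv, n_assessed, n_alien) < 0:
        raise ValueError("effect_factor inputs must be nonnegative")
    if not 0.0 <= phi_inv <= 1.0:
        raise ValueError(f"phi_inv must lie in [0, 1], got {phi_inv}")
    if n_assessed == 0:
        return float("nan"), float("nan"), STATUS_ZERO_ASSESSED
    pdf = n_threatened * phi_inv / n_assessed
    if n_alien == 0:
        return pdf, float("nan"), STATUS_ZERO_ALIEN
    if phi_inv == 0.0:
        return pdf, 0.0, STATUS_ZERO_PHI
    return pdf, pdf / n_alien, STATUS_OK


def compute_ef_table(
    dataset: StudyDataset,
    tfr: ThreatFrequencyResult,
    alien_mode: str = "sighted",
    include_dd: bool = True,
) -> EffectFactorTable:
    """Assemble the per-ecoregion effect-factor table."""
    eco = dataset.ecoregions.frame
    tfr_ids = list(tfr.phi_inv.index)
    if tfr_ids != list(eco["ecoregion_id"]):
        raise ValidationError(
            "threat-frequency result ecoregions do not match the dataset"
        )
    if alien_mode not in ALIEN_MODES:
        raise ValueError(f"alien mode must be one of {ALIEN_MODES}, got {alien_mode!r}")

    rows = []
    for rid, name, lat in eco[["ecoregion_id", "name", "centroid_latitude"]].itertuples(
        index=False
    ):
        n_assessed = count_assessed(dataset, rid)
        n_sighted = count_aliens(dataset, rid, "sighted")
        n_total = count_aliens(dataset, rid, "total")
        n_alien = n_sighted if alien_mode == "sighted" else n_total
        n_listed, t_dd = threatened_mass(dataset, rid, include_dd=include_dd)
        n_threatened = n_listed + t_dd
        phi_inv = float(tfr.phi_inv[rid])
        pdf, ef, status = effect_factor(n_threatened, phi_inv, n_assessed, n_alien)
        rows.append(
            {
                "ecoregion_id": rid,
                "name": name,
                "centroid_latitude": lat,
                "n_assessed": n_assessed,
                "n_alien_sighted": n_sighted,
                "n_alien_total": n_total,
                "n_alien": n_alien,
                "n_threatened_listed": n_listed,
                "t_dd": t_dd,
                "n_threatened": n_threatened,
                "phi_inv": phi_inv,
                "pdf": pdf,
                "ef": ef,
                "status": status,
            }
        )
    return EffectFactorTable(pd.DataFrame(rows, columns=list(EffectFactorTable.COLUMNS)))


def compare_variants(dataset: StudyDataset, tfr: ThreatFrequencyResult) -> VariantComparison:
    """EF under (sighted, DD), (total, DD) and (sighted, no-DD), with the
    sighted-vs-total gap summarized over co-defined ecoregions."""
    ef_sighted = compute_ef_table(dataset, tfr, "sighted", include_dd=True).frame
    ef_total = compute_ef_table(dataset, tfr, "total", include_dd=True).frame
    ef_no_dd = compute_ef_table(dataset, tfr, "sighted", include_dd=False).frame

    frame = pd.DataFrame(
        {
            "ecoregion_id": ef_sighted["ecoregion_id"],
            "ef_sighted": ef_sighted["ef"],
            "ef_total": ef_total["ef"],
            "ef_no_dd": ef_no_dd["ef"],
        }
    )
    both = frame["ef_sighted"].notna() & frame["ef_total"].notna()
    diffs = frame.loc[both, "ef_sighted"] - frame.loc[both, "ef_total"]
    mean_difference = float(diffs.mean()) if both.any() else float("nan")
    max_gap = float(diffs.max()) if both.any() else float("nan")
    return VariantComparison(frame=frame, mean_difference=mean_difference, max_gap=max_gap)
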