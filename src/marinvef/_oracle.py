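"""Naive triple-loop reference implementation.

This module recomputes habitat ranges, threat intensities, Φ_inv and effect
factors with plain Python loops over dictionaries — deliberately sharing no
arithmetic with the vectorized pipeline in ``threat_frequency`` and
``effect_factors``. It is the normative reference for planted ground truth in
the synthetic generator and the independent side of every equivalence check.
Quadratic and slow by design; use only at test scale.
"""

from __future__ import annotations

from math import fsum, nan

from .data_model import StudyDataset

_THREATENED = {"NT", "VU", "EN", "CR", "EW", "EX"}


def _unpack(dataset: StudyDataset):
    eco = [
        (str(r.ecoregion_id), float(r.area_km2))
        for r in dataset.ecoregions.frame.itertuples(index=False)
    ]
    occ = [
        (str(r.species_name), str(r.ecoregion_id), bool(r.is_alien), str(r.alien_provenance))
        for r in dataset.occurrences.frame.itertuples(index=False)
    ]
    assess = {}
    for r in dataset.assessments.frame.itertuples(index=False):
        prob = float(r.dd_threat_probability) if r.dd_threat_probability == r.dd_threat_probability else 0.0
        assess[str(r.species_name)] = (str(r.threat_level), set(r.threat_codes), prob)
    return eco, occ, assess


def oracle_ranges(dataset: StudyDataset) -> dict:
    eco, occ, _ = _unpack(dataset)
    areas = dict(eco)
    regions_of = {}
    for sp, rid, _, _ in occ:
        regions_of.setdefault(sp, set()).add(rid)
    return {sp: fsum(areas[r] for r in regions) for sp, regions in regions_of.items()}


def oracle_intensity(dataset: StudyDataset) -> dict:
    """{ecoregion_id: {threat_code: intensity}} over the full code universe."""
    eco, occ, assess = _unpack(dataset)
    ranges = oracle_ranges(dataset)
    codes = set()
    for level, threat_codes, _ in assess.values():
        codes |= threat_codes
    if dataset.taxonomy.codes is not None:
        codes |= set(dataset.taxonomy.codes)
    codes.add(dataset.invasion_threat_code)

    natives_in = {rid: set() for rid, _ in eco}
    for sp, rid, is_alien, _ in occ:
        if not is_alien:
            natives_in[rid].add(sp)

    out = {}
    for rid, area in eco:
        row = {}
        for t in sorted(codes):
            contributing = []
            for sp in natives_in[rid]:
                if sp not in assess:
                    continue
                level, threat_codes, _ = assess[sp]
                if level in _THREATENED and t in threat_codes:
                    contributing.append(ranges[sp])
            denom = fsum(contributing)
            row[t] = area / denom if denom > 0 else 0.0
        out[rid] = row
    return out


def oracle_phi(dataset: StudyDataset) -> dict:
    """{ecoregion_id: {threat_code: normalized intensity}}; zero rows stay zero."""
    intensity = oracle_intensity(dataset)
    phi = {}
    for rid, row in intensity.items():
        total = fsum(row.values())
        if total > 0:
            phi[rid] = {t: v / total for t, v in row.items()}
        else:
            phi[rid] = {t: 0.0 for t in row}
    return phi


def oracle_phi_inv(dataset: StudyDataset) -> dict:
    phi = oracle_phi(dataset)
    inv = dataset.invasion_threat_code
    return {rid: row[inv] for rid, row in phi.items()}


def oracle_effect_factors(
    dataset: StudyDataset, alien_mode: str = "sighted", include_dd: bool = True
) -> dict:
    """{ecoregion_id: {"phi_inv", "pdf", "ef", "status"}} by direct counting."""
    eco, occ, assess = _unpack(dataset)
    phi_inv = oracle_phi_inv(dataset)
    inv = dataset.invasion_threat_code

    out = {}
    for rid, _ in eco:
        assessed = set()
        aliens = set()
        natives = set()
        for sp, r, is_alien, prov in occ:
            if r != rid:
                continue
            if sp in assess:
                assessed.add(sp)
            if is_alien and (prov == "sighted" or alien_mode == "total"):
                aliens.add(sp)
            if not is_alien:
                natives.add(sp)
        n_listed = 0
        dd_probs = []
        for sp in natives:
            if sp not in assess:
                continue
            level, threat_codes, prob = assess[sp]
            if level in _THREATENED and inv in threat_codes:
                n_listed += 1
            if level == "DD" and include_dd:
                dd_probs.append(prob)
        n_threatened = n_listed + fsum(dd_probs)
        p = phi_inv[rid]
        if len(assessed) == 0:
            pdf, ef, status = nan, nan, "zero_assessed_na"
        else:
            pdf = n_threatened * p / len(assessed)
            if len(aliens) == 0:
                ef, status = nan, "zero_alien_na"
            elif p == 0.0:
                ef, status = 0.0, "zero_phi"
            else:
                ef, status = pdf / len(aliens), "ok"
        out[rid] = {"phi_inv": p, "pdf": pdf, "ef": ef, "status": status}
    return out
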