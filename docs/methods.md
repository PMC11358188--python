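# Methods

## Model

The package computes a regionalized effect factor (EF) for marine invasion
impacts: the potentially disappeared fraction (PDF) of native species per
alien species introduction, per marine ecoregion. Ecoregions are treated as
units of homogeneous species composition — an occurrence anywhere in an
ecoregion counts as presence throughout it — and every computation is
retrospective, reading recorded threat assessments rather than projecting
dynamics.

For ecoregion *r*:

```
EF_r = (N_Threatened_r · Φ_inv,r) / N_Assessed_r / N_Alien_r
```

`EF` is linear in the threatened count and in Φ_inv, and reciprocal in the
assessed and alien counts — so sparsely assessed or barely invaded
ecoregions produce extreme values by construction, a property users should
keep in mind when interpreting outputs from thin data.

### Counts

- **N_Assessed** counts distinct assessed species with *any* occurrence
  (native or alien) in *r* — the denominator mirrors the per-ecoregion
  species lists the occurrences came from. Species occurring without an
  assessment are retained in the dataset, flagged, and excluded from every
  count.
- **N_Threatened** = listed count + `T_DD`. The listed count takes distinct
  *native* species of *r* whose category is NT, VU, EN, CR, EW or EX and
  whose threat-code set contains the invasion code. Extinct categories count
  because the model reads damage already done. `T_DD` sums the externally
  predicted probability-of-being-threatened over all DD natives of *r*,
  without a threat-code filter: DD species rarely carry threat listings, and
  Φ_inv already rescales total threat to the invasion share. (Restricting
  `T_DD` to invasion-coded DD species would require data that generally does
  not exist; the `include_dd` switch provides the no-DD variant instead.)
- **N_Alien** counts alien occurrences, in two modes: `sighted`
  (coordinate-backed records only — the headline variant) and `total`
  (including coordinate-free attributions). Alien counting does not require
  the alien itself to be assessed.

### Relative invasion-threat frequency Φ_inv

1. A species' habitat range is the summed marine area (km², land excluded)
   of every ecoregion where any occurrence of it exists — native or alien,
   since presence is presence. Areas are *inputs*, precomputed externally in
   an equal-area projection; the package does no geometry.
2. The intensity of threat *t* in ecoregion *r* is
   `area(r) / Σ ranges of native, threatened species of r carrying t`.
   The inverse-range form means a threat borne by narrow endemics is intense,
   one borne by wide-ranging species is dilute. An (r, t) pair with no
   qualifying species has intensity 0, not undefined: no species, no signal.
3. Within each ecoregion the intensities are normalized to sum to 1
   (all-zero rows stay zero); Φ_inv is the invasion column of the normalized
   matrix.

Two consequences of the inverse-range form are worth spelling out, because
both are verified by tests and the second is easy to get backwards:

- adding a wide-ranging species that carries the invasion threat *dilutes*
  Φ_inv (it enlarges the invasion denominator);
- adding a threatened native that carries only *other* threats *raises*
  Φ_inv (it enlarges a competing denominator, shrinking that threat's share).

A sole threatened endemic with *k* distinct threats therefore has
Φ_inv = 1/k exactly — the closed form the scenario fixtures pin down.

DD species never enter the intensity matrix; their mass lives only in
`T_DD`. Species with a threatened category but an empty code set contribute
to no column. Φ_inv does not distinguish marine from terrestrial invaders
behind a threat listing, and no per-threat impact-score weighting is applied.

### Degenerate semantics

Each ecoregion row carries exactly one status:

| status             | meaning                                | pdf | ef  |
|--------------------|----------------------------------------|-----|-----|
| `ok`               | all quantities defined                 | num | num |
| `zero_phi`         | Φ_inv = 0: no recorded invasion threat | 0   | 0   |
| `zero_alien_na`    | no alien records: EF undefined         | num | n/a |
| `zero_assessed_na` | no assessed species: PDF undefined     | n/a | n/a |

`n/a` is a status, never a numeric 0 — a region with no recorded aliens is
not a region where invasion is harmless. In CSV output `n/a` renders as an
empty cell beside its status code.

## Inputs and join

Three UTF-8 CSVs (ecoregions; occurrences; assessments — see the README for
columns). The join is exact on the whitespace-normalized scientific name; no
synonym resolution is attempted, so name harmonization is the data
supplier's job. The join log accounts for every row (rows in = rows kept +
rows flagged) and is written beside the outputs.

Threat codes are canonicalized through a configurable taxonomy. The default
collapses hierarchical codes to their top-level category except that
"8.1"-prefixed codes (invasive non-native/alien species/diseases) map to the
single invasion code "8.1" — attribution granularity is a modelling choice,
so an identity taxonomy (codes used verbatim, with an optional closed code
set) is also provided and is what the synthetic generator uses. DD species
lacking a probability default to 0 (treated as not threatened) with a logged
warning; the default is configurable, and a probability on a non-DD species
is an error in strict mode or dropped with a warning in lenient mode.

## Synthetic data and what passing tests show

The generator draws, from a single seeded RNG stream with deterministic
identifiers: ecoregion areas uniform on 5·10³–1.5·10⁶ km² and latitudes
uniform on ±90°; species placed by an independent occupancy probability
(default 0.08, resampled so every species occurs somewhere); 8% of
occurrences alien, 80% of those coordinate-backed; Red List categories from
a marine-shaped weight vector (LC 0.60, DD 0.15, NT 0.06, VU 0.09, EN 0.05,
CR 0.03, EW 0.005, EX 0.015); 1 + Poisson(1.5) threat codes per threatened
species (mean 2.5); DD probabilities uniform on 0.1–0.9. A fifth of LC
species also carry threat codes, which must never count. The optional
latitude-gradient mode plants the invasion threat preferentially on
high-latitude natives so that rank-correlation recovery can be checked.

Ground truth is computed by a triple-loop oracle written against the model
definition with plain dictionaries and `math.fsum`, sharing no arithmetic
with the vectorized pipeline; the hand-derived closed-form values were fixed
first and the oracle verified against them.

The generator emulates table *shape*, not biogeography: no spatial
autocorrelation, no taxonomic structure, no observer or assessment-effort
bias, and independence everywhere. Passing tests therefore demonstrate that
the implementation computes the defined model exactly and deterministically —
not that the model's outputs on real exports are unbiased, which the data's
known observer biases preclude.

## Numerical choices

- All arithmetic in float64; row sums via numpy's pairwise summation, the
  oracle's via `fsum`. Equivalence is asserted at 1e-10 elementwise,
  normalization at 1e-12.
- Zero denominators are resolved before division (masked), never by
  exception handling on NaN.
- Matrix rows follow input ecoregion order; columns are sorted threat codes;
  ties never arise because keys are unique by validation.
- Latitude bands are the six 30° intervals from 90°N to 90°S; a boundary
  latitude joins its poleward band (closed on the equator side), the poles
  close their bands, and exactly 0° joins the northern 0–30 band by
  convention.

## Problem sizes

Defaults are desk-scale: the reference synthetic study uses 30 ecoregions ×
300 species × 12 threats; property suites run 100 randomized studies of at
most 10 ecoregions, 50 species and 12 threats each, sizes at which the
quadratic oracle is instantaneous and the whole suite stays comfortably
interactive. The pipeline itself is vectorized and handles
hundreds-of-ecoregions × tens-of-thousands-of-species inputs without
special handling.

## Known limitations

- Exact-name joining: unharmonized synonyms silently become distinct species.
- Global (not regional) threat assessments: a species globally threatened
  counts as threatened in every ecoregion it inhabits natively.
- Φ_inv is a frequency rescaling, not a mechanistic attribution; it inherits
  every bias of the underlying threat listings.
- No fate modelling: these are effect factors only, intended to be combined
  with introduction fate factors downstream.
- Uncertainty is not quantified; the assessments carry none to propagate.
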