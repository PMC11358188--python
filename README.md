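# marinvef

Regionalized **effect factors for marine biological invasions**: per marine
ecoregion, how much native biodiversity is at risk per introduced alien
species.

Life-cycle impact assessment (LCIA) quantifies ecological damage as a
*potentially disappeared fraction* (PDF) of species per unit of environmental
pressure. For marine invasions the pressure is the introduction of an alien
species — typically via shipping — and the effect factor of ecoregion *r* is

```
EF_r = PDF_r / N_Alien_r = (N_Threatened_r · Φ_inv,r) / N_Assessed_r / N_Alien_r
```

where, within ecoregion *r*:

- `N_Assessed` — Red-List-assessed species with any occurrence in *r*;
- `N_Threatened` — native species threatened by invasive species (category
  NT, VU, EN, CR, EW or EX with the invasion threat code), plus `T_DD`, the
  summed probability-of-being-threatened of the data-deficient natives;
- `N_Alien` — introduced alien species, counted either from coordinate-backed
  records only (`sighted`) or including coordinate-free attributions
  (`total`);
- `Φ_inv` — the *relative invasion-threat frequency*: species are usually
  threatened by several simultaneous threats (fishing, pollution, climate …),
  so the total threat signal is rescaled to the share attributable to
  invasion. The intensity of threat *t* in *r* is the ecoregion's marine area
  divided by the summed habitat ranges of the native, threatened species
  carrying *t* (a species' range being the total area of the ecoregions where
  it occurs); intensities are normalized within each ecoregion to sum to 1,
  and Φ_inv is the invasion entry.

Degenerate cases keep distinct meanings: Φ_inv = 0 gives EF = 0 (no recorded
invasion threat), while zero aliens or zero assessed species give an explicit
`n/a` status — never a numeric zero.

The package is aimed at LCIA method developers and invasion ecologists. It
consumes three CSV tables (ecoregions with areas and centroid latitudes;
species × ecoregion occurrences with alien flags and record provenance;
per-species Red List assessments with threat codes and DD probabilities) —
the shape of a harmonized citizen-science/Red-List join — and ships a seeded
synthetic generator so the whole pipeline is testable without database
exports.

## Worked example

```sh
cat > config.yaml <<EOF
generator:
  n_ecoregions: 12
  n_species: 120
  occupancy: 0.2
  alien_fraction: 0.15
seed: 42
out_dir: out
EOF
marinvef run --config config.yaml
```

`out/effect_factors.csv` then begins:

```
ecoregion_id  n_assessed  n_alien  n_threatened  phi_inv      pdf       ef   status
        ER01          35        2        7.3247 0.109980 0.023016 0.011508       ok
        ER02          25        1        2.1256 0.268333 0.022815 0.022815       ok
        ER03          33        6        4.4349 0.034410 0.004624 0.000771       ok
        ER04          25        1        1.9690 0.000000 0.000000 0.000000 zero_phi
```

ER01: of 35 assessed species, 7.32 (6 listed natives plus 1.32 expected from
DD species) are threatened, 11% of the local threat signal is invasion, so
the local PDF attributable to invasion is 0.023; divided over 2 introduced
aliens, each introduction accounts for EF ≈ 0.0115 PDF·alien⁻¹. ER04 has
threatened natives but none coded for invasion, hence Φ_inv = 0 and EF = 0
(`zero_phi`), not `n/a`.

The bundle also contains the intensity and Φ matrices, a
sighted/total/no-DD variant comparison (`variants.csv`), 30°-latitude-band
summaries of EF and Φ_inv (`latitude_summary.csv`), the join log, and a
manifest with SHA-256 checksums — two runs with the same config and seed are
byte-identical.

Other subcommands: `marinvef generate` (emit synthetic fixtures with planted
oracle truth), `compute`, `summarize`, `compare-variants`.

As a library:

```python
from marinvef import compute_threat_frequencies, compute_ef_table
from marinvef.synthetic import GeneratorConfig, generate_dataset

dataset, truth = generate_dataset(GeneratorConfig(seed=42))
tfr = compute_threat_frequencies(dataset)      # intensity, Φ matrix, Φ_inv
table = compute_ef_table(dataset, tfr, alien_mode="sighted", include_dd=True)
```

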