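import pandas as pd
import pytest

from marinvef import synthetic

#: number of independent random study conditions used by the property suites
N_RANDOM_STUDIES = 100


@pytest.fixture(scope="session")
def scenarios():
    return synthetic.scenario_library()


@pytest.fixture(scope="session")
def random_studies():
    """100 small randomized studies (≤10 ecoregions, ≤50 species, ≤12 threats)
    with oracle-computed planted truth."""
    studies = []
    for seed in range(N_RANDOM_STUDIES):
        config = synthetic.varied_config(seed)
        dataset, truth = synthetic.generate_dataset(config)
        studies.append((seed, dataset, truth))
    return studies


def toy_dataset(eco_rows, occ_rows, assess_rows, codes, invasion="invasion"):
    """Hand-assemble a StudyDataset from plain tuples (tests' construction kit)."""
    from marinvef.data_model import (
        AssessmentTable,
        EcoregionTable,
        OccurrenceTable,
        ThreatTaxonomy,
        build_dataset,
    )

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
    return build_dataset(eco, occ, assess, invasion_threat_code=invasion,
                         taxonomy=ThreatTaxonomy.identity(codes))
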