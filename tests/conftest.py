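import numpy as np
import pytest

import f8landscape as f8


@pytest.fixture(scope="session")
def grid_profile():
    """Conservation profile from a 100-species alignment with targets on a
    0.1..1.0 grid (each target repeated over 5 consecutive positions)."""
    targets = np.repeat(np.linspace(0.1, 1.0, 10).round(2), 5)
    aln, realized = f8.make_msa(
        f8.MsaSpec(n_species=100, ref_length=50, conservation_targets=targets, seed=101)
    )
    return f8.conservation(aln), targets, aln


@pytest.fixture(scope="session")
def fixtures_bundle():
    return f8.load_paper_fixtures()


@pytest.fixture(scope="session")
def synthetic_catalog(grid_profile):
    """A merged+annotated catalog with its panel and ground truth."""
    from f8landscape import catalog as cat

    profile, _targets, _aln = grid_profile
    spec = f8.VariantTableSpec(
        counts={"UniProt": 3, "ClinVar_Path": 6, "ClinVar_VUS": 8,
                "Geno2MP": 5, "gnomAD": 10},
        gnomad_overlap=0.6, cross_overlap=0.2, seed=77,
    )
    tables = f8.make_variant_tables(spec, profile)
    truth = tables.pop("truth")
    panel = tables.pop("panel")
    merged = cat.merge_sources(tables)
    merged = cat.annotate_conservation(merged, profile)
    return merged, panel, truth
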