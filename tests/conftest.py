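import numpy as np
import pytest

from hemotype.catalog import write_haplotype_table, write_variant_table
from hemotype.fixtures import cis_trans_catalog, toy_catalog
from hemotype.simulate import generate_synthetic_catalog


@pytest.fixture(scope="session")
def toy_cat():
    """Bundled toy catalog: ABO-like, RH-like, 8 synthetic systems."""
    return toy_catalog()


@pytest.fixture(scope="session")
def cis_trans_cat():
    """Minimal 4-allele cis/trans ambiguity system."""
    return cis_trans_catalog()


@pytest.fixture(scope="session")
def synthetic_cat():
    """Mid-size synthetic catalog shared across tests (deterministic)."""
    return generate_synthetic_catalog(n_systems=6, alleles_per_system=(4, 8),
                                      variants_per_system=(4, 10), seed=42)


@pytest.fixture()
def catalog_dir(tmp_path, cis_trans_cat):
    """The cis/trans catalog written out as a catalog directory."""
    d = tmp_path / "catalog"
    d.mkdir()
    variants = [v for s in cis_trans_cat.system_names() for v in cis_trans_cat.variants(s)]
    alleles = [a for s in cis_trans_cat.system_names() for a in cis_trans_cat.alleles(s)]
    write_variant_table(variants, d / "variants.tsv")
    write_haplotype_table(alleles, d / "haplotypes.tsv")
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
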