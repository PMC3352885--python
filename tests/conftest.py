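import numpy as np
import pytest

from taxocat.catalog import SpeciesRecord, TaxonomicCatalog
from taxocat.synthetic import make_fixture_suite


def build_catalog(rows, class_name="Diplopoda"):
    """rows: (order, family, genus, epithet[, year[, countries]])."""
    records = []
    for row in rows:
        order, family, genus, epithet = row[:4]
        year = row[4] if len(row) > 4 else None
        countries = tuple(row[5]) if len(row) > 5 else ()
        records.append(
            SpeciesRecord(
                order_name=order,
                family_name=family,
                genus_name=genus,
                species_epithet=epithet,
                year_described=year,
                countries=countries,
            )
        )
    return TaxonomicCatalog(records=tuple(records), class_name=class_name)


def random_catalog(rng, max_species=200):
    """A random rank-complete catalog for oracle comparisons."""
    s = int(rng.integers(2, max_species + 1))
    n_orders = int(rng.integers(1, 5))
    rows = []
    for i in range(s):
        o = int(rng.integers(n_orders))
        f = int(rng.integers(1, 4))
        g = int(rng.integers(1, 6))
        rows.append((f"O{o}", f"O{o}F{f}", f"O{o}F{f}G{g}", f"sp{i}"))
    return build_catalog(rows)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    return make_fixture_suite(seed=1, outdir=tmp_path_factory.mktemp("fixtures"))


@pytest.fixture
def rng():
    return np.random.default_rng(20120515)
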