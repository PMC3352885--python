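"""Synthetic catalogs, description histories, and country tables.

Real Linnean catalogs are strongly imbalanced: most genera hold one or two
species while a few hold hundreds. The catalog generator reproduces this with
a two-parameter preferential-allocation (Pitman–Yor / discounted
Chinese-restaurant) scheme applied at each rank step: the i-th species joins
an existing genus with probability proportional to (genus size − discount)
and founds a new genus with probability proportional to
(concentration + discount × number of genera). The discount fattens the tail
(a few giant genera) while keeping many singletons — a single-parameter
scheme cannot jointly match a 68% fraction of ≤2-species genera and a mean
of ~4 species per genus, which is why both knobs are exposed.

Description histories are thinned renewal draws: each of N true species gets
a latent description year from a logistic curve, and is actually described
with the era's effort factor — species thinned away stay latent, so the true
richness behind every series is known exactly.

Country tables draw log-normal areas and populations and Poisson species
counts with a log link on log area plus a tropical effect, mirroring the
structure the geographic regressions assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import (
    DescriptionSeries,
    SpeciesRecord,
    TaxonomicCatalog,
    write_catalog,
)
from .geography import CountryRecord
from .richness import write_series_csv

# Defaults calibrated so a ~3,000-species catalog lands near the imbalance
# observed in real millipede data: ~68% of genera with ≤2 species and ~4
# species per genus on average.
DEFAULT_GENUS_CONCENTRATION = 70.0
DEFAULT_GENUS_DISCOUNT = 0.45


@dataclass(frozen=True)
class CatalogSimConfig:
    """Allocation parameters per rank step, species → genus upward."""

    total_species: int
    genus_concentration: float = DEFAULT_GENUS_CONCENTRATION
    genus_discount: float = DEFAULT_GENUS_DISCOUNT
    family_concentration: float = 2.0
    family_discount: float = 0.4
    order_concentration: float = 0.8
    order_discount: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.total_species < 1:
            raise ValueError("total_species must be ≥1")
        for name in ("genus", "family", "order"):
            conc = getattr(self, f"{name}_concentration")
            disc = getattr(self, f"{name}_discount")
            if conc <= 0:
                raise ValueError(f"{name}_concentration must be positive")
            if not 0 <= disc < 1:
                raise ValueError(f"{name}_discount must be in [0, 1)")


@dataclass(frozen=True)
class HistorySimConfig:
    """Thinned logistic discovery history.

    ``era_effort`` maps (start_year, end_year) intervals (inclusive) to
    retention probabilities; years not covered default to effort 1.
    """

    true_richness: int
    midpoint: float = 1920.0
    scale: float = 40.0
    start_year: int = 1758
    end_year: int = 2007
    era_effort: tuple[tuple[int, int, float], ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_richness < 1:
            raise ValueError("true_richness must be ≥1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 1758 <= self.start_year <= self.end_year <= 2100:
            raise ValueError("year range must lie within 1758..2100")
        for lo, hi, f in self.era_effort:
            if not 0 <= f <= 1:
                raise ValueError("effort factors must lie in [0, 1]")
            if lo > hi:
                raise ValueError("era interval reversed")


@dataclass(frozen=True)
class GeoSimConfig:
    n_countries: int = 120
    log_area_mean: float = 11.5  # exp(11.5) ≈ 1.0e5 km²
    log_area_sd: float = 1.8
    log_pop_mean: float = 15.5
    log_pop_sd: float = 1.5
    tropical_prob: float = 0.45
    richness_intercept: float = -2.0
    log_area_slope: float = 0.5
    tropical_effect: float = 0.4
    noise_sd: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        for name in ("log_area_sd", "log_pop_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.tropical_prob <= 1:
            raise ValueError("tropical_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# Pitman–Yor allocation
# ---------------------------------------------------------------------------

def _py_allocate(n: int, concentration: float, discount: float, rng) -> np.ndarray:
    """Assign n items to clusters by the two-parameter CRP; returns labels."""
    labels = np.empty(n, dtype=int)
    sizes: list[float] = []
    for i in range(n):
        k = len(sizes)
        if k == 0:
            sizes.append(1.0)
            labels[i] = 0
            continue
        w = np.array(sizes) - discount
        w_new = concentration + discount * k
        total = w.sum() + w_new
        u = rng.random() * total
        if u < w_new:
            labels[i] = k
            sizes.append(1.0)
        else:
            j = int(np.searchsorted(np.cumsum(w), u - w_new, side="right"))
            labels[i] = j
            sizes[j] += 1.0
    return labels


def simulate_classification(config: CatalogSimConfig) -> TaxonomicCatalog:
    """Draw a rank-complete catalog with preferential species allocation.

    Species are allocated to genera, genera to families, and families to
    orders, each by an independent Pitman–Yor draw. The realized fraction of
    ≤2-species genera is recorded in the catalog metadata.
    """
    rng = np.random.default_rng(config.seed)
    s = config.total_species
    genus_of_species = _py_allocate(
        s, config.genus_concentration, config.genus_discount, rng
    )
    n_genera = genus_of_species.max() + 1
    family_of_genus = _py_allocate(
        n_genera, config.family_concentration, config.family_discount, rng
    )
    n_families = family_of_genus.max() + 1
    order_of_family = _py_allocate(
        n_families, config.order_concentration, config.order_discount, rng
    )

    per_genus_counter = np.zeros(n_genera, dtype=int)
    records = []
    for i in range(s):
        g = genus_of_species[i]
        f = family_of_genus[g]
        o = order_of_family[f]
        per_genus_counter[g] += 1
        records.append(
            SpeciesRecord(
                order_name=f"Order{o + 1:02d}",
                family_name=f"Family{f + 1:03d}",
                genus_name=f"Genus{g + 1:04d}",
                species_epithet=f"sp{per_genus_counter[g]:04d}",
            )
        )
    genus_sizes = np.bincount(genus_of_species)
    frac_small = float(np.mean(genus_sizes <= 2))
    return TaxonomicCatalog(
        records=tuple(records),
        class_name="Simulata",
        metadata={
            "generator": "pitman_yor",
            "seed": config.seed,
            "fraction_small_genera": frac_small,
            "mean_species_per_genus": float(s / n_genera),
        },
    )


# ---------------------------------------------------------------------------
# Description histories
# ---------------------------------------------------------------------------

def _effort_for_years(config: HistorySimConfig, years: np.ndarray) -> np.ndarray:
    effort = np.ones(len(years))
    for lo, hi, f in config.era_effort:
        effort[(years >= lo) & (years <= hi)] = f
    return effort


def simulate_description_history(
    config: HistorySimConfig,
) -> tuple[DescriptionSeries, dict]:
    """Thinned logistic discovery draw; returns the series and a truth record.

    Each of the N species receives a latent description year from
    logistic(midpoint, scale). Years inside the observation window are kept
    with the era's effort probability; everything else — thinned species and
    species whose latent year falls outside the window — stays latent. The
    truth record carries N and the latent bookkeeping so richness estimators
    can be scored against exact truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.true_richness
    latent = config.midpoint + config.scale * np.log(
        (u := rng.uniform(1e-12, 1 - 1e-12, n)) / (1 - u)
    )
    latent_years = np.floor(latent).astype(int)
    years = np.arange(config.start_year, config.end_year + 1)
    effort = _effort_for_years(config, years)
    in_window = (latent_years >= config.start_year) & (latent_years <= config.end_year)
    keep = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(in_window)
    if len(idx):
        p = effort[latent_years[idx] - config.start_year]
        keep[idx] = rng.random(len(idx)) < p
    counts = np.bincount(
        latent_years[keep] - config.start_year, minlength=len(years)
    )
    series = DescriptionSeries(years=years, counts=counts)
    truth = {
        "true_richness": n,
        "midpoint": config.midpoint,
        "scale": config.scale,
        "n_described": int(keep.sum()),
        "n_latent": int(n - keep.sum()),
        "seed": config.seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Country tables
# ---------------------------------------------------------------------------

def simulate_geography(config: GeoSimConfig) -> list[CountryRecord]:
    """Country table with log-area-driven Poisson richness.

    species ~ Poisson(exp(intercept + slope·log(area) + tropical·effect + ε)),
    ε ~ Normal(0, noise_sd). Countries drawing zero species are dropped,
    matching the admission rule of the geographic analyses.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_countries
    areas = np.exp(rng.normal(config.log_area_mean, config.log_area_sd, k))
    pops = np.exp(rng.normal(config.log_pop_mean, config.log_pop_sd, k))
    tropical = rng.random(k) < config.tropical_prob
    eta = (
        config.richness_intercept
        + config.log_area_slope * np.log(areas)
        + config.tropical_effect * tropical
        + rng.normal(0, config.noise_sd, k)
    )
    species = rng.poisson(np.exp(eta))
    out = []
    for i in range(k):
        if species[i] < 1:
            continue
        pct = rng.uniform(50, 100) if tropical[i] else rng.uniform(0, 50 - 1e-9)
        out.append(
            CountryRecord(
                name=f"Country{i + 1:03d}",
                species_count=int(species[i]),
                land_area_km2=float(areas[i]),
                population=float(pops[i]),
                percent_tropical=float(pct),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSuite:
    catalog_path: Path
    series_path: Path
    countries_path: Path
    truth_path: Path
    catalog: TaxonomicCatalog
    series: DescriptionSeries
    countries: list[CountryRecord]
    truth: dict


def _date_catalog(
    catalog: TaxonomicCatalog, history: HistorySimConfig, rng
) -> TaxonomicCatalog:
    """Stamp description years (logistic draw) and countries onto a catalog."""
    from dataclasses import replace

    pool = ["BR", "US", "DE", "CD", "AU", "IN", "MG", "ZA", "MX", "VN"]
    records = []
    for r in catalog.records:
        u = rng.uniform(1e-9, 1 - 1e-9)
        year = int(np.floor(history.midpoint + history.scale * np.log(u / (1 - u))))
        year = min(max(year, history.start_year), history.end_year)
        if rng.random() < 0.05:  # ~5% undated records, as real catalogs have
            year = None
        n_c = rng.integers(0, 4)
        countries = tuple(sorted(rng.choice(pool, size=n_c, replace=False)))
        records.append(replace(r, year_described=year, countries=countries))
    return TaxonomicCatalog(
        records=tuple(records),
        class_name=catalog.class_name,
        metadata=dict(catalog.metadata),
    )


def make_fixture_suite(seed: int, outdir) -> FixtureSuite:
    """Write a deterministic bundle of small CSV fixtures plus a truth JSON.

    The bundle contains a dated catalog (with a few unplaced species so the
    placeholder rule is exercised), a description-history series with known
    true richness, and a country table — each in the exact dialect its
    consuming reader expects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cat_cfg = CatalogSimConfig(total_species=400, seed=int(rng.integers(2**31 - 1)))
    hist_for_dates = HistorySimConfig(true_richness=400, seed=None)
    catalog = _date_catalog(simulate_classification(cat_cfg), hist_for_dates, rng)
    # knock a few species out of their families to exercise placeholder logic
    from dataclasses import replace as _replace

    recs = list(catalog.records)
    unplaced_idx = rng.choice(len(recs), size=6, replace=False)
    for i in unplaced_idx:
        recs[i] = _replace(recs[i], family_name="")
    catalog = TaxonomicCatalog(
        records=tuple(recs), class_name=catalog.class_name, metadata=dict(catalog.metadata)
    )

    hist_cfg = HistorySimConfig(
        true_richness=2000,
        midpoint=1900.0,
        scale=30.0,
        era_effort=((1914, 1918, 0.3), (1939, 1945, 0.3)),
        seed=int(rng.integers(2**31 - 1)),
    )
    series, truth_hist = simulate_description_history(hist_cfg)

    geo_cfg = GeoSimConfig(n_countries=60, seed=int(rng.integers(2**31 - 1)))
    countries = simulate_geography(geo_cfg)

    catalog_path = outdir / "catalog.csv"
    series_path = outdir / "series.csv"
    countries_path = outdir / "countries.csv"
    truth_path = outdir / "truth.json"

    write_catalog(catalog, catalog_path)
    write_series_csv(series, series_path)
    with open(countries_path, "w", encoding="utf-8") as fh:
        fh.write("country,species,land_area_km2,population,percent_tropical\n")
        for c in countries:
            fh.write(
                f"{c.name},{c.species_count},{c.land_area_km2!r},"
                f"{c.population!r},{c.percent_tropical!r}\n"
            )
    truth = {
        "seed": seed,
        "catalog": {
            "n_species": len(catalog),
            "n_unplaced": int(len(unplaced_idx)),
            "fraction_small_genera": catalog.metadata["fraction_small_genera"],
        },
        "history": truth_hist,
        "geography": {"n_countries": len(countries)},
    }
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return FixtureSuite(
        catalog_path=catalog_path,
        series_path=series_path,
        countries_path=countries_path,
        truth_path=truth_path,
        catalog=catalog,
        series=series,
        countries=countries,
        truth=truth,
    )
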