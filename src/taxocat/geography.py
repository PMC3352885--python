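"""Country-level description-effort statistics.

Described richness per country is regressed on land area and on human
population, countries are stratified as tropical (≥50% of land area within
the tropics) versus nontropical, stratum means are compared with a Welch
two-sample t-test, and description densities (species per km² of stratum
land) are tabulated. Only countries with at least one described species are
admitted — a country absent from the catalog says nothing about its fauna,
only about effort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import stats

TROPICAL_CUTOFF = 50.0  # percent of land area within the tropics


@dataclass(frozen=True)
class CountryRecord:
    name: str
    species_count: int
    land_area_km2: float
    population: float
    percent_tropical: float

    def __post_init__(self) -> None:
        if self.species_count < 1:
            raise ValueError(
                f"{self.name}: only countries with ≥1 described species are admitted"
            )
        if self.land_area_km2 <= 0:
            raise ValueError(f"{self.name}: land area must be positive")
        if not 0 <= self.percent_tropical <= 100:
            raise ValueError(
                f"{self.name}: percent_tropical must be in [0, 100], "
                f"got {self.percent_tropical}"
            )


@dataclass(frozen=True)
class StratumSummary:
    n_countries: int
    species_total: int
    species_mean: float
    land_area_total: float
    species_per_km2: float


@dataclass(frozen=True)
class TropicalComparison:
    """Tropical vs nontropical strata with the Welch t-test on country means."""

    tropical: StratumSummary
    nontropical: StratumSummary
    t_statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class GeoRegressionFit:
    predictor: str
    stratum: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_countries: int
    excluded: tuple[str, ...] = ()


def classify_tropical(record: CountryRecord) -> str:
    """"tropical" iff at least half the country's land lies within the tropics."""
    if not 0 <= record.percent_tropical <= 100:
        raise ValueError("percent_tropical out of range")
    return "tropical" if record.percent_tropical >= TROPICAL_CUTOFF else "nontropical"


def _select(
    dataset: list[CountryRecord], stratum: str, exclude: tuple[str, ...]
) -> list[CountryRecord]:
    if exclude:
        known = {r.name for r in dataset}
        missing = [e for e in exclude if e not in known]
        if missing:
            raise ValueError(f"exclusions not in dataset: {', '.join(missing)}")
    kept = [r for r in dataset if r.name not in exclude]
    if stratum != "all":
        kept = [r for r in kept if classify_tropical(r) == stratum]
    return kept


def richness_regression(
    dataset: list[CountryRecord],
    predictor: str = "land_area",
    stratum: str = "all",
    exclude: tuple[str, ...] = (),
    log_predictor: bool = False,
) -> GeoRegressionFit:
    """OLS of described species count on land area or population.

    ``stratum`` restricts to tropical / nontropical countries; ``exclude``
    names countries dropped before fitting (every exclusion must exist in the
    dataset — nothing is dropped silently). Predictors are untransformed by
    default; ``log_predictor`` fits against the natural log instead.
    """
    attr = {"land_area": "land_area_km2", "population": "population"}.get(predictor)
    if attr is None:
        raise ValueError(f"unknown predictor {predictor!r}")
    kept = _select(dataset, stratum, exclude)
    if len(kept) < 3:
        raise ValueError(f"need ≥3 countries after filtering, have {len(kept)}")
    x = np.array([getattr(r, attr) for r in kept], dtype=float)
    if log_predictor:
        x = np.log(x)
    y = np.array([r.species_count for r in kept], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; r² undefined")
    fit = stats.linregress(x, y)
    return GeoRegressionFit(
        predictor=predictor + ("_log" if log_predictor else ""),
        stratum=stratum,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_countries=len(kept),
        excluded=tuple(exclude),
    )


def _summarize(records: list[CountryRecord]) -> StratumSummary:
    total = sum(r.species_count for r in records)
    area = sum(r.land_area_km2 for r in records)
    return StratumSummary(
        n_countries=len(records),
        species_total=total,
        species_mean=total / len(records),
        land_area_total=area,
        species_per_km2=total / area,
    )


def tropical_comparison(dataset: list[CountryRecord]) -> TropicalComparison:
    """Compare tropical and nontropical strata.

    Totals, per-country means and species-per-km² densities per stratum,
    plus the Welch unequal-variance t-test (with Welch–Satterthwaite df) on
    the per-country species counts.
    """
    trop = [r for r in dataset if classify_tropical(r) == "tropical"]
    nontrop = [r for r in dataset if classify_tropical(r) == "nontropical"]
    if not trop or not nontrop:
        raise ValueError("both strata must be non-empty")
    a = np.array([r.species_count for r in trop], dtype=float)
    b = np.array([r.species_count for r in nontrop], dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TropicalComparison(
        tropical=_summarize(trop),
        nontropical=_summarize(nontrop),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


COUNTRY_HEADER = ["country", "species", "land_area_km2", "population", "percent_tropical"]


def read_countries_csv(path) -> list[CountryRecord]:
    """Read ``country,species,land_area_km2,population,percent_tropical``."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != COUNTRY_HEADER:
            raise ValueError(f"{path}: expected header {','.join(COUNTRY_HEADER)}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    CountryRecord(
                        name=row["country"].strip(),
                        species_count=int(row["species"]),
                        land_area_km2=float(row["land_area_km2"]),
                        population=float(row["population"]),
                        percent_tropical=float(row["percent_tropical"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {i}: {exc}") from None
    return out


def write_comparison_tsv(comparison: TropicalComparison, path) -> None:
    rows = [
        ("n_countries", "{}", lambda s: s.n_countries),
        ("species_total", "{}", lambda s: s.species_total),
        ("species_mean", "{:.2f}", lambda s: s.species_mean),
        ("land_area_km2", "{:.1f}", lambda s: s.land_area_total),
        ("species_per_km2", "{:.4e}", lambda s: s.species_per_km2),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("quantity\ttropical\tnontropical\n")
        for name, fmt, get in rows:
            fh.write(
                f"{name}\t{fmt.format(get(comparison.tropical))}\t"
                f"{fmt.format(get(comparison.nontropical))}\n"
            )
        fh.write(f"welch_t\t{comparison.t_statistic:.4f}\t\n")
        fh.write(f"welch_df\t{comparison.df:.2f}\t\n")
        fh.write(f"welch_p\t{comparison.p_value:.4f}\t\n")
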