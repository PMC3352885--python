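"""Linnean catalog data model, validation, and rank summaries.

A catalog is a flat table of species records carrying the four classification
ranks actually used in millipede taxonomy (order, family, genus, species),
the year each species was described, and the countries it is recorded from.
Sub-ranks (subgenus, tribe, subfamily, ...) are deliberately rejected: they
are used too inconsistently across groups to support rank-based comparison.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

EARLIEST_YEAR = 1758  # Systema Naturae, 10th edition: the nomenclatural epoch

CATALOG_HEADER = ["class", "order", "family", "genus", "species", "year", "countries"]

#: header names that indicate sub-rank columns we refuse to consume
_SUBRANK_NAMES = frozenset(
    {"subspecies", "subgenus", "subfamily", "superfamily", "suborder", "tribe", "subtribe"}
)

PLACEHOLDER_PREFIX = "INCERTAE_SEDIS_"

COUNTRY_DELIMITER = ";"


class CatalogError(ValueError):
    """Raised for malformed catalog input or invariant violations."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One described species with its Linnean placement.

    ``family_name`` may be empty for species not yet assigned to a family
    (incertae sedis); :func:`assign_placeholders` resolves these before any
    tree-based analysis. ``year_described`` is ``None`` when the description
    year is unknown; such records still contribute to distinctness but are
    excluded from description-rate series.
    """

    order_name: str
    family_name: str
    genus_name: str
    species_epithet: str
    year_described: int | None = None
    countries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.order_name:
            raise CatalogError("order_name must be non-empty")
        if not self.genus_name:
            raise CatalogError("genus_name must be non-empty")
        if not self.species_epithet:
            raise CatalogError("species_epithet must be non-empty")
        if self.year_described is not None and self.year_described < EARLIEST_YEAR:
            raise CatalogError(
                f"year_described {self.year_described} predates {EARLIEST_YEAR}"
            )

    @property
    def path(self) -> tuple[str, str, str, str]:
        return (self.order_name, self.family_name, self.genus_name, self.species_epithet)

    @property
    def binomial(self) -> str:
        return f"{self.genus_name} {self.species_epithet}"


@dataclass(frozen=True)
class TaxonomicCatalog:
    """An immutable collection of :class:`SpeciesRecord` under one class."""

    records: tuple[SpeciesRecord, ...]
    class_name: str = "Diplopoda"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        dupes = [p for p, k in Counter(r.path for r in self.records).items() if k > 1]
        if dupes:
            shown = ", ".join("/".join(p) for p in sorted(dupes)[:5])
            raise CatalogError(f"duplicate species paths in catalog: {shown}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_unplaced(self) -> bool:
        return any(not r.family_name for r in self.records)


@dataclass(frozen=True)
class RankSummary:
    """Counts of distinct taxa per rank and the derived packing ratios.

    ``fraction_small_genera`` is the fraction of genera that are monotypic or
    contain only two species — the headline measure of taxonomic imbalance.
    Ratios are rounded to two decimals, matching how such tables are printed.
    """

    n_species: int
    n_genera: int
    n_families: int
    n_orders: int
    species_per_genus: float
    species_per_family: float
    fraction_small_genera: float


@dataclass(frozen=True)
class DescriptionSeries:
    """New species descriptions per calendar year, with cumulative totals.

    Years are consecutive; ``counts[i]`` is the number of species first
    described in ``years[i]`` and ``cumulative[i]`` the running total.
    """

    years: np.ndarray
    counts: np.ndarray
    n_missing_year: int = 0

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        if np.all(counts == np.floor(counts)):
            counts = counts.astype(int)  # keep integer dtype for real histograms
        if years.shape != counts.shape:
            raise ValueError("years and counts must have equal length")
        if len(years) and np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return len(self.years)


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def _parse_year(text: str, lineno: int) -> int | None:
    text = text.strip()
    if not text:
        return None
    try:
        year = int(text)
    except ValueError:
        raise CatalogError(f"line {lineno}: year {text!r} is not an integer") from None
    if year < EARLIEST_YEAR:
        raise CatalogError(f"line {lineno}: year {year} predates {EARLIEST_YEAR}")
    return year


def read_catalog(path, *, delimiter: str = ",") -> TaxonomicCatalog:
    """Read a catalog CSV with header ``class,order,family,genus,species,year,countries``.

    An empty family field marks an unplaced (incertae sedis) species; the
    countries field is ``;``-separated. Malformed rows and duplicate species
    paths raise :class:`CatalogError` naming the offending line.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_catalog_stream(fh, delimiter=delimiter, name=str(path))


def _read_catalog_stream(fh, *, delimiter: str, name: str) -> TaxonomicCatalog:
    reader = csv.reader(fh, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise CatalogError(f"{name}: empty file") from None
    header = [h.strip().lower() for h in header]
    subranks = sorted(set(header) & _SUBRANK_NAMES)
    if subranks:
        raise CatalogError(
            f"{name}: sub-rank columns not supported: {', '.join(subranks)}"
        )
    if header != CATALOG_HEADER:
        raise CatalogError(
            f"{name}: expected header {','.join(CATALOG_HEADER)}, got {','.join(header)}"
        )

    records: list[SpeciesRecord] = []
    class_names: set[str] = set()
    seen: dict[tuple, int] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(CATALOG_HEADER):
            raise CatalogError(
                f"line {lineno}: expected {len(CATALOG_HEADER)} fields, got {len(row)}"
            )
        cls, order, fam, gen, sp, year, countries = (c.strip() for c in row)
        try:
            rec = SpeciesRecord(
                order_name=order,
                family_name=fam,
                genus_name=gen,
                species_epithet=sp,
                year_described=_parse_year(year, lineno),
                countries=tuple(
                    c.strip() for c in countries.split(COUNTRY_DELIMITER) if c.strip()
                ),
            )
        except CatalogError as exc:
            raise CatalogError(f"line {lineno}: {exc}") from None
        if rec.path in seen:
            raise CatalogError(
                f"line {lineno}: duplicate species path {'/'.join(rec.path)} "
                f"(first seen on line {seen[rec.path]})"
            )
        seen[rec.path] = lineno
        class_names.add(cls)
        records.append(rec)

    class_name = class_names.pop() if len(class_names) == 1 else "Unknown"
    return TaxonomicCatalog(records=tuple(records), class_name=class_name)


def write_catalog(catalog: TaxonomicCatalog, path) -> None:
    """Write the catalog in the dialect :func:`read_catalog` consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_HEADER)
        for r in catalog.records:
            writer.writerow(
                [
                    catalog.class_name,
                    r.order_name,
                    r.family_name,
                    r.genus_name,
                    r.species_epithet,
                    "" if r.year_described is None else r.year_described,
                    COUNTRY_DELIMITER.join(r.countries),
                ]
            )


def catalog_to_csv_text(catalog: TaxonomicCatalog) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(CATALOG_HEADER)
    for r in catalog.records:
        writer.writerow(
            [
                catalog.class_name,
                r.order_name,
                r.family_name,
                r.genus_name,
                r.species_epithet,
                "" if r.year_described is None else r.year_described,
                COUNTRY_DELIMITER.join(r.countries),
            ]
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Placeholder families
# ---------------------------------------------------------------------------

def assign_placeholders(catalog: TaxonomicCatalog) -> TaxonomicCatalog:
    """Collect each order's family-less species into one placeholder family.

    The placeholder is namespaced per order (``INCERTAE_SEDIS_<order>``) so
    that unplaced species within an order are mutually confamilial. Pooling
    them into a single family deliberately *deflates* the average taxonomic
    distance relative to scattering them over artificial singleton families.
    """
    out = []
    for r in catalog.records:
        if r.family_name:
            out.append(r)
        else:
            out.append(replace(r, family_name=f"{PLACEHOLDER_PREFIX}{r.order_name}"))
    return TaxonomicCatalog(
        records=tuple(out), class_name=catalog.class_name, metadata=dict(catalog.metadata)
    )


# ---------------------------------------------------------------------------
# Rank summaries and description series
# ---------------------------------------------------------------------------

def summarize_ranks(catalog: TaxonomicCatalog) -> RankSummary:
    """Count distinct taxa per rank and the species-per-taxon ratios.

    Taxa are identified by their full path (a genus name reused in two
    families counts twice). Placeholder families count as families — that is
    the point of pooling unplaced species.
    """
    if not catalog.records:
        raise CatalogError("cannot summarize an empty catalog")
    orders = {r.order_name for r in catalog.records}
    families = {(r.order_name, r.family_name) for r in catalog.records}
    genus_sizes = Counter((r.order_name, r.family_name, r.genus_name) for r in catalog.records)
    n_species = len(catalog.records)
    n_genera = len(genus_sizes)
    small = sum(1 for n in genus_sizes.values() if n <= 2)
    return RankSummary(
        n_species=n_species,
        n_genera=n_genera,
        n_families=len(families),
        n_orders=len(orders),
        species_per_genus=round(n_species / n_genera, 2),
        species_per_family=round(n_species / len(families), 2),
        fraction_small_genera=small / n_genera,
    )


def description_series(
    catalog: TaxonomicCatalog, start_year: int, end_year: int
) -> DescriptionSeries:
    """Histogram of description years over [start_year, end_year].

    Years with no descriptions appear as explicit zeros. Records without a
    year (and records dated outside the window) are excluded and counted in
    ``n_missing_year``.
    """
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    years = np.arange(start_year, end_year + 1)
    counts = np.zeros(len(years), dtype=int)
    missing = 0
    for r in catalog.records:
        y = r.year_described
        if y is None or y < start_year or y > end_year:
            missing += 1
        else:
            counts[y - start_year] += 1
    return DescriptionSeries(years=years, counts=counts, n_missing_year=missing)
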