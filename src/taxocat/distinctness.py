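"""Average taxonomic distinctness (Δ+) from classification trees.

The Linnean hierarchy (class → order → family → genus → species) is read as a
rooted tree with four inter-rank steps. The distinctness weight ω between two
species is the path length climbed to their lowest shared taxon; Δ+ for a
group is the mean ω over all unordered species pairs. With four equal steps
scaled so the longest possible path is 100, congeners are 25 apart,
confamilial species 50, con-ordinal species 75, and species in different
orders 100.

Δ+ is a classification-based stand-in for phylodiversity: groups whose
species are spread over many higher taxa score high, groups whose species are
packed into few genera score low, independently of species number. Plotting
Δ+ against log10 richness and fitting a line gives a yardstick against which
related groups can be overlaid.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog import CatalogError, TaxonomicCatalog

DEFAULT_MAX_PATH = 100.0
RANK_STEPS = 4  # species→genus→family→order→root(class)


@dataclass(frozen=True)
class ClassificationTree:
    """A Linnean classification laid out as a rooted, rank-balanced tree.

    Every leaf is a species sitting at depth four below the class root. The
    tree is stored columnar (one row per species) because every quantity we
    need — node counts, pairwise ω, Δ+ — is a function of the rank paths,
    not of an explicit node structure.

    ``step_lengths`` holds the four inter-rank step lengths from the species
    level upward; they sum to ``max_path``, the distance between two species
    sharing no taxon below the class.
    """

    class_name: str
    orders: tuple[str, ...]
    families: tuple[str, ...]
    genera: tuple[str, ...]
    species: tuple[str, ...]
    step_lengths: tuple[float, float, float, float]
    max_path: float

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.step_lengths), self.max_path):
            raise ValueError("step lengths must sum to max_path")
        if any(s <= 0 for s in self.step_lengths):
            raise ValueError("step lengths must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_nodes(self) -> int:
        """Total node count: root + distinct taxa at each rank + leaves."""
        orders = set(self.orders)
        families = set(zip(self.orders, self.families))
        genera = set(zip(self.orders, self.families, self.genera))
        return 1 + len(orders) + len(families) + len(genera) + self.n_species

    @property
    def cumulative_distances(self) -> tuple[float, float, float, float]:
        """ω for pairs splitting at genus, family, order, and class level."""
        c = np.cumsum(self.step_lengths)
        return tuple(float(x) for x in c)

    def _group_mask(self, group: str) -> np.ndarray:
        if group == self.class_name:
            return np.ones(self.n_species, dtype=bool)
        mask = np.array([o == group for o in self.orders])
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
        return mask

    def leaf_index(self, binomial: str) -> int:
        matches = [
            i
            for i, (g, s) in enumerate(zip(self.genera, self.species))
            if f"{g} {s}" == binomial
        ]
        if not matches:
            raise KeyError(f"unknown species {binomial!r}")
        if len(matches) > 1:
            raise KeyError(f"ambiguous species name {binomial!r}")
        return matches[0]


@dataclass(frozen=True)
class DistinctnessResult:
    """Δ+ of one group together with its species richness."""

    group_name: str
    s: int
    delta_plus: float

    @property
    def log10_s(self) -> float:
        return math.log10(self.s)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of Δ+ on log10 species richness."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    excluded_groups: tuple[str, ...] = ()

    def predict(self, log10_s: float) -> float:
        return self.intercept + self.slope * log10_s


@dataclass(frozen=True)
class OverlayGroup:
    group_name: str
    s: int
    delta_plus: float
    predicted: float
    residual: float
    sign: str  # "above" | "on" | "below"


@dataclass(frozen=True)
class OverlayReport:
    """Groups placed against an existing fit without refitting it."""

    fit: RegressionFit
    groups: tuple[OverlayGroup, ...]
    on_tolerance: float

    @property
    def all_below_or_on(self) -> bool:
        return all(g.sign in ("below", "on") for g in self.groups)


# ---------------------------------------------------------------------------
# Tree construction and pairwise distances
# ---------------------------------------------------------------------------

def build_classification_tree(
    catalog: TaxonomicCatalog,
    max_path: float = DEFAULT_MAX_PATH,
    step_lengths: tuple[float, float, float, float] | None = None,
) -> ClassificationTree:
    """Translate a fully placed catalog into a classification tree.

    By default the four inter-rank steps are equal (each ``max_path / 4``).
    Passing explicit ``step_lengths`` enables variable steps (e.g.
    proportional to the drop in taxon counts between ranks); they are
    rescaled to sum to ``max_path``.
    """
    if not catalog.records:
        raise CatalogError("cannot build a tree from an empty catalog")
    if catalog.has_unplaced:
        raise CatalogError(
            "catalog has species without a family; run assign_placeholders first"
        )
    if max_path <= 0:
        raise ValueError("max_path must be positive")
    if step_lengths is None:
        steps = (max_path / RANK_STEPS,) * RANK_STEPS
    else:
        if len(step_lengths) != RANK_STEPS:
            raise ValueError(f"expected {RANK_STEPS} step lengths")
        total = sum(step_lengths)
        steps = tuple(s * max_path / total for s in step_lengths)
    recs = catalog.records
    return ClassificationTree(
        class_name=catalog.class_name,
        orders=tuple(r.order_name for r in recs),
        families=tuple(r.family_name for r in recs),
        genera=tuple(r.genus_name for r in recs),
        species=tuple(r.species_epithet for r in recs),
        step_lengths=steps,
        max_path=float(max_path),
    )


def pairwise_distance(tree: ClassificationTree, species_a: str, species_b: str) -> float:
    """Distinctness weight ω between two species, named by binomial.

    ω is the summed step length from the species level up to the lowest
    taxon the two share; identical species are at distance zero.
    """
    ia = tree.leaf_index(species_a)
    ib = tree.leaf_index(species_b)
    return _leaf_distance(tree, ia, ib)


def _leaf_distance(tree: ClassificationTree, ia: int, ib: int) -> float:
    if ia == ib:
        return 0.0
    d_genus, d_family, d_order, d_class = tree.cumulative_distances
    if tree.orders[ia] != tree.orders[ib]:
        return d_class
    if tree.families[ia] != tree.families[ib]:
        return d_order
    if tree.genera[ia] != tree.genera[ib]:
        return d_family
    if tree.species[ia] != tree.species[ib]:
        return d_genus
    return 0.0  # same path, distinct leaf slots cannot occur in a valid catalog


# ---------------------------------------------------------------------------
# Δ+
# ---------------------------------------------------------------------------

def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def taxonomic_distinctness(tree: ClassificationTree, group: str) -> DistinctnessResult:
    """Average taxonomic distinctness Δ+ of a group (an order, or the class).

    Δ+ = Σ_{i<j} ω_ij / (s(s−1)/2). Rather than enumerating the O(s²) pairs,
    pairs are binned by the rank at which they split, counted from the genus,
    family and order multiplicities. A singleton group has Δ+ = 0 by
    convention (there are no pairs to average).
    """
    mask = tree._group_mask(group)
    s = int(mask.sum())
    if s == 0:
        raise KeyError(f"group {group!r} contains no species")
    if s == 1:
        return DistinctnessResult(group_name=group, s=1, delta_plus=0.0)

    orders = [tree.orders[i] for i in np.flatnonzero(mask)]
    families = [
        (tree.orders[i], tree.families[i]) for i in np.flatnonzero(mask)
    ]
    genera = [
        (tree.orders[i], tree.families[i], tree.genera[i]) for i in np.flatnonzero(mask)
    ]
    pairs_total = _pairs(s)
    pairs_within_order = sum(_pairs(n) for n in Counter(orders).values())
    pairs_within_family = sum(_pairs(n) for n in Counter(families).values())
    pairs_within_genus = sum(_pairs(n) for n in Counter(genera).values())

    d_genus, d_family, d_order, d_class = tree.cumulative_distances
    total = (
        d_genus * pairs_within_genus
        + d_family * (pairs_within_family - pairs_within_genus)
        + d_order * (pairs_within_order - pairs_within_family)
        + d_class * (pairs_total - pairs_within_order)
    )
    return DistinctnessResult(group_name=group, s=s, delta_plus=total / pairs_total)


def distinctness_by_order(tree: ClassificationTree) -> list[DistinctnessResult]:
    """Δ+ for every order in the tree, in first-appearance order."""
    seen: list[str] = []
    for o in tree.orders:
        if o not in seen:
            seen.append(o)
    return [taxonomic_distinctness(tree, o) for o in seen]


# ---------------------------------------------------------------------------
# Regression and overlay
# ---------------------------------------------------------------------------

DEFAULT_MIN_SPECIES = 4  # drops groups too small for a meaningful Δ+
DEFAULT_ON_TOLERANCE = 0.5  # Δ+ units within which a point counts as "on" the line


def distinctness_regression(
    results: list[DistinctnessResult], min_species: int = DEFAULT_MIN_SPECIES
) -> RegressionFit:
    """OLS of Δ+ on log10 richness, excluding groups below ``min_species``.

    Returns the slope, intercept, r², and the two-sided p-value of the slope,
    along with the names of excluded groups.
    """
    used = [r for r in results if r.s >= min_species]
    excluded = tuple(r.group_name for r in results if r.s < min_species)
    if len(used) < 3:
        raise ValueError(
            f"need at least 3 groups with ≥{min_species} species; have {len(used)}"
        )
    x = np.array([r.log10_s for r in used])
    y = np.array([r.delta_plus for r in used])
    if np.ptp(x) == 0:
        raise ValueError("log richness has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_points=len(used),
        excluded_groups=excluded,
    )


def overlay_groups(
    fit: RegressionFit,
    extra: list[DistinctnessResult],
    on_tolerance: float = DEFAULT_ON_TOLERANCE,
) -> OverlayReport:
    """Place comparison groups against an existing fit without refitting.

    Each group's residual (observed Δ+ − predicted Δ+) is classified as
    "on" when |residual| ≤ ``on_tolerance``, else "above"/"below" by sign.
    The fit coefficients are untouched — overlays have no bearing on the line.
    """
    groups = []
    for r in extra:
        pred = fit.predict(r.log10_s)
        resid = r.delta_plus - pred
        if abs(resid) <= on_tolerance:
            sign = "on"
        else:
            sign = "above" if resid > 0 else "below"
        groups.append(
            OverlayGroup(
                group_name=r.group_name,
                s=r.s,
                delta_plus=r.delta_plus,
                predicted=pred,
                residual=resid,
                sign=sign,
            )
        )
    return OverlayReport(fit=fit, groups=tuple(groups), on_tolerance=on_tolerance)


# ---------------------------------------------------------------------------
# Pre-aggregated group tables (regression-only runs)
# ---------------------------------------------------------------------------

def read_groups_csv(path) -> list[DistinctnessResult]:
    """Read a pre-aggregated ``group,s,delta_plus`` table."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"group", "s", "delta_plus"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header group,s,delta_plus")
        for row in reader:
            out.append(
                DistinctnessResult(
                    group_name=row["group"],
                    s=int(row["s"]),
                    delta_plus=float(row["delta_plus"]),
                )
            )
    return out


def write_results_tsv(results: list[DistinctnessResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\ts\tdelta_plus\tlog10_s\n")
        for r in results:
            fh.write(f"{r.group_name}\t{r.s}\t{r.delta_plus:.4f}\t{r.log10_s:.4f}\n")
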