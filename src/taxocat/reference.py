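"""Bundled reference tabulations for millipedes and comparison arthropods.

Group-level summaries compiled from the published myriapod and arachnid
literature: per-order described-species counts with their average taxonomic
distinctness (Δ+ on the 0–100 scale), class-level rank counts, the
tropical/nontropical description-effort strata, and the reference-fauna
ratios used for global richness extrapolation. These tables let the
regression, overlay, and extrapolation stages be replayed without access to
the underlying specimen catalog, which is not publicly deposited.
"""

from __future__ import annotations

from .distinctness import DistinctnessResult

#: (order, described species, Δ+) for the millipede orders. The two orders
#: with fewer than four species (Siphoniulida, Siphonocryptida) are excluded
#: from the regression by the default min_species rule but are listed here.
DIPLOPOD_ORDERS: tuple[DistinctnessResult, ...] = tuple(
    DistinctnessResult(group_name=n, s=s, delta_plus=d)
    for n, s, d in [
        ("Polyxenida", 108, 82.81),
        ("Glomeridesmida", 32, 41.54),
        ("Glomerida", 283, 71.76),
        ("Sphaerotheriida", 332, 79.21),
        ("Platydesmida", 68, 76.76),
        ("Polyzoniida", 130, 62.9),
        ("Siphonophorida", 121, 45.72),
        ("Siphonocryptida", 3, 31.25),
        ("Siphoniulida", 2, 25.0),
        ("Julida", 1342, 88.1),
        ("Spirobolida", 1247, 89.0),
        ("Spirostreptida", 1906, 88.42),
        ("Chordeumatida", 1138, 96.7),
        ("Callipodida", 125, 85.07),
        ("Stemmiulida", 144, 56.0),
        ("Polydesmida", 5070, 96.26),
    ]
)

#: Centipede orders overlaid on the millipede fit. Craterostigmomorpha
#: (a single species, Δ+ = 0 by the singleton convention) is excluded from
#: overlays, as in the published comparison.
CHILOPOD_ORDERS: tuple[DistinctnessResult, ...] = tuple(
    DistinctnessResult(group_name=n, s=s, delta_plus=d)
    for n, s, d in [
        ("Scutigeromorpha", 206, 71.61),
        ("Lithobiomorpha", 1861, 60.89),
        ("Craterostigmomorpha", 1, 0.0),
        ("Scolopendromorpha", 1328, 78.3),
        ("Geophilomorpha", 1665, 90.53),
    ]
)

PSEUDOSCORPIONES = DistinctnessResult(
    group_name="Pseudoscorpiones", s=3432, delta_plus=95.62
)

#: class-level rank counts: (species, genera, families)
RANK_COUNTS: dict[str, tuple[int, int, int]] = {
    "Diplopoda": (12116, 3005, 146),
    "Araneae": (42055, 3821, 110),
    "Pseudoscorpiones": (3433, 443, 25),
    "Chilopoda": (5062, 401, 25),
}

#: tropical/nontropical strata: (species total, land area km²)
TROPICAL_STRATA: dict[str, tuple[int, float]] = {
    "tropical": (4743, 77_971_681.7),
    "nontropical": (5311, 42_630_129.9),
}

#: reference-fauna global:regional ratios for richness extrapolation
EXTRAPOLATION_RATIOS: dict[str, float] = {
    "avian_us": 11.07,
    "avian_europe": 11.98,
    "mammal_us": 12.47,
    "mammal_europe": 13.41,
}

#: described millipede richness of the reference regions
MILLIPEDE_RICHNESS_US = 1235
MILLIPEDE_RICHNESS_EUROPE = 1529


def diplopod_regression_inputs() -> list[DistinctnessResult]:
    """The millipede (Δ+, richness) points, small orders included.

    Feed to ``distinctness_regression`` with the default ``min_species`` to
    reproduce the published fit over 14 orders.
    """
    return list(DIPLOPOD_ORDERS)


def overlay_inputs() -> list[DistinctnessResult]:
    """Centipede orders (singleton excluded) plus the pseudoscorpions."""
    return [r for r in CHILOPOD_ORDERS if r.s > 1] + [PSEUDOSCORPIONES]
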