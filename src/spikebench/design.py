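"""Sample-design arithmetic for multispecies spike-in benchmarks.

A benchmark pair (Sample A, Sample B) is mixed from per-species digest
stocks at a common peptide concentration, in volumetric ratios such as
65:30:5 (A) vs 65:15:20 (B) for human:yeast:E. coli.  Because the stocks
share one concentration, the volumetric fraction of a species equals its
mass fraction, and the expected log2 fold change A/B of every protein of
that species is simply log2(fraction_A / fraction_B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "MixDesign",
    "expected_log2fc",
    "on_column_amounts",
    "stock_concentration",
    "read_mix_design",
    "block_randomized_order",
]

_FRACTION_TOL = 1e-9
MIN_SPECIES = 2
MAX_SPECIES = 4


@dataclass(frozen=True)
class MixDesign:
    """Volumetric mixing design of the two benchmark samples.

    Parameters
    ----------
    species_names
        Labels of the mixed species, e.g. ``["human", "yeast", "ecoli"]``.
        Between 2 and 4 species are supported.
    fraction_a, fraction_b
        Per-species volumetric fractions in Samples A and B.  May be given
        as ratios (e.g. ``[65, 30, 5]``); they are normalized to sum to 1.
    total_concentration
        Total peptide concentration of each mixed sample, in ug/uL.
    injection_volume
        Injected volume per run, in uL.
    stock_concentrations
        Optional per-species stock concentration override (ug/uL) for
        designs mixed from stocks of unequal concentration.  When given,
        mass fractions are re-derived from volume x concentration.  This
        is an extension beyond the equal-concentration design.
    """

    species_names: tuple[str, ...]
    fraction_a: tuple[float, ...]
    fraction_b: tuple[float, ...]
    total_concentration: float = 0.18
    injection_volume: float = 5.0
    stock_concentrations: tuple[float, ...] | None = field(default=None)

    def __init__(
        self,
        species_names: Sequence[str],
        fraction_a: Sequence[float],
        fraction_b: Sequence[float],
        total_concentration: float = 0.18,
        injection_volume: float = 5.0,
        stock_concentrations: Sequence[float] | None = None,
    ) -> None:
        names = tuple(str(s) for s in species_names)
        n = len(names)
        if not MIN_SPECIES <= n <= MAX_SPECIES:
            raise ValueError(
                f"a mix design requires {MIN_SPECIES}-{MAX_SPECIES} species, got {n}"
            )
        if len(set(names)) != n:
            raise ValueError("duplicate species names in design")
        if len(fraction_a) != n or len(fraction_b) != n:
            raise ValueError("fraction_a/fraction_b must have one entry per species")
        fa = _normalize_fractions(fraction_a, "fraction_a")
        fb = _normalize_fractions(fraction_b, "fraction_b")
        if stock_concentrations is not None:
            stocks = tuple(float(c) for c in stock_concentrations)
            if len(stocks) != n:
                raise ValueError("stock_concentrations must have one entry per species")
            if any(c <= 0 for c in stocks):
                raise ValueError("stock concentrations must be positive")
            # unequal stocks: convert volume fractions to mass fractions
            fa = _normalize_fractions([f * c for f, c in zip(fa, stocks)], "fraction_a")
            fb = _normalize_fractions([f * c for f, c in zip(fb, stocks)], "fraction_b")
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "fraction_a", fa)
        object.__setattr__(self, "fraction_b", fb)
        object.__setattr__(self, "total_concentration", float(total_concentration))
        object.__setattr__(self, "injection_volume", float(injection_volume))
        object.__setattr__(
            self,
            "stock_concentrations",
            None if stock_concentrations is None else tuple(map(float, stock_concentrations)),
        )

    def swapped(self) -> "MixDesign":
        """The same design with Samples A and B exchanged."""
        return MixDesign(
            self.species_names,
            self.fraction_b,
            self.fraction_a,
            self.total_concentration,
            self.injection_volume,
        )


def _normalize_fractions(values: Sequence[float], name: str) -> tuple[float, ...]:
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise ValueError(f"{name} contains negative values")
    total = sum(vals)
    if total <= 0:
        raise ValueError(f"{name} sums to zero")
    out = tuple(v / total for v in vals)
    assert abs(sum(out) - 1.0) < _FRACTION_TOL
    return out


def expected_log2fc(design: MixDesign) -> dict[str, float]:
    """Expected log2 fold change (A/B) per species.

    For the canonical 65:30:5 vs 65:15:20 human/yeast/E. coli design this
    is 0 for human, +1 for yeast and -2 for E. coli.

    Raises
    ------
    ValueError
        If a species present in Sample A has zero fraction in Sample B
        (infinite fold change is unsupported).
    """
    out: dict[str, float] = {}
    for name, fa, fb in zip(design.species_names, design.fraction_a, design.fraction_b):
        if fb == 0:
            if fa == 0:
                raise ValueError(f"species {name!r} absent from both samples")
            raise ValueError(
                f"species {name!r} has zero fraction in Sample B: "
                "infinite fold change unsupported"
            )
        out[name] = math.log2(fa / fb)
    return out


def on_column_amounts(design: MixDesign) -> dict[str, dict[str, float]]:
    """Per-species on-column mass (ng) per sample, plus the total load.

    Returns a mapping ``{"A": {species: ng, ...}, "B": {...},
    "total_ng": float}``.  Total load = concentration x injection volume;
    species loads are the total split by mass fraction.
    """
    if design.total_concentration <= 0:
        raise ValueError("total_concentration must be positive")
    if design.injection_volume <= 0:
        raise ValueError("injection_volume must be positive")
    total_ng = design.total_concentration * design.injection_volume * 1000.0
    return {
        "A": {s: total_ng * f for s, f in zip(design.species_names, design.fraction_a)},
        "B": {s: total_ng * f for s, f in zip(design.species_names, design.fraction_b)},
        "total_ng": total_ng,
    }


def stock_concentration(mass_ug: float, volume_uL: float) -> float:
    """Concentration (ug/uL) of ``mass_ug`` dissolved in ``volume_uL``."""
    if volume_uL <= 0:
        raise ValueError("volume must be positive")
    if mass_ug < 0:
        raise ValueError("mass must be non-negative")
    return mass_ug / volume_uL


def read_mix_design(path: str | Path) -> MixDesign:
    """Read a mix design from a small YAML or TSV file.

    YAML layout::

        species: [human, yeast, ecoli]
        fraction_a: [65, 30, 5]
        fraction_b: [65, 15, 20]
        total_concentration: 0.18
        injection_volume: 5

    TSV layout: columns ``species``, ``fraction_a``, ``fraction_b``; the
    scalars default to the canonical 0.18 ug/uL and 5 uL.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return MixDesign(
            data["species"],
            data["fraction_a"],
            data["fraction_b"],
            total_concentration=float(data.get("total_concentration", 0.18)),
            injection_volume=float(data.get("injection_volume", 5.0)),
        )
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    for col in ("species", "fraction_a", "fraction_b"):
        if col not in table.columns:
            raise ValueError(f"design file missing column {col!r}")
    return MixDesign(
        list(table["species"]),
        list(table["fraction_a"]),
        list(table["fraction_b"]),
    )


def block_randomized_order(
    run_ids_a: Sequence[str], run_ids_b: Sequence[str], seed: int = 0
) -> list[str]:
    """Convenience: a seeded block-randomized acquisition order.

    Each A/B pair forms a block whose internal order is shuffled; block
    order itself is fixed.  Utility only — not a validated randomization
    scheme.
    """
    import random

    if len(run_ids_a) != len(run_ids_b):
        raise ValueError("need equal numbers of A and B runs to form blocks")
    rng = random.Random(seed)
    order: list[str] = []
    for a, b in zip(run_ids_a, run_ids_b):
        block = [a, b]
        rng.shuffle(block)
        order.extend(block)
    return order
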