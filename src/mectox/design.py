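"""Exposure design: toxicant panel, mixture combinatorics, sample manifest.

The study design crosses every toxicant combination (singles, all binary,
ternary and the quaternary subset of a four-toxicant panel) with a small set
of volume ratios and an equivalent-concentration (EC) gradient {1,3,5,7,10},
where EC 10 means each component sits at its volume-fraction share of its
maximum stock concentration.  The manifest resolves every (setup, EC,
replicate) cell to per-component concentrations in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Toxicant",
    "ExposureSetup",
    "DEFAULT_PANEL",
    "DEFAULT_RATIOS",
    "DEFAULT_EC_LEVELS",
    "enumerate_setups",
    "expand_manifest",
    "component_ppm",
]

EC_DOMAIN = range(1, 11)
DEFAULT_EC_LEVELS = (1, 3, 5, 7, 10)

#: Default volume ratios per mixture order (number of components).
DEFAULT_RATIOS: dict[int, tuple[tuple[int, ...], ...]] = {
    1: ((1,),),
    2: ((1, 1), (2, 1), (1, 2)),
    3: ((1, 1, 1), (2, 1, 1), (1, 2, 1), (1, 1, 2)),
    4: ((1, 1, 1, 1), (2, 1, 1, 1), (1, 2, 1, 1), (1, 1, 2, 1), (1, 1, 1, 2)),
}


@dataclass(frozen=True)
class Toxicant:
    """A panel member: name plus maximum stock concentration (ppm)."""

    name: str
    c_max: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("toxicant name must be non-empty")
        if not self.c_max > 0:
            raise ValueError(f"c_max must be positive, got {self.c_max}")


#: The four-toxicant panel with its maximum stock concentrations.
DEFAULT_PANEL: tuple[Toxicant, ...] = (
    Toxicant("formaldehyde", 200.0),
    Toxicant("tetracycline", 5.0),
    Toxicant("silver_nitrate", 100.0),
    Toxicant("copper_sulfate", 100.0),
)


@dataclass(frozen=True)
class ExposureSetup:
    """One exposure condition: an ordered toxicant subset and its volume ratio."""

    setup_id: str
    components: tuple[str, ...]
    volume_ratio: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.volume_ratio):
            raise ValueError("ratio length must equal component count")
        if len(set(self.components)) != len(self.components):
            raise ValueError("setup components must be distinct")
        if any(v <= 0 for v in self.volume_ratio):
            raise ValueError("volume ratio entries must be positive integers")

    @property
    def order(self) -> int:
        return len(self.components)

    def volume_fractions(self) -> dict[str, float]:
        total = sum(self.volume_ratio)
        return {c: v / total for c, v in zip(self.components, self.volume_ratio)}


def _setup_id(components: Sequence[str], ratio: Sequence[int]) -> str:
    return "+".join(components) + "@" + ":".join(str(v) for v in ratio)


def enumerate_setups(
    panel: Sequence[Toxicant] = DEFAULT_PANEL,
    ratio_config: Mapping[int, Sequence[Sequence[int]]] | None = None,
) -> list[ExposureSetup]:
    """Enumerate every exposure setup of the mixture design.

    Singles come first, then binary, ternary, ... mixtures.  Within an order,
    setups are sorted lexicographically by component-name tuple, then by
    ratio tuple, so two calls always produce identical ordered output.

    With the default four-toxicant panel and default ratios this yields
    4 singles + 18 binary + 16 ternary + 5 quaternary = 43 setups.
    """
    if len(panel) < 1:
        raise ValueError("panel must contain at least one toxicant")
    names = [t.name for t in panel]
    if len(set(names)) != len(names):
        raise ValueError("panel toxicant names must be unique")
    if ratio_config is None:
        ratio_config = DEFAULT_RATIOS

    setups: list[ExposureSetup] = []
    for order in range(1, len(panel) + 1):
        ratios = [tuple(int(v) for v in r) for r in ratio_config.get(order, ())]
        if not ratios:
            continue
        combos = sorted(combinations(sorted(names), order))
        for combo in combos:
            for ratio in sorted(ratios):
                setups.append(ExposureSetup(_setup_id(combo, ratio), combo, ratio))
    return setups


def component_ppm(
    setup: ExposureSetup, panel: Sequence[Toxicant], ec_level: float
) -> dict[str, float]:
    """Per-component concentration (ppm) of a setup at one EC level.

    ppm_j = c_max_j * (v_j / sum(v)) * (ec / 10); toxicants absent from the
    setup get exactly 0.  The toxic-unit sum  sum_j ppm_j / c_max_j  then
    equals ec/10 for every setup, which is what makes the EC gradient a
    shared dose axis across mixtures.
    """
    cmax = {t.name: t.c_max for t in panel}
    unknown = set(setup.components) - set(cmax)
    if unknown:
        raise KeyError(f"setup components not in panel: {sorted(unknown)}")
    fracs = setup.volume_fractions()
    out = {name: 0.0 for name in cmax}
    for name in setup.components:
        out[name] = cmax[name] * fracs[name] * (ec_level / 10.0)
    return out


def expand_manifest(
    setups: Iterable[ExposureSetup],
    panel: Sequence[Toxicant] = DEFAULT_PANEL,
    ec_levels: Sequence[int] = DEFAULT_EC_LEVELS,
    n_replicates: int = 6,
) -> pd.DataFrame:
    """Expand setups × EC levels × replicates into the sample manifest.

    Returns a DataFrame with one row per physical sample: sample_id,
    setup_id, components, ratio, ec_level, replicate, and one ppm column
    per panel toxicant (``ppm_<name>``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ec_levels = list(ec_levels)
    for ec in ec_levels:
        if ec not in EC_DOMAIN:
            raise ValueError(f"ec_level {ec} outside {{1..10}}")

    rows = []
    for setup in setups:
        for ec in ec_levels:
            ppm = component_ppm(setup, panel, ec)
            for rep in range(1, n_replicates + 1):
                row = {
                    "sample_id": f"{setup.setup_id}|ec{ec}|r{rep}",
                    "setup_id": setup.setup_id,
                    "components": "+".join(setup.components),
                    "ratio": ":".join(str(v) for v in setup.volume_ratio),
                    "ec_level": ec,
                    "replicate": rep,
                }
                row.update({f"ppm_{k}": v for k, v in ppm.items()})
                rows.append(row)
    if not rows:
        cols = ["sample_id", "setup_id", "components", "ratio", "ec_level", "replicate"]
        cols += [f"ppm_{t.name}" for t in panel]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def panel_from_mapping(mapping: Mapping[str, float]) -> tuple[Toxicant, ...]:
    """Build a panel from a {name: c_max} mapping (e.g. parsed YAML)."""
    return tuple(Toxicant(str(k), float(v)) for k, v in mapping.items())
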