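"""Hierarchical threshold gating and per-population geometric MFI.

Gating assigns each event to the first population (in declared order) whose
conjunction of threshold gates it satisfies; events matching none are labeled
``"ungated"``.  Declaring the dead/viability gate first reproduces the
conventional live-gate-first strategy.  Geometric MFI — ``exp(mean(log x))``
over positive intensities — is the per-well summary the internalization
formulas (the P_n / Q_n terms) consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyPopulationError

__all__ = [
    "Gate",
    "PopulationGate",
    "GateConfig",
    "WellMeasurement",
    "apply_gates",
    "geometric_mfi",
    "geometric_mean",
    "well_measurements",
]

UNGATED = "ungated"


@dataclass(frozen=True)
class Gate:
    """One threshold gate: events pass if intensity is strictly above/below."""

    channel: str
    direction: str  # "above" | "below"
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ConfigurationError(f"gate direction must be above/below, got {self.direction!r}")

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        if self.channel not in events.columns:
            raise ConfigurationError(f"gate channel {self.channel!r} missing from event table")
        x = events[self.channel].to_numpy(dtype=float)
        return x > self.threshold if self.direction == "above" else x < self.threshold


@dataclass(frozen=True)
class PopulationGate:
    """A population defined as the conjunction of threshold gates."""

    name: str
    gates: tuple[Gate, ...]


@dataclass(frozen=True)
class GateConfig:
    """Ordered population definitions; order encodes the gating hierarchy."""

    populations: tuple[PopulationGate, ...] = ()

    @classmethod
    def from_dict(cls, spec: Mapping[str, Sequence[Mapping]]) -> "GateConfig":
        """Build from a mapping ``{population: [{channel, direction, threshold}, ...]}``.

        Insertion order of the mapping defines the hierarchy.
        """
        pops = tuple(
            PopulationGate(
                name,
                tuple(Gate(g["channel"], g["direction"], float(g["threshold"])) for g in gates),
            )
            for name, gates in spec.items()
        )
        return cls(pops)

    def to_dict(self) -> dict:
        return {
            p.name: [
                {"channel": g.channel, "direction": g.direction, "threshold": g.threshold}
                for g in p.gates
            ]
            for p in self.populations
        }

    def channels(self) -> set[str]:
        return {g.channel for p in self.populations for g in p.gates}

    def substitute_channel(self, old: str, new: str) -> "GateConfig":
        """Return a config with every gate on ``old`` moved to ``new``.

        Used when the test antibody occupies a phenotyping channel (e.g. an
        anti-CD19 sensor forces the B-cell gate onto a CD20 stain).
        """
        pops = tuple(
            PopulationGate(
                p.name,
                tuple(
                    replace(g, channel=new) if g.channel == old else g for g in p.gates
                ),
            )
            for p in self.populations
        )
        return GateConfig(pops)


@dataclass(frozen=True)
class WellMeasurement:
    """Geometric MFI of one (well, population) cell with its event counts.

    Whether the value plays the P_n (−quencher) or Q_n (+quencher) role is
    determined by the well's ``quencher`` metadata flag.
    """

    geo_mfi: float
    n_events: int
    n_excluded: int = 0
    population: str = ""
    channel: str = ""
    meta: Mapping = field(default_factory=dict)


def apply_gates(events: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Label every event with its population (or ``"ungated"``).

    Populations are evaluated in declared order and the first match wins, so
    the hierarchy is mutually exclusive by construction.  Returns a copy with
    a ``population`` column.
    """
    missing = config.channels() - set(events.columns)
    if missing:
        raise ConfigurationError(f"gate channels missing from event table: {sorted(missing)}")
    labels = np.full(len(events), UNGATED, dtype=object)
    unassigned = np.ones(len(events), dtype=bool)
    for pop in config.populations:
        mask = unassigned.copy()
        for gate in pop.gates:
            mask &= gate.mask(events)
        labels[mask] = pop.name
        unassigned &= ~mask
    out = events.copy()
    out["population"] = labels
    return out


def geometric_mean(x: np.ndarray) -> tuple[float, int]:
    """Geometric mean of the positive entries of ``x``; returns (gm, n_excluded)."""
    x = np.asarray(x, dtype=float)
    positive = x[x > 0]
    n_excluded = int(x.size - positive.size)
    if positive.size == 0:
        raise EmptyPopulationError("no positive intensities for geometric mean")
    return float(math.exp(np.mean(np.log(positive)))), n_excluded


def geometric_mfi(
    events: pd.DataFrame,
    population: str | None = None,
    channel: str = "Cy5",
    meta: Mapping | None = None,
) -> WellMeasurement:
    """Geometric MFI of ``channel`` over one population of an event table.

    Nonpositive intensities are excluded (not offset — offsets would distort
    the quench ratios); a warning is issued if more than 10% are dropped.
    """
    if population is not None:
        if "population" not in events.columns:
            raise ConfigurationError("event table has no 'population' column; run apply_gates")
        events = events[events["population"] == population]
    if channel not in events.columns:
        raise ConfigurationError(f"channel {channel!r} missing from event table")
    if len(events) == 0:
        raise EmptyPopulationError(f"no events in population {population!r}")
    gm, n_excluded = geometric_mean(events[channel].to_numpy())
    n_total = len(events)
    if n_excluded > 0.10 * n_total:
        warnings.warn(
            f"{n_excluded}/{n_total} nonpositive events excluded from geometric MFI "
            f"({population!r}, {channel!r})",
            stacklevel=2,
        )
    return WellMeasurement(
        geo_mfi=gm,
        n_events=n_total - n_excluded,
        n_excluded=n_excluded,
        population=population or "",
        channel=channel,
        meta=dict(meta or {}),
    )


def well_measurements(
    events: pd.DataFrame,
    channel: str = "Cy5",
    by: Iterable[str] = (
        "condition",
        "donor",
        "replicate",
        "timepoint_min",
        "temperature",
        "quencher",
        "population",
    ),
    drop_populations: Iterable[str] = (UNGATED, "dead"),
) -> pd.DataFrame:
    """Per-(well, population) geometric MFIs as a tidy DataFrame.

    Groups the gated event table by the ``by`` metadata columns, skipping the
    populations in ``drop_populations`` (debris/dead are never quantified).
    """
    by = [c for c in by if c in events.columns]
    drop = set(drop_populations)
    rows = []
    for keys, grp in events.groupby(by, sort=True, observed=True):
        meta = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        if meta.get("population") in drop:
            continue
        try:
            gm, n_excl = geometric_mean(grp[channel].to_numpy())
        except EmptyPopulationError:
            continue
        rows.append({**meta, "geo_mfi": gm, "n_events": len(grp) - n_excl, "n_excluded": n_excl})
    return pd.DataFrame(rows)
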