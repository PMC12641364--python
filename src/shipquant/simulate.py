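"""Synthetic assay generator: sensor assembly, gel lanes and event-level cytometry.

Every input the downstream pipeline consumes can be produced here with known
ground truth, so gating, quantification and statistics are all testable by
parameter recovery.  The cytometry model is deliberately phenomenological:

* each cell draws a bound-sensor count from a log-normal receptor-expression
  distribution (scaled by a per-donor log-normal effect),
* the internalized fraction follows first-order kinetics
  ``f(t) = f_max * (1 - exp(-k * t))`` at 37 °C and is zero at 4 °C,
* a membrane-impermeable quencher multiplies the *surface* part of the signal
  by the residual transmission ``1 - qe_true`` and leaves the internalized
  part untouched,
* the detector gain multiplies the whole optical signal (autofluorescence
  included), so ratio statistics are exactly gain-invariant,
* phenotyping channels and autofluorescence are log-normal per population,
  and all intensities carry multiplicative log-normal measurement noise.

Spillover/compensation, doublets and receptor recycling are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError

__all__ = [
    "AssemblyParams",
    "ReceptorKinetics",
    "PopulationSpec",
    "ReceptorSpec",
    "AssayDesign",
    "LaneProfile",
    "SENSOR_CHANNEL",
    "PHENO_CHANNELS",
    "METADATA_COLUMNS",
    "simulate_assembly",
    "simulate_gel_lane",
    "simulate_cytometry",
    "ground_truth",
]

#: Sensor (Cy5-like) fluorescence channel name used throughout.
SENSOR_CHANNEL = "Cy5"

#: Default phenotyping + viability channels (mirrors a CD4/CD8/B panel:
#: CD19-BV421, CD4-BV510, CD8-BV785, TCR-PE, viability dye).
PHENO_CHANNELS = ("BV421", "BV510", "BV785", "PE", "Viability")

#: Metadata columns attached to every event row.  ``true_population`` is the
#: simulator's hidden ground-truth label, retained for testing only.
METADATA_COLUMNS = (
    "condition",
    "donor",
    "replicate",
    "timepoint_min",
    "temperature",
    "quencher",
    "true_population",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class AssemblyParams:
    """One-pot staple/DNA/mAb assembly mixture.

    The staple (DNA-binding protein fused to an anti-Fc nanobody), the Cy5
    fluorescent internalization probe DNA and the mouse IgG1 antibody are
    mixed at a 1:1:1 molar ratio; each staple independently captures a mAb
    with probability ``p_capture_mab`` and a DNA with ``p_capture_dna``.
    """

    staple_conc: float = 1.0
    dna_conc: float = 1.0
    mab_conc: float = 1.0
    p_capture_mab: float = 0.98
    p_capture_dna: float = 0.33

    def __post_init__(self) -> None:
        for name in ("staple_conc", "dna_conc", "mab_conc"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        _check_prob("p_capture_mab", self.p_capture_mab)
        _check_prob("p_capture_dna", self.p_capture_dna)


@dataclass(frozen=True)
class ReceptorKinetics:
    """First-order internalization kinetics: ``f(t) = f_max*(1 - exp(-k t))``.

    Parameters
    ----------
    f_max : plateau of the internalized fraction, in [0, 1].
    k : rate constant in 1/min, >= 0.
    """

    f_max: float
    k: float

    def __post_init__(self) -> None:
        _check_prob("f_max", self.f_max)
        if self.k < 0:
            raise ParameterError("k must be >= 0")

    def fraction_internalized(self, t_min: float) -> float:
        """Internalized fraction of bound sensor after ``t_min`` minutes at 37 °C."""
        if t_min < 0:
            raise ParameterError("time must be >= 0")
        return self.f_max * (1.0 - math.exp(-self.k * t_min))


@dataclass(frozen=True)
class PopulationSpec:
    """One cell subpopulation of the simulated PBMC mixture.

    ``phenotype_means`` maps channel name -> geometric mean of that channel's
    log-normal intensity for this population (so dead cells are given a high
    viability-dye mean).  ``autofluor_mean`` is the geometric mean of the
    sensor-channel autofluorescence; 0 disables it.
    """

    name: str
    fraction: float
    phenotype_means: Mapping[str, float]
    autofluor_mean: float = 0.0
    phenotype_gsd: float = 2.0

    def __post_init__(self) -> None:
        _check_prob("fraction", self.fraction)
        if self.phenotype_gsd <= 1.0:
            raise ParameterError("phenotype_gsd must be > 1")
        if self.autofluor_mean < 0:
            raise ParameterError("autofluor_mean must be >= 0")


@dataclass(frozen=True)
class ReceptorSpec:
    """Target receptor / antibody condition for the simulator.

    ``expression_gm`` maps population name -> geometric mean bound-sensor
    signal on that population (0 or missing = the antibody does not bind that
    population specifically).  ``nonspecific_gm`` is the isotype-level
    background, either a scalar or a per-population mapping.
    """

    name: str
    expression_gm: Mapping[str, float]
    kinetics: ReceptorKinetics
    expression_gsd: float = 2.0
    nonspecific_gm: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if self.expression_gsd <= 1.0:
            raise ParameterError("expression_gsd must be > 1")
        for pop, gm in self.expression_gm.items():
            if gm < 0:
                raise ParameterError(f"expression_gm[{pop!r}] must be >= 0")

    def nonspecific_for(self, population: str) -> float:
        if isinstance(self.nonspecific_gm, Mapping):
            return float(self.nonspecific_gm.get(population, 0.0))
        return float(self.nonspecific_gm)


@dataclass(frozen=True)
class AssayDesign:
    """Well layout and instrument/assay-level parameters.

    Each 37 °C timepoint gets a ±quencher well pair; a 4 °C pair at the
    longest timepoint provides the no-internalization quenching-efficiency
    control.  ``qe_true`` is the ground-truth quenching efficiency: quenched
    surface signal retains ``1 - qe_true`` of its value.
    """

    timepoints: tuple[float, ...] = (30.0, 240.0)
    temperatures: tuple[str, ...] = ("37C", "4C")
    quencher_arms: tuple[str, ...] = ("minus", "plus")
    qe_true: float = 0.97
    n_events: int = 5000
    n_tech: int = 3
    n_donors: int = 1
    donor_gsd: float = 1.4
    noise_gsd: float = 1.05
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("qe_true", self.qe_true)
        if not self.timepoints or any(t < 0 for t in self.timepoints):
            raise DesignError("timepoints must be nonempty and >= 0")
        if self.n_events < 1 or self.n_tech < 1 or self.n_donors < 1:
            raise DesignError("n_events, n_tech and n_donors must be >= 1")
        if self.donor_gsd < 1.0 or self.noise_gsd < 1.0:
            raise DesignError("donor_gsd and noise_gsd must be >= 1")
        if self.gain <= 0:
            raise DesignError("gain must be > 0")
        bad = set(self.temperatures) - {"37C", "4C"}
        if bad:
            raise DesignError(f"unknown temperatures: {sorted(bad)}")
        bad = set(self.quencher_arms) - {"minus", "plus"}
        if bad:
            raise DesignError(f"unknown quencher arms: {sorted(bad)}")

    def wells(self):
        """Yield (timepoint, temperature, quencher_flag) for every well arm.

        4 °C wells are placed only at the longest timepoint, matching the
        bench protocol (the 4 °C control is run for the longest incubation).
        """
        t_max = max(self.timepoints)
        for temp in self.temperatures:
            tps = self.timepoints if temp == "37C" else (t_max,)
            for t in tps:
                for arm in self.quencher_arms:
                    yield t, temp, arm == "plus"


@dataclass(frozen=True)
class LaneProfile:
    """A 1-D gel-lane intensity trace with named band windows.

    ``band_windows`` maps band name -> half-open index interval [start, stop).
    """

    positions: np.ndarray
    intensity: np.ndarray
    band_windows: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensity):
            raise DesignError("positions and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise DesignError("lane intensity must be nonnegative")
        spans = sorted(self.band_windows.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise DesignError("band windows must be disjoint")
        n = len(self.positions)
        for name, (start, stop) in self.band_windows.items():
            if not (0 <= start < stop <= n):
                raise DesignError(f"band {name!r} window [{start}, {stop}) outside trace")


def simulate_assembly(
    params: AssemblyParams, n_staples: int, seed: int | np.random.Generator = 0
) -> dict[str, float]:
    """Monte-Carlo draw of the one-pot assembly outcome.

    Each of ``n_staples`` staples independently captures a mAb with
    ``p_capture_mab`` and a FIP-DNA with ``p_capture_dna``.  Returns the
    fractions of staples carrying a mAb, a DNA, both (``frac_full_sensor``,
    i.e. functional sensors), and the fraction of mAb-bearing staples that are
    fluorescently labeled.
    """
    if n_staples < 1:
        raise ParameterError("n_staples must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    has_mab = rng.random(n_staples) < params.p_capture_mab
    has_dna = rng.random(n_staples) < params.p_capture_dna
    full = has_mab & has_dna
    n_mab = int(has_mab.sum())
    return {
        "frac_with_mab": n_mab / n_staples,
        "frac_with_dna": float(has_dna.mean()),
        "frac_full_sensor": float(full.mean()),
        "labeled_fraction_of_captured_mab": (int(full.sum()) / n_mab) if n_mab else float("nan"),
    }


def simulate_gel_lane(
    band_fractions: Mapping[str, float],
    total_area: float = 1000.0,
    band_centers: Mapping[str, float] | None = None,
    band_widths: Mapping[str, float] | float = 5.0,
    length: int = 120,
    noise_sd: float = 0.0,
    window_halfwidth: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> LaneProfile:
    """Simulate a 1-D gel-lane trace with Gaussian bands for densitometry.

    Each named band is a Gaussian bump of area ``fraction * total_area`` at its
    center with standard deviation ``band_widths``; additive baseline noise of
    standard deviation ``noise_sd`` is applied and the trace is clipped at 0.
    Band windows span ``center ± window_halfwidth * width``.
    """
    fractions = dict(band_fractions)
    if not fractions:
        raise DesignError("at least one band is required")
    if any(f < 0 for f in fractions.values()):
        raise ParameterError("band fractions must be >= 0")
    if abs(sum(fractions.values()) - 1.0) > 1e-8:
        raise DesignError("band fractions must sum to 1")
    if total_area <= 0:
        raise ParameterError("total_area must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    if band_centers is None:
        # evenly spaced defaults
        step = length / (len(fractions) + 1)
        band_centers = {name: step * (i + 1) for i, name in enumerate(fractions)}
    if not isinstance(band_widths, Mapping):
        band_widths = {name: float(band_widths) for name in fractions}

    positions = np.arange(length)
    intensity = np.zeros(length, dtype=float)
    windows: dict[str, tuple[int, int]] = {}
    for name, frac in fractions.items():
        center = float(band_centers[name])
        width = float(band_widths[name])
        if width <= 0:
            raise ParameterError(f"band {name!r} width must be > 0")
        lo = center - window_halfwidth * width
        hi = center + window_halfwidth * width
        if lo < 0 or hi > length:
            raise DesignError(f"band {name!r} does not fit inside the trace")
        intensity += (
            frac
            * total_area
            / (width * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((positions - center) / width) ** 2)
        )
        windows[name] = (int(math.floor(lo)), int(math.ceil(hi)))

    spans = sorted(windows.values())
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise DesignError("band windows overlap; move centers apart")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=length)
    return LaneProfile(positions, np.clip(intensity, 0.0, None), windows)


def _lognormal(rng: np.random.Generator, gm: float, gsd: float, n: int) -> np.ndarray:
    """Log-normal draws with geometric mean ``gm`` and geometric SD ``gsd``."""
    if gm <= 0:
        return np.zeros(n)
    return rng.lognormal(math.log(gm), math.log(gsd), size=n)


def simulate_cytometry(
    design: AssayDesign,
    populations: Sequence[PopulationSpec],
    receptors: Sequence[ReceptorSpec],
    labeled_fraction: float = 1.0,
    dol: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an event table for every well of ``design`` x ``receptors``.

    For each event: a population is drawn by its fraction; the bound-sensor
    count is the sum of a specific log-normal component (expression_gm,
    expression_gsd, scaled by a per-donor log-normal factor) and a
    nonspecific isotype-level component; the sensor-channel signal is::

        autofluorescence + gain * dol * labeled_fraction * N * (f + (1-f)*T)

    with internalized fraction ``f = f(t)`` at 37 °C (0 at 4 °C) and quencher
    transmission ``T = 1`` (−quencher) or ``1 - qe_true`` (+quencher), times
    multiplicative log-normal noise.  Phenotyping channels are drawn per
    population.  Returns one long DataFrame with channel + metadata columns;
    identical ``seed`` implies an identical table.
    """
    if not populations:
        raise ParameterError("at least one population is required")
    if not receptors:
        raise ParameterError("at least one receptor is required")
    if dol <= 0:
        raise ParameterError("dol must be > 0")
    _check_prob("labeled_fraction", labeled_fraction)
    fractions = np.array([p.fraction for p in populations], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise DesignError("population fractions must sum to 1")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    # Donor effects are drawn once, up front, so the donor panel is stable
    # across receptors within a run.
    donor_factors = {
        f"D{i + 1}": (
            rng.lognormal(0.0, math.log(design.donor_gsd)) if design.donor_gsd > 1 else 1.0
        )
        for i in range(design.n_donors)
    }

    channels = set()
    for pop in populations:
        channels.update(pop.phenotype_means)
    pheno_channels = [c for c in PHENO_CHANNELS if c in channels]
    pheno_channels += sorted(channels - set(pheno_channels))

    wells = list(design.wells())
    frames: list[pd.DataFrame] = []
    sigma_noise = math.log(design.noise_gsd) if design.noise_gsd > 1 else 0.0
    for receptor in receptors:
        for donor, dfac in donor_factors.items():
            for rep in range(1, design.n_tech + 1):
                for t, temp, quenched in wells:
                    n = design.n_events
                    pop_idx = rng.choice(len(populations), size=n, p=fractions)
                    cols: dict[str, np.ndarray] = {}
                    sensor = np.zeros(n)
                    f = (
                        receptor.kinetics.fraction_internalized(t)
                        if temp == "37C"
                        else 0.0
                    )
                    transmission = (1.0 - design.qe_true) if quenched else 1.0
                    arm_factor = f + (1.0 - f) * transmission
                    scale = dol * labeled_fraction * arm_factor
                    for i, pop in enumerate(populations):
                        mask = pop_idx == i
                        m = int(mask.sum())
                        if m == 0:
                            continue
                        bound = _lognormal(
                            rng,
                            receptor.expression_gm.get(pop.name, 0.0) * dfac,
                            receptor.expression_gsd,
                            m,
                        )
                        bound = bound + _lognormal(
                            rng,
                            receptor.nonspecific_for(pop.name) * dfac,
                            receptor.expression_gsd,
                            m,
                        )
                        autofl = _lognormal(rng, pop.autofluor_mean, pop.phenotype_gsd, m)
                        sensor[mask] = autofl + scale * bound
                    noise = (
                        rng.lognormal(0.0, sigma_noise, size=n) if sigma_noise else 1.0
                    )
                    # detector gain is a detector-stage factor: it multiplies
                    # the whole optical signal, autofluorescence included, so
                    # ratio statistics are exactly gain-invariant
                    cols[SENSOR_CHANNEL] = design.gain * sensor * noise
                    for ch in pheno_channels:
                        vals = np.zeros(n)
                        for i, pop in enumerate(populations):
                            mask = pop_idx == i
                            m = int(mask.sum())
                            if m:
                                vals[mask] = _lognormal(
                                    rng, pop.phenotype_means.get(ch, 0.0), pop.phenotype_gsd, m
                                )
                        cols[ch] = vals
                    frame = pd.DataFrame(cols)
                    frame["condition"] = receptor.name
                    frame["donor"] = donor
                    frame["replicate"] = rep
                    frame["timepoint_min"] = float(t)
                    frame["temperature"] = temp
                    frame["quencher"] = quenched
                    frame["true_population"] = pd.Categorical(
                        [populations[i].name for i in pop_idx]
                    )
                    frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["true_population"] = out["true_population"].astype(str)
    return out


def ground_truth(
    design: AssayDesign,
    populations: Sequence[PopulationSpec],
    receptors: Sequence[ReceptorSpec],
) -> dict:
    """Ground-truth sidecar for a simulation: true f(t), qe_true, fractions."""
    return {
        "qe_true": design.qe_true,
        "population_fractions": {p.name: p.fraction for p in populations},
        "internalized_fraction": {
            r.name: {str(t): r.kinetics.fraction_internalized(t) for t in design.timepoints}
            for r in receptors
        },
    }
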