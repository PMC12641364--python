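"""Assay quantification: DOL, quenching efficiency, internalization %, uptake,
isotype-gated eligibility and gel densitometry.

The central quantity is the receptor internalization efficiency.  With P the
geometric MFI of the −quencher well, Q that of the matched +quencher well and
q_eff the quenching efficiency measured on a 4 °C (no-internalization)
control pair, the surface-bound signal is estimated as S = (P − Q) / q_eff
and the internalized fraction as::

    %internalized = (1 - (P - Q) / (P * q_eff)) * 100
    q_eff         = 1 - Q(4°C) / P(4°C)

This pair is exact under the quencher model (the quencher multiplies surface
signal by 1 − q_eff and leaves internalized signal untouched): a pure-surface
well gives 0%, a fully internalized one 100%, and feeding the model's exact
expectations returns the true internalized fraction identically.  Raw
(unclamped) values are kept alongside the clamped ones for diagnostics.

MFIs are divided by the antibody's degree of labeling (DOL, dyes per
protein, from absorbance spectra) before cross-antibody comparison;
internalization is a ratio and is DOL- and gain-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    InsufficientReplicatesError,
    InvalidMeasurementError,
    InvalidSpectrumError,
    ParameterError,
)
from .simulate import LaneProfile

__all__ = [
    "DolInputs",
    "QuenchPair",
    "QuenchEfficiency",
    "InternalizationEstimate",
    "EligibilityResult",
    "InternalizationResult",
    "degree_of_labeling",
    "normalize_by_dol",
    "quench_efficiency",
    "internalization_percent",
    "uptake",
    "association",
    "eligibility",
    "densitometry_fraction",
]

#: Empirical 280-nm correction factor for the Cy5-labeled probe DNA.
CY5_FIP_CF = 0.55


@dataclass(frozen=True)
class DolInputs:
    """Absorbance inputs for the degree-of-labeling computation.

    ``a_dye`` is the absorbance at the dye maximum (649 nm for Cy5), ``a280``
    the conjugate absorbance at 280 nm, ``eps_*`` the molar extinction
    coefficients (M^-1 cm^-1) and ``cf`` the empirical correction factor for
    the dye's own 280-nm absorbance (≈0.55 for the Cy5 probe).
    """

    a_dye: float
    a280: float
    eps_dye: float
    eps_protein: float
    cf: float = CY5_FIP_CF

    def __post_init__(self) -> None:
        if self.a_dye < 0 or self.a280 < 0:
            raise ParameterError("absorbances must be >= 0")
        if self.eps_dye <= 0 or self.eps_protein <= 0:
            raise ParameterError("extinction coefficients must be > 0")
        if self.cf < 0:
            raise ParameterError("correction factor must be >= 0")


def degree_of_labeling(inputs: DolInputs) -> float:
    """Average dyes per protein: ``A_dye * eps_protein / (eps_dye * (A280 - CF*A_dye))``."""
    corrected = inputs.a280 - inputs.cf * inputs.a_dye
    if corrected <= 0:
        raise InvalidSpectrumError(
            "corrected protein absorbance A280 - CF*A_dye must be > 0 "
            f"(got {corrected:.4g})"
        )
    return inputs.a_dye * inputs.eps_protein / (inputs.eps_dye * corrected)


def normalize_by_dol(mfi: float, dol: float) -> float:
    """Divide an MFI by the degree of labeling for cross-antibody comparison."""
    if dol <= 0:
        raise ParameterError(f"dol must be > 0, got {dol!r}")
    return mfi / dol


@dataclass(frozen=True)
class QuenchPair:
    """Matched ±quencher geometric MFIs of one well pair.

    ``p`` is the −quencher well (P_n), ``q`` the +quencher well (Q_n); both
    halves of one sample, sharing donor/replicate/condition metadata.
    """

    p: float
    q: float
    temperature: str = "37C"
    timepoint_min: float = 0.0
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise InvalidMeasurementError("unquenched geometric MFI P must be > 0")
        if self.q < 0:
            raise InvalidMeasurementError("quenched geometric MFI Q must be >= 0")


@dataclass(frozen=True)
class QuenchEfficiency:
    """Quenching efficiency with its raw (unclamped) residual ratio for audit."""

    q_eff: float
    residual_ratio: float  # Q/P at 4 °C, may exceed 1 under noise

    def __float__(self) -> float:
        return self.q_eff


def quench_efficiency(pair_4c: QuenchPair) -> QuenchEfficiency:
    """Quenching efficiency from a 4 °C control pair: ``q_eff = 1 - Q/P``.

    At 4 °C no internalization occurs, so all bound sensor sits on the
    surface and the ±quencher ratio isolates the quencher's effect.  The
    result is clamped to [0, 1]; the raw ratio Q/P is retained.
    """
    if pair_4c.temperature != "4C":
        raise InvalidMeasurementError(
            f"quenching efficiency requires a 4C pair, got {pair_4c.temperature!r}"
        )
    ratio = pair_4c.q / pair_4c.p
    return QuenchEfficiency(q_eff=min(max(1.0 - ratio, 0.0), 1.0), residual_ratio=ratio)


@dataclass(frozen=True)
class InternalizationEstimate:
    """Clamped internalization percentage plus the raw value for diagnostics."""

    pct: float
    raw_pct: float

    def __float__(self) -> float:
        return self.pct


def internalization_percent(
    pair_37c: QuenchPair, q_eff: float | QuenchEfficiency
) -> InternalizationEstimate:
    """Internalization % from a 37 °C ±quencher pair and a quenching efficiency.

    Surface estimate S = (P − Q)/q_eff; internalized fraction 1 − S/P; the
    percentage is clamped to [0, 100] (noise can push the raw value outside).
    """
    qe = float(q_eff)
    if qe <= 0:
        raise InvalidMeasurementError(
            "q_eff must be > 0: the quencher had no measurable effect; "
            "check the 4 °C control pair"
        )
    if qe > 1:
        raise ParameterError(f"q_eff must be <= 1, got {qe!r}")
    raw = (1.0 - (pair_37c.p - pair_37c.q) / (pair_37c.p * qe)) * 100.0
    return InternalizationEstimate(pct=min(max(raw, 0.0), 100.0), raw_pct=raw)


def uptake(pair_37c: QuenchPair, dol: float = 1.0) -> float:
    """Absolute internalized signal: the +quencher geometric MFI, DOL-normalized."""
    return normalize_by_dol(pair_37c.q, dol)


def association(pair_37c: QuenchPair, dol: float = 1.0) -> float:
    """Total cell-bound signal: the −quencher geometric MFI, DOL-normalized."""
    return normalize_by_dol(pair_37c.p, dol)


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    p_adjusted: float
    mean_association: float
    mean_isotype: float


def eligibility(
    association_per_donor: Sequence[float],
    isotype_per_donor: Sequence[float],
    alpha: float = 0.05,
    other_groups: Sequence[Sequence[float]] | None = None,
    log_scale: bool = True,
) -> EligibilityResult:
    """Decide whether a receptor's association clears the isotype background.

    Internalization is a ratio of uptake to association, so low-association
    antibodies amplify noise; a receptor is eligible only if its mean
    association exceeds the isotype control's and the Dunnett-adjusted
    many-to-one p-value is below ``alpha``.  ``other_groups`` supplies the
    associations of the remaining panel antibodies so the familywise
    adjustment reflects the whole screen; with none, the family has size one
    and the test reduces to an unpaired t-test.

    By default the test runs on log10 associations: geometric MFIs are
    log-scale quantities, and the pooled-variance many-to-one model is badly
    mis-calibrated on raw MFIs when panel antibodies span orders of magnitude
    (a genuine 10x-over-background signal would drown in the donor spread of
    a 1000x-over-background antibody).
    """
    a = np.asarray(association_per_donor, dtype=float)
    iso = np.asarray(isotype_per_donor, dtype=float)
    if a.size < 2 or iso.size < 2:
        raise InsufficientReplicatesError(
            "eligibility requires >= 2 donors (or replicates) per group"
        )
    from .stats import dunnett_raw

    groups = [a] + [np.asarray(g, dtype=float) for g in (other_groups or [])]
    if log_scale:
        if any((g <= 0).any() for g in groups) or (iso <= 0).any():
            raise ParameterError("log-scale eligibility requires positive MFIs")
        p_adj = dunnett_raw([np.log10(g) for g in groups], np.log10(iso))[0]
    else:
        p_adj = dunnett_raw(groups, iso)[0]
    eligible = bool(a.mean() > iso.mean() and p_adj < alpha)
    return EligibilityResult(
        eligible=eligible,
        p_adjusted=float(p_adj),
        mean_association=float(a.mean()),
        mean_isotype=float(iso.mean()),
    )


@dataclass(frozen=True)
class InternalizationResult:
    """Per (receptor, population, timepoint) summary over donors.

    ``internalization_pct``/``sd`` are means over donor means of technical
    replicates; ``None`` when the receptor is ineligible (rendered as "#").
    """

    receptor: str
    population: str
    timepoint_min: float
    q_eff: float
    association: float
    association_sd: float
    uptake: float
    uptake_sd: float
    eligible: bool
    p_adjusted: float
    internalization_pct: float | None
    internalization_sd: float | None
    n_donors: int


def densitometry_fraction(lane: LaneProfile, band: str) -> float:
    """Percentage of a gel lane's signal inside one named band window.

    The baseline is the median intensity outside all declared band windows;
    it is subtracted, negatives are clipped to zero, and the band integral is
    ratioed to the whole-lane integral.
    """
    if band not in lane.band_windows:
        raise ParameterError(
            f"unknown band {band!r}; declared: {sorted(lane.band_windows)}"
        )
    outside = np.ones(len(lane.intensity), dtype=bool)
    for start, stop in lane.band_windows.values():
        outside[start:stop] = False
    baseline = float(np.median(lane.intensity[outside])) if outside.any() else 0.0
    corrected = np.clip(lane.intensity - baseline, 0.0, None)
    total = float(corrected.sum())
    if total <= 0:
        raise InvalidMeasurementError("total lane signal above baseline is <= 0")
    start, stop = lane.band_windows[band]
    return 100.0 * float(corrected[start:stop].sum()) / total
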