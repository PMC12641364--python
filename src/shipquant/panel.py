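"""Shipped presets: PBMC population mixture, gating hierarchy and the
13-antibody lymphocyte screening panel.

The panel covers T-cell receptors (CD2, CD3, CD4, CD5, CD7, CD8a), B-cell
receptors (CD19, CD20, CD22), shared markers (CD27, CD38) and pan-lymphocyte
markers (CD44, CD45), plus the mIgG1 isotype control that defines the
nonspecific background.  Expression magnitudes are calibrated to typical
DOL-normalized geometric MFIs of primary human PBMC screens (e.g. CD45 and
CD44 tens of thousands, CD19 ≈1.5e3 on B cells, isotype background ≈1e1 on
T cells and ≈1.5e2 on B cells); kinetics reproduce the qualitative classes:
fast/efficient (CD3, CD7, CD22), slow/inefficient (CD4, CD8a, CD44, CD45)
and intermediate (CD2, CD5, CD19, CD20, CD27, CD38).
"""

from __future__ import annotations

from dataclasses import dataclass

from .gating import GateConfig
from .simulate import PopulationSpec, ReceptorKinetics, ReceptorSpec

__all__ = [
    "AntibodySpec",
    "default_populations",
    "default_gate_config",
    "preset_panel",
    "ISOTYPE_NAME",
    "tfr_demo_receptor",
]

ISOTYPE_NAME = "mIgG1"

# Phenotyping channel roles in the default simulated panel:
#   BV421 = CD19 (B cells), BV510 = CD4, BV785 = CD8, PE = TCR, Viability = dead-cell dye.
_POS, _NEG = 8000.0, 150.0
_VIAB_LIVE, _VIAB_DEAD = 100.0, 10000.0
_AUTOFLUOR = 5.0


def default_populations() -> list[PopulationSpec]:
    """CD4 T / CD8 T / B / dead mixture with well-separated phenotype means."""
    return [
        PopulationSpec(
            "CD4T",
            0.38,
            {"BV421": _NEG, "BV510": _POS, "BV785": _NEG, "PE": _POS, "Viability": _VIAB_LIVE},
            autofluor_mean=_AUTOFLUOR,
        ),
        PopulationSpec(
            "CD8T",
            0.27,
            {"BV421": _NEG, "BV510": _NEG, "BV785": _POS, "PE": _POS, "Viability": _VIAB_LIVE},
            autofluor_mean=_AUTOFLUOR,
        ),
        PopulationSpec(
            "B",
            0.20,
            {"BV421": _POS, "BV510": _NEG, "BV785": _NEG, "PE": _NEG, "Viability": _VIAB_LIVE},
            autofluor_mean=_AUTOFLUOR,
        ),
        PopulationSpec(
            "dead",
            0.15,
            {"BV421": _NEG, "BV510": _NEG, "BV785": _NEG, "PE": _NEG, "Viability": _VIAB_DEAD},
            autofluor_mean=_AUTOFLUOR,
        ),
    ]


def default_gate_config() -> GateConfig:
    """Viability-first hierarchy: dead → TCR± split → CD4/CD8 → B (CD19+)."""
    thr = 1000.0
    return GateConfig.from_dict(
        {
            "dead": [{"channel": "Viability", "direction": "above", "threshold": thr}],
            "CD4T": [
                {"channel": "PE", "direction": "above", "threshold": thr},
                {"channel": "BV510", "direction": "above", "threshold": thr},
            ],
            "CD8T": [
                {"channel": "PE", "direction": "above", "threshold": thr},
                {"channel": "BV785", "direction": "above", "threshold": thr},
            ],
            "B": [
                {"channel": "PE", "direction": "below", "threshold": thr},
                {"channel": "BV421", "direction": "above", "threshold": thr},
            ],
        }
    )


@dataclass(frozen=True)
class AntibodySpec:
    """One panel entry: the receptor model, its DOL and the isotype flag."""

    receptor: ReceptorSpec
    dol: float = 1.0
    isotype: bool = False

    @property
    def name(self) -> str:
        return self.receptor.name


_T_BACKGROUND = {"CD4T": 18.0, "CD8T": 13.0, "B": 151.0}


def _receptor(name, expr, f_max, k, nonspecific=_T_BACKGROUND):
    return ReceptorSpec(
        name=name,
        expression_gm=expr,
        kinetics=ReceptorKinetics(f_max=f_max, k=k),
        nonspecific_gm=nonspecific,
    )


def preset_panel() -> list[AntibodySpec]:
    """The 13-antibody lymphocyte screen plus the mIgG1 isotype control."""
    specs = [
        _receptor("CD2", {"CD4T": 8700, "CD8T": 11300}, 0.25, 0.010),
        _receptor("CD3", {"CD4T": 13000, "CD8T": 14400}, 0.95, 0.0125),
        _receptor("CD4", {"CD4T": 15000}, 0.30, 0.0025),
        _receptor("CD5", {"CD4T": 11700, "CD8T": 13900}, 0.72, 0.006),
        _receptor("CD7", {"CD4T": 9000, "CD8T": 9000}, 0.62, 0.033),
        _receptor("CD8a", {"CD8T": 16000}, 0.30, 0.0025),
        _receptor("CD19", {"B": 1540}, 0.55, 0.008),
        _receptor("CD20", {"B": 12700}, 0.17, 0.010),
        _receptor("CD22", {"B": 23300}, 0.908, 0.0162),
        _receptor("CD27", {"CD4T": 4900, "CD8T": 4500, "B": 1200}, 0.30, 0.010),
        _receptor("CD38", {"CD4T": 890, "CD8T": 410, "B": 1500}, 0.30, 0.010),
        _receptor("CD44", {"CD4T": 22000, "CD8T": 22000, "B": 31300}, 0.04, 0.010),
        _receptor("CD45", {"CD4T": 62000, "CD8T": 62000, "B": 53900}, 0.10, 0.010),
    ]
    panel = [AntibodySpec(r) for r in specs]
    panel.append(
        AntibodySpec(
            _receptor(ISOTYPE_NAME, {}, 0.0, 0.0),
            isotype=True,
        )
    )
    return panel


def tfr_demo_receptor() -> ReceptorSpec:
    """Transferrin-receptor-like demo condition: high expression, fast turnover."""
    return _receptor(
        "TfR",
        {"CD4T": 5700, "CD8T": 5700, "B": 5700},
        f_max=0.90,
        k=0.0435,
        nonspecific=5.0,
    )
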