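"""End-to-end orchestration: simulate → gate → quantify → test → report.

A :class:`RunConfig` (built in code or from a YAML mapping) describes the
simulated assay: well design, population mixture, gating hierarchy and the
antibody panel with per-antibody DOL.  :func:`run` executes the pipeline
deterministically for a given master seed and writes tidy CSV reports, a
ground-truth sidecar and summary plots.  Ineligible receptors (association
not significantly above the mIgG1 isotype control) carry a ``"#"`` marker
and no internalization value.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import gating, quantify, stats
from .errors import ConfigurationError
from .gating import GateConfig
from .panel import (
    AntibodySpec,
    default_gate_config,
    default_populations,
    preset_panel,
)
from .quantify import DolInputs, degree_of_labeling
from .simulate import (
    SENSOR_CHANNEL,
    AssayDesign,
    PopulationSpec,
    ReceptorKinetics,
    ReceptorSpec,
    ground_truth,
    simulate_cytometry,
)

__all__ = ["RunConfig", "RunReport", "validate", "run", "quantify_measurements"]

INELIGIBLE_MARKER = "#"


@dataclass
class RunConfig:
    """Full description of one simulated screening run."""

    timepoints: tuple[float, ...] = (30.0, 240.0)
    n_events: int = 5000
    n_tech: int = 3
    n_donors: int = 3
    qe_true: float = 0.97
    donor_gsd: float = 1.4
    noise_gsd: float = 1.05
    gain: float = 1.0
    labeled_fraction: float = 0.33
    seed: int = 0
    alpha: float = 0.05
    stats_mode: str = "donor-means"
    quencher_arms: tuple[str, ...] = ("minus", "plus")
    temperatures: tuple[str, ...] = ("37C", "4C")
    # assay metadata carried into reports (not used by the math)
    quencher_nM: float = 500.0
    sensor_nM: float = 10.0
    # when the test antibody is anti-CD19 the B gate moves to another channel
    cd19_substitution: tuple[str, str] | None = None
    panel: list[AntibodySpec] = field(default_factory=preset_panel)
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    gates: GateConfig = field(default_factory=default_gate_config)

    def design(self) -> AssayDesign:
        return AssayDesign(
            timepoints=tuple(float(t) for t in self.timepoints),
            temperatures=tuple(self.temperatures),
            quencher_arms=tuple(self.quencher_arms),
            qe_true=self.qe_true,
            n_events=self.n_events,
            n_tech=self.n_tech,
            n_donors=self.n_donors,
            donor_gsd=self.donor_gsd,
            noise_gsd=self.noise_gsd,
            gain=self.gain,
            seed=self.seed,
        )

    def dols(self) -> dict[str, float]:
        return {ab.name: ab.dol for ab in self.panel}

    def isotype_name(self) -> str:
        names = [ab.name for ab in self.panel if ab.isotype]
        if len(names) != 1:
            raise ConfigurationError(f"panel must declare exactly one isotype, got {names}")
        return names[0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML mapping.

        Unspecified keys fall back to the shipped defaults (preset panel,
        default populations and gates).  A panel entry looks like::

            panel:
              - name: CD22
                expression_gm: {B: 23300}
                f_max: 0.908
                k: 0.0162
                nonspecific_gm: {CD4T: 18, CD8T: 13, B: 151}
                dol_inputs: {a_dye: 0.25, a280: 0.5, eps_dye: 250000, eps_protein: 210000}
              - name: mIgG1
                isotype: true
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        simple = (
            "timepoints n_events n_tech n_donors qe_true donor_gsd noise_gsd gain "
            "labeled_fraction seed alpha stats_mode quencher_nM sensor_nM"
        ).split()
        for key in simple:
            if key in raw:
                kwargs[key] = raw[key]
        if "timepoints" in kwargs:
            kwargs["timepoints"] = tuple(float(t) for t in kwargs["timepoints"])
        for key in ("quencher_arms", "temperatures"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "cd19_substitution" in raw and raw["cd19_substitution"]:
            kwargs["cd19_substitution"] = tuple(raw["cd19_substitution"])
        if "populations" in raw:
            kwargs["populations"] = [
                PopulationSpec(
                    name=p["name"],
                    fraction=float(p["fraction"]),
                    phenotype_means={k: float(v) for k, v in p["phenotype_means"].items()},
                    autofluor_mean=float(p.get("autofluor_mean", 0.0)),
                    phenotype_gsd=float(p.get("phenotype_gsd", 2.0)),
                )
                for p in raw["populations"]
            ]
        if "gates" in raw:
            kwargs["gates"] = GateConfig.from_dict(raw["gates"])
        if "panel" in raw:
            kwargs["panel"] = [_antibody_from_dict(entry) for entry in raw["panel"]]
        return cls(**kwargs)


def _antibody_from_dict(entry: Mapping) -> AntibodySpec:
    if "dol_inputs" in entry:
        dol = degree_of_labeling(DolInputs(**entry["dol_inputs"]))
    else:
        dol = float(entry.get("dol", 1.0))
    receptor = ReceptorSpec(
        name=entry["name"],
        expression_gm={k: float(v) for k, v in entry.get("expression_gm", {}).items()},
        kinetics=ReceptorKinetics(
            f_max=float(entry.get("f_max", 0.0)), k=float(entry.get("k", 0.0))
        ),
        expression_gsd=float(entry.get("expression_gsd", 2.0)),
        nonspecific_gm=entry.get("nonspecific_gm", 0.0),
    )
    return AntibodySpec(receptor=receptor, dol=dol, isotype=bool(entry.get("isotype", False)))


def validate(config: RunConfig) -> list[str]:
    """Return configuration violations; an empty list means :func:`run` can proceed."""
    violations: list[str] = []
    isotypes = [ab.name for ab in config.panel if ab.isotype]
    if len(isotypes) == 0:
        violations.append("panel declares no isotype control")
    elif len(isotypes) > 1:
        violations.append(f"panel declares multiple isotype controls: {isotypes}")
    if not config.timepoints:
        violations.append("no timepoints declared")
    if not (0.0 <= config.qe_true <= 1.0):
        violations.append("qe_true must be in [0, 1]")
    design = None
    try:
        design = config.design()
    except Exception as exc:  # surfaced as a violation, not a crash
        violations.append(f"invalid design: {exc}")
    if design is not None:
        arms = set(design.quencher_arms)
        if arms != {"minus", "plus"}:
            violations.append(
                "every 37C condition needs a ±quencher pair (both arms required)"
            )
        if "4C" not in design.temperatures:
            violations.append("a 4C control pair is required for quenching efficiency")
    fractions = sum(p.fraction for p in config.populations)
    if abs(fractions - 1.0) > 1e-8:
        violations.append(f"population fractions sum to {fractions}, not 1")
    names = [ab.name for ab in config.panel]
    if len(names) != len(set(names)):
        violations.append("duplicate antibody names in panel")
    if config.stats_mode not in ("donor-means", "per-donor-mean-p"):
        violations.append(f"unknown stats mode {config.stats_mode!r}")
    return violations


@dataclass
class RunReport:
    """Outputs of one pipeline run."""

    summary: pd.DataFrame
    per_replicate: pd.DataFrame
    stats: pd.DataFrame
    gate_report: pd.DataFrame
    seed: int
    config_hash: str
    paths: dict[str, str] = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def quantify_measurements(
    measurements: pd.DataFrame,
    dols: Mapping[str, float],
    isotype: str,
    t_ref: float,
    alpha: float = 0.05,
    stats_mode: str = "donor-means",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Quench-correct and summarize per-(well, population) geometric MFIs.

    ``measurements`` is the tidy output of :func:`shipquant.gating.well_measurements`.
    Per (condition, population, donor, replicate): the 4 °C pair at ``t_ref``
    gives q_eff (replicate q_effs averaged within donor); each 37 °C ±quencher
    pair gives association P/DOL, uptake Q/DOL and the internalization
    percentage computed with the donor's q_eff.  Technical replicates are then
    averaged within donor, and donors summarized as mean ± SD.  Eligibility is
    decided per (population, timepoint) by a Dunnett many-to-one test of
    donor-mean associations against the isotype control.

    Returns ``(per_replicate, summary, stats_table)``.
    """
    rep_rows: list[dict] = []
    meas = measurements.copy()
    meas["timepoint_min"] = meas["timepoint_min"].astype(float)

    keys = ["condition", "population", "donor"]
    for (cond, pop, donor), grp in meas.groupby(keys, sort=True, observed=True):
        dol = float(dols.get(cond, 1.0))
        # quenching efficiency from the 4C pair at the reference timepoint
        q_effs = []
        cold = grp[(grp["temperature"] == "4C") & (grp["timepoint_min"] == t_ref)]
        for rep, rep_grp in cold.groupby("replicate"):
            p_row = rep_grp[~rep_grp["quencher"]]
            q_row = rep_grp[rep_grp["quencher"]]
            if len(p_row) == 1 and len(q_row) == 1:
                pair = quantify.QuenchPair(
                    p=float(p_row["geo_mfi"].iloc[0]),
                    q=float(q_row["geo_mfi"].iloc[0]),
                    temperature="4C",
                    timepoint_min=t_ref,
                )
                q_effs.append(quantify.quench_efficiency(pair).q_eff)
        donor_q_eff = float(np.mean(q_effs)) if q_effs else float("nan")

        warm = grp[grp["temperature"] == "37C"]
        for (t, rep), rep_grp in warm.groupby(["timepoint_min", "replicate"]):
            p_row = rep_grp[~rep_grp["quencher"]]
            q_row = rep_grp[rep_grp["quencher"]]
            if len(p_row) != 1 or len(q_row) != 1:
                continue
            pair = quantify.QuenchPair(
                p=float(p_row["geo_mfi"].iloc[0]),
                q=float(q_row["geo_mfi"].iloc[0]),
                temperature="37C",
                timepoint_min=float(t),
            )
            if np.isfinite(donor_q_eff) and donor_q_eff > 0:
                est = quantify.internalization_percent(pair, donor_q_eff)
                pct, raw = est.pct, est.raw_pct
            else:
                pct = raw = float("nan")
            rep_rows.append(
                {
                    "condition": cond,
                    "population": pop,
                    "donor": donor,
                    "replicate": rep,
                    "timepoint_min": float(t),
                    "q_eff": donor_q_eff,
                    "association": quantify.association(pair, dol),
                    "uptake": quantify.uptake(pair, dol),
                    "internalization_pct": pct,
                    "internalization_raw_pct": raw,
                    "n_events": int(p_row["n_events"].iloc[0] + q_row["n_events"].iloc[0]),
                }
            )

    per_replicate = pd.DataFrame(rep_rows)
    if per_replicate.empty:
        raise ConfigurationError("no complete ±quencher well pairs found")

    # donor means of technical replicates
    donor_means = (
        per_replicate.groupby(["condition", "population", "timepoint_min", "donor"])
        .agg(
            association=("association", "mean"),
            uptake=("uptake", "mean"),
            internalization_pct=("internalization_pct", "mean"),
            q_eff=("q_eff", "mean"),
            n_events=("n_events", "sum"),
        )
        .reset_index()
    )

    # eligibility + stats per (population, timepoint), Dunnett vs isotype
    stats_rows: list[dict] = []
    eligibility: dict[tuple[str, str, float], tuple[bool, float]] = {}
    for (pop, t), grp in donor_means.groupby(["population", "timepoint_min"]):
        # geometric MFIs are log-scale quantities: the many-to-one test runs
        # on log10 associations so low- and high-expression antibodies share
        # a common variance scale (see shipquant.quantify.eligibility)
        tidy = grp.rename(columns={"condition": "group"})[["group", "donor"]].assign(
            value=np.log10(grp["association"].to_numpy())
        )
        if isotype not in set(tidy["group"]):
            continue
        enough = tidy.groupby("group").size().min() >= 2
        if not enough or tidy["group"].nunique() < 2:
            for cond in tidy["group"].unique():
                if cond != isotype:
                    eligibility[(cond, pop, t)] = (True, float("nan"))
            continue
        results = stats.dunnett(tidy, control=isotype, mode=stats_mode)
        iso_mean = tidy.loc[tidy["group"] == isotype, "value"].mean()
        for res in results:
            cond = res.comparison.split(" vs ")[0]
            cond_mean = tidy.loc[tidy["group"] == cond, "value"].mean()
            eligible = bool(cond_mean > iso_mean and res.p_adjusted < alpha)
            eligibility[(cond, pop, t)] = (eligible, res.p_adjusted)
            stats_rows.append(
                {
                    "population": pop,
                    "timepoint_min": t,
                    "comparison": res.comparison,
                    "mean_log10_ratio": res.statistic,
                    "p_adjusted": res.p_adjusted,
                    "stars": res.stars,
                    "mode": res.mode,
                    "eligible": eligible,
                }
            )

    # across-donor summary
    sum_rows: list[dict] = []
    for (cond, pop, t), grp in donor_means.groupby(
        ["condition", "population", "timepoint_min"]
    ):
        n = len(grp)
        eligible, p_adj = eligibility.get((cond, pop, t), (cond != isotype, float("nan")))
        if cond == isotype:
            eligible = False
        pct = float(grp["internalization_pct"].mean())
        pct_sd = float(grp["internalization_pct"].std(ddof=1)) if n > 1 else float("nan")
        sum_rows.append(
            {
                "condition": cond,
                "population": pop,
                "timepoint_min": t,
                "q_eff": float(grp["q_eff"].mean()),
                "association": float(grp["association"].mean()),
                "association_sd": float(grp["association"].std(ddof=1)) if n > 1 else float("nan"),
                "uptake": float(grp["uptake"].mean()),
                "uptake_sd": float(grp["uptake"].std(ddof=1)) if n > 1 else float("nan"),
                "eligible": eligible,
                "p_adjusted": p_adj,
                "internalization_pct": pct if eligible else float("nan"),
                "internalization_sd": pct_sd if eligible else float("nan"),
                "marker": "" if eligible else INELIGIBLE_MARKER,
                "n_donors": n,
            }
        )
    summary = pd.DataFrame(sum_rows)
    return per_replicate, summary, pd.DataFrame(stats_rows)


def _gate_events(events: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Apply the gate hierarchy per condition, honoring the CD19 substitution."""
    frames = []
    for cond, grp in events.groupby("condition", sort=True):
        gates = config.gates
        if config.cd19_substitution and "cd19" in str(cond).lower():
            gates = gates.substitute_channel(*config.cd19_substitution)
        frames.append(gating.apply_gates(grp, gates))
    return pd.concat(frames, ignore_index=True)


def _plots(summary: pd.DataFrame, outdir: Path) -> dict[str, str]:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    paths = {}
    t_max = summary["timepoint_min"].max()
    end = summary[summary["timepoint_min"] == t_max]

    def bar(metric: str, fname: str, title: str) -> None:
        fig = Figure(figsize=(9, 4))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        pops = sorted(end["population"].unique())
        conds = sorted(end["condition"].unique())
        width = 0.8 / max(len(pops), 1)
        x = np.arange(len(conds))
        for i, pop in enumerate(pops):
            sub = end[end["population"] == pop].set_index("condition")
            vals = [sub[metric].get(c, np.nan) for c in conds]
            errs = [sub.get(metric + "_sd", pd.Series()).get(c, np.nan) for c in conds]
            ax.bar(x + i * width, vals, width=width, yerr=errs, capsize=2, label=pop)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(conds, rotation=60, ha="right")
        ax.set_ylabel(f"{metric} (geo. MFI / DOL)")
        ax.set_title(title)
        ax.set_yscale("log")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        paths[fname] = str(outdir / fname)

    bar("association", "association.png", f"Cell association at {t_max:g} min")
    bar("uptake", "uptake.png", f"Uptake (+quencher MFI) at {t_max:g} min")

    fig = Figure(figsize=(7, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for (cond, pop), grp in summary.groupby(["condition", "population"]):
        if grp["internalization_pct"].notna().any():
            grp = grp.sort_values("timepoint_min")
            ax.errorbar(
                grp["timepoint_min"],
                grp["internalization_pct"],
                yerr=grp["internalization_sd"],
                marker="o",
                capsize=2,
                label=f"{cond}/{pop}",
            )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("internalization (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "internalization_vs_time.png", dpi=120)
    paths["internalization_vs_time.png"] = str(outdir / "internalization_vs_time.png")
    return paths


def run(
    config: RunConfig,
    outdir: str | Path,
    write_event_files: bool = False,
    make_plots: bool = True,
) -> RunReport:
    """Execute the full pipeline; deterministic for a given config + seed."""
    problems = validate(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = config.design()
    receptors = [ab.receptor for ab in config.panel]
    events = simulate_cytometry(
        design,
        config.populations,
        receptors,
        labeled_fraction=config.labeled_fraction,
        dol=1.0,
    )
    # per-antibody DOL scales the raw fluorescence; normalization divides it
    # back out during quantification
    dols = config.dols()
    scale = events["condition"].map(dols).astype(float)
    events[SENSOR_CHANNEL] = events[SENSOR_CHANNEL] * scale

    if write_event_files:
        events.to_csv(outdir / "events.csv", index=False)

    gated = _gate_events(events, config)
    gate_report = (
        gated.groupby(
            ["condition", "donor", "replicate", "timepoint_min", "temperature", "quencher"]
        )["population"]
        .value_counts()
        .unstack(fill_value=0)
        .reset_index()
    )

    measurements = gating.well_measurements(gated, channel=SENSOR_CHANNEL)
    per_replicate, summary, stats_table = quantify_measurements(
        measurements,
        dols=dols,
        isotype=config.isotype_name(),
        t_ref=max(config.timepoints),
        alpha=config.alpha,
        stats_mode=config.stats_mode,
    )

    paths: dict[str, str] = {}
    for name, frame in (
        ("gate_report.csv", gate_report),
        ("quantification.csv", per_replicate),
        ("summary.csv", summary),
        ("stats.csv", stats_table),
    ):
        frame.to_csv(outdir / name, index=False)
        paths[name] = str(outdir / name)

    truth = ground_truth(design, config.populations, receptors)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    paths["ground_truth.json"] = str(outdir / "ground_truth.json")

    cfg_hash = _config_hash(config)
    meta = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_events_simulated": int(len(events)),
        "quencher_nM": config.quencher_nM,
        "sensor_nM": config.sensor_nM,
        "stats_mode": config.stats_mode,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    paths["run_metadata.json"] = str(outdir / "run_metadata.json")

    if make_plots:
        paths.update(_plots(summary, outdir))

    return RunReport(
        summary=summary,
        per_replicate=per_replicate,
        stats=stats_table,
        gate_report=gate_report,
        seed=config.seed,
        config_hash=cfg_hash,
        paths=paths,
    )
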