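"""End-to-end orchestration: simulate → DE → qPCR → reconcile → network.

The pipeline runs the full study workflow on synthetic data with
planted ground truth: two-color arrays are simulated and taken
through background correction, normalization and DE calling; the
selected miRNAs are re-measured by simulated qPCR and reconciled with
the array calls; the reconciled directions feed the miRNA–target
network, whose degree-≥3 hub targets get a predicted direction of
mRNA change; finally the hub genes themselves are measured by
simulated ΔΔCp qPCR and scored for concordance with the prediction.

Every stage writes its output table (TSV with a config-hash header
comment) before the next stage starts, and the run report summarizes
counts from all stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets
from .array_de import DEConfig, de_results_to_frame, run_array_de
from .network import (FilterThresholds, build_network, export_network,
                      filter_mti, find_hubs, load_mti_sources,
                      predict_target_direction)
from .qpcr import (DdcpResult, ddcp_relative_level, mirna_group_change,
                   qpcr_results_to_frame, reconcile_calls, reconciled_to_frame)
from .simulate import (ArraySimConfig, MTISimConfig, QpcrSimConfig,
                       simulate_arrays, simulate_ct, simulate_mti,
                       write_array_files, write_ct_file, write_mti_files)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "validate_concordance",
]

UNDETECTED_BASELINE = 46.0  # beyond the 45-cycle ceiling: never amplifies


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration for a full pipeline run.

    Defaults reproduce the published study conditions: 300 probes on
    2 + 2 arrays with the example panel's eight log2 effects planted,
    six qPCR samples per group with the validation-panel effects (one
    assay left undetectable), score thresholds 80.0 / −1.2, hub
    minimum degree 3, and unanimity direction prediction.
    """

    seed: int = 1
    out_dir: str = "results/run"
    n_probes: int = 300
    n_arrays_per_group: int = 2
    array_noise_sd: float = 0.05
    dye_bias_amplitude: float = 0.4
    array_planted_effects: dict[str, float] | None = None
    n_samples_per_group: int = 6
    sd_ct: float = 0.15
    qpcr_planted_effects: dict[str, float] | None = None
    undetected_assays: tuple[str, ...] | None = None
    de: DEConfig = field(default_factory=DEConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_degree: int = 3
    direction_rule: str = "unanimity"
    n_planted_hubs: int = 4
    n_decoy_targets: int = 200
    target_planted_log2: float = 0.85  # ~1.8-fold mRNA increase
    reference_gene: str = "GAPDH"
    selected_genes: tuple[str, ...] | None = None  # None: all hubs

    def resolved_array_effects(self) -> dict[str, float]:
        if self.array_planted_effects is not None:
            return dict(self.array_planted_effects)
        panel = datasets.example_array_results()
        return dict(zip(panel["mirna"], panel["mean_log2"]))

    def resolved_qpcr_effects(self) -> dict[str, float]:
        if self.qpcr_planted_effects is not None:
            return dict(self.qpcr_planted_effects)
        panel = datasets.example_qpcr_results()
        return {row["mirna"]: float(row["mean_log2"])
                for _, row in panel.iterrows() if row["detected"]}

    def resolved_undetected(self) -> tuple[str, ...]:
        if self.undetected_assays is not None:
            return tuple(self.undetected_assays)
        panel = datasets.example_qpcr_results()
        return tuple(panel.loc[~panel["detected"], "mirna"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "de" in raw and isinstance(raw["de"], dict):
            raw["de"] = DEConfig(**raw["de"])
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        for key in ("undetected_assays", "selected_genes"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunReport:
    """Counts and per-stage outcomes of one pipeline run."""

    config_hash: str
    n_probes_tested: int
    n_selected: int
    n_confirmed: int
    n_final_down: int
    n_final_up: int
    n_edges: int
    n_hubs: int
    hub_table: pd.DataFrame = field(repr=False)
    concordance: pd.DataFrame = field(repr=False)
    reconciliation_summary: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("probes_tested", self.n_probes_tested),
            ("mirnas_selected", self.n_selected),
            ("mirnas_confirmed", self.n_confirmed),
            ("final_down", self.n_final_down),
            ("final_up", self.n_final_up),
            ("network_edges", self.n_edges),
            ("hub_targets", self.n_hubs),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])

    def to_text(self) -> str:
        lines = [f"pipeline run (config {self.config_hash})", ""]
        for _, row in self.to_frame().iterrows():
            lines.append(f"  {row['quantity']:<18} {row['count']}")
        lines.append("")
        if len(self.hub_table):
            lines.append("hub targets (degree >= threshold):")
            for _, row in self.hub_table.iterrows():
                lines.append(f"  {row['target']:<16} degree {row['degree']}"
                             f"  predicted {row['predicted_direction']}")
        if len(self.concordance):
            lines.append("")
            lines.append("hub mRNA validation:")
            for _, row in self.concordance.iterrows():
                lines.append(
                    f"  {row['gene']:<16} predicted {row['predicted']:<5}"
                    f" measured {row['measured']:<5} concordant={row['concordant']}")
        return "\n".join(lines) + "\n"


def _write_stage(df: pd.DataFrame, path: Path, config_hash: str, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} stage={stage}\n")
        df.to_csv(fh, sep="\t", index=False)


def validate_concordance(
    hub_predictions: dict[str, str],
    mrna_results: dict[str, DdcpResult],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Compare predicted hub-gene directions with measured ΔΔCp levels.

    The measured direction is the sign of the treated-vs-control mean
    level change, carrying its significance; genes without a
    measurement are marked unmeasured.
    """
    rows = []
    for gene, predicted in sorted(hub_predictions.items()):
        res = mrna_results.get(gene)
        if res is None:
            rows.append({"gene": gene, "predicted": predicted, "measured": "n.m.",
                         "significant": False, "ratio": float("nan"),
                         "concordant": False})
            continue
        measured = "up" if res.ratio > 1.0 else "down"
        significant = res.p_value is not None and res.p_value < p_threshold
        rows.append({"gene": gene, "predicted": predicted, "measured": measured,
                     "significant": significant, "ratio": res.ratio,
                     "concordant": bool(significant and measured == predicted)})
    return pd.DataFrame(rows, columns=["gene", "predicted", "measured",
                                       "significant", "ratio", "concordant"])


def run_pipeline(config: RunConfig | None = None) -> RunReport:
    """Execute every stage in order, writing outputs as it goes."""
    config = config or RunConfig()
    out = Path(config.out_dir)
    chash = config.config_hash()
    header = f"config_hash={chash}"

    # --- stage 1: simulate and analyze the arrays -----------------------
    array_cfg = ArraySimConfig(
        n_probes=config.n_probes,
        n_arrays_per_group=config.n_arrays_per_group,
        noise_sd=config.array_noise_sd,
        dye_bias_amplitude=config.dye_bias_amplitude,
        planted_effects=config.resolved_array_effects(),
        seed=config.seed,
    )
    intensities, metadata, array_truth = simulate_arrays(array_cfg)
    write_array_files(intensities, metadata, out / "simulated", header=header)
    de_results = run_array_de(intensities, metadata, config.de)
    de_frame = de_results_to_frame(de_results)
    _write_stage(de_frame, out / "de_results.tsv", chash, "de")
    selected = de_frame[de_frame["tier"] != "not_selected"]

    # --- stage 2: qPCR validation of the selected miRNAs ----------------
    qpcr_effects = config.resolved_qpcr_effects()
    undetected = set(config.resolved_undetected())
    baselines = {m: (UNDETECTED_BASELINE if m in undetected else 25.0)
                 for m in selected["mirna"]}
    qpcr_cfg = QpcrSimConfig(
        n_samples_per_group=config.n_samples_per_group,
        baselines=baselines,
        planted_effects={m: qpcr_effects.get(m, 0.0) for m in baselines
                         if m not in undetected},
        sd_ct=config.sd_ct,
        seed=config.seed + 1,
    )
    ct, _ = simulate_ct(qpcr_cfg)
    write_ct_file(ct, out / "simulated" / "mirna_ct.tsv", header=header)
    qpcr_results = [mirna_group_change(ct, m) for m in sorted(baselines)]
    qpcr_frame = qpcr_results_to_frame(qpcr_results)
    _write_stage(qpcr_frame, out / "qpcr_results.tsv", chash, "qpcr")

    # --- stage 3: reconcile array and qPCR calls ------------------------
    calls, summary = reconcile_calls(
        selected.rename(columns={"mean_log2": "mean_log2"}),
        qpcr_frame, p_threshold=config.de.p_threshold,
        log2_threshold=config.de.log2_threshold)
    recon_frame = reconciled_to_frame(calls)
    _write_stage(recon_frame, out / "reconciled_calls.tsv", chash, "reconcile")
    directions = {c.mirna: c.final_direction for c in calls}

    # --- stage 4: MTI sources, network, hubs ----------------------------
    down_mirnas = {m: d for m, d in directions.items() if d == "down"}
    feasible = len(down_mirnas) >= config.min_degree
    mti_cfg = MTISimConfig(
        mirna_directions=down_mirnas,
        n_planted_hubs=config.n_planted_hubs if feasible else 0,
        hub_degree_min=1 if not feasible else config.min_degree,
        hub_degree_max=1 if not feasible else config.min_degree,
        n_decoy_targets=config.n_decoy_targets if down_mirnas else 0,
        seed=config.seed + 2,
    )
    frames, mti_truth = simulate_mti(mti_cfg)
    paths = write_mti_files(frames, out / "simulated", header=header)
    records, _skipped = load_mti_sources(
        [(paths[d], d) for d in sorted(paths)])
    retained = filter_mti(records, config.thresholds)
    g = build_network(retained, directions)
    hubs = find_hubs(g, min_degree=config.min_degree)
    if config.direction_rule != "unanimity":
        hubs = [dataclasses.replace(
            h, predicted_direction=predict_target_direction(
                g, h.regulators, rule=config.direction_rule))
            for h in hubs]
    hub_frame = pd.DataFrame(
        [{"target": h.target_symbol, "degree": h.degree,
          "regulators": ",".join(sorted(h.regulators)),
          "predicted_direction": h.predicted_direction} for h in hubs],
        columns=["target", "degree", "regulators", "predicted_direction"])
    _write_stage(hub_frame, out / "hub_targets.tsv", chash, "network")
    export_network(g, hubs, out / "network")

    # --- stage 5: hub mRNA validation by ddCp qPCR ----------------------
    genes = (list(config.selected_genes) if config.selected_genes is not None
             else [h.target_symbol for h in hubs])
    predictions = {h.target_symbol: h.predicted_direction for h in hubs
                   if h.target_symbol in genes}
    target_effects = {}
    for gene in genes:
        direction = predictions.get(gene, "up")
        sign = {"up": 1.0, "down": -1.0}.get(direction, 0.0)
        target_effects[gene] = sign * config.target_planted_log2
    mrna_cfg = QpcrSimConfig(
        n_samples_per_group=config.n_samples_per_group,
        baselines={**{g_: 24.0 for g_ in genes}, config.reference_gene: 18.0},
        planted_effects=target_effects,
        reference_assays=(config.reference_gene,),
        sd_ct=config.sd_ct,
        sample_offset_sd=0.3,
        seed=config.seed + 3,
    )
    mrna_ct, _ = simulate_ct(mrna_cfg)
    write_ct_file(mrna_ct, out / "simulated" / "mrna_ct.tsv", header=header)
    mrna_results = {gene: ddcp_relative_level(mrna_ct, gene, config.reference_gene)
                    for gene in genes}
    concordance = validate_concordance(predictions, mrna_results,
                                       p_threshold=config.de.p_threshold)
    _write_stage(concordance, out / "concordance.tsv", chash, "validate")

    report = RunReport(
        config_hash=chash,
        n_probes_tested=len(de_frame),
        n_selected=len(selected),
        n_confirmed=summary["n_confirmed"],
        n_final_down=summary["n_final_down"],
        n_final_up=summary["n_final_up"],
        n_edges=g.number_of_edges(),
        n_hubs=len(hubs),
        hub_table=hub_frame,
        concordance=concordance,
        reconciliation_summary=summary,
    )
    _write_stage(report.to_frame(), out / "report.tsv", chash, "report")
    (out / "report.txt").write_text(report.to_text())
    return report
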