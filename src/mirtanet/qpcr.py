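"""qRT-PCR quantification and microarray/qPCR reconciliation.

Crossing-point (Cp) tables are tidy DataFrames with columns
``sample_id, group, assay, cp`` where an empty/NaN ``cp`` means the
assay never crossed threshold within the 45-cycle protocol
(undetermined). Lower Cp means more template, so a planted log2
expression increase of L shows up as a Cp decrease of L cycles.

Three quantification layers:

* miRNA group changes from raw Cp differences (optionally normalized
  to a reference assay), with signed fold changes and abundance
  classes relative to an abundant anchor miRNA;
* target-mRNA relative levels by the Livak 2^−ΔΔCp method against a
  reference gene, with the control group as calibrator;
* an efficiency-corrected variant replacing base 2 with the measured
  per-assay amplification efficiency.

Reconciliation compares the array direction of each selected miRNA
with its qPCR direction and significance and reports confirmation
(yes / no / n.d.) plus the final consensus direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import signed_fold_change, welch_t_test

__all__ = [
    "QpcrExpressionResult",
    "ReconciledCall",
    "PrimerAssay",
    "DdcpResult",
    "CP_CEILING",
    "classify_abundance",
    "mirna_group_change",
    "ddcp_relative_level",
    "efficiency_corrected_level",
    "reconcile_calls",
    "read_ct_table",
    "read_assay_registry",
    "qpcr_results_to_frame",
    "reconciled_to_frame",
]

CP_CEILING = 45.0  # cycles; the protocol runs 45 cycles

_MIN_SAMPLES_PER_GROUP = 2


@dataclass(frozen=True)
class QpcrExpressionResult:
    """Group-level qPCR expression change for one assay."""

    assay: str
    detected: bool
    mean_log2_change: float | None = None
    sd_log2: float | None = None
    fold_change: float | None = None
    p_value: float | None = None
    abundance_class: str = "n.d."


@dataclass(frozen=True)
class ReconciledCall:
    """Array-versus-qPCR consensus for one miRNA."""

    mirna: str
    array_direction: str       # up / down / none
    qpcr_direction: str        # up / down / n.d.
    final_direction: str       # up / down
    confirmation: str          # yes / no / n.d.
    flagged: bool = False      # detected but non-significant qPCR


@dataclass(frozen=True)
class PrimerAssay:
    """Primer-pair annotation with measured amplification efficiency."""

    target: str
    efficiency: float
    product_size: int = 0
    forward_primer: str = ""
    reverse_primer: str = ""

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")


@dataclass(frozen=True)
class DdcpResult:
    """Per-sample relative levels and group comparison for one target."""

    target: str
    reference_gene: str
    samples: pd.DataFrame = field(repr=False)  # sample_id, group, dcp, ddcp, level
    control_mean_level: float = float("nan")
    treated_mean_level: float = float("nan")
    ratio: float = float("nan")
    p_value: float | None = None
    n_dropped: int = 0


def classify_abundance(mean_cp_assay: float, mean_cp_reference: float) -> str:
    """Abundance class from the ΔCt to an abundant reference miRNA.

    Δ = mean Cp of the assay minus mean Cp of the reference; Δ < 6 is
    ``high``, Δ > 10 is ``low``, anything between (boundaries
    included) is ``intermediate``.
    """
    if not (math.isfinite(mean_cp_assay) and math.isfinite(mean_cp_reference)):
        raise ValueError("mean Cp values must be finite")
    delta = mean_cp_assay - mean_cp_reference
    if delta < 6.0:
        return "high"
    if delta > 10.0:
        return "low"
    return "intermediate"


def _group_cp(ct: pd.DataFrame, assay: str) -> dict[str, np.ndarray]:
    sub = ct[(ct["assay"] == assay) & ct["cp"].notna()]
    return {g: sub.loc[sub["group"] == g, "cp"].to_numpy(dtype=float)
            for g in ("control", "neuropathy")}


def mirna_group_change(
    ct: pd.DataFrame,
    assay: str,
    reference_assay: str | None = None,
    p_threshold: float = 0.05,
    abundance_reference: str | None = None,
) -> QpcrExpressionResult:
    """Group log2 expression change of a miRNA from its Cp values.

    Per-sample ΔCp is the raw Cp by default, or Cp minus the reference
    assay's Cp in the same sample when ``reference_assay`` is given.
    The mean log2 change is −(mean ΔCp neuropathy − mean ΔCp control);
    the p-value is a Welch test on the per-sample ΔCp. The assay is
    ``detected`` only when at least two samples per group amplified
    before the cycle ceiling.
    """
    values = _group_cp(ct, assay)
    if any(len(v) < _MIN_SAMPLES_PER_GROUP for v in values.values()):
        return QpcrExpressionResult(assay=assay, detected=False)

    if reference_assay is not None:
        merged = _paired_cp(ct, assay, reference_assay)
        dcp = {g: (merged.loc[merged["group"] == g, "cp_target"]
                   - merged.loc[merged["group"] == g, "cp_reference"]).to_numpy()
               for g in ("control", "neuropathy")}
        if any(len(v) < _MIN_SAMPLES_PER_GROUP for v in dcp.values()):
            return QpcrExpressionResult(assay=assay, detected=False)
    else:
        dcp = values

    mean_log2 = -(dcp["neuropathy"].mean() - dcp["control"].mean())
    # spread of per-sample log2 changes in the treated group relative
    # to the control mean; ΔCp is on the log2 scale already
    sd_log2 = float(np.std(dcp["neuropathy"], ddof=1))
    test = welch_t_test(dcp["neuropathy"], dcp["control"])

    abundance = "n.d."
    if abundance_reference is not None:
        ref_cp = ct[(ct["assay"] == abundance_reference) & ct["cp"].notna()]["cp"]
        if len(ref_cp) == 0:
            raise ValueError(f"abundance reference {abundance_reference!r} absent")
        all_cp = np.concatenate([values["control"], values["neuropathy"]])
        abundance = classify_abundance(float(all_cp.mean()), float(ref_cp.mean()))

    return QpcrExpressionResult(
        assay=assay,
        detected=True,
        mean_log2_change=float(mean_log2),
        sd_log2=sd_log2,
        fold_change=signed_fold_change(mean_log2),
        p_value=test.p_value,
        abundance_class=abundance,
    )


def _paired_cp(ct: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    t = ct[(ct["assay"] == target) & ct["cp"].notna()]
    r = ct[(ct["assay"] == reference) & ct["cp"].notna()]
    merged = t.merge(r, on=["sample_id", "group"], suffixes=("_target", "_reference"))
    return merged


def ddcp_relative_level(
    ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    test_on: str = "levels",
) -> DdcpResult:
    """Relative mRNA levels of a target gene by the 2^−ΔΔCp method.

    ΔCp_s = Cp_target,s − Cp_reference,s per sample; ΔΔCp_s subtracts
    the arithmetic mean ΔCp of the control group (the calibrator), and
    the level is 2^−ΔΔCp_s, so the control group averages 1 by
    construction. Samples lacking the reference gene are dropped with
    a warning. The group comparison is a Welch test on the linear
    levels (``test_on="levels"``) or on ΔCp (``test_on="dcp"``).
    """
    if test_on not in ("levels", "dcp"):
        raise ValueError("test_on must be 'levels' or 'dcp'")
    t = ct[(ct["assay"] == target) & ct["cp"].notna()]
    merged = _paired_cp(ct, target, reference_gene)
    n_dropped = len(t) - len(merged)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sample(s) dropped for {target!r}: reference "
            f"{reference_gene!r} missing", stacklevel=2,
        )
    if merged.empty or (merged["group"] == "control").sum() == 0:
        raise ValueError(f"no usable control samples for target {target!r}")

    merged = merged.copy()
    merged["dcp"] = merged["cp_target"] - merged["cp_reference"]
    calibrator = merged.loc[merged["group"] == "control", "dcp"].mean()
    merged["ddcp"] = merged["dcp"] - calibrator
    merged["level"] = 2.0 ** (-merged["ddcp"])

    ctrl = merged[merged["group"] == "control"]
    trt = merged[merged["group"] == "neuropathy"]
    p: float | None = None
    if len(ctrl) >= 2 and len(trt) >= 2:
        if test_on == "levels":
            p = welch_t_test(trt["level"], ctrl["level"]).p_value
        else:
            p = welch_t_test(trt["dcp"], ctrl["dcp"]).p_value
    ctrl_mean = float(ctrl["level"].mean())
    trt_mean = float(trt["level"].mean()) if len(trt) else float("nan")
    samples = merged[["sample_id", "group", "dcp", "ddcp", "level"]].reset_index(drop=True)
    return DdcpResult(
        target=target,
        reference_gene=reference_gene,
        samples=samples,
        control_mean_level=ctrl_mean,
        treated_mean_level=trt_mean,
        ratio=trt_mean / ctrl_mean if ctrl_mean else float("nan"),
        p_value=p,
        n_dropped=n_dropped,
    )


def efficiency_corrected_level(
    ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    assays: dict[str, PrimerAssay],
    test_on: str = "levels",
) -> DdcpResult:
    """ΔΔCp quantification with measured amplification efficiencies.

    Replaces the ideal doubling assumption with the per-assay
    efficiency E: level_s = E_t^−(Cp_t,s − calibrator_t) /
    E_r^−(Cp_r,s − calibrator_r), each calibrator being the control
    mean of the respective assay. With E = 2 for both assays this
    reduces exactly to :func:`ddcp_relative_level`.
    """
    for name in (target, reference_gene):
        if name not in assays:
            raise ValueError(f"no efficiency registered for assay {name!r}")
    e_t = assays[target].efficiency
    e_r = assays[reference_gene].efficiency

    merged = _paired_cp(ct, target, reference_gene)
    if merged.empty or (merged["group"] == "control").sum() == 0:
        raise ValueError(f"no usable control samples for target {target!r}")
    merged = merged.copy()
    ctrl_mask = merged["group"] == "control"
    cal_t = merged.loc[ctrl_mask, "cp_target"].mean()
    cal_r = merged.loc[ctrl_mask, "cp_reference"].mean()
    merged["dcp"] = merged["cp_target"] - merged["cp_reference"]
    merged["ddcp"] = merged["dcp"] - (cal_t - cal_r)
    merged["level"] = (e_t ** -(merged["cp_target"] - cal_t)
                       / e_r ** -(merged["cp_reference"] - cal_r))

    ctrl = merged[ctrl_mask]
    trt = merged[~ctrl_mask]
    p: float | None = None
    if len(ctrl) >= 2 and len(trt) >= 2:
        key = "level" if test_on == "levels" else "dcp"
        p = welch_t_test(trt[key], ctrl[key]).p_value
    ctrl_mean = float(ctrl["level"].mean())
    trt_mean = float(trt["level"].mean()) if len(trt) else float("nan")
    samples = merged[["sample_id", "group", "dcp", "ddcp", "level"]].reset_index(drop=True)
    return DdcpResult(
        target=target,
        reference_gene=reference_gene,
        samples=samples,
        control_mean_level=ctrl_mean,
        treated_mean_level=trt_mean,
        ratio=trt_mean / ctrl_mean if ctrl_mean else float("nan"),
        p_value=p,
    )


def _is_significant(row, p_threshold: float) -> bool:
    if "significant" in row.index and not pd.isna(row["significant"]):
        return bool(row["significant"])
    return bool(pd.notna(row.get("p_value")) and row["p_value"] < p_threshold)


def reconcile_calls(
    array_results: pd.DataFrame,
    qpcr_results: pd.DataFrame,
    p_threshold: float = 0.05,
    log2_threshold: float = 0.6,
) -> tuple[list[ReconciledCall], dict[str, int]]:
    """Reconcile array DE calls with their qPCR validation.

    ``array_results`` needs columns ``mirna, mean_log2`` and either
    ``p_value`` or a boolean ``significant``; ``qpcr_results`` needs
    ``mirna, detected, mean_log2`` plus ``p_value``/``significant``.

    Confirmation is ``yes`` when the qPCR assay is detected,
    significant, and direction-concordant with the array; ``no`` when
    detected but discordant or non-significant (the latter flagged);
    ``n.d.`` when not detected. The final direction follows the qPCR
    sign when detected and significant, the array sign otherwise.
    Returns the per-miRNA calls and summary counts.
    """
    q = qpcr_results.set_index("mirna")
    calls: list[ReconciledCall] = []
    for _, row in array_results.iterrows():
        name = row["mirna"]
        if name not in q.index:
            raise ValueError(f"array-selected miRNA {name!r} missing from qPCR results")
        mean = row["mean_log2"]
        array_dir = "none"
        if abs(mean) > log2_threshold:
            array_dir = "up" if mean > 0 else "down"
        qrow = q.loc[name]
        if not bool(qrow["detected"]):
            calls.append(ReconciledCall(
                mirna=name, array_direction=array_dir, qpcr_direction="n.d.",
                final_direction="up" if mean > 0 else "down",
                confirmation="n.d."))
            continue
        q_sig = _is_significant(qrow, p_threshold)
        q_dir = "up" if qrow["mean_log2"] > 0 else "down"
        concordant = (q_dir == array_dir)
        if q_sig and concordant:
            confirmation, flagged = "yes", False
        elif q_sig:
            confirmation, flagged = "no", False
        else:
            confirmation, flagged = "no", True
        final = q_dir if q_sig else ("up" if mean > 0 else "down")
        calls.append(ReconciledCall(
            mirna=name, array_direction=array_dir, qpcr_direction=q_dir,
            final_direction=final, confirmation=confirmation, flagged=flagged))
    summary = {
        "n_confirmed": sum(c.confirmation == "yes" for c in calls),
        "n_final_down": sum(c.final_direction == "down" for c in calls),
        "n_final_up": sum(c.final_direction == "up" for c in calls),
        "n_undetected": sum(c.confirmation == "n.d." for c in calls),
    }
    return calls, summary


def read_ct_table(path) -> pd.DataFrame:
    """Read a Cp TSV (sample_id, group, assay, cp; empty cp = undetermined)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "group", "assay", "cp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    present = df["cp"].dropna()
    if ((present <= 0) | (present > CP_CEILING)).any():
        raise ValueError(f"cp values must lie in (0, {CP_CEILING}]")
    if df.duplicated(["sample_id", "assay"]).any():
        raise ValueError("duplicate (sample, assay) entries")
    return df


def read_assay_registry(path) -> dict[str, PrimerAssay]:
    """Read a primer/efficiency registry TSV keyed by target name."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"target", "efficiency"} <= set(df.columns):
        raise ValueError("assay registry needs columns target, efficiency")
    out = {}
    for _, row in df.iterrows():
        out[row["target"]] = PrimerAssay(
            target=row["target"],
            efficiency=float(row["efficiency"]),
            product_size=int(row.get("product_size", 0) or 0),
            forward_primer=str(row.get("forward_primer", "") or ""),
            reverse_primer=str(row.get("reverse_primer", "") or ""),
        )
    return out


def qpcr_results_to_frame(results: list[QpcrExpressionResult]) -> pd.DataFrame:
    """Serialize qPCR results into the output table layout."""
    columns = ["mirna", "detected", "mean_log2", "sd_log2", "fold_change",
               "p_value", "abundance_class"]
    return pd.DataFrame([{
        "mirna": r.assay,
        "detected": r.detected,
        "mean_log2": r.mean_log2_change,
        "sd_log2": r.sd_log2,
        "fold_change": r.fold_change,
        "p_value": r.p_value,
        "abundance_class": r.abundance_class,
    } for r in results], columns=columns)


def reconciled_to_frame(calls: list[ReconciledCall]) -> pd.DataFrame:
    columns = ["mirna", "array_direction", "qpcr_direction",
               "final_direction", "confirmation", "flagged"]
    return pd.DataFrame([{
        "mirna": c.mirna,
        "array_direction": c.array_direction,
        "qpcr_direction": c.qpcr_direction,
        "final_direction": c.final_direction,
        "confirmation": c.confirmation,
        "flagged": c.flagged,
    } for c in calls], columns=columns)
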