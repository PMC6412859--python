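"""Synthetic data generators with known ground truth.

Every pipeline input can be simulated: two-color array foreground
intensities under the normal-plus-exponential generative model with
planted group effects and a smooth intensity-dependent dye bias; Cp
tables with planted fold changes, a stable reference gene and a
45-cycle detection ceiling; and miRNA–target source files with
planted degree-≥3 hubs hidden among low-degree or sub-threshold
decoys. Each generator is a pure function of its config: the same
seed reproduces the same tables byte for byte, and a truth object is
returned alongside every dataset so downstream recovery can be scored
without re-reading the config.

The array design mirrors the pooled two-color study layout this
package targets: six animals per group pooled three-and-three into
2 arrays per group, each hybridized sample-vs-common-reference, and
qPCR with six samples per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .array_de import CHANNEL_REFERENCE, CHANNEL_SAMPLE

__all__ = [
    "ArraySimConfig",
    "QpcrSimConfig",
    "MTISimConfig",
    "SyntheticTruth",
    "simulate_arrays",
    "simulate_ct",
    "simulate_mti",
    "write_array_files",
    "write_ct_file",
    "write_mti_files",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth written alongside every simulated dataset."""

    probe_effects: dict[str, float] = field(default_factory=dict)
    assay_effects: dict[str, float] = field(default_factory=dict)
    hubs: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "probe_effect", "name": k, "value": v, "members": ""}
                for k, v in sorted(self.probe_effects.items())]
        rows += [{"kind": "assay_effect", "name": k, "value": v, "members": ""}
                 for k, v in sorted(self.assay_effects.items())]
        rows += [{"kind": "hub", "name": k, "value": float(len(v)),
                  "members": ",".join(sorted(v))}
                 for k, v in sorted(self.hubs.items())]
        return pd.DataFrame(rows, columns=["kind", "name", "value", "members"])


@dataclass(frozen=True)
class ArraySimConfig:
    """Two-color array simulation settings.

    Foreground = Normal(background_mu, background_sigma²) + true
    signal; each probe's baseline signal is one exponential draw with
    mean ``alpha`` shared across arrays and channels, modulated on the
    log2 scale by the planted group effect (sample channel of treated
    arrays only), per-hybridization noise, and a smooth dye bias on
    the sample channel. Planted probes get a floor of
    ``planted_min_signal_frac × alpha`` on their baseline so the
    effects to be recovered are not parked below the detection limit.

    ``noise_sd`` applies to the sample channel (distinct RNA pools per
    array: biological plus technical variation);
    ``reference_noise_sd`` applies to the reference channel, which is
    the same labeled pool on every array and therefore varies only
    technically.
    """

    n_probes: int = 300
    n_arrays_per_group: int = 2
    background_mu: float = 100.0
    background_sigma: float = 15.0
    alpha: float = 5000.0
    dye_bias_amplitude: float = 0.4
    planted_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    reference_noise_sd: float = 0.02
    planted_min_signal_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_sigma, self.alpha) <= 0:
            raise ValueError("scale parameters must be > 0")
        if min(self.noise_sd, self.reference_noise_sd,
               self.dye_bias_amplitude) < 0:
            raise ValueError("noise SDs and dye_bias_amplitude must be >= 0")
        if len(self.planted_effects) > self.n_probes:
            raise ValueError("more planted effects than probes")


@dataclass(frozen=True)
class QpcrSimConfig:
    """Cp-table simulation settings.

    Cp = baseline − planted_log2_effect·[neuropathy] + sample loading
    offset + Normal(0, sd_ct); the loading offset is shared by every
    assay of a sample (what reference-gene normalization removes) and
    reference assays get their own stability noise. Values beyond the
    45-cycle ceiling are recorded as undetermined.
    """

    n_samples_per_group: int = 6
    baselines: dict[str, float] = field(default_factory=dict)
    planted_effects: dict[str, float] = field(default_factory=dict)
    reference_assays: tuple[str, ...] = ()
    reference_stability_sd: float = 0.0
    sd_ct: float = 0.15
    sample_offset_sd: float = 0.0
    ceiling: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_ct < 0 or self.reference_stability_sd < 0 or self.sample_offset_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.ceiling != 45.0:
            raise ValueError("protocol runs 45 cycles")


@dataclass(frozen=True)
class MTISimConfig:
    """Planted-hub MTI simulation settings.

    Planted hubs receive ``hub_degree`` interactions with
    threshold-passing scores spread across the three source dialects;
    decoy targets receive at most two passing interactions and may
    additionally receive sub-threshold ones that only the score filter
    keeps from promoting them to hubs.
    """

    mirna_directions: dict[str, str] = field(default_factory=dict)
    n_planted_hubs: int = 4
    hub_degree_min: int = 3
    hub_degree_max: int = 3
    n_decoy_targets: int = 200
    high_good_pass: tuple[float, float] = (85.0, 99.0)
    high_good_fail: tuple[float, float] = (55.0, 80.0)
    low_good_pass: tuple[float, float] = (-5.0, -1.5)
    low_good_fail: tuple[float, float] = (-1.2, -0.1)
    decoy_fail_edge_prob: float = 0.4
    species: str = "rno"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hub_degree_max > len(self.mirna_directions) and self.n_planted_hubs:
            raise ValueError("hub degree exceeds number of miRNAs")
        if self.hub_degree_min < 1 or self.hub_degree_min > self.hub_degree_max:
            raise ValueError("invalid hub degree range")


def _dye_bias(log2_abundance: np.ndarray, lo: float, hi: float,
              amplitude: float) -> np.ndarray:
    """Smooth sinusoid-plus-trend bias in log2 units.

    A fixed function of the observed spot abundance, anchored to the
    experiment-wide intensity range [lo, hi] so every array sees the
    same intensity-dependent distortion.
    """
    span = max(hi - lo, 1e-9)
    t = np.clip((log2_abundance - lo) / span, 0.0, 1.0)
    return amplitude * np.sin(1.5 * np.pi * t) + 0.25 * amplitude * (t - 0.5)


def simulate_arrays(
    config: ArraySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a two-color array experiment.

    Returns the tidy intensity table, the array metadata table, and
    the planted truth (per-probe log2 effects, zero for decoys).
    """
    rng = np.random.default_rng(config.seed)
    planted = dict(sorted(config.planted_effects.items()))
    n_decoys = config.n_probes - len(planted)
    probes = list(planted) + [f"decoy-{i:04d}" for i in range(n_decoys)]
    effects = np.array([planted.get(p, 0.0) for p in probes])

    base = rng.exponential(config.alpha, size=config.n_probes)
    if planted:
        floor = config.planted_min_signal_frac * config.alpha
        # memoryless truncation: floor + fresh exponential draw
        base[: len(planted)] = floor + rng.exponential(config.alpha, size=len(planted))

    arrays = ([(f"ctrl-{i+1}", "control") for i in range(config.n_arrays_per_group)]
              + [(f"neuro-{i+1}", "neuropathy") for i in range(config.n_arrays_per_group)])
    abund0 = np.log2(np.maximum(base, 1e-9))
    bias_lo, bias_hi = float(abund0.min()), float(abund0.max())

    rows = []
    n_floored = 0
    for array_id, group in arrays:
        for channel in (CHANNEL_SAMPLE, CHANNEL_REFERENCE):
            sd = (config.noise_sd if channel == CHANNEL_SAMPLE
                  else config.reference_noise_sd)
            abund = abund0 + rng.normal(0.0, sd, size=config.n_probes)
            if channel == CHANNEL_SAMPLE:
                if group == "neuropathy":
                    abund = abund + effects
                # dye bias follows the spot's observed abundance
                abund = abund + _dye_bias(abund, bias_lo, bias_hi,
                                          config.dye_bias_amplitude)
            signal = 2.0**abund
            observed = signal + rng.normal(config.background_mu,
                                           config.background_sigma,
                                           size=config.n_probes)
            n_floored += int((observed < 0).sum())
            observed = np.maximum(observed, 0.0)
            for p, v in zip(probes, observed):
                rows.append((p, array_id, channel, v))
    intensities = pd.DataFrame(rows, columns=["probe_id", "array_id",
                                              "channel", "foreground"])
    metadata = pd.DataFrame(arrays, columns=["array_id", "group"])
    truth = SyntheticTruth(probe_effects={p: float(e)
                                          for p, e in zip(probes, effects)})
    return intensities, metadata, truth


def simulate_ct(config: QpcrSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a Cp table with planted fold changes.

    Assays are the union of ``baselines`` keys; assays without a
    baseline default to 25 cycles. A planted log2 effect of L lowers
    the treated group's Cp by L cycles (more template, earlier
    crossing).
    """
    rng = np.random.default_rng(config.seed)
    assays = sorted(set(config.baselines) | set(config.planted_effects)
                    | set(config.reference_assays))
    samples = ([(f"ctrl-{i+1}", "control") for i in range(config.n_samples_per_group)]
               + [(f"neuro-{i+1}", "neuropathy")
                  for i in range(config.n_samples_per_group)])
    offsets = {sid: rng.normal(0.0, config.sample_offset_sd) if config.sample_offset_sd
               else 0.0 for sid, _ in samples}
    rows = []
    for assay in assays:
        baseline = config.baselines.get(assay, 25.0)
        effect = config.planted_effects.get(assay, 0.0)
        extra_sd = (config.reference_stability_sd
                    if assay in config.reference_assays else 0.0)
        for sid, group in samples:
            cp = baseline + offsets[sid] + rng.normal(0.0, config.sd_ct)
            if extra_sd:
                cp += rng.normal(0.0, extra_sd)
            if group == "neuropathy":
                cp -= effect
            rows.append((sid, group, assay, cp if cp <= config.ceiling else np.nan))
    ct = pd.DataFrame(rows, columns=["sample_id", "group", "assay", "cp"])
    truth = SyntheticTruth(assay_effects={a: float(config.planted_effects.get(a, 0.0))
                                          for a in assays})
    return ct, truth


def simulate_mti(
    config: MTISimConfig,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate the three MTI source tables with planted hubs.

    Returns ``{"predicted_high_good": df, "predicted_low_good": df,
    "validated": df}`` (columns mirna, target, score, species; score
    empty for validated) and the truth with hub regulator sets.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = sorted(config.mirna_directions)
    if not mirnas and (config.n_planted_hubs or config.n_decoy_targets):
        raise ValueError("need at least one miRNA")
    tables: dict[str, list[tuple]] = {s: [] for s in
                                      ("predicted_high_good",
                                       "predicted_low_good", "validated")}

    def add_edge(mirna: str, target: str, passing: bool) -> None:
        if passing:
            dialect = ("predicted_high_good", "predicted_low_good",
                       "validated")[rng.integers(3)]
            if dialect == "predicted_high_good":
                score = rng.uniform(*config.high_good_pass)
            elif dialect == "predicted_low_good":
                score = rng.uniform(*sorted(config.low_good_pass))
            else:
                score = None
            tables[dialect].append((mirna, target, score, config.species))
        else:
            # failing records exist only in the predicted dialects
            dialect = ("predicted_high_good",
                       "predicted_low_good")[rng.integers(2)]
            if dialect == "predicted_high_good":
                score = rng.uniform(*config.high_good_fail)
            else:
                score = rng.uniform(*sorted(config.low_good_fail))
            tables[dialect].append((mirna, target, score, config.species))

    hubs: dict[str, frozenset[str]] = {}
    for i in range(config.n_planted_hubs):
        name = f"HUB-{i+1:02d}"
        degree = int(rng.integers(config.hub_degree_min,
                                  config.hub_degree_max + 1))
        regs = sorted(rng.choice(mirnas, size=degree, replace=False))
        for m in regs:
            add_edge(m, name, passing=True)
        hubs[name] = frozenset(regs)

    for i in range(config.n_decoy_targets):
        name = f"decoygene-{i+1:04d}"
        n_pass = int(rng.integers(1, 3))  # 1 or 2 passing regulators
        regs = list(rng.choice(mirnas, size=min(n_pass, len(mirnas)),
                               replace=False))
        for m in regs:
            add_edge(m, name, passing=True)
        if rng.random() < config.decoy_fail_edge_prob and len(mirnas) > len(regs):
            # sub-threshold records that would make this decoy a hub if
            # the score filter were skipped
            remaining = [m for m in mirnas if m not in regs]
            n_fail = 3 - len(regs) + int(rng.integers(0, 2))
            for m in rng.choice(remaining, size=min(n_fail, len(remaining)),
                                replace=False):
                add_edge(m, name, passing=False)

    frames = {
        dialect: pd.DataFrame(rows, columns=["mirna", "target", "score", "species"])
        for dialect, rows in tables.items()
    }
    return frames, SyntheticTruth(hubs=hubs)


def write_array_files(
    intensities: pd.DataFrame,
    metadata: pd.DataFrame,
    out_dir: str | Path,
    header: str = "",
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"intensities": out_dir / "array_intensities.tsv",
             "metadata": out_dir / "array_metadata.tsv"}
    _write_tsv(intensities, paths["intensities"], header)
    _write_tsv(metadata, paths["metadata"], header)
    return paths


def write_ct_file(ct: pd.DataFrame, path: str | Path, header: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_tsv(ct, path, header)
    return path


def write_mti_files(
    frames: dict[str, pd.DataFrame],
    out_dir: str | Path,
    header: str = "",
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for dialect, df in frames.items():
        p = out_dir / f"mti_{dialect}.tsv"
        _write_tsv(df, p, header)
        paths[dialect] = p
    return paths


def _write_tsv(df: pd.DataFrame, path: Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
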