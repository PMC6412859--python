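"""Bundled example dataset: a rat sensory-neuropathy cardiac miRNA panel.

Published group-level results from a capsaicin-induced sensory
neuropathy study in rat heart: eight differentially expressed miRNAs
with their microarray log2 ratios, the matching qRT-PCR validation
panel, the four hub target genes with their regulator matrix, primer
efficiencies for the mRNA validation assays, and body-weight
summaries. These serve as worked inputs for the reconciliation and
hub-selection stages and as regression anchors for the fold-change
transform.

Significance markers from the source tables are carried as boolean
flags (the underlying p-values were not published).
"""

from __future__ import annotations

import pandas as pd

from .network import MTIRecord
from .qpcr import PrimerAssay
from .stats import GroupSummary

__all__ = [
    "example_array_results",
    "example_qpcr_results",
    "example_hub_records",
    "example_mirna_directions",
    "example_primer_assays",
    "example_body_weight_summaries",
    "SELECTED_TARGET_GENES",
    "SHORT_TO_MATURE",
]

SELECTED_TARGET_GENES = ("IGF-1", "SLC2a-12", "EIF-4e", "ULK-2")

SHORT_TO_MATURE = {
    "miR-344b": "rno-miR-344b-1-3p",
    "miR-466b": "rno-miR-466b-1-3p",
    "miR-98": "rno-miR-98-5p",
    "let-7a": "rno-let-7a-5p",
    "miR-1": "rno-miR-1-3p",
    "miR-206": "rno-miR-206-3p",
    "miR-34b": "rno-miR-34b-3p",
    "miR-181a": "rno-miR-181a-2-3p",
}

# microarray panel: mean log2 ratio (neuropathy / control), SD over the
# four cross-pair comparisons, and the published significance flag
_ARRAY_ROWS = [
    ("rno-miR-344b-1-3p", -1.95, 0.47, True),
    ("rno-miR-466b-1-3p", -1.10, 0.49, True),
    ("rno-miR-98-5p", -1.07, 1.26, False),
    ("rno-let-7a-5p", -1.03, 1.21, False),
    ("rno-miR-1-3p", -0.88, 1.19, False),
    ("rno-miR-206-3p", -0.86, 1.23, False),
    ("rno-miR-34b-3p", 0.63, 0.46, False),
    ("rno-miR-181a-2-3p", 0.75, 0.27, True),
]

# qRT-PCR validation panel: mean log2 change, SD, published signed fold
# change, significance flag; miR-344b never amplified (not detected)
_QPCR_ROWS = [
    ("rno-miR-344b-1-3p", False, None, None, None, None),
    ("rno-miR-466b-1-3p", True, -3.19, 1.59, -9.13, True),
    ("rno-miR-98-5p", True, -2.45, 1.19, -5.48, True),
    ("rno-let-7a-5p", True, -2.03, 0.54, -4.07, True),
    ("rno-miR-1-3p", True, -2.85, 1.03, -7.21, True),
    ("rno-miR-206-3p", True, -5.19, 1.58, -36.42, True),
    ("rno-miR-34b-3p", True, -2.93, 1.76, -7.60, True),
    ("rno-miR-181a-2-3p", True, 3.81, 1.55, 14.03, True),
]

# hub regulator matrix: which down-regulated miRNAs target each of the
# four validated hub genes (12 interactions in total)
_HUB_EDGES = {
    "IGF-1": ("miR-466b", "miR-1", "miR-206"),
    "SLC2a-12": ("miR-466b", "miR-98", "let-7a"),
    "EIF-4e": ("miR-1", "miR-206", "miR-34b"),
    "ULK-2": ("miR-98", "let-7a", "miR-34b"),
}

_PRIMER_ROWS = [
    ("IGF-1", 1.966, 211),
    ("SLC2a-12", 1.704, 251),
    ("EIF-4e", 1.743, 163),
    ("ULK-2", 2.00, 161),
    ("GAPDH", 1.991, 105),
]


def example_array_results() -> pd.DataFrame:
    """Microarray DE panel (mirna, mean_log2, sd_log2, significant)."""
    return pd.DataFrame(_ARRAY_ROWS,
                        columns=["mirna", "mean_log2", "sd_log2", "significant"])


def example_qpcr_results() -> pd.DataFrame:
    """qRT-PCR validation panel (mirna, detected, mean_log2, sd_log2,
    fold_change, significant)."""
    return pd.DataFrame(_QPCR_ROWS,
                        columns=["mirna", "detected", "mean_log2", "sd_log2",
                                 "fold_change", "significant"])


def example_hub_records() -> list[MTIRecord]:
    """The 12 validated miRNA–target interactions of the four hub genes."""
    records = []
    for target, regulators in _HUB_EDGES.items():
        for short in regulators:
            records.append(MTIRecord(
                mirna=SHORT_TO_MATURE[short], target_symbol=target,
                source="validated", species="rno"))
    return records


def example_mirna_directions() -> dict[str, str]:
    """Final consensus direction per panel miRNA (qPCR where detected)."""
    return {
        "rno-miR-344b-1-3p": "down",
        "rno-miR-466b-1-3p": "down",
        "rno-miR-98-5p": "down",
        "rno-let-7a-5p": "down",
        "rno-miR-1-3p": "down",
        "rno-miR-206-3p": "down",
        "rno-miR-34b-3p": "down",
        "rno-miR-181a-2-3p": "up",
    }


def example_primer_assays() -> dict[str, PrimerAssay]:
    """Measured amplification efficiencies of the mRNA validation assays."""
    return {name: PrimerAssay(target=name, efficiency=eff, product_size=size)
            for name, eff, size in _PRIMER_ROWS}


def example_body_weight_summaries() -> dict[str, tuple[GroupSummary, GroupSummary]]:
    """Morphometry summaries as (control, neuropathy) mean ± SD pairs."""
    return {
        "delta_body_weight_g": (GroupSummary(41.0, 20.0, 6),
                                GroupSummary(7.0, 5.0, 6)),
        "heart_weight_mg": (GroupSummary(1167.0, 116.0, 6),
                            GroupSummary(972.0, 98.0, 6)),
    }
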