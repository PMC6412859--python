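"""miRNA–target interaction integration and bipartite hub analysis.

Interaction records come from three source dialects mirroring the
public MTI databases a practitioner would query:

* ``predicted_high_good`` — prediction scores where higher is better
  (miRDB-style, scores in (50, 100]); records at or below the
  threshold (default 80.0) are poor predictions and removed;
* ``predicted_low_good`` — regression scores where more negative is
  stronger (mirSVR-style); records at or above the threshold
  (default −1.2) are removed;
* ``validated`` — experimentally validated interactions
  (miRTarBase-style), kept unconditionally and allowed to lack a
  score.

Retained records are merged by union into a strictly bipartite graph
(one edge per (miRNA, target) pair, provenance records every
supporting source). Hub targets are those regulated by at least
``min_degree`` distinct miRNAs (default 3); their expected direction
of change is the opposite of their regulators' shared direction,
since miRNAs repress their targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "SOURCES",
    "MTIRecord",
    "FilterThresholds",
    "HubTarget",
    "load_mti_sources",
    "filter_mti",
    "build_network",
    "find_hubs",
    "predict_target_direction",
    "export_network",
    "read_graphml_network",
]

SOURCES = ("predicted_high_good", "predicted_low_good", "validated")


@dataclass(frozen=True)
class MTIRecord:
    """One miRNA–target interaction assertion from one source."""

    mirna: str
    target_symbol: str
    source: str
    score: float | None = None
    species: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source dialect {self.source!r}")
        if self.source != "validated" and self.score is None:
            raise ValueError("predicted records must carry a score")


@dataclass(frozen=True)
class FilterThresholds:
    """Score cut-offs for the two predicted dialects.

    ``high_good_min_exclusive``: predicted_high_good records kept only
    with score strictly above it. ``low_good_max_exclusive``:
    predicted_low_good records kept only with score strictly below it.
    """

    high_good_min_exclusive: float = 80.0
    low_good_max_exclusive: float = -1.2


@dataclass(frozen=True)
class HubTarget:
    """Target gene regulated by at least ``min_degree`` distinct miRNAs."""

    target_symbol: str
    regulators: frozenset[str]
    degree: int
    predicted_direction: str  # up / down / ambiguous

    def __post_init__(self) -> None:
        if self.degree != len(self.regulators):
            raise ValueError("degree must equal the number of regulators")


def _norm_mirna(name: str) -> str:
    # case-insensitive matching; the mature-arm suffix (-3p/-5p) is part
    # of the lowered identifier and therefore must match exactly
    return name.strip().lower()


def load_mti_sources(
    paths_with_dialects: list[tuple[str | Path, str]],
    species: str = "",
    strict_species: bool = False,
) -> tuple[list[MTIRecord], dict[str, int]]:
    """Parse MTI source TSVs (columns ``mirna, target, score``).

    Each file declares its dialect. Malformed rows (missing names, or
    a predicted row without a score) are skipped and counted. Returns
    the records plus per-reason skip counts.
    """
    records: list[MTIRecord] = []
    skipped = {"missing_fields": 0, "missing_score": 0, "species_mismatch": 0}
    for path, dialect in paths_with_dialects:
        if dialect not in SOURCES:
            raise ValueError(f"unknown dialect {dialect!r} for {path}")
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"mirna", "target"} <= set(df.columns):
            raise ValueError(f"{path}: MTI table needs columns mirna, target")
        for _, row in df.iterrows():
            if pd.isna(row["mirna"]) or pd.isna(row["target"]):
                skipped["missing_fields"] += 1
                continue
            score = row.get("score")
            score = None if pd.isna(score) else float(score)
            if dialect != "validated" and score is None:
                skipped["missing_score"] += 1
                continue
            row_species = str(row.get("species", "") or "")
            if strict_species and species and row_species and row_species != species:
                skipped["species_mismatch"] += 1
                continue
            records.append(MTIRecord(
                mirna=str(row["mirna"]), target_symbol=str(row["target"]),
                source=dialect, score=score, species=row_species))
    return records, skipped


def filter_mti(
    records: list[MTIRecord],
    thresholds: FilterThresholds | None = None,
) -> list[MTIRecord]:
    """Drop poor predictions; validated records are always retained.

    Keeps predicted_high_good iff score > high_good_min_exclusive and
    predicted_low_good iff score < low_good_max_exclusive (boundary
    values removed in both dialects). Idempotent and order-preserving.
    """
    thresholds = thresholds or FilterThresholds()
    out = []
    for rec in records:
        if rec.source == "validated":
            out.append(rec)
        elif rec.source == "predicted_high_good":
            if rec.score > thresholds.high_good_min_exclusive:
                out.append(rec)
        else:  # predicted_low_good
            if rec.score < thresholds.low_good_max_exclusive:
                out.append(rec)
    return out


def build_network(
    records: list[MTIRecord],
    mirna_directions: dict[str, str],
) -> nx.Graph:
    """Build the bipartite miRNA–target graph from retained records.

    miRNA nodes carry their expression direction; edges carry the set
    of supporting sources and any retained scores. Records whose miRNA
    is absent from the direction map are dropped with a warning
    (matching is case-insensitive; arm suffixes must match). Multiple
    records for the same (miRNA, target) pair collapse onto one edge.
    """
    directions = {_norm_mirna(k): (k, v) for k, v in mirna_directions.items()}
    g = nx.Graph()
    n_dropped = 0
    for rec in records:
        key = _norm_mirna(rec.mirna)
        if key not in directions:
            n_dropped += 1
            continue
        canonical, direction = directions[key]
        if not g.has_node(canonical):
            g.add_node(canonical, kind="mirna", direction=direction)
        target = rec.target_symbol
        if not g.has_node(target):
            g.add_node(target, kind="target")
        if g.has_edge(canonical, target):
            g[canonical][target]["provenance"].add(rec.source)
            if rec.score is not None:
                g[canonical][target]["scores"][rec.source] = rec.score
        else:
            scores = {} if rec.score is None else {rec.source: rec.score}
            g.add_edge(canonical, target, provenance={rec.source}, scores=scores)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} record(s) dropped: miRNA not in direction map",
            stacklevel=2,
        )
    return g


def mirna_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "mirna"]


def target_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "target"]


def find_hubs(g: nx.Graph, min_degree: int = 3) -> list[HubTarget]:
    """Targets regulated by at least ``min_degree`` distinct miRNAs.

    Degree counts distinct regulator miRNAs, never supporting records.
    Sorted by degree descending, then target name.
    """
    hubs = []
    for t in target_nodes(g):
        regulators = frozenset(g.neighbors(t))
        if len(regulators) >= min_degree:
            hubs.append(HubTarget(
                target_symbol=t,
                regulators=regulators,
                degree=len(regulators),
                predicted_direction=predict_target_direction(g, regulators),
            ))
    hubs.sort(key=lambda h: (-h.degree, h.target_symbol))
    return hubs


def predict_target_direction(
    g: nx.Graph,
    regulators: frozenset[str] | set[str],
    rule: str = "unanimity",
    majority_fraction: float = 0.5,
) -> str:
    """Predicted direction of target mRNA change from its regulators.

    miRNAs repress: unanimously down-regulated regulators release
    repression, so the target is predicted ``up`` (and vice versa).
    Under ``rule="unanimity"`` any mix yields ``ambiguous``; under
    ``rule="majority"`` the side holding strictly more than
    ``majority_fraction`` of regulators wins.
    """
    dirs = []
    for m in regulators:
        d = g.nodes[m].get("direction")
        if d not in ("up", "down"):
            raise ValueError(f"regulator {m!r} lacks a direction")
        dirs.append(d)
    n_down = dirs.count("down")
    n_up = dirs.count("up")
    if rule == "unanimity":
        if n_up == 0:
            return "up"
        if n_down == 0:
            return "down"
        return "ambiguous"
    if rule == "majority":
        if n_down > majority_fraction * len(dirs):
            return "up"
        if n_up > majority_fraction * len(dirs):
            return "down"
        return "ambiguous"
    raise ValueError(f"unknown rule {rule!r}")


def export_network(
    g: nx.Graph,
    hubs: list[HubTarget],
    out_dir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write node/edge TSVs, a Cytoscape SIF, and GraphML.

    The GraphML round-trips through :func:`read_graphml_network`; the
    TSVs are sorted so repeated exports are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hub_names = {h.target_symbol for h in hubs}

    node_rows = []
    for n, d in sorted(g.nodes(data=True)):
        node_rows.append({
            "id": n,
            "kind": d.get("kind", ""),
            "direction": d.get("direction", ""),
            "degree": g.degree(n),
            "is_hub": n in hub_names,
        })
    nodes = pd.DataFrame(node_rows, columns=["id", "kind", "direction",
                                             "degree", "is_hub"])

    edge_rows = []
    for u, v, d in g.edges(data=True):
        m, t = (u, v) if g.nodes[u].get("kind") == "mirna" else (v, u)
        scores = d.get("scores", {})
        edge_rows.append({
            "mirna": m,
            "target": t,
            "provenance": ",".join(sorted(d.get("provenance", set()))),
            "scores": ";".join(f"{k}={scores[k]:g}" for k in sorted(scores)),
        })
    edges = pd.DataFrame(edge_rows, columns=["mirna", "target",
                                             "provenance", "scores"])
    edges = edges.sort_values(["mirna", "target"]).reset_index(drop=True)

    paths = {
        "nodes": out_dir / f"{prefix}_nodes.tsv",
        "edges": out_dir / f"{prefix}_edges.tsv",
        "sif": out_dir / f"{prefix}.sif",
        "graphml": out_dir / f"{prefix}.graphml",
    }
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    with open(paths["sif"], "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['mirna']}\ttargets\t{row['target']}\n")

    gml = nx.Graph()
    for _, row in nodes.iterrows():
        gml.add_node(row["id"], kind=row["kind"], direction=row["direction"])
    for _, row in edges.iterrows():
        gml.add_edge(row["mirna"], row["target"],
                     provenance=row["provenance"], scores=row["scores"])
    nx.write_graphml(gml, paths["graphml"])
    return paths


def read_graphml_network(path: str | Path) -> nx.Graph:
    """Read back a GraphML export, restoring provenance sets."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for n, d in raw.nodes(data=True):
        attrs = {"kind": d.get("kind", "")}
        if d.get("direction"):
            attrs["direction"] = d["direction"]
        g.add_node(n, **attrs)
    for u, v, d in raw.edges(data=True):
        provenance = set(d.get("provenance", "").split(",")) - {""}
        scores = {}
        for item in (d.get("scores") or "").split(";"):
            if item:
                k, val = item.split("=")
                scores[k] = float(val)
        g.add_edge(u, v, provenance=provenance, scores=scores)
    return g
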