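"""Cross-feeding network extraction from community flux solutions.

For each shared pool metabolite with at least one secreting strain
(exchange flux > epsilon) and one consuming strain (< -epsilon), directed
donor -> recipient edges are created.  When several donors and/or
recipients touch the same metabolite the flux is allocated
proportionally:

    alloc(d, r) = secretion_d * uptake_r / (total_secretion + import)

which is unique, order-independent, and conserves mass: summed over
donors and recipients plus the import-fed share it reproduces every
recipient's uptake.  Pool imports are never attributed to a donor
strain.

A strain appearing as donor in at least one edge and as recipient in
none is a unidirectional donor — the altruist/potentiator signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .community import CommunitySolution
from .core import ModelError, SolverStatus
from .fba import FLUX_EPSILON

__all__ = [
    "CrossFeedingNetwork",
    "ExchangeEvent",
    "MetaboliteClassMap",
    "compare_conditions",
    "default_class_map",
    "export_network",
    "extract_cross_feeding",
    "import_network",
    "network_summary",
]

METABOLITE_CLASSES = (
    "amino_acid", "organic_acid", "carbohydrate", "vitamin", "nucleotide", "other",
)


@dataclass
class MetaboliteClassMap:
    """Metabolite id -> class label; unknown ids default to 'other'."""

    classes: Dict[str, str] = field(default_factory=dict)
    source: str = "builtin"

    def __post_init__(self) -> None:
        bad = {m: c for m, c in self.classes.items() if c not in METABOLITE_CLASSES}
        if bad:
            raise ModelError(f"unknown metabolite class(es): {bad}")

    def class_of(self, met_id: str) -> str:
        return self.classes.get(met_id, "other")

    @classmethod
    def from_tsv(cls, path) -> "MetaboliteClassMap":
        frame = pd.read_csv(path, sep="\t", comment="#")
        if not {"metabolite_id", "class"} <= set(frame.columns):
            raise ModelError(
                f"class map {path} must have columns metabolite_id, class"
            )
        return cls(
            classes=dict(zip(frame["metabolite_id"], frame["class"])),
            source=str(path),
        )


def default_class_map() -> MetaboliteClassMap:
    """Built-in table covering commonly exchanged compounds (amino acids,
    organic acids, sugars, vitamins, nucleotides) plus the toy ids."""
    with resources.files("gemcom.data").joinpath("metabolite_classes.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#")
    return MetaboliteClassMap(
        classes=dict(zip(frame["metabolite_id"], frame["class"])),
        source="gemcom.data/metabolite_classes.tsv",
    )


@dataclass
class ExchangeEvent:
    metabolite: str
    donor: str
    recipient: str
    donor_flux: float
    recipient_flux: float
    allocated_flux: float
    met_class: str = "other"

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ModelError("cross-feeding edge cannot be a self-loop")
        if self.allocated_flux > min(self.donor_flux, self.recipient_flux) + 1e-6:
            raise ModelError(
                f"allocation {self.allocated_flux} exceeds donor/recipient flux "
                f"for {self.metabolite!r}"
            )


@dataclass
class CrossFeedingNetwork:
    nodes: List[str]
    edges: List[ExchangeEvent]
    condition: str = ""

    @property
    def per_class_counts(self) -> Dict[Tuple[str, str, str], int]:
        """(donor, recipient, class) -> number of distinct metabolite types."""
        mets: Dict[Tuple[str, str, str], Set[str]] = {}
        for e in self.edges:
            mets.setdefault((e.donor, e.recipient, e.met_class), set()).add(e.metabolite)
        return {key: len(v) for key, v in mets.items()}

    @property
    def unidirectional_donors(self) -> Set[str]:
        donors = {e.donor for e in self.edges}
        recipients = {e.recipient for e in self.edges}
        return donors - recipients

    @property
    def metabolites(self) -> Set[str]:
        return {e.metabolite for e in self.edges}


def extract_cross_feeding(
    solution: CommunitySolution,
    class_map: Optional[MetaboliteClassMap] = None,
    epsilon: float = FLUX_EPSILON,
    condition: str = "",
) -> CrossFeedingNetwork:
    """Directed donor -> recipient edges per metabolite from a solution.

    Requires an optimal solution; fluxes within ``epsilon`` of zero never
    create edges, so LP-degenerate noise is suppressed.
    """
    if solution.status is not SolverStatus.OPTIMAL:
        raise ModelError("cross-feeding requires an optimal solution")
    if class_map is None:
        class_map = MetaboliteClassMap()
    nodes = sorted(solution.strain_biomass)
    edges: List[ExchangeEvent] = []
    for met_id in sorted(solution.pool_flows):
        flow = solution.pool_flows[met_id]
        donors = {k: v for k, v in flow.per_strain.items() if v > epsilon}
        recipients = {k: -v for k, v in flow.per_strain.items() if v < -epsilon}
        if not donors or not recipients:
            continue
        denom = sum(donors.values()) + max(flow.imported, 0.0)
        met_class = class_map.class_of(met_id)
        for donor, d_flux in sorted(donors.items()):
            for recipient, r_flux in sorted(recipients.items()):
                allocated = d_flux * r_flux / denom
                if allocated <= epsilon:
                    continue
                edges.append(
                    ExchangeEvent(
                        metabolite=met_id,
                        donor=donor,
                        recipient=recipient,
                        donor_flux=d_flux,
                        recipient_flux=r_flux,
                        allocated_flux=allocated,
                        met_class=met_class,
                    )
                )
    return CrossFeedingNetwork(nodes=nodes, edges=edges, condition=condition)


def network_summary(
    network: CrossFeedingNetwork,
    conditions: Optional[Sequence[CrossFeedingNetwork]] = None,
) -> Dict[str, object]:
    """Degrees, net-donor flags, per-class totals, and the potentiator
    signature (donor in every supplied condition, recipient in none).

    When ``conditions`` is omitted the signature is evaluated on the
    single network.
    """
    nets = list(conditions) if conditions else [network]
    per_strain: Dict[str, Dict[str, object]] = {}
    donated: Dict[str, Set[str]] = {s: set() for s in network.nodes}
    received: Dict[str, Set[str]] = {s: set() for s in network.nodes}
    for e in network.edges:
        donated.setdefault(e.donor, set()).add(e.metabolite)
        received.setdefault(e.recipient, set()).add(e.metabolite)
    for strain in network.nodes:
        out_deg = len(donated.get(strain, ()))
        in_deg = len(received.get(strain, ()))
        per_strain[strain] = {
            "out_degree": out_deg,
            "in_degree": in_deg,
            "net_donor": out_deg > in_deg,
        }
    per_class: Dict[str, int] = {}
    for (_d, _r, met_class), count in network.per_class_counts.items():
        per_class[met_class] = per_class.get(met_class, 0) + count
    potentiators = set(network.nodes)
    for net in nets:
        donors = {e.donor for e in net.edges}
        recipients = {e.recipient for e in net.edges}
        potentiators &= donors
        potentiators -= recipients
    return {
        "per_strain": per_strain,
        "per_class_exchanged_types": per_class,
        "total_edges": len(network.edges),
        "total_metabolite_types": len(network.metabolites),
        "unidirectional_donors": sorted(network.unidirectional_donors),
        "potentiator_signature": sorted(potentiators),
    }


def compare_conditions(
    networks: Mapping[str, CrossFeedingNetwork]
) -> pd.DataFrame:
    """Exchanged-type counts per (donor, recipient, class) across >= 2
    conditions, their pairwise-to-first differences, and the metabolites
    unique to each condition."""
    if len(networks) < 2:
        raise ModelError("need at least two conditions to compare")
    labels = list(networks)
    strain_sets = {label: set(net.nodes) for label, net in networks.items()}
    first = strain_sets[labels[0]]
    for label, s in strain_sets.items():
        if s != first:
            raise ModelError(
                f"condition {label!r} covers strains {sorted(s)}, "
                f"expected {sorted(first)}"
            )
    keys: Set[Tuple[str, str, str]] = set()
    counts: Dict[str, Dict[Tuple[str, str, str], int]] = {}
    for label, net in networks.items():
        counts[label] = net.per_class_counts
        keys |= set(counts[label])
    rows = []
    base = labels[0]
    for donor, recipient, met_class in sorted(keys):
        row: Dict[str, object] = {
            "donor": donor, "recipient": recipient, "class": met_class,
        }
        for label in labels:
            row[f"types[{label}]"] = counts[label].get((donor, recipient, met_class), 0)
        for label in labels[1:]:
            row[f"delta[{label}-{base}]"] = (
                row[f"types[{label}]"] - row[f"types[{base}]"]
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    unique: Dict[str, List[str]] = {}
    all_mets = {label: net.metabolites for label, net in networks.items()}
    for label in labels:
        others = set().union(*(m for l2, m in all_mets.items() if l2 != label))
        unique[label] = sorted(all_mets[label] - others)
    frame.attrs["unique_metabolites"] = unique
    return frame


def to_multigraph(network: CrossFeedingNetwork) -> nx.MultiDiGraph:
    graph = nx.MultiDiGraph(condition=network.condition)
    for node in network.nodes:
        graph.add_node(node, strain_id=node)
    for e in network.edges:
        graph.add_edge(
            e.donor,
            e.recipient,
            metabolite=e.metabolite,
            met_class=e.met_class,
            allocated_flux=e.allocated_flux,
            donor_flux=e.donor_flux,
            recipient_flux=e.recipient_flux,
        )
    return graph


def export_network(network: CrossFeedingNetwork, path, format: str = "graphml") -> None:
    """GraphML (node attr strain_id; edge attrs metabolite, class, flux)
    or a flat edge TSV; both round-trip through :func:`import_network`."""
    if format == "graphml":
        nx.write_graphml(to_multigraph(network), path)
    elif format == "edge_tsv":
        rows = [
            {
                "donor": e.donor,
                "recipient": e.recipient,
                "metabolite": e.metabolite,
                "class": e.met_class,
                "allocated_flux": e.allocated_flux,
                "donor_flux": e.donor_flux,
                "recipient_flux": e.recipient_flux,
                "condition": network.condition,
            }
            for e in network.edges
        ]
        pd.DataFrame(
            rows,
            columns=[
                "donor", "recipient", "metabolite", "class", "allocated_flux",
                "donor_flux", "recipient_flux", "condition",
            ],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ModelError(f"unknown export format {format!r}")


def import_network(path, format: str = "graphml") -> CrossFeedingNetwork:
    if format == "graphml":
        graph = nx.read_graphml(path, force_multigraph=True)
        edges = [
            ExchangeEvent(
                metabolite=data["metabolite"],
                donor=u,
                recipient=v,
                donor_flux=float(data["donor_flux"]),
                recipient_flux=float(data["recipient_flux"]),
                allocated_flux=float(data["allocated_flux"]),
                met_class=data["met_class"],
            )
            for u, v, data in graph.edges(data=True)
        ]
        return CrossFeedingNetwork(
            nodes=sorted(graph.nodes),
            edges=edges,
            condition=str(graph.graph.get("condition", "")),
        )
    if format == "edge_tsv":
        frame = pd.read_csv(path, sep="\t")
        edges = [
            ExchangeEvent(
                metabolite=row["metabolite"],
                donor=row["donor"],
                recipient=row["recipient"],
                donor_flux=float(row["donor_flux"]),
                recipient_flux=float(row["recipient_flux"]),
                allocated_flux=float(row["allocated_flux"]),
                met_class=row["class"],
            )
            for _, row in frame.iterrows()
        ]
        nodes = sorted({e.donor for e in edges} | {e.recipient for e in edges})
        condition = str(frame["condition"].iloc[0]) if len(frame) else ""
        return CrossFeedingNetwork(nodes=nodes, edges=edges, condition=condition)
    raise ModelError(f"unknown import format {format!r}")
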