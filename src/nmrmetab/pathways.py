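"""Pathway over-representation, topology impact and the metabolite-protein
network.

Enrichment is the standard hypergeometric upper tail over a compound
universe, BH-adjusted across pathways. Topology impact is the sum of
normalized betweenness centralities of the matched compounds divided by the
pathway total (on graphs where every node has zero betweenness, e.g.
complete graphs, uniform node weights are substituted so a full match still
scores 1). Pathways with impact strictly above the screening threshold
(default 0.1) are retained, ranked by impact with enrichment p as the
tiebreak.

The packaged pathway graphs are small hand-curated synthetic sketches of
the corresponding KEGG maps (see ``nmrmetab.data``); they reproduce the
computation, not the database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .biomarkers import normalize_name
from .data import PATHWAY_INDEX, PROTEIN_MAP, fixture_path

DEFAULT_IMPACT_THRESHOLD = 0.1

#: the curated hypertension-related protein set
CURATED_PROTEINS = frozenset(
    {"TH", "CBS", "DDC", "CTH", "TYR", "HDC", "PLD2", "AGXT2", "KAT", "ALT"}
)


@dataclass
class PathwayGraph:
    id: str
    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() < 2:
            raise ValueError(f"{self.id}: pathway needs at least 2 nodes")
        if not nx.is_connected(self.graph):
            warnings.warn(f"pathway {self.id} ({self.name}) is not connected",
                          stacklevel=2)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    matched: list[str]
    enrichment_p: float
    impact: float
    enrichment_p_adjusted: float | None = None


@dataclass
class MetaboliteProteinMap:
    edges: list[tuple[str, str]]  # (metabolite, protein symbol)

    def __post_init__(self) -> None:
        bad = {p for _, p in self.edges} - CURATED_PROTEINS
        if bad:
            raise ValueError(f"proteins outside the curated set: {sorted(bad)}")


def load_pathways(index_path: str | Path | None = None) -> list[PathwayGraph]:
    """Load the pathway graph fixtures listed in an index CSV."""
    index_path = fixture_path(PATHWAY_INDEX) if index_path is None else Path(index_path)
    base = Path(index_path).parent
    index = pd.read_csv(index_path)
    out = []
    for _, row in index.iterrows():
        edges = pd.read_csv(base / row["file"], sep="\t", header=None,
                            names=["u", "v"])
        g = nx.Graph()
        g.add_edges_from(
            (normalize_name(u), normalize_name(v))
            for u, v in zip(edges["u"], edges["v"])
        )
        out.append(PathwayGraph(str(row["id"]), str(row["name"]), g))
    return out


def load_protein_map(path: str | Path | None = None) -> MetaboliteProteinMap:
    path = fixture_path(PROTEIN_MAP) if path is None else Path(path)
    frame = pd.read_csv(path)
    return MetaboliteProteinMap(
        edges=[(str(m), str(p)) for m, p in zip(frame["metabolite"], frame["protein"])]
    )


def _normalized_set(names: Iterable[str]) -> set[str]:
    return {normalize_name(n) for n in names}


def enrich(
    biomarkers: Iterable[str],
    pathways: Sequence[PathwayGraph],
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation p per pathway, BH-adjusted.

    ``background`` defaults to the union of all pathway nodes. Biomarkers
    absent from the background cannot be drawn in the sampling model; they
    are excluded with a warning rather than failing the analysis.
    """
    marks = _normalized_set(biomarkers)
    universe = (
        set().union(*(p.nodes for p in pathways))
        if background is None
        else _normalized_set(background)
    )
    for p in pathways:
        if not p.nodes <= universe:
            raise ValueError(f"{p.id}: background must contain all pathway nodes")
    unmapped = marks - universe
    if unmapped:
        warnings.warn(f"biomarkers not in the compound universe, excluded: "
                      f"{sorted(unmapped)}", stacklevel=2)
    drawn = marks & universe
    rows = []
    for p in pathways:
        k = len(drawn & p.nodes)
        pval = float(
            stats.hypergeom.sf(k - 1, len(universe), len(p.nodes), len(drawn))
        ) if drawn else 1.0
        rows.append((p.id, p.name, k, min(pval, 1.0)))
    frame = pd.DataFrame(rows, columns=["pathway_id", "name", "hits", "p"])
    frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame.set_index("pathway_id")


def topology_impact(biomarkers: Iterable[str], pathway: PathwayGraph) -> float:
    """Relative-betweenness pathway impact in [0, 1]."""
    if pathway.graph.number_of_nodes() == 0:
        raise ValueError("empty pathway graph")
    marks = _normalized_set(biomarkers)
    bc = nx.betweenness_centrality(pathway.graph, normalized=True)
    total = sum(bc.values())
    if total <= 0:
        # no through-traffic anywhere (e.g. complete graph): weight uniformly
        n = pathway.graph.number_of_nodes()
        return len(marks & pathway.nodes) / n
    return sum(v for node, v in bc.items() if node in marks) / total


def analyze_pathways(
    biomarkers: Iterable[str],
    pathways: Sequence[PathwayGraph] | None = None,
    background: Iterable[str] | None = None,
) -> list[PathwayResult]:
    """Enrichment + impact for every pathway."""
    pathways = load_pathways() if pathways is None else list(pathways)
    marks = _normalized_set(biomarkers)
    enr = enrich(biomarkers, pathways, background)
    out = []
    for p in pathways:
        out.append(
            PathwayResult(
                pathway_id=p.id,
                name=p.name,
                matched=sorted(marks & p.nodes),
                enrichment_p=float(enr.loc[p.id, "p"]),
                enrichment_p_adjusted=float(enr.loc[p.id, "p_adjusted"]),
                impact=topology_impact(biomarkers, p),
            )
        )
    return out


def screen_pathways(
    results: Sequence[PathwayResult],
    impact_threshold: float = DEFAULT_IMPACT_THRESHOLD,
) -> list[PathwayResult]:
    """Retain pathways with impact strictly above the threshold, sorted by
    impact descending with enrichment p ascending as tiebreak."""
    kept = [r for r in results if r.impact > impact_threshold]
    return sorted(kept, key=lambda r: (-r.impact, r.enrichment_p, r.pathway_id))


def build_metabolite_protein_network(
    biomarkers: Iterable[str], protein_map: MetaboliteProteinMap | None = None
) -> nx.Graph:
    """Bipartite metabolite-protein graph restricted to the biomarkers."""
    protein_map = load_protein_map() if protein_map is None else protein_map
    marks = _normalized_set(biomarkers)
    g = nx.Graph()
    for metabolite, protein in protein_map.edges:
        if normalize_name(metabolite) in marks:
            g.add_node(metabolite, kind="metabolite")
            g.add_node(protein, kind="protein")
            g.add_edge(metabolite, protein)
    if g.number_of_edges() == 0:
        warnings.warn("no biomarker maps to a curated protein; empty network",
                      stacklevel=2)
    return g


def export_edge_list(graph: nx.Graph, path: str | Path) -> Path:
    """Write a simple tab-separated edge list usable by graph viewers."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{u}\t{v}\n")
    return path
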