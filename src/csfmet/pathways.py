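"""Metabolite-set over-representation with topology impact.

Per-pathway enrichment uses the hypergeometric upper tail on the overlap
between a query compound set and the pathway's compound set, with BH FDR
across the whole library. The impact score is the summed relative
betweenness centrality of hit compounds in the pathway's reaction graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from csfmet.diffstats import bh_fdr


@dataclass
class PathwayDef:
    pathway_id: str
    name: str
    compounds: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for a, b in self.edges:
            if a not in self.compounds or b not in self.compounds:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge ({a}, {b}) references "
                    "a compound outside the pathway")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compounds)
        g.add_edges_from(self.edges)
        return g


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int  # hits
    K: int  # pathway size
    p_hyper: float
    fdr: float
    impact: float

    @property
    def coverage(self) -> str:
        return f"{self.k}/{self.K}"


def ora_hypergeometric(
    query: set[str], pathway: PathwayDef, universe: set[str]
) -> tuple[int, int, float]:
    """Hypergeometric over-representation p-value P(X >= k).

    Population = universe size, successes = pathway size, draws = query
    compounds that map into the universe; unmapped query ids are dropped
    with a warning.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not pathway.compounds <= universe:
        raise ValueError(f"pathway {pathway.pathway_id} has compounds outside the universe")
    mapped = query & universe
    if len(mapped) < len(query):
        warnings.warn(
            f"{len(query) - len(mapped)} query compounds not in universe; dropped",
            stacklevel=2)
    K = len(pathway.compounds)
    k = len(mapped & pathway.compounds)
    n = len(mapped)
    p = float(hypergeom.sf(k - 1, len(universe), K, n))
    return k, K, min(p, 1.0)


def pathway_impact(hits: set[str], pathway: PathwayDef) -> float:
    """Relative betweenness-centrality impact of the hit compounds.

    impact = sum of BC over hits / sum of BC over all pathway compounds,
    with impact defined as 0 when the denominator is 0 (e.g. complete
    graphs or pathways with <= 2 nodes). Disconnected graphs are fine: the
    normalization constant is shared by all nodes and cancels in the ratio.
    """
    if not hits <= pathway.compounds:
        raise ValueError("hits must be a subset of the pathway's compounds")
    bc = nx.betweenness_centrality(pathway.graph(), normalized=True)
    denom = sum(bc.values())
    if denom == 0:
        return 0.0
    return sum(bc[v] for v in hits) / denom


def enrich_all(
    query: set[str],
    pathway_library: list[PathwayDef],
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """ORA + impact for every pathway, BH-corrected across the library.

    The default universe is the union of all library compounds. Pathways
    with zero hits stay in the FDR denominator. Results come back sorted by
    raw p ascending (ties by pathway id).
    """
    if not pathway_library:
        raise ValueError("pathway library is empty")
    if universe is None:
        universe = set().union(*(p.compounds for p in pathway_library))
    rows = []
    for pw in pathway_library:
        k, K, p = ora_hypergeometric(query, pw, universe)
        hits = (query & universe) & pw.compounds
        rows.append((pw, k, K, p, pathway_impact(hits, pw)))
    fdrs = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(pw.pathway_id, pw.name, k, K, p, q, imp)
        for (pw, k, K, p, imp), q in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.pathway_id))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"pathway_id": r.pathway_id, "name": r.name, "coverage": r.coverage,
         "p_value": r.p_hyper, "fdr": r.fdr, "impact": r.impact}
        for r in results
    ]).set_index("pathway_id")


def plot_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    """Bubble plot: pathway vs -log10 p, bubble size = impact."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.name for r in results]
    logp = [-math.log10(max(r.p_hyper, 1e-300)) for r in results]
    sizes = [60 + 600 * r.impact for r in results]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(results) + 1.5))
    ax.scatter(logp, range(len(results)), s=sizes, alpha=0.6)
    ax.set_yticks(range(len(results)))
    ax.set_yticklabels(names)
    ax.axvline(-math.log10(0.05), color="red", lw=1)
    ax.set_xlabel("-log10 p")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# GMT + edge-list I/O
# ---------------------------------------------------------------------------

def write_gmt(pathways: list[PathwayDef], path: str | Path) -> None:
    lines = [
        "\t".join([p.pathway_id, p.name, *sorted(p.compounds)]) for p in pathways
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[PathwayDef]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out.append(PathwayDef(parts[0], parts[1], set(parts[2:])))
    return out


def write_edges(pathways: list[PathwayDef], path: str | Path) -> None:
    lines = ["pathway_id\tcompound_a\tcompound_b"]
    for p in pathways:
        for a, b in sorted(p.edges):
            lines.append(f"{p.pathway_id}\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges(path: str | Path, pathways: list[PathwayDef]) -> list[PathwayDef]:
    """Attach edges from a TSV (pathway_id, compound_a, compound_b)."""
    by_id = {p.pathway_id: p for p in pathways}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        pid, a, b = line.split("\t")
        pw = by_id.get(pid)
        if pw is None:
            raise ValueError(f"edge references unknown pathway {pid}")
        if a not in pw.compounds or b not in pw.compounds:
            raise ValueError(f"edge ({a}, {b}) outside pathway {pid}")
        pw.edges.append((a, b))
    return pathways
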