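"""GO over-representation with Bonferroni correction and DAG thinning,
plus subcellular-localization tabulation of candidate lists.

The enrichment statistic is the upper-tail hypergeometric (shared kernel
with :mod:`spaceomics.integration`).  After testing, the term list is
*thinned* to a compact, non-redundant report by applying, in order:

1.  Bonferroni-corrected p <= alpha (multiplicity = number of terms with at
    least one differentially expressed annotation);
2.  background term size within [4, 750] (drops poorly annotated and
    overly broad terms);
3.  more than one differentially expressed gene in the term;
4.  within each branch — the subtree under each direct child of the
    biological_process root — only the two surviving terms of minimal depth
    (shortest is_a distance to the root; ties broken by smaller p, then id);
5.  among terms annotating an identical DE-gene set, only the deepest
    (most specific) term.

Up- and down-regulated candidate lists are analysed in separate runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

from .integration import OverlapSpec, hypergeometric_upper_tail

__all__ = [
    "Ontology",
    "EnrichmentParams",
    "load_obo",
    "propagate_annotations",
    "enrich",
    "thin_terms",
    "assign_localizations",
]

logger = logging.getLogger(__name__)

BP_ROOT_NAME = "biological_process"


@dataclass
class Ontology:
    """is_a DAG of one GO namespace; edges point child -> parent."""

    graph: nx.DiGraph
    root: str

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by is_a edges (excluding the term itself)."""
        return nx.descendants(self.graph, term)

    def depth(self, term: str) -> int:
        """Shortest is_a path length from term to the namespace root."""
        return nx.shortest_path_length(self.graph, term, self.root)

    def branch_roots(self) -> list[str]:
        """Direct children of the namespace root, each heading one branch."""
        return sorted(self.graph.predecessors(self.root))

    def branches_of(self, term: str) -> set[str]:
        """Branch roots whose subtree contains the term (DAG: possibly several)."""
        if term == self.root:
            return set()
        anc = self.ancestors(term) | {term}
        return {b for b in self.branch_roots() if b in anc}


@dataclass(frozen=True)
class EnrichmentParams:
    alpha: float = 0.05
    min_term_size: int = 4
    max_term_size: int = 750
    min_de_hits: int = 2
    terms_per_branch: int = 2


def load_obo(path, namespace: str = "biological_process") -> Ontology:
    """Parse an OBO file into a single-namespace is_a DAG.

    Only ``id``, ``name``, ``namespace`` and ``is_a`` are used; obsolete
    terms are dropped (obonet discards them by default).  Raises if the
    resulting graph is cyclic, naming one offending cycle.
    """
    raw = obonet.read_obo(path)
    keep = [n for n, d in raw.nodes(data=True) if d.get("namespace", namespace) == namespace]
    g = nx.DiGraph()
    for n in keep:
        g.add_node(n, name=raw.nodes[n].get("name", n))
    for child, parent, key in raw.edges(keys=True):
        if key == "is_a" and child in g and parent in g:
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    named = [r for r in roots if g.nodes[r].get("name") == BP_ROOT_NAME]
    root = named[0] if named else max(roots, key=lambda r: len(nx.ancestors(g, r)))
    unreachable = [n for n in g.nodes if n != root and not nx.has_path(g, n, root)]
    if unreachable:
        logger.warning("dropping %d terms that do not reach the root", len(unreachable))
        g.remove_nodes_from(unreachable)
    return Ontology(graph=g, root=root)


def propagate_annotations(annotations: pd.DataFrame, ontology: Ontology) -> pd.DataFrame:
    """Apply the true-path rule: annotate each gene to all ancestor terms.

    ``annotations`` has columns ``gene_id`` and ``term_id``.  Unknown term
    ids are skipped with a warning.  Idempotent.
    """
    pairs: set[tuple[str, str]] = set()
    known = set(ontology.graph.nodes)
    for gene, term in annotations[["gene_id", "term_id"]].itertuples(index=False):
        if term not in known:
            logger.warning("unknown term id %s for gene %s; skipped", term, gene)
            continue
        pairs.add((gene, term))
        for anc in ontology.ancestors(term):
            pairs.add((gene, anc))
    out = pd.DataFrame(sorted(pairs), columns=["gene_id", "term_id"])
    return out


def enrich(
    de_genes,
    background,
    annotations: pd.DataFrame,
    ontology: Ontology,
    params: EnrichmentParams = EnrichmentParams(),
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric over-representation.

    ``annotations`` must already be propagated.  Multiplicity for the
    Bonferroni correction is the number of terms carrying at least one DE
    annotation — terms that cannot reject are not counted as tests.
    Returns one row per tested term with counts, p_raw, p_bonferroni and
    depth; thinning status is assigned by :func:`thin_terms`.
    """
    de = set(de_genes)
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene set")
    if not de <= bg:
        raise ValueError("DE genes must be a subset of the background")
    ann = annotations[annotations["gene_id"].isin(bg)]
    term_genes = ann.groupby("term_id")["gene_id"].agg(set)

    rows = []
    for term, genes in term_genes.items():
        hits = de & genes
        if not hits:
            continue
        spec = OverlapSpec(N=len(bg), k=len(genes), n=len(de), x=len(hits))
        rows.append(
            {
                "term_id": term,
                "term_name": ontology.name(term),
                "n_de_in_term": len(hits),
                "n_background_in_term": len(genes),
                "de_genes_in_term": ",".join(sorted(hits)),
                "p_raw": hypergeometric_upper_tail(spec),
                "depth": ontology.depth(term),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "n_de_in_term", "n_background_in_term", "de_genes_in_term", "p_raw", "depth"],
    )
    m = len(out)
    out["p_bonferroni"] = (out["p_raw"] * m).clip(upper=1.0)
    out["status"] = "retained"
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)


def thin_terms(
    records: pd.DataFrame,
    ontology: Ontology,
    params: EnrichmentParams = EnrichmentParams(),
) -> pd.DataFrame:
    """Assign a final thinning status to each enrichment record.

    ``status`` names the first rule that dropped the term:
    dropped_alpha -> dropped_size -> dropped_hits -> dropped_depth ->
    dropped_redundant; survivors stay ``retained``.
    """
    rec = records.copy()
    status = pd.Series("retained", index=rec.index)

    status[rec["p_bonferroni"] > params.alpha] = "dropped_alpha"
    ok = status == "retained"
    bad_size = ~rec["n_background_in_term"].between(params.min_term_size, params.max_term_size)
    status[ok & bad_size] = "dropped_size"
    ok = status == "retained"
    status[ok & (rec["n_de_in_term"] < params.min_de_hits)] = "dropped_hits"

    # per-branch minimal-depth selection
    surviving = rec.index[status == "retained"]
    selected: set = set()
    for branch in ontology.branch_roots():
        members = [
            i for i in surviving if branch in ontology.branches_of(rec.at[i, "term_id"])
        ]
        members.sort(key=lambda i: (rec.at[i, "depth"], rec.at[i, "p_raw"], rec.at[i, "term_id"]))
        selected.update(members[: params.terms_per_branch])
    for i in surviving:
        if i not in selected:
            status[i] = "dropped_depth"

    # identical-gene-set redundancy: keep the deepest (most specific) term
    surviving = rec.index[status == "retained"]
    by_geneset: dict[str, list] = {}
    for i in surviving:
        by_geneset.setdefault(rec.at[i, "de_genes_in_term"], []).append(i)
    for members in by_geneset.values():
        if len(members) > 1:
            members.sort(key=lambda i: (-rec.at[i, "depth"], rec.at[i, "p_raw"], rec.at[i, "term_id"]))
            for i in members[1:]:
                status[i] = "dropped_redundant"

    rec["status"] = status
    return rec


def assign_localizations(feature_ids, annotation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate consensus subcellular locations for a candidate list.

    ``annotation`` has columns ``feature_id`` and ``location`` (one consensus
    label per feature, SUBA-style).  Features absent from the table are
    labelled ``"unknown"``.  Returns (assignments, distribution) where the
    distribution carries counts and fractions per label.
    """
    dup = annotation[annotation["feature_id"].duplicated(keep=False)]
    conflicts = dup.groupby("feature_id")["location"].nunique()
    if (conflicts > 1).any():
        bad = sorted(conflicts[conflicts > 1].index)
        raise ValueError(f"conflicting location labels for {bad}")
    lookup = annotation.drop_duplicates("feature_id").set_index("feature_id")["location"]
    ids = list(feature_ids)
    labels = [lookup.get(f, "unknown") for f in ids]
    assignments = pd.DataFrame({"feature_id": ids, "location": labels})
    if ids:
        counts = assignments["location"].value_counts()
        distribution = pd.DataFrame(
            {"location": counts.index, "count": counts.values, "fraction": counts.values / len(ids)}
        )
    else:
        distribution = pd.DataFrame(columns=["location", "count", "fraction"])
    return assignments, distribution


def membership_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Term x gene 0/1 membership matrix of retained terms (heat-map input)."""
    retained = records[records["status"] == "retained"]
    genes = sorted({g for s in retained["de_genes_in_term"] for g in s.split(",") if s})
    mat = pd.DataFrame(0, index=retained["term_id"].tolist(), columns=genes, dtype=int)
    for _, row in retained.iterrows():
        for g in row["de_genes_in_term"].split(","):
            if g:
                mat.at[row["term_id"], g] = 1
    return mat
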