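"""Cell-wall GO annotation: filtering, functional classification, summaries.

Highly-variable genes are restricted to the cell-wall transcriptome using
four GO terms covering wall biogenesis and organization, plus an optional
curated gene list; retained genes are then classed into biosynthesis,
modification, and signaling via a gene-family lookup.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Cell-wall GO terms used to define the cell-wall transcriptome:
#: plant-type cell wall biogenesis, cell wall organization, cell wall
#: organization or biogenesis, and cell wall biogenesis.
CELL_WALL_GO_TERMS = frozenset({
    "GO:0009832",
    "GO:0071555",
    "GO:0071554",
    "GO:0042546",
})

GO_ID_RE = re.compile(r"^GO:\d{7}$")

FUNCTION_CATEGORIES = ("biosynthesis", "modification", "signaling")

#: Default gene-family -> function-category map.  Glycosyltransferases and
#: synthases build wall polymers (biosynthesis); expansins, XTHs,
#: peroxidases, pectin-active enzymes and glycosyl hydrolases remodel them
#: (modification); wall-associated and receptor-like kinases sense wall
#: state (signaling).  Overridable via a two-column TSV.
DEFAULT_FAMILY_MAP: dict = {
    "cellulose synthase": "biosynthesis",
    "cellulose synthase-like": "biosynthesis",
    "glycosyltransferase": "biosynthesis",
    "mixed-linkage glucan synthase": "biosynthesis",
    "callose synthase": "biosynthesis",
    "acetyltransferase": "biosynthesis",
    "methyltransferase": "biosynthesis",
    "expansin": "modification",
    "xyloglucan endotransglucosylase/hydrolase": "modification",
    "peroxidase": "modification",
    "pectin methylesterase": "modification",
    "pectate lyase": "modification",
    "polygalacturonase": "modification",
    "glycosyl hydrolase": "modification",
    "laccase": "modification",
    "wall-associated kinase": "signaling",
    "receptor-like kinase": "signaling",
    "leucine-rich repeat kinase": "signaling",
}

DEFAULT_CATEGORY = "modification"


@dataclass
class GOAnnotationSet:
    """Gene -> GO-term mapping plus curated list and gene-family map."""

    gene_to_terms: dict = field(default_factory=dict)
    curated: set = field(default_factory=set)
    families: dict = field(default_factory=dict)

    def terms(self, gene: str) -> frozenset:
        return frozenset(self.gene_to_terms.get(gene, ()))

    def write_tsv(self, path) -> None:
        """Write the mapping as a two-column ``gene_id TAB GO:NNNNNNN`` TSV."""
        with open(path, "w") as fh:
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")

    def write_curated(self, path) -> None:
        Path(path).write_text("".join(f"{g}\n" for g in sorted(self.curated)))

    def write_families(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tfamily\n")
            for gene in sorted(self.families):
                fh.write(f"{gene}\t{self.families[gene]}\n")


def load_gene2go_tsv(path) -> dict:
    """Parse a two-column ``gene TAB GO id`` TSV into a gene -> term-set dict.

    Raises ``ValueError`` naming the offending line for malformed GO ids.
    """
    mapping: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            gene, term = parts[0], parts[1]
            if not GO_ID_RE.match(term):
                raise ValueError(f"{path}:{lineno}: malformed GO id {term!r}")
            mapping.setdefault(gene, set()).add(term)
    return mapping


def load_gaf(path) -> dict:
    """Parse a GAF 2.x association file into a gene -> term-set dict.

    Uses column 2 (DB object id) as the gene identifier and column 5 as
    the GO id; comment lines starting with ``!`` are skipped.
    """
    mapping: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: GAF line has fewer than 5 columns")
            gene, term = cols[1], cols[4]
            if not GO_ID_RE.match(term):
                raise ValueError(f"{path}:{lineno}: malformed GO id {term!r}")
            mapping.setdefault(gene, set()).add(term)
    return mapping


def load_annotations(path, curated_path=None, families_path=None) -> GOAnnotationSet:
    """Load annotations from a GAF or two-column TSV (auto-detected)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!") or len(first.split("\t")) >= 15:
        mapping = load_gaf(path)
    else:
        mapping = load_gene2go_tsv(path)
    curated = set()
    if curated_path is not None:
        curated = {ln.strip() for ln in Path(curated_path).read_text().splitlines() if ln.strip()}
    families = {}
    if families_path is not None:
        fam = pd.read_csv(families_path, sep="\t")
        families = dict(zip(fam["gene_id"], fam["family"]))
    return GOAnnotationSet(gene_to_terms=mapping, curated=curated, families=families)


def propagate_terms(mapping: dict, obo_path) -> dict:
    """Optionally propagate annotations up the ontology graph (off by default
    in the pipeline): each gene inherits all ancestors of its direct terms
    along ``is_a`` edges of the supplied OBO file."""
    import obonet
    import networkx as nx

    graph = obonet.read_obo(obo_path)
    out = {}
    for gene, terms in mapping.items():
        full = set(terms)
        for t in terms:
            if t in graph:
                # edges point child -> parent in obonet's graph
                full |= nx.descendants(graph, t)
        out[gene] = full
    return out


def filter_by_go(genes: Iterable[str], annotations: GOAnnotationSet,
                 terms: frozenset = CELL_WALL_GO_TERMS) -> dict:
    """Restrict a gene set to cell-wall-related genes.

    A gene is retained when it carries at least one of the four cell-wall
    GO terms or appears in the curated list.  Returns an ordered mapping
    ``gene -> tuple of matching tags`` where tags are the matched GO ids
    and/or ``"curated"``.
    """
    retained: dict = {}
    for gene in genes:
        tags = tuple(sorted(annotations.terms(gene) & terms))
        if gene in annotations.curated:
            tags = tags + ("curated",)
        if tags:
            retained[gene] = tags
    return retained


def classify_function(gene: str, annotations: GOAnnotationSet,
                      family_map: Mapping[str, str] | None = None) -> tuple:
    """Assign a gene to biosynthesis / modification / signaling.

    Returns ``(category, flagged)`` where ``flagged`` is True when the
    gene's family is absent from the map and the default category was used.
    """
    family_map = DEFAULT_FAMILY_MAP if family_map is None else family_map
    family = annotations.families.get(gene)
    if family is not None and family in family_map:
        return family_map[family], False
    return DEFAULT_CATEGORY, True


@dataclass
class CWSummary:
    """Counts of cell-wall HVGs by tissue x treatment x category, plus a
    per-gene report with focus-week log-fold changes and trend labels."""

    counts: pd.DataFrame
    gene_table: pd.DataFrame

    def write_tsv(self, counts_path, genes_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        self.gene_table.to_csv(genes_path, sep="\t", index=False)


def trend_label(mean_l: float, band: float) -> str:
    if np.isnan(mean_l):
        return "NA"
    if mean_l > band:
        return "increased"
    if mean_l < -band:
        return "decreased"
    return "no change"


def summarize_counts(cw_tags: Mapping[str, tuple], collection, annotations: GOAnnotationSet,
                     tissue: str, family_map: Mapping[str, str] | None = None,
                     focus_weeks: tuple = (7, 14), trend_band: float = 0.25,
                     period_windows: Mapping[str, tuple] | None = None) -> CWSummary:
    """Build the count summary over the cell-wall HVG set.

    Parameters
    ----------
    cw_tags : mapping
        Output of :func:`filter_by_go` over the merged HVG set.
    collection : HVGCollection
        Result of :func:`wallwise.hvg.build_and_merge_lists`; supplies the
        source-list membership and the per-gene fold-change trajectories.
    tissue : str
        Tissue label for the summary rows.
    period_windows : mapping, optional
        Condition -> (lo, hi) inclusive week window over which the main
        trend is evaluated; defaults to the full course per condition.
    """
    from .config import DROUGHT_WEEKS, POSTFLOWERING_WEEKS

    period_windows = period_windows or {
        "preflowering": DROUGHT_WEEKS, "postflowering": POSTFLOWERING_WEEKS}

    rows = []
    for gene, tags in cw_tags.items():
        category, flagged = classify_function(gene, annotations, family_map)
        treatments = sorted({lab.split(".")[0] for lab in collection.merged.get(gene, [])})
        row = {
            "gene_id": gene, "tissue": tissue, "category": category,
            "category_flagged": flagged, "go_tags": ";".join(tags),
            "source_lists": ";".join(collection.merged.get(gene, [])),
            "treatments": ";".join(treatments),
        }
        for cond in treatments:
            L = collection.gene_trajectory(gene, cond)  # Series week -> mean L
            if L is None:
                continue
            for wk in focus_weeks:
                row[f"L_week{wk}_{cond}"] = float(L.get(wk, np.nan))
                if wk not in L.index:
                    log.warning("week %s absent from design; NA extract for %s", wk, gene)
            lo, hi = period_windows.get(cond, (L.index.min(), L.index.max()))
            in_win = L.loc[(L.index >= lo) & (L.index <= hi)]
            row[f"trend_{cond}"] = trend_label(float(in_win.mean()) if len(in_win) else np.nan,
                                               trend_band)
        rows.append(row)

    gene_table = pd.DataFrame(rows)
    counts = []
    for cond in sorted({c for r in rows for c in r["treatments"].split(";") if c}):
        sub = [r for r in rows if cond in r["treatments"].split(";")]
        for cat in FUNCTION_CATEGORIES:
            counts.append({"tissue": tissue, "treatment": cond, "category": cat,
                           "n_genes": sum(1 for r in sub if r["category"] == cat)})
    counts_df = pd.DataFrame(counts, columns=["tissue", "treatment", "category", "n_genes"])
    return CWSummary(counts=counts_df, gene_table=gene_table)
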