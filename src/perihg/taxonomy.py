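"""Consensus taxonomy for HgcA candidates.

Two independent assigners are reconciled per query protein:

* **similarity**: best alignment hit after threshold filtering
  (E <= 1e-20, identity >= 40%, query coverage >= 80%), ties across
  families resolved by lowest common ancestor;
* **phylogenetic**: placement on a reference tree — the smallest ancestral
  clade of the query containing at least one reference leaf assigns its
  taxon when all its reference leaves agree at the requested rank, and
  nothing otherwise.

The consensus keeps the shared label when both agree; a similarity-only
label is retained but flagged hypothetical.  The agreement percentage
counts queries where the two assigners match at the comparison rank, with
both-unassigned counting as agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

__all__ = [
    "RANKS",
    "TaxonomyLineage",
    "AlignmentHit",
    "PlacementTree",
    "ConsensusRecord",
    "filter_hits",
    "similarity_assign",
    "clade_assign",
    "consensus_compare",
]

RANKS = ("domain", "phylum", "class", "order", "family")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered domain→family lineage; trailing ranks may be unassigned.

    Ranks must be filled top-down: a name at some rank requires names at
    all shallower ranks.
    """

    domain: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        names = self.as_tuple()
        seen_gap = False
        for name in names:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(f"lineage not filled top-down: {names}")

    def as_tuple(self) -> tuple[str | None, ...]:
        return (self.domain, self.phylum, self.class_, self.order, self.family)

    def at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.as_tuple()[RANKS.index(rank)]

    def depth(self) -> int:
        """Number of assigned ranks (0 = fully unassigned)."""
        return sum(n is not None for n in self.as_tuple())

    def truncate(self, rank: str) -> "TaxonomyLineage":
        """Lineage cut off below ``rank``."""
        idx = RANKS.index(rank)
        names = [n if i <= idx else None for i, n in enumerate(self.as_tuple())]
        return TaxonomyLineage(*names)

    def lca(self, other: "TaxonomyLineage") -> "TaxonomyLineage":
        """Deepest shared prefix of two lineages."""
        names: list[str | None] = []
        agree = True
        for a, b in zip(self.as_tuple(), other.as_tuple()):
            if agree and a is not None and a == b:
                names.append(a)
            else:
                agree = False
                names.append(None)
        return TaxonomyLineage(*names)

    @classmethod
    def from_names(cls, names) -> "TaxonomyLineage":
        names = list(names)[: len(RANKS)]
        names += [None] * (len(RANKS) - len(names))
        clean = [None if n in (None, "", "unassigned", "NA") else str(n) for n in names]
        return cls(*clean)

    def __str__(self) -> str:
        return ";".join(n if n is not None else "unassigned" for n in self.as_tuple())


UNASSIGNED = TaxonomyLineage()


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-vs-reference alignment hit with subject lineage."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage: float
    bit_score: float
    subject_lineage: TaxonomyLineage

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent identity outside [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise ValueError("query coverage outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


def filter_hits(
    hits: list[AlignmentHit],
    max_evalue: float = 1e-20,
    min_identity: float = 40.0,
    min_query_coverage: float = 80.0,
) -> list[AlignmentHit]:
    """Keep hits passing all three thresholds (inclusive), order preserved."""
    return [
        h
        for h in hits
        if h.evalue <= max_evalue
        and h.percent_identity >= min_identity
        and h.query_coverage >= min_query_coverage
    ]


def similarity_assign(
    hits: list[AlignmentHit], rank: str = "family"
) -> TaxonomyLineage:
    """Best-hit taxonomy for one query's filtered hits.

    Highest bit score wins; exact score ties disagreeing at ``rank``
    resolve to the LCA of the tied hits (which may leave ``rank``
    unassigned).  No hits → fully unassigned.
    """
    if not hits:
        return UNASSIGNED
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    best_score = max(h.bit_score for h in hits)
    tied = [h for h in hits if h.bit_score == best_score]
    lineage = tied[0].subject_lineage
    for h in tied[1:]:
        lineage = lineage.lca(h.subject_lineage)
    return lineage.truncate(rank)


@dataclass
class PlacementTree:
    """Rooted reference tree with query tips grafted in.

    Every non-query leaf carries a lineage; query leaves are the sequences
    to classify.  The Newick topology is used as written (no re-rooting).
    """

    topology: TreeNode
    leaf_taxa: dict[str, TaxonomyLineage]
    query_leaves: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        tips = {t.name for t in self.topology.tips()}
        missing = self.query_leaves - tips
        if missing:
            raise ValueError(f"query leaves absent from tree: {sorted(missing)}")
        unlabeled = tips - self.query_leaves - set(self.leaf_taxa)
        if unlabeled:
            raise ValueError(f"reference leaves without lineage: {sorted(unlabeled)}")


def clade_assign(
    tree: PlacementTree, query: str, rank: str = "family"
) -> TaxonomyLineage:
    """Clade-based taxonomy of one query leaf.

    Walks rootward from the query to the smallest ancestral node containing
    at least one reference leaf; if all reference leaves under that node
    share one name at ``rank`` the query takes the lineage truncated at
    ``rank``, otherwise it stays unassigned.  Other query leaves are
    ignored throughout.
    """
    if query not in tree.query_leaves:
        raise ValueError(f"{query!r} is not a query leaf of the tree")
    node = tree.topology.find(query)
    for anc in node.ancestors():
        ref_names = [
            t.name for t in anc.tips() if t.name not in tree.query_leaves
        ]
        if not ref_names:
            continue
        labels = {tree.leaf_taxa[n].at(rank) for n in ref_names}
        if len(labels) == 1 and None not in labels:
            # all references in the smallest containing clade agree
            return tree.leaf_taxa[ref_names[0]].truncate(rank)
        return UNASSIGNED
    return UNASSIGNED


@dataclass(frozen=True)
class ConsensusRecord:
    """Reconciled taxonomy for one query."""

    query_id: str
    tax_similarity: TaxonomyLineage
    tax_tree: TaxonomyLineage
    agree: bool
    tax_consensus: TaxonomyLineage
    hypothetical: bool


def _comparison_rank(a: TaxonomyLineage, b: TaxonomyLineage, rank: str | None) -> str:
    if rank is not None:
        return rank
    depth = min(a.depth(), b.depth())
    if depth == 0:
        return "family"
    return RANKS[min(depth, len(RANKS)) - 1]


def consensus_compare(
    assignments: list[tuple[str, TaxonomyLineage, TaxonomyLineage]],
    rank: str | None = None,
) -> tuple[list[ConsensusRecord], float]:
    """Reconcile similarity and tree assignments and compute agreement.

    ``assignments`` holds ``(query_id, tax_similarity, tax_tree)`` triples.
    ``rank`` fixes the comparison rank; by default each pair is compared at
    the most specific rank both assigners reached (family when both are
    fully unassigned).  Both-unassigned counts as agreement.  Returns the
    filled records and the agreement percentage.
    """
    if not assignments:
        raise ValueError("no assignments to compare")
    records = []
    n_agree = 0
    for query_id, tax_sim, tax_tree in assignments:
        cmp_rank = _comparison_rank(tax_sim, tax_tree, rank)
        a, b = tax_sim.at(cmp_rank), tax_tree.at(cmp_rank)
        agree = a == b  # both None (unassigned) counts as agreement
        if agree:
            n_agree += 1
            consensus = tax_sim if tax_sim.depth() >= tax_tree.depth() else tax_tree
            hypothetical = False
        else:
            # keep the similarity taxonomy but flag it as hypothetical
            consensus = tax_sim
            hypothetical = True
        records.append(
            ConsensusRecord(query_id, tax_sim, tax_tree, agree, consensus, hypothetical)
        )
    return records, 100.0 * n_agree / len(records)
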