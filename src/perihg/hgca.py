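"""HgcA screening of predicted proteins.

HgcA is the corrinoid iron-sulfur protein required (with HgcB) for
microbial Hg methylation.  Candidates come from a profile search of
predicted proteins; this module applies the classification on top of the
search scores:

* bit score >= 100 makes a candidate; >= 164 together with one of the six
  conserved cap-helix motifs (NVWCAAGK and variants) makes a *complete*
  identification, 100 <= score without the motif a *partial* one (contigs
  too short to span the motif region);
* each surviving candidate contributes its contig's mean read coverage to
  a taxon-level abundance;
* merA (EC 1.16.1.1) and merB (EC 4.99.1.2) demethylation genes are
  counted from functional annotations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

from perihg.taxonomy import TaxonomyLineage

__all__ = [
    "CONSERVED_MOTIFS",
    "ProteinRecord",
    "ScreenConfig",
    "HgcACandidate",
    "MerGeneHit",
    "scan_conserved_motifs",
    "assign_confidence_tier",
    "screen_candidates",
    "coverage_weighted_abundance",
    "screen_mer_genes",
]

#: Conserved cap-helix motif variants diagnostic for HgcA.
CONSERVED_MOTIFS = (
    "NVWCAAGK",
    "NVWCASGK",
    "NVWCAGGK",
    "NIWCAAGK",
    "NIWCAGGK",
    "NVWCSAGK",
)

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBXZJUO*]+$")

MERA_EC = "1.16.1.1"
MERB_EC = "4.99.1.2"


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its contig context."""

    protein_id: str
    contig_id: str
    sequence: str
    contig_length: int | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        if not _AA_RE.match(self.sequence):
            raise ValueError(f"{self.protein_id}: non-amino-acid characters")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError("coverage must be non-negative")


@dataclass(frozen=True)
class ScreenConfig:
    """Score thresholds and motif set for the HgcA screen."""

    min_score_candidate: float = 100.0
    min_score_complete: float = 164.0
    motifs: tuple[str, ...] = CONSERVED_MOTIFS

    def __post_init__(self) -> None:
        if self.min_score_complete < self.min_score_candidate:
            raise ValueError("complete threshold below candidate threshold")
        if any(len(m) != 8 for m in self.motifs):
            raise ValueError("all motifs must be 8-mers")


@dataclass(frozen=True)
class HgcACandidate:
    """A screened protein with its confidence tier and taxonomy slots."""

    protein: ProteinRecord
    hmm_score: float
    motif_found: bool
    motif_hit: str | None
    tier: Literal["complete", "partial", "rejected"]
    abundance: float | None = None
    taxonomy_similarity: TaxonomyLineage | None = None
    taxonomy_tree: TaxonomyLineage | None = None
    taxonomy_consensus: TaxonomyLineage | None = None


@dataclass(frozen=True)
class MerGeneHit:
    """Count of merA or merB annotations in one sample."""

    sample_id: str
    gene: Literal["merA", "merB"]
    ec_number: str
    count: int

    def __post_init__(self) -> None:
        if self.ec_number not in (MERA_EC, MERB_EC):
            raise ValueError(f"unexpected EC number {self.ec_number}")
        if self.count < 0:
            raise ValueError("negative count")


def scan_conserved_motifs(
    sequence: str, cfg: ScreenConfig | None = None
) -> tuple[bool, str | None]:
    """Exact-substring scan for the conserved motifs.

    The leftmost match wins; position ties break by motif list order.
    An empty sequence simply finds nothing.
    """
    cfg = cfg or ScreenConfig()
    best: tuple[int, int] | None = None  # (position, motif index)
    for idx, motif in enumerate(cfg.motifs):
        pos = sequence.find(motif)
        if pos >= 0 and (best is None or (pos, idx) < best):
            best = (pos, idx)
    if best is None:
        return False, None
    return True, cfg.motifs[best[1]]


def assign_confidence_tier(
    score: float, motif_found: bool, cfg: ScreenConfig | None = None
) -> str:
    """Classify a scored hit: complete / partial / rejected.

    Thresholds are inclusive.  A score past the complete threshold without
    the motif stays partial, with a warning (truncated contig or anomaly).
    """
    cfg = cfg or ScreenConfig()
    if score < cfg.min_score_candidate:
        return "rejected"
    if score >= cfg.min_score_complete:
        if motif_found:
            return "complete"
        warnings.warn(
            f"score {score} >= {cfg.min_score_complete} but conserved motif "
            "absent; kept as partial (contig may be too short)",
            stacklevel=2,
        )
    return "partial"


def screen_candidates(
    scored: list[tuple[ProteinRecord, float]],
    cfg: ScreenConfig | None = None,
    keep_rejected: bool = False,
) -> list[HgcACandidate]:
    """Run the motif scan and tier assignment over scored proteins.

    Rejected proteins are dropped unless ``keep_rejected``.
    """
    cfg = cfg or ScreenConfig()
    out = []
    for protein, score in scored:
        found, hit = scan_conserved_motifs(protein.sequence, cfg)
        tier = assign_confidence_tier(score, found, cfg)
        if tier == "rejected" and not keep_rejected:
            continue
        out.append(HgcACandidate(protein, score, found, hit, tier))
    return out


def with_taxonomy(
    candidates: list[HgcACandidate],
    consensus: dict[str, tuple[TaxonomyLineage, TaxonomyLineage, TaxonomyLineage]],
) -> list[HgcACandidate]:
    """Attach (similarity, tree, consensus) lineages keyed by protein id."""
    out = []
    for c in candidates:
        tax = consensus.get(c.protein.protein_id)
        if tax is None:
            out.append(c)
        else:
            sim, tree, cons = tax
            out.append(
                replace(
                    c,
                    taxonomy_similarity=sim,
                    taxonomy_tree=tree,
                    taxonomy_consensus=cons,
                )
            )
    return out


def coverage_weighted_abundance(
    candidates: list[HgcACandidate], rank: str = "family"
) -> tuple[dict[str, float], dict[str, float]]:
    """Coverage-weighted abundance per taxon at ``rank``.

    Each non-rejected candidate contributes 1 x its contig coverage to the
    taxon named by its consensus lineage at ``rank`` ("unassigned" when the
    lineage is missing or blank there).  Returns absolute sums and
    relative fractions.
    """
    usable = [c for c in candidates if c.tier != "rejected"]
    missing = [c.protein.protein_id for c in usable if c.protein.coverage is None]
    if missing:
        raise ValueError(f"candidates without coverage: {missing}")
    totals: dict[str, float] = {}
    for c in usable:
        lineage = c.taxonomy_consensus
        taxon = lineage.at(rank) if lineage is not None else None
        key = taxon if taxon is not None else "unassigned"
        totals[key] = totals.get(key, 0.0) + c.protein.coverage
    grand = sum(totals.values())
    fractions = {k: (v / grand if grand > 0 else 0.0) for k, v in totals.items()}
    return totals, fractions


def screen_mer_genes(annotations, sample_id: str) -> list[MerGeneHit]:
    """Count merA/merB annotations for one sample.

    ``annotations`` is an iterable of (gene_id, ec_number) pairs or a
    DataFrame with those columns.  Rows whose EC string is not a dotted
    number are skipped with a warning; zero counts are reported explicitly.
    """
    if hasattr(annotations, "itertuples"):
        pairs = [(r.gene_id, r.ec_number) for r in annotations.itertuples(index=False)]
    else:
        pairs = list(annotations)
    ec_re = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
    counts = {MERA_EC: 0, MERB_EC: 0}
    for gene_id, ec in pairs:
        ec = str(ec).strip()
        if not ec_re.match(ec):
            warnings.warn(f"gene {gene_id}: malformed EC {ec!r}; skipped", stacklevel=2)
            continue
        if ec in counts:
            counts[ec] += 1
    return [
        MerGeneHit(sample_id, "merA", MERA_EC, counts[MERA_EC]),
        MerGeneHit(sample_id, "merB", MERB_EC, counts[MERB_EC]),
    ]
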