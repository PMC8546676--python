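"""Readers and writers for the tabular and sequence formats the pipeline
consumes: tracer TSV, speciation TSV, protein FASTA, profile-search tabular
output, coverage/annotation TSVs, 12-column alignment tables, Newick trees
with leaf-lineage maps, and ASV count/lineage/metadata TSVs.

Censored tracer measurements are stored as the literal ``ND`` in the
``mmhg200_t`` column; reading restores them as value = detection limit with
a censored flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from perihg.hgca import ProteinRecord
from perihg.taxonomy import RANKS, AlignmentHit, PlacementTree, TaxonomyLineage

__all__ = [
    "parse_hmm_hits",
    "read_tracer_table",
    "write_tracer_table",
    "read_speciation_table",
    "read_protein_fasta",
    "read_hmm_table",
    "join_hmm_hits",
    "read_coverage_table",
    "read_annotation_table",
    "read_alignment_hits",
    "read_lineage_table",
    "read_placement_tree",
    "read_asv_tables",
]

TRACER_COLUMNS = [
    "site_id",
    "replicate_id",
    "ihg200_0",
    "mmhg198_0",
    "mmhg200_t",
    "mmhg198_t",
    "t_days",
    "lod_mmhg",
]


def read_tracer_table(path) -> pd.DataFrame:
    """Read a tracer-incubation TSV; "ND" product values become censored."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "replicate_id": str})
    missing = set(TRACER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    censored = df["mmhg200_t"].astype(str).str.strip().str.upper() == "ND"
    df["mmhg200_censored"] = censored
    df.loc[censored, "mmhg200_t"] = df.loc[censored, "lod_mmhg"]
    df["mmhg200_t"] = df["mmhg200_t"].astype(float)
    return df


def write_tracer_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "mmhg200_censored" in out.columns:
        flagged = out["mmhg200_censored"].astype(bool)
        out["mmhg200_t"] = out["mmhg200_t"].astype(object)
        out.loc[flagged, "mmhg200_t"] = "ND"
        out = out.drop(columns=["mmhg200_censored"])
    out.to_csv(path, sep="\t", index=False)


def read_speciation_table(path) -> pd.DataFrame:
    """Speciation TSV keyed by site_id and matrix; blank cells = absent."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "matrix": str})
    for col in ("mmhg", "thg", "ihg"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def read_protein_fasta(path) -> dict[str, ProteinRecord]:
    """Protein FASTA whose headers may carry ``key=value`` contig fields.

    Recognised fields: ``contig`` (contig id, default = protein id) and
    ``contig_len`` (bp).
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            token.split("=", 1) for token in rec.description.split()[1:] if "=" in token
        )
        records[rec.id] = ProteinRecord(
            protein_id=rec.id,
            contig_id=fields.get("contig", rec.id),
            sequence=str(rec.seq).upper(),
            contig_length=int(fields["contig_len"]) if "contig_len" in fields else None,
        )
    return records


def read_hmm_table(path) -> list[tuple[str, float]]:
    """Per-target profile-search table: (target id, full-sequence bit score).

    Accepts the whitespace-separated per-target table layout of hmmer's
    ``--tblout`` (score in column 6) as well as a simple two-column
    ``id<TAB>score`` file.  Comment lines start with ``#``.
    """
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) >= 6:
                hits.append((parts[0], float(parts[5])))
            elif len(parts) == 2:
                hits.append((parts[0], float(parts[1])))
            else:
                raise ValueError("unrecognised column count")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed hit row ({exc})") from None
    return hits


def join_hmm_hits(
    hits: list[tuple[str, float]],
    proteins: dict[str, ProteinRecord],
    coverage: dict[str, float] | None = None,
) -> list[tuple[ProteinRecord, float]]:
    """Resolve hit ids against the FASTA and attach contig coverage."""
    from dataclasses import replace

    joined = []
    for target, score in hits:
        if target not in proteins:
            raise KeyError(f"hit id {target!r} absent from protein FASTA")
        rec = proteins[target]
        if coverage is not None:
            if rec.contig_id not in coverage:
                raise KeyError(f"contig {rec.contig_id!r} absent from coverage table")
            rec = replace(rec, coverage=float(coverage[rec.contig_id]))
        joined.append((rec, score))
    return joined


def read_coverage_table(path) -> dict[str, float]:
    """Coverage TSV with columns contig_id, mean_depth."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    return dict(zip(df["contig_id"], df["mean_depth"].astype(float)))


def read_annotation_table(path) -> pd.DataFrame:
    """Functional-annotation TSV with columns gene_id, ec_number
    (and optionally sample_id)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_lineage_table(path, id_column: str | None = None) -> dict[str, TaxonomyLineage]:
    """TSV mapping an id column to domain..family lineage columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if id_column is None:
        id_column = df.columns[0]
    out = {}
    for d in df.to_dict(orient="records"):
        out[d[id_column]] = TaxonomyLineage.from_names([d.get(r, "") for r in RANKS])
    return out


def read_alignment_hits(
    path,
    subject_lineages: dict[str, TaxonomyLineage],
    query_lengths: dict[str, int] | None = None,
) -> list[AlignmentHit]:
    """12-column tabular alignment hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Query coverage is computed as 100*(qend-qstart+1)/query_length when
    query lengths are supplied; a 13th ``qcovs`` column is used instead
    when present.
    """
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise ValueError(f"{path}:{lineno}: expected >= 12 columns")
        qid, sid = parts[0], parts[1]
        qstart, qend = int(parts[6]), int(parts[7])
        if len(parts) >= 13:
            qcov = float(parts[12])
        elif query_lengths is not None:
            if qid not in query_lengths:
                raise KeyError(f"{path}:{lineno}: unknown query length for {qid!r}")
            qcov = 100.0 * (abs(qend - qstart) + 1) / query_lengths[qid]
        else:
            raise ValueError(
                f"{path}:{lineno}: need query lengths or a 13th qcovs column"
            )
        if sid not in subject_lineages:
            raise KeyError(f"{path}:{lineno}: subject {sid!r} has no lineage")
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=sid,
                percent_identity=float(parts[2]),
                evalue=float(parts[10]),
                query_coverage=min(qcov, 100.0),
                bit_score=float(parts[11]),
                subject_lineage=subject_lineages[sid],
            )
        )
    return hits


def read_placement_tree(
    newick_path, leaf_lineage_path, query_leaves: set[str]
) -> PlacementTree:
    """Newick tree plus leaf→lineage TSV; query leaves carry no lineage."""
    tree = TreeNode.read(str(newick_path), convert_underscores=False)
    leaf_taxa = read_lineage_table(leaf_lineage_path)
    return PlacementTree(tree, leaf_taxa, set(query_leaves))


def read_asv_tables(counts_path, lineage_path, metadata_path):
    """Counts, lineage and metadata TSVs into an AsvTable."""
    from perihg.community import AsvTable

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lineages = pd.read_csv(lineage_path, sep="\t", index_col=0, dtype=str).fillna("")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return AsvTable(counts=counts, lineages=lineages, metadata=metadata)


def parse_hmm_hits(
    hits_path,
    fasta_path,
    coverage_path=None,
) -> list[tuple[ProteinRecord, float]]:
    """Convenience wrapper: read the hit table and FASTA and join them."""
    hits = read_hmm_table(hits_path)
    proteins = read_protein_fasta(fasta_path)
    coverage = read_coverage_table(coverage_path) if coverage_path else None
    return join_hmm_hits(hits, proteins, coverage)
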