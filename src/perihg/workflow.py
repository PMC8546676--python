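"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — simulate (optional) → rates → budget →
screen-hgca → taxonomy → community — writing per-stage TSVs, a run log with
the seed and every threshold actually applied, and a combined JSON report
(site rate table, %MMHg table, candidate/abundance tables, consensus
agreement, ordination and PERMANOVA summaries).  Each stage is a plain
function over files, so stages can be re-run individually from intermediate
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from perihg import budget as budget_mod
from perihg import community as comm
from perihg import hgca, io, taxonomy
from perihg.kinetics import TracerKineticsModel
from perihg.synthetic import SimulationSpec, generate_all

logger = logging.getLogger("perihg")

__all__ = ["RunConfig", "run_pipeline", "rates_stage", "budget_stage",
           "screen_stage", "taxonomy_stage", "community_stage"]


@dataclass
class RunConfig:
    """Pipeline configuration: stage inputs, thresholds and seed.

    When ``simulate`` is true the synthetic generators produce every input
    under ``outdir/simulated`` first; otherwise the per-stage paths must
    point at existing files.
    """

    outdir: str = "perihg_out"
    seed: int = 0
    simulate: bool = True
    tracer_table: str | None = None
    speciation_table: str | None = None
    proteins_fasta: str | None = None
    hmm_table: str | None = None
    coverage_table: str | None = None
    similarity_hits: str | None = None
    subject_lineages: str | None = None
    tree_newick: str | None = None
    leaf_lineages: str | None = None
    query_list: str | None = None
    asv_counts: str | None = None
    asv_lineages: str | None = None
    sample_metadata: str | None = None
    screen: hgca.ScreenConfig = field(default_factory=hgca.ScreenConfig)
    max_evalue: float = 1e-20
    min_identity: float = 40.0
    min_query_coverage: float = 80.0
    lump_threshold: float = 0.02
    n_perm: int = 999
    alpha: float = 0.05
    community_factor: str = "site"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        screen = data.pop("screen", None)
        cfg = cls(**data)
        if screen:
            cfg.screen = hgca.ScreenConfig(**screen)
        return cfg


def _require(path, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no input configured for {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def rates_stage(tracer_table, outdir, alpha: float = 0.05) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = io.read_tracer_table(tracer_table)
    results = TracerKineticsModel.from_dataframe(df).fit(alpha=alpha)
    results.estimates.to_csv(outdir / "rate_estimates.tsv", sep="\t", index=False)
    site_table = results.site_table()
    site_table.to_csv(outdir / "rate_summaries.tsv", sep="\t", index=False)
    (outdir / "rates_summary.txt").write_text(results.summary() + "\n")
    anova = {
        kind: None
        if res is None
        else {"F": res[0], "p": res[1],
              "pairwise": {f"{a}|{b}": p for (a, b), p in res[2].items()}}
        for kind, res in results.anova.items()
    }
    return {"site_rates": site_table.to_dict(orient="records"), "anova": anova}


def budget_stage(speciation_table, outdir, spike_conc: float = 4.0) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = io.read_speciation_table(speciation_table)
    rows = []
    water = []
    for r in df.itertuples(index=False):
        m = budget_mod.SpeciationMeasurement(
            site_id=r.site_id,
            matrix=r.matrix,
            mmhg=None if pd.isna(r.mmhg) else float(r.mmhg),
            thg=None if pd.isna(r.thg) else float(r.thg),
            ihg=None if pd.isna(r.ihg) else float(r.ihg),
        )
        if m.thg is not None and m.mmhg is not None and m.ihg is None:
            m = budget_mod.ihg_by_subtraction(m)
        rows.append(
            {
                "site_id": m.site_id,
                "matrix": m.matrix,
                "mmhg": m.mmhg,
                "thg": m.total(),
                "ihg": m.ihg,
                "percent_mmhg": round(budget_mod.percent_mmhg(m), 1),
            }
        )
        if m.matrix == "water":
            water.append(m)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "speciation.tsv", sep="\t", index=False)
    folds = {}
    if water:
        folds = {
            "thg_fold": budget_mod.spike_fold_ratio(spike_conc, water, "thg"),
            "mmhg_fold": budget_mod.spike_fold_ratio(spike_conc, water, "mmhg"),
        }
    return {"speciation": table.to_dict(orient="records"), "spike_folds": folds}


def screen_stage(proteins_fasta, hmm_table, coverage_table, outdir,
                 cfg: hgca.ScreenConfig | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scored = io.parse_hmm_hits(hmm_table, proteins_fasta, coverage_table)
    candidates = hgca.screen_candidates(scored, cfg)
    table = pd.DataFrame(
        [
            {
                "protein_id": c.protein.protein_id,
                "contig_id": c.protein.contig_id,
                "hmm_score": c.hmm_score,
                "motif_found": c.motif_found,
                "motif_hit": c.motif_hit or "",
                "tier": c.tier,
                "coverage": c.protein.coverage,
            }
            for c in candidates
        ]
    )
    table.to_csv(outdir / "hgca_candidates.tsv", sep="\t", index=False)
    return {
        "n_candidates": len(candidates),
        "n_complete": sum(c.tier == "complete" for c in candidates),
        "n_partial": sum(c.tier == "partial" for c in candidates),
        "_candidates": candidates,
    }


def taxonomy_stage(similarity_hits, subject_lineages, tree_newick, leaf_lineages,
                   query_list, proteins_fasta, outdir,
                   max_evalue=1e-20, min_identity=40.0, min_query_coverage=80.0,
                   candidates=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    queries = [
        q.strip() for q in Path(query_list).read_text().splitlines() if q.strip()
    ]
    subjects = io.read_lineage_table(subject_lineages)
    proteins = io.read_protein_fasta(proteins_fasta)
    qlens = {pid: len(rec.sequence) for pid, rec in proteins.items()}
    hits = io.read_alignment_hits(similarity_hits, subjects, qlens)
    hits = taxonomy.filter_hits(hits, max_evalue, min_identity, min_query_coverage)
    by_query: dict[str, list] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    tree = io.read_placement_tree(tree_newick, leaf_lineages, set(queries))
    assignments = []
    for q in queries:
        sim = taxonomy.similarity_assign(by_query.get(q, []))
        placed = taxonomy.clade_assign(tree, q)
        assignments.append((q, sim, placed))
    records, agreement = taxonomy.consensus_compare(assignments)
    table = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "tax_similarity": str(r.tax_similarity),
                "tax_tree": str(r.tax_tree),
                "agree": r.agree,
                "tax_consensus": str(r.tax_consensus),
                "hypothetical": r.hypothetical,
            }
            for r in records
        ]
    )
    table.to_csv(outdir / "consensus_taxonomy.tsv", sep="\t", index=False)
    result = {"agreement_percent": agreement, "n_queries": len(records)}
    if candidates is not None:
        consensus_map = {
            r.query_id: (r.tax_similarity, r.tax_tree, r.tax_consensus)
            for r in records
        }
        enriched = hgca.with_taxonomy(candidates, consensus_map)
        totals, fractions = hgca.coverage_weighted_abundance(enriched)
        pd.DataFrame(
            [
                {"taxon": k, "abundance": v, "fraction": fractions[k]}
                for k, v in sorted(totals.items(), key=lambda kv: -kv[1])
            ]
        ).to_csv(outdir / "hgca_abundance.tsv", sep="\t", index=False)
        result["abundance"] = totals
        result["abundance_fraction"] = fractions
    return result


def community_stage(asv_counts, asv_lineages, sample_metadata, outdir,
                    factor="site", lump_threshold=0.02, n_perm=999, seed=0) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = io.read_asv_tables(asv_counts, asv_lineages, sample_metadata)
    fractions = comm.relative_abundance(table, rank="phylum")
    fractions.to_csv(outdir / "phylum_fractions.tsv", sep="\t")
    lumped = comm.lump_rare(fractions, lump_threshold)
    lumped.to_csv(outdir / "phylum_fractions_lumped.tsv", sep="\t")
    dm = comm.bray_curtis(fractions_asv(table))
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
        outdir / "bray_curtis.tsv", sep="\t"
    )
    ordination = comm.pcoa(dm)
    ordination.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    results = {}
    for fac in ([factor] if isinstance(factor, str) else factor):
        groups = table.metadata[fac]
        res = comm.permanova(dm, groups, n_perm=n_perm, seed=seed)
        results[fac] = {
            "pseudo_F": res.pseudo_F, "r2": res.r2, "p": res.p, "n_perm": res.n_perm
        }
    mean_phylum = fractions.join(table.metadata["site"]).groupby("site").mean()
    mean_phylum.to_csv(outdir / "phylum_mean_by_site.tsv", sep="\t")
    return {
        "permanova": results,
        "explained_fraction": [float(x) for x in ordination.explained_fraction[:4]],
        "mean_phylum_by_site": mean_phylum.round(4).to_dict(),
    }


def fractions_asv(table: comm.AsvTable) -> pd.DataFrame:
    """Per-sample relative ASV abundances (ordination input)."""
    totals = table.counts.sum(axis=1)
    return table.counts.div(totals, axis=0)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the combined report (also written to
    ``outdir/report.json``).  A stage failure aborts with the stage name,
    keeping earlier outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("run: seed=%s outdir=%s", cfg.seed, outdir)
    logger.info(
        "thresholds: screen=%s evalue<=%g id>=%g qcov>=%g lump<%g n_perm=%d alpha=%g",
        cfg.screen, cfg.max_evalue, cfg.min_identity, cfg.min_query_coverage,
        cfg.lump_threshold, cfg.n_perm, cfg.alpha,
    )
    report: dict = {"seed": cfg.seed, "thresholds": {
        "min_score_candidate": cfg.screen.min_score_candidate,
        "min_score_complete": cfg.screen.min_score_complete,
        "max_evalue": cfg.max_evalue,
        "min_identity": cfg.min_identity,
        "min_query_coverage": cfg.min_query_coverage,
        "lump_threshold": cfg.lump_threshold,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
    }}
    if cfg.simulate:
        sim_dir = outdir / "simulated"
        generate_all(SimulationSpec(seed=cfg.seed), sim_dir)
        cfg.tracer_table = cfg.tracer_table or str(sim_dir / "tracer/tracer.tsv")
        cfg.proteins_fasta = cfg.proteins_fasta or str(sim_dir / "metagenome/proteins.faa")
        cfg.hmm_table = cfg.hmm_table or str(sim_dir / "metagenome/hgca_hits.tbl")
        cfg.coverage_table = cfg.coverage_table or str(sim_dir / "metagenome/coverage.tsv")
        cfg.similarity_hits = cfg.similarity_hits or str(
            sim_dir / "metagenome/similarity_hits.tsv")
        cfg.subject_lineages = cfg.subject_lineages or str(
            sim_dir / "metagenome/subject_lineages.tsv")
        cfg.tree_newick = cfg.tree_newick or str(sim_dir / "tree/reference_tree.nwk")
        cfg.leaf_lineages = cfg.leaf_lineages or str(sim_dir / "tree/leaf_lineages.tsv")
        cfg.query_list = cfg.query_list or str(sim_dir / "tree/query_leaves.txt")
        cfg.asv_counts = cfg.asv_counts or str(sim_dir / "community/asv_counts.tsv")
        cfg.asv_lineages = cfg.asv_lineages or str(
            sim_dir / "community/asv_lineages.tsv")
        cfg.sample_metadata = cfg.sample_metadata or str(
            sim_dir / "community/sample_metadata.tsv")

    def stage(name, fn, *args, **kwargs):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    report["rates"] = stage(
        "rates", rates_stage,
        _require(cfg.tracer_table, "tracer table"), outdir / "rates", cfg.alpha,
    )
    if cfg.speciation_table is not None:
        report["budget"] = stage(
            "budget", budget_stage,
            _require(cfg.speciation_table, "speciation table"), outdir / "budget",
        )
    screen_report = stage(
        "screen-hgca", screen_stage,
        _require(cfg.proteins_fasta, "protein FASTA"),
        _require(cfg.hmm_table, "hmm hit table"),
        _require(cfg.coverage_table, "coverage table"),
        outdir / "screen", cfg.screen,
    )
    candidates = screen_report.pop("_candidates")
    report["screen"] = screen_report
    report["taxonomy"] = stage(
        "taxonomy", taxonomy_stage,
        _require(cfg.similarity_hits, "similarity hits"),
        _require(cfg.subject_lineages, "subject lineages"),
        _require(cfg.tree_newick, "reference tree"),
        _require(cfg.leaf_lineages, "leaf lineages"),
        _require(cfg.query_list, "query list"),
        _require(cfg.proteins_fasta, "protein FASTA"),
        outdir / "taxonomy",
        cfg.max_evalue, cfg.min_identity, cfg.min_query_coverage,
        candidates=candidates,
    )
    report["community"] = stage(
        "community", community_stage,
        _require(cfg.asv_counts, "ASV counts"),
        _require(cfg.asv_lineages, "ASV lineages"),
        _require(cfg.sample_metadata, "sample metadata"),
        outdir / "community",
        factor=[cfg.community_factor, "treatment"],
        lump_threshold=cfg.lump_threshold,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
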