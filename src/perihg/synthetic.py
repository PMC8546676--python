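"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the field study's data layout: three sites
(natural, flooded, constructed wetland), triplicate 48-h tracer
incubations spiked with ~4 ng/L of each enriched isotope, a wetland-only
set of HgcA-bearing proteins on short contigs plus decoys, a reference
tree with family-monophyletic clades for placement, and a 27-sample
(3 sites x 3 treatments x 3 replicates) Dirichlet-multinomial ASV table
with a site effect and no treatment effect.

Every generator takes a ``numpy.random.Generator`` (or derives one from
the spec seed) and is byte-deterministic under a fixed seed.  Ground
truth (rates, planted families, tiers, base compositions) is returned
alongside the written files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from perihg.hgca import CONSERVED_MOTIFS
from perihg.kinetics import (
    KineticParams,
    TracerSpike,
    simulate_coupled_tracers,
    simulate_simplified_tracers,
)
from perihg.taxonomy import RANKS, TaxonomyLineage

__all__ = [
    "TracerSpec",
    "MetagenomeSpec",
    "TreeSpec",
    "CommunitySpec",
    "SimulationSpec",
    "gen_tracer_experiment",
    "gen_hgca_metagenome_fixture",
    "gen_reference_tree_fixture",
    "gen_asv_table",
    "generate_all",
]

SITES = ("natural", "flooded", "wetland")
TREATMENTS = ("t0", "incubated_control", "incubated_spiked")

#: Reference families for HgcA carriers, mirroring known methylator clades.
HGCA_FAMILIES: dict[str, TaxonomyLineage] = {
    "Geobacteraceae": TaxonomyLineage(
        "Bacteria", "Proteobacteria", "Deltaproteobacteria",
        "Desulfuromonadales", "Geobacteraceae"),
    "Desulfobacteraceae": TaxonomyLineage(
        "Bacteria", "Proteobacteria", "Deltaproteobacteria",
        "Desulfobacterales", "Desulfobacteraceae"),
    "Desulfuromonadaceae": TaxonomyLineage(
        "Bacteria", "Proteobacteria", "Deltaproteobacteria",
        "Desulfuromonadales", "Desulfuromonadaceae"),
    "Syntrophaceae": TaxonomyLineage(
        "Bacteria", "Proteobacteria", "Deltaproteobacteria",
        "Syntrophobacterales", "Syntrophaceae"),
    "Nitrospiraceae": TaxonomyLineage(
        "Bacteria", "Nitrospirae", "Nitrospira",
        "Nitrospirales", "Nitrospiraceae"),
    "Coriobacteriaceae": TaxonomyLineage(
        "Bacteria", "Actinobacteria", "Coriobacteriia",
        "Coriobacteriales", "Coriobacteriaceae"),
    "Bacteroidaceae": TaxonomyLineage(
        "Bacteria", "Bacteroidetes", "Bacteroidia",
        "Bacteroidales", "Bacteroidaceae"),
    "Methanoregulaceae": TaxonomyLineage(
        "Archaea", "Euryarchaeota", "Methanomicrobia",
        "Methanomicrobiales", "Methanoregulaceae"),
}

#: How many of the 24 planted HgcA queries fall in each family
#: (iron-reducing Geobacteraceae dominant, as in wetland periphyton).
_FAMILY_COUNTS = {
    "Geobacteraceae": 8,
    "Desulfobacteraceae": 3,
    "Desulfuromonadaceae": 2,
    "Syntrophaceae": 2,
    "Nitrospiraceae": 3,
    "Coriobacteriaceae": 2,
    "Bacteroidaceae": 2,
    "Methanoregulaceae": 2,
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TracerSpec:
    """Tracer-incubation design: per-site true rate constants (1/day),
    4 ng/L spikes, 48-h incubation, triplicates, 10% multiplicative noise,
    0.01 ng/L MMHg detection limit."""

    rates: dict[str, KineticParams] = field(
        default_factory=lambda: {
            "natural": KineticParams(km=2.6e-3, kd=1.40),
            "flooded": KineticParams(km=2.9e-3, kd=2.10),
            "wetland": KineticParams(km=5.9e-3, kd=1.80),
        }
    )
    spike: TracerSpike = field(default_factory=lambda: TracerSpike(4.0, 4.0))
    t: float = 2.0
    n_replicates: int = 3
    noise_cv: float = 0.10
    lod_mmhg: float = 0.01
    mode: str = "coupled"


@dataclass
class MetagenomeSpec:
    """HgcA fixture sizes: planted complete/partial carriers and decoys."""

    n_complete: int = 16
    n_partial: int = 8
    n_decoys: int = 50
    protein_length: tuple[int, int] = (100, 290)
    coverage_logmean: float = 1.8
    coverage_logsigma: float = 0.6

    @property
    def n_true(self) -> int:
        return self.n_complete + self.n_partial


@dataclass
class TreeSpec:
    """Reference-tree fixture: leaves per family clade and how many of the
    24 queries are planted so the two assigners disagree (placed at a mixed
    clade while similarity still names a family)."""

    leaves_per_family: int = 4
    n_disagree: int = 4


@dataclass
class CommunitySpec:
    """ASV-table design: Dirichlet-multinomial around site base
    compositions; treatment has no effect."""

    depth: int = 10_000
    concentration: float = 150.0
    n_replicates: int = 3
    molecules: tuple[str, ...] = ("rDNA",)
    asvs_per_taxon: int = 2


@dataclass
class SimulationSpec:
    """Full-study simulation: one seed drives every generator."""

    seed: int = 0
    tracer: TracerSpec = field(default_factory=TracerSpec)
    metagenome: MetagenomeSpec = field(default_factory=MetagenomeSpec)
    tree: TreeSpec = field(default_factory=TreeSpec)
    community: CommunitySpec = field(default_factory=CommunitySpec)


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def gen_tracer_experiment(
    spec: TracerSpec, rng: np.random.Generator, outdir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the tracer incubations; returns (table, truth).

    Measurements get independent multiplicative lognormal noise; product
    concentrations at or below the detection limit are left-censored
    (written as ``ND``).
    """
    rows = []
    for site in spec.rates:
        params = spec.rates[site]
        for rep in range(1, spec.n_replicates + 1):
            if spec.mode == "coupled":
                mm200, _, mm198, _ = simulate_coupled_tracers(params, spec.spike, spec.t)
            elif spec.mode == "simplified":
                mm200, mm198 = simulate_simplified_tracers(params, spec.spike, spec.t)
            else:
                raise ValueError(f"unknown tracer mode {spec.mode!r}")
            mm200 *= _noise(rng, spec.noise_cv)
            mm198 *= _noise(rng, spec.noise_cv)
            censored = mm200 <= spec.lod_mmhg
            rows.append(
                {
                    "site_id": site,
                    "replicate_id": f"{site}_r{rep}",
                    "ihg200_0": spec.spike.ihg200_0,
                    "mmhg198_0": spec.spike.mmhg198_0,
                    "mmhg200_t": spec.lod_mmhg if censored else mm200,
                    "mmhg198_t": mm198,
                    "t_days": spec.t,
                    "lod_mmhg": spec.lod_mmhg,
                    "mmhg200_censored": censored,
                }
            )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "site_id": list(spec.rates),
            "km_true": [p.km for p in spec.rates.values()],
            "kd_true": [p.kd for p in spec.rates.values()],
        }
    )
    if outdir is not None:
        from perihg.io import write_tracer_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracer_table(table, outdir / "tracer.tsv")
        truth.to_csv(outdir / "tracer_truth.tsv", sep="\t", index=False)
    return table, truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _assign_query_families() -> list[str]:
    fams = []
    for fam, n in _FAMILY_COUNTS.items():
        fams.extend([fam] * n)
    return fams


def gen_hgca_metagenome_fixture(
    spec: MetagenomeSpec, rng: np.random.Generator, outdir=None
) -> dict:
    """Planted HgcA proteins plus decoys, with search scores, coverage,
    reference lineages and similarity hits.

    Complete carriers embed one conserved motif and score >= 164; partial
    carriers are motif-free truncations scoring in [100, 164); decoys are
    composition-preserving shuffles of true sequences scoring below 100.
    Every true protein gets a similarity best hit to a reference subject of
    its planted family.
    """
    lo, hi = spec.protein_length
    families = _assign_query_families()
    if len(families) != spec.n_true:
        # keep the planted-family roster aligned with the requested size
        reps = int(np.ceil(spec.n_true / len(families)))
        families = (families * reps)[: spec.n_true]
    proteins = []  # (id, contig, contig_len, sequence)
    scores = {}
    truth_rows = []
    for i in range(spec.n_true):
        pid = f"hgca_{i + 1:03d}"
        contig = f"ctg_{i + 1:04d}"
        complete = i < spec.n_complete
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        if complete:
            motif = str(rng.choice(CONSERVED_MOTIFS))
            pos = int(rng.integers(0, length - 8))
            seq = seq[:pos] + motif + seq[pos + 8 :]
            score = float(np.round(rng.uniform(164.0, 320.0), 1))
        else:
            # truncated: strip any chance motif occurrence by resampling
            while any(m in seq for m in CONSERVED_MOTIFS):
                seq = _random_protein(rng, length)
            score = float(np.round(rng.uniform(100.0, 163.9), 1))
        contig_len = int(rng.integers(308, 1373))
        proteins.append((pid, contig, contig_len, seq))
        scores[pid] = score
        truth_rows.append(
            {
                "protein_id": pid,
                "family": families[i],
                "tier": "complete" if complete else "partial",
            }
        )
    true_seqs = [p[3] for p in proteins]
    for j in range(spec.n_decoys):
        pid = f"decoy_{j + 1:03d}"
        contig = f"dctg_{j + 1:04d}"
        if true_seqs:
            src = list(true_seqs[int(rng.integers(0, len(true_seqs)))])
            rng.shuffle(src)
        else:
            src = list(_random_protein(rng, int(rng.integers(lo, hi + 1))))
        proteins.append((pid, contig, int(rng.integers(308, 1373)), "".join(src)))
        scores[pid] = float(np.round(rng.uniform(20.0, 99.5), 1))
    coverage = {
        contig: float(
            np.round(rng.lognormal(spec.coverage_logmean, spec.coverage_logsigma), 3)
        )
        for _, contig, _, _ in proteins
    }

    # reference subjects: a few per family, with lineages
    subject_rows = []
    subjects_by_family = {}
    for fam, lineage in HGCA_FAMILIES.items():
        ids = [f"ref_{fam}_{k + 1}" for k in range(3)]
        subjects_by_family[fam] = ids
        for sid in ids:
            subject_rows.append({"subject_id": sid, **dict(zip(RANKS, lineage.as_tuple()))})
    # similarity hits: one strong in-family best hit per true protein,
    # plus a weaker out-of-family hit that must not win
    hit_rows = []
    for row, (pid, _, _, seq) in zip(truth_rows, proteins):
        fam = row["family"]
        qlen = len(seq)
        qend = int(np.ceil(qlen * rng.uniform(0.82, 1.0)))
        sid = str(rng.choice(subjects_by_family[fam]))
        hit_rows.append(
            (
                pid, sid, float(np.round(rng.uniform(45, 90), 1)), qend, 0, 0,
                1, qend, 1, qend,
                float(f"{rng.uniform(1e-60, 1e-25):.2e}"),
                float(np.round(rng.uniform(220, 420), 1)),
            )
        )
        other_fam = str(rng.choice([f for f in HGCA_FAMILIES if f != fam]))
        weak_end = max(int(qlen * 0.5), 10)
        hit_rows.append(
            (
                pid, subjects_by_family[other_fam][0],
                float(np.round(rng.uniform(41, 55), 1)), weak_end, 0, 0,
                1, weak_end, 1, weak_end,
                float(f"{rng.uniform(1e-24, 1e-21):.2e}"),
                float(np.round(rng.uniform(120, 200), 1)),
            )
        )

    out = {
        "proteins": proteins,
        "scores": scores,
        "coverage": coverage,
        "subjects": pd.DataFrame(subject_rows),
        "hits": hit_rows,
        "truth": pd.DataFrame(truth_rows),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "proteins.faa", "w") as fh:
            for pid, contig, clen, seq in proteins:
                fh.write(f">{pid} contig={contig} contig_len={clen}\n{seq}\n")
        with open(outdir / "hgca_hits.tbl", "w") as fh:
            fh.write("# target accession query accession evalue score bias\n")
            for pid, *_ in proteins:
                fh.write(f"{pid} - hgcA_profile - 1e-30 {scores[pid]} 0.1\n")
        pd.DataFrame(
            [(c, d) for c, d in coverage.items()], columns=["contig_id", "mean_depth"]
        ).to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        out["subjects"].to_csv(outdir / "subject_lineages.tsv", sep="\t", index=False)
        with open(outdir / "similarity_hits.tsv", "w") as fh:
            for h in hit_rows:
                fh.write("\t".join(str(x) for x in h) + "\n")
        out["truth"].to_csv(outdir / "hgca_truth.tsv", sep="\t", index=False)
    return out


def gen_reference_tree_fixture(
    spec: TreeSpec,
    rng: np.random.Generator,
    query_families: dict[str, str] | None = None,
    outdir=None,
) -> dict:
    """Family-monophyletic reference tree with planted query placements.

    ``query_families`` maps query leaf → planted family; by default the
    24-query roster of the metagenome fixture is used.  The last
    ``n_disagree`` queries (preferring the families the study called
    hypothetical) are attached outside every family clade, so clade
    assignment leaves them unassigned while their similarity hit still
    names a family.
    """
    if len(HGCA_FAMILIES) < 2:
        raise ValueError("need at least two reference families")
    if query_families is None:
        query_families = {
            f"hgca_{i + 1:03d}": fam for i, fam in enumerate(_assign_query_families())
        }
    queries = list(query_families)
    # queries placed at a mixed position: prefer the "hypothetical" families
    preferred = [
        q
        for q in queries
        if query_families[q]
        in ("Desulfobacteraceae", "Desulfuromonadaceae", "Bacteroidaceae")
    ]
    mixed = (preferred + [q for q in queries if q not in preferred])[: spec.n_disagree]
    mixed_set = set(mixed)

    leaf_rows = []
    clade_strings = []
    for fam, lineage in HGCA_FAMILIES.items():
        leaves = [f"{fam}_ref{k + 1}" for k in range(spec.leaves_per_family)]
        for name in leaves:
            leaf_rows.append({"leaf": name, **dict(zip(RANKS, lineage.as_tuple()))})
        members = [f"{leaf}:{rng.uniform(0.02, 0.15):.4f}" for leaf in leaves]
        members += [
            f"{q}:{rng.uniform(0.02, 0.1):.4f}"
            for q in queries
            if query_families[q] == fam and q not in mixed_set
        ]
        clade_strings.append(f"({','.join(members)}):{rng.uniform(0.1, 0.3):.4f}")
    top = clade_strings + [f"{q}:{rng.uniform(0.2, 0.4):.4f}" for q in mixed]
    newick = f"({','.join(top)});"
    leaf_taxa = pd.DataFrame(leaf_rows)
    out = {
        "newick": newick,
        "leaf_taxa": leaf_taxa,
        "query_families": query_families,
        "mixed_queries": mixed_set,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "reference_tree.nwk").write_text(newick + "\n")
        leaf_taxa.to_csv(outdir / "leaf_lineages.tsv", sep="\t", index=False)
        (outdir / "query_leaves.txt").write_text("\n".join(queries) + "\n")
    return out


# Site base compositions at phylum level (fractions sum to 1 per site);
# Proteobacteria averages 0.363 across sites and the wetland is enriched
# in anaerobic methylator-associated groups.
_PHYLUM_FRACS = {
    #                 natural flooded wetland
    "Proteobacteria": (0.370, 0.362, 0.357),
    "Cyanobacteria": (0.320, 0.280, 0.200),
    "Verrucomicrobia": (0.090, 0.100, 0.110),
    "Acidobacteria": (0.070, 0.080, 0.090),
    "Chloroflexi": (0.050, 0.060, 0.070),
    "Bacteroidetes": (0.040, 0.050, 0.060),
    "Planctomycetes": (0.030, 0.028, 0.030),
    "Euryarchaeota": (0.002, 0.004, 0.023),
    "Firmicutes": (0.010, 0.012, 0.020),
    "Nitrospirae": (0.008, 0.010, 0.020),
    "Armatimonadetes": (0.010, 0.014, 0.020),
}

# family split within each phylum (fixed across sites)
_FAMILY_SPLIT = {
    "Proteobacteria": {
        ("Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"): 0.45,
        ("Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"): 0.30,
        ("Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae"): 0.14,
        ("Deltaproteobacteria", "Desulfuromonadales", "Geobacteraceae"): 0.05,
        ("Deltaproteobacteria", "Desulfobacterales", "Desulfobacteraceae"): 0.02,
        ("Deltaproteobacteria", "Desulfobacterales", "Desulfobulbaceae"): 0.015,
        ("Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae"): 0.01,
        ("Deltaproteobacteria", "Syntrophobacterales", "Syntrophaceae"): 0.015,
    },
    "Euryarchaeota": {
        ("Methanomicrobia", "Methanomicrobiales", "Methanoregulaceae"): 0.6,
        ("Methanomicrobia", "Methanosarcinales", "Methanosaetaceae"): 0.4,
    },
}


def _community_taxa() -> list[tuple[TaxonomyLineage, dict[str, float]]]:
    taxa = []
    for phylum, fracs in _PHYLUM_FRACS.items():
        domain = "Archaea" if phylum == "Euryarchaeota" else "Bacteria"
        split = _FAMILY_SPLIT.get(phylum)
        if split is None:
            lineage = TaxonomyLineage(domain, phylum, f"{phylum}_cls",
                                      f"{phylum}_ord", f"{phylum}_fam")
            taxa.append((lineage, dict(zip(SITES, fracs))))
        else:
            for (cls, order, fam), w in split.items():
                lineage = TaxonomyLineage(domain, phylum, cls, order, fam)
                taxa.append(
                    (lineage, {s: f * w for s, f in zip(SITES, fracs)})
                )
    return taxa


def gen_asv_table(
    spec: CommunitySpec, rng: np.random.Generator, outdir=None
) -> dict:
    """Dirichlet-multinomial ASV counts over the 27-sample design.

    Per sample, composition ~ Dirichlet(concentration * site base
    fractions) and counts ~ Multinomial(depth).  Treatment and molecule
    labels are assigned but carry no compositional effect.
    """
    taxa = _community_taxa()
    asv_ids = []
    lineage_rows = []
    base = {site: [] for site in SITES}
    for i, (lineage, fracs) in enumerate(taxa):
        # split each taxon across ASVs with fixed uneven weights
        weights = np.linspace(1.0, 2.0, spec.asvs_per_taxon)
        weights /= weights.sum()
        for k, w in enumerate(weights):
            asv = f"asv_{i + 1:03d}_{k + 1}"
            asv_ids.append(asv)
            lineage_rows.append({"asv_id": asv, **dict(zip(RANKS, lineage.as_tuple()))})
            for site in SITES:
                base[site].append(fracs[site] * w)
    counts = {}
    meta_rows = []
    for molecule in spec.molecules:
        for site in SITES:
            alpha = spec.concentration * np.asarray(base[site])
            for treatment in TREATMENTS:
                for rep in range(1, spec.n_replicates + 1):
                    sample = f"{molecule}_{site}_{treatment}_r{rep}"
                    p = rng.dirichlet(alpha)
                    counts[sample] = rng.multinomial(spec.depth, p)
                    meta_rows.append(
                        {
                            "sample_id": sample,
                            "site": site,
                            "treatment": treatment,
                            "molecule": molecule,
                        }
                    )
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=asv_ids)
    counts_df.index.name = "sample_id"
    lineages_df = pd.DataFrame(lineage_rows).set_index("asv_id")
    metadata_df = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(
        [
            {"site": site, **{
                f"frac_{phylum}": fracs[SITES.index(site)]
                for phylum, fracs in _PHYLUM_FRACS.items()
            }}
            for site in SITES
        ]
    )
    out = {
        "counts": counts_df,
        "lineages": lineages_df,
        "metadata": metadata_df,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts_df.to_csv(outdir / "asv_counts.tsv", sep="\t")
        lineages_df.to_csv(outdir / "asv_lineages.tsv", sep="\t")
        metadata_df.to_csv(outdir / "sample_metadata.tsv", sep="\t")
        truth.to_csv(outdir / "community_truth.tsv", sep="\t", index=False)
    return out


def generate_all(spec: SimulationSpec, outdir) -> dict:
    """Run every generator with streams derived from one seed."""
    outdir = Path(outdir)
    ss = np.random.SeedSequence(spec.seed)
    rng_tracer, rng_meta, rng_tree, rng_comm = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    tracer_table, tracer_truth = gen_tracer_experiment(
        spec.tracer, rng_tracer, outdir / "tracer"
    )
    meta = gen_hgca_metagenome_fixture(spec.metagenome, rng_meta, outdir / "metagenome")
    query_families = dict(zip(meta["truth"]["protein_id"], meta["truth"]["family"]))
    tree = gen_reference_tree_fixture(
        spec.tree, rng_tree, query_families, outdir / "tree"
    )
    community = gen_asv_table(spec.community, rng_comm, outdir / "community")
    return {
        "tracer": (tracer_table, tracer_truth),
        "metagenome": meta,
        "tree": tree,
        "community": community,
    }
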