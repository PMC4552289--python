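"""End-to-end orchestration: simulate -> classify -> dnds -> stats -> domains.

A run is configured by :class:`RunConfig` (YAML-serializable, every
threshold surfaced as a named key), writes all stage artifacts as
headered TSV / FASTA / JSON into a run directory, and is byte-for-byte
reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import omega as pomega
from . import selstats, sitecall, synth, topodomains

__all__ = [
    "GroupSpec",
    "RunConfig",
    "run_all",
    "report_tables",
    "s_ratio_percent",
    "fixed_poly_ratio",
]

logger = logging.getLogger("poolsel")


@dataclass(frozen=True)
class GroupSpec:
    """One simulated gene group: a family tag plus its generator settings."""

    family_tag: str
    simulation: synth.SimulationConfig


def _default_groups():
    return (
        GroupSpec("OR", synth.SimulationConfig(
            n_genes=8, length_range=(180, 220),
            fixed_syn_rate=0.0039, fixed_nonsyn_rate=0.0035)),
        GroupSpec("NC", synth.SimulationConfig(
            n_genes=30, length_range=(150, 250),
            fixed_syn_rate=0.0043, fixed_nonsyn_rate=0.0005)),
    )


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and inputs of one pipeline run.

    Defaults mirror the source study: gene-level mean coverage >= 10x,
    allele presence at max(5 reads, 5 %), fixed-site majority 0.95,
    reciprocal orthology at 95 % identity, topology consensus support 2.
    """

    out_dir: str = "run"
    seed: int = 1
    groups: tuple = field(default_factory=_default_groups)
    min_mean_cov: float = 10.0
    min_site_depth: int = 10
    presence_floor: int = 5
    presence_frac: float = 0.05
    fixed_major_freq: float = 0.95
    min_identity: float = 0.95
    min_support: int = 2
    codon_freq_mode: str = "F3x4"
    compute_lrt: bool = True
    topology_jitter_sd: float = 2.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [
            {"family_tag": g.family_tag, "simulation": asdict(g.simulation)}
            for g in self.groups
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        groups = []
        for g in d.pop("groups", []):
            sim = dict(g["simulation"])
            for key in ("length_range", "minor_allele_freq_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            groups.append(GroupSpec(g["family_tag"], synth.SimulationConfig(**sim)))
        if groups:
            d["groups"] = tuple(groups)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def _config_hash(config: RunConfig) -> str:
    payload = config.to_dict()
    payload.pop("out_dir", None)  # hash the analysis settings, not the path
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig, out: Path) -> dict:
    """Generate all gene groups and write pools, pileups and truth tables."""
    ancestral_all: dict[str, str] = {}
    families: dict[str, str] = {}
    pileups = []
    truth_fixed, truth_poly = [], []
    consensus = {"A": {}, "B": {}}
    pool_records = {"A": [], "B": []}

    for idx, group in enumerate(config.groups):
        sim = replace(group.simulation, seed=config.seed * 997 + idx)
        ancestral = synth.generate_ancestral_cds(sim)
        pool_a, pool_b, truth = synth.evolve_species_pair(ancestral, sim)
        prefix = group.family_tag
        rename = {g: f"{prefix}_{g}" for g in ancestral}
        for g, name in rename.items():
            ancestral_all[name] = ancestral[g]
            families[name] = group.family_tag
            consensus["A"][name] = pool_a.consensus(g)
            consensus["B"][name] = pool_b.consensus(g)
        for pool, species in ((pool_a, "A"), (pool_b, "B")):
            frame = synth.simulate_pileups(pool, sim)
            frame["gene_id"] = frame["gene_id"].map(rename)
            pileups.append(frame)
            for rid, seq in pool.fasta_records():
                gene, rest = rid.split("|", 1)
                pool_records[species].append((f"{rename[gene]}|{rest}", seq))
        fixed = truth.fixed_frame()
        fixed["gene_id"] = fixed["gene_id"].map(rename)
        truth_fixed.append(fixed)
        poly = truth.poly_frame()
        poly["gene_id"] = poly["gene_id"].map(rename)
        truth_poly.append(poly)

    pileup_frame = pd.concat(pileups, ignore_index=True)
    pio.write_tsv(pileup_frame, out / "pileups.tsv")
    pio.write_tsv(pd.concat(truth_fixed, ignore_index=True), out / "truth_fixed.tsv")
    pio.write_tsv(pd.concat(truth_poly, ignore_index=True), out / "truth_poly.tsv")
    pio.write_tsv(
        pd.DataFrame(
            sorted(families.items()), columns=["gene_id", "family_tag"]
        ),
        out / "families.tsv",
    )
    for species in "AB":
        pio.write_fasta(sorted(consensus[species].items()), out / f"consensus_{species}.fasta")
        pio.write_fasta(sorted(pool_records[species]), out / f"pool_{species}.fasta")
    logger.info("simulate: %d genes, %d pileup rows", len(ancestral_all), len(pileup_frame))
    return {
        "ancestral": ancestral_all,
        "families": families,
        "pileups": pileup_frame,
        "consensus": consensus,
    }


def classify_stage(config: RunConfig, out: Path, pileups: pd.DataFrame,
                   orfs: dict, families: dict) -> dict:
    """Site classification, gene tallies and fixed-difference alignments."""
    variations, all_calls = [], []
    alignments: dict[str, tuple[str, str]] = {}
    by_gene = {k: v for k, v in pileups.groupby("gene_id")}
    for gene_id in sorted(orfs):
        gene_rows = by_gene.get(gene_id)
        if gene_rows is None:
            gene_rows = pileups.iloc[0:0]
        rows_a = gene_rows[gene_rows["species"] == "A"]
        rows_b = gene_rows[gene_rows["species"] == "B"]
        variation, calls = sitecall.classify_gene(
            rows_a, rows_b, orfs[gene_id], gene_id,
            family_tag=families.get(gene_id, "unknown"),
            min_mean_cov=config.min_mean_cov,
            min_site_depth=config.min_site_depth,
            fixed_major_freq=config.fixed_major_freq,
            presence_floor=config.presence_floor,
            presence_frac=config.presence_frac,
        )
        variations.append(variation)
        all_calls.extend(calls)
        if variation.passes_coverage and variation.n_fixed > 0:
            cons_a = "".join(
                c.major_a if c.major_a else orfs[gene_id][c.pos - 1] for c in calls
            )
            cons_b = "".join(
                c.major_b if c.major_b else orfs[gene_id][c.pos - 1] for c in calls
            )
            aln = sitecall.build_fixed_alignment(cons_a, cons_b, calls)
            # drop the terminal stop codon before dN/dS estimation
            alignments[gene_id] = (aln[0][:-3], aln[1][:-3])

    gene_frame = sitecall.gene_variation_frame(variations)
    call_frame = sitecall.site_calls_frame(all_calls)
    pio.write_tsv(gene_frame, out / "genes.tsv")
    pio.write_tsv(call_frame, out / "site_calls.tsv")
    aln_dir = out / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for gene_id, (sa, sb) in sorted(alignments.items()):
        pio.write_fasta(
            [(f"{gene_id}|A", sa), (f"{gene_id}|B", sb)],
            aln_dir / f"{gene_id}.fasta",
        )
    logger.info(
        "classify: %d genes (%d pass coverage), %d fixed-difference alignments",
        len(variations), int(gene_frame["passes_coverage"].sum()), len(alignments),
    )
    return {"variations": variations, "calls": all_calls,
            "gene_frame": gene_frame, "alignments": alignments}


def dnds_stage(config: RunConfig, out: Path, alignments: dict,
               variations=None) -> pd.DataFrame:
    """Pairwise dN/dS on every fixed-difference alignment."""
    results = []
    for gene_id in sorted(alignments):
        seq_a, seq_b = alignments[gene_id]
        results.append(
            pomega.fit_gene(gene_id, seq_a, seq_b, config.codon_freq_mode,
                            compute_lrt=config.compute_lrt)
        )
    frame = pomega.omega_table(results, variations)
    pio.write_tsv(frame, out / "omega.tsv")
    logger.info("dnds: %d gene fits", len(results))
    return frame


def stats_stage(config: RunConfig, out: Path, gene_frame: pd.DataFrame,
                omega_frame: pd.DataFrame) -> dict:
    """Gene-set contingency battery and rank tests."""
    results = selstats.gene_set_contingencies(gene_frame, omega_frame)
    rows = []
    for name, value in results.items():
        if name == "tallies":
            continue
        table, test = value
        rows.append({
            "test": name,
            "statistic": test.statistic,
            "p": test.p,
            "method": test.method,
            "table": json.dumps(table.values()) if table else "",
        })
    pio.write_tsv(pd.DataFrame(rows, columns=["test", "statistic", "p", "method", "table"]),
                  out / "stats.tsv")
    return results


def domains_stage(config: RunConfig, out: Path, gene_frame: pd.DataFrame,
                  omega_frame: pd.DataFrame, calls, orfs: dict,
                  families: dict) -> dict:
    """Topology consensus + substitution mapping for receptors with dN/dS > 1."""
    omega_by_gene = omega_frame.set_index("gene_id")["omega"].to_dict() if len(omega_frame) else {}
    fixed_nonsyn_by_gene: dict[str, list[int]] = {}
    for call in calls:
        if call.site_class == "fixed" and call.effect == "nonsyn":
            fixed_nonsyn_by_gene.setdefault(call.gene_id, []).append(call.pos)

    per_gene_rows = []
    enrichment_inputs = []
    profile_counts = None
    profile_labels = topodomains.canonical_domain_order(7)
    topo_annotations = []
    for gi, gene_id in enumerate(sorted(fixed_nonsyn_by_gene)):
        if families.get(gene_id) not in ("OR", "IR"):
            continue
        om = omega_by_gene.get(gene_id)
        if om is None or not (om > 1 or np.isinf(om)):
            continue
        protein_length = len(orfs[gene_id]) // 3 - 1  # exclude the stop codon
        try:
            _truth, predictors = synth_topology_for(
                gene_id, protein_length, config.seed, config.topology_jitter_sd
            )
        except ValueError:
            continue  # protein too short for a 7-TM architecture
        consensus = topodomains.consensus_topology(predictors, config.min_support)
        topo_annotations.extend(predictors + [consensus])
        sites = [
            topodomains.SubstitutionSite(gene_id, (pos - 1) // 3 + 1, gene_id)
            for pos in sorted(fixed_nonsyn_by_gene[gene_id])
        ]
        _counts, assignments = topodomains.map_substitutions(sites, consensus)
        n_in = sum(1 for _s, _l, in_lbd, _f in assignments if in_lbd)
        fraction = topodomains.domain_fraction(consensus, {"TM"})
        per_gene_rows.append({
            "gene_id": gene_id,
            "family_tag": families[gene_id],
            "n_fixed_nonsyn": len(sites),
            "n_in_lbd": n_in,
            "lbd_fraction": fraction,
        })
        if 0.0 < fraction < 1.0:
            enrichment_inputs.append((len(sites), n_in, fraction))
        profile = topodomains.spatial_profile(sites, consensus)
        if profile.labels == profile_labels:
            if profile_counts is None:
                profile_counts = np.zeros(len(profile_labels), dtype=int)
            profile_counts += np.array(profile.counts)

    domain_frame = pd.DataFrame(
        per_gene_rows,
        columns=["gene_id", "family_tag", "n_fixed_nonsyn", "n_in_lbd", "lbd_fraction"],
    )
    pio.write_tsv(domain_frame, out / "domains.tsv")
    if topo_annotations:
        pio.write_topologies(topo_annotations, out / "topologies.tsv")

    result: dict = {"per_gene": domain_frame}
    if enrichment_inputs:
        result["enrichment"] = topodomains.lbd_enrichment(enrichment_inputs)
    if len(domain_frame) >= 3 and domain_frame["n_fixed_nonsyn"].nunique() > 1 \
            and domain_frame["n_in_lbd"].nunique() > 1:
        result["pearson"] = selstats.pearson_r(
            domain_frame["n_fixed_nonsyn"], domain_frame["n_in_lbd"]
        )
    if profile_counts is not None:
        result["profile"] = (profile_labels, profile_counts.tolist())
        pio.write_tsv(
            pd.DataFrame({"domain": profile_labels, "n_substitutions": profile_counts}),
            out / "spatial_profile.tsv",
        )
    return result


def synth_topology_for(gene_id: str, protein_length: int, seed: int, jitter_sd: float):
    """Deterministic per-gene predictor topologies (fixture backend)."""
    gene_seed = int(hashlib.sha256(f"{seed}:{gene_id}".encode()).hexdigest()[:8], 16)
    return synth.synth_topologies(
        protein_length, n_tm=7, jitter_sd=jitter_sd, seed=gene_seed,
        protein_id=gene_id,
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Execute every stage and write a machine-readable summary.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = simulate_stage(config, out)
    cls = classify_stage(config, out, sim["pileups"], sim["ancestral"], sim["families"])
    omega_frame = dnds_stage(config, out, cls["alignments"], cls["variations"])
    stats = stats_stage(config, out, cls["gene_frame"], omega_frame)
    domains = domains_stage(config, out, cls["gene_frame"], omega_frame,
                            cls["calls"], sim["ancestral"], sim["families"])

    tallies = stats["tallies"]
    chemo, nc = tallies["chemosensory"], tallies["NC"]
    summary = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_genes": int(len(cls["gene_frame"])),
        "n_pass_coverage": int(cls["gene_frame"]["passes_coverage"].sum()),
        "n_fixed_sites": chemo.n_fixed + nc.n_fixed,
        "n_polymorphic_sites": chemo.n_polymorphic + nc.n_polymorphic,
        "n_variable_sites": (chemo.n_fixed + nc.n_fixed
                             + chemo.n_polymorphic + nc.n_polymorphic),
        "fixed_poly_ratio_chemo": fixed_poly_ratio(chemo.n_fixed, chemo.n_polymorphic),
        "fixed_poly_ratio_nc": fixed_poly_ratio(nc.n_fixed, nc.n_polymorphic),
        "s_ratio_chemo_pct": s_ratio_percent(chemo.n_omega_gt1, chemo.n_genes),
        "s_ratio_nc_pct": s_ratio_percent(nc.n_omega_gt1, nc.n_genes),
        "fisher_fixed_vs_poly_p": stats["fixed_vs_polymorphic"][1].p
        if "fixed_vs_polymorphic" in stats else None,
        "fisher_fixed_nonsyn_vs_syn_p": stats["fixed_nonsyn_vs_syn"][1].p
        if "fixed_nonsyn_vs_syn" in stats else None,
        "fisher_omega_gt1_p": stats["omega_gt1_enrichment"][1].p
        if "omega_gt1_enrichment" in stats else None,
        "fisher_receptor_p": stats["receptor_enrichment"][1].p
        if "receptor_enrichment" in stats else None,
        "dn_mann_whitney_p": stats["dn_mann_whitney"][1].p
        if "dn_mann_whitney" in stats else None,
        "ds_mann_whitney_p": stats["ds_mann_whitney"][1].p
        if "ds_mann_whitney" in stats else None,
        "tm_chi2": domains["enrichment"].statistic if "enrichment" in domains else None,
        "tm_chi2_p": domains["enrichment"].p if "enrichment" in domains else None,
        "tm_in_count": int(domains["per_gene"]["n_in_lbd"].sum())
        if len(domains["per_gene"]) else 0,
        "lbd_pearson_r": domains["pearson"].statistic if "pearson" in domains else None,
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    report_tables(out)
    return summary


def s_ratio_percent(n_omega_gt1: int, n_genes: int) -> float:
    """Share of a gene set with dN/dS > 1, as a percentage (1 dp)."""
    if n_genes == 0:
        return float("nan")
    return round(100.0 * n_omega_gt1 / n_genes, 1)


def fixed_poly_ratio(n_fixed: int, n_polymorphic: int) -> float:
    """Fixed-to-polymorphic variable-site ratio (2 dp)."""
    if n_polymorphic == 0:
        return float("inf") if n_fixed else float("nan")
    return round(n_fixed / n_polymorphic, 2)


def report_tables(run_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family accounting table and the dN/dS > 1 gene table.

    Reads ``genes.tsv`` and ``omega.tsv`` from a completed run directory
    and writes ``table2.tsv`` / ``table3.tsv`` next to them.
    """
    run_dir = Path(run_dir)
    for name in ("genes.tsv", "omega.tsv"):
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"incomplete run: missing {name}")
    genes = pio.read_tsv(run_dir / "genes.tsv")
    omega = pio.read_tsv(run_dir / "omega.tsv")
    genes = genes[genes["passes_coverage"]].copy()
    rates = omega[["gene_id", "omega", "dn", "ds"]].copy()
    for column in ("omega", "dn", "ds"):
        rates[column] = pd.to_numeric(rates[column], errors="coerce")
    merged = genes.merge(rates, on="gene_id", how="left")
    merged["n_fixed"] = merged["n_fixed_syn"] + merged["n_fixed_nonsyn"]
    merged["n_poly"] = merged["n_poly_syn"] + merged["n_poly_nonsyn"]
    merged["omega_gt1"] = ((merged["omega"] > 1) | np.isinf(merged["omega"])).fillna(False)

    rows = []
    families = sorted(merged["family_tag"].unique())
    chemo_mask = merged["family_tag"].isin(selstats.CHEMOSENSORY_FAMILIES)
    blocks = [(fam, merged[merged["family_tag"] == fam]) for fam in families
              if fam in selstats.CHEMOSENSORY_FAMILIES]
    if chemo_mask.any():
        blocks.append(("Total", merged[chemo_mask]))
    if (~chemo_mask).any():
        blocks.append(("NC", merged[~chemo_mask]))
    for name, sub in blocks:
        with_fixed = sub[sub["n_fixed"] > 0]
        n_gt1 = int(sub["omega_gt1"].sum())
        rows.append({
            "family": name,
            "unique_genes": len(sub),
            "variable_genes": int(((sub["n_fixed"] + sub["n_poly"]) > 0).sum()),
            "n_poly_syn": int(sub["n_poly_syn"].sum()),
            "n_poly_nonsyn": int(sub["n_poly_nonsyn"].sum()),
            "n_fixed_syn": int(sub["n_fixed_syn"].sum()),
            "n_fixed_nonsyn": int(sub["n_fixed_nonsyn"].sum()),
            "genes_fixed": len(with_fixed),
            "mean_dn": round(float(with_fixed["dn"].mean()), 7) if len(with_fixed) else 0.0,
            "mean_ds": round(float(with_fixed["ds"].mean()), 7) if len(with_fixed) else 0.0,
            "mean_dnds": round(float((with_fixed["dn"] / with_fixed["ds"])
                                     .replace([np.inf, -np.inf], np.nan).mean()), 7)
            if len(with_fixed) else 0.0,
            "n_omega_gt1": n_gt1,
            "s_ratio_pct": s_ratio_percent(n_gt1, len(sub)),
        })
    table2 = pd.DataFrame(rows)
    table3 = omega[omega["gene_id"].isin(merged.loc[merged["omega_gt1"], "gene_id"])].copy()
    pio.write_tsv(table2, run_dir / "table2.tsv")
    pio.write_tsv(table3, run_dir / "table3.tsv")
    return table2, table3
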