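"""End-to-end orchestration: registry -> haplotypes -> distances ->
networks -> GMYC -> consensus -> report.

The pipeline consumes a plain-text YAML config (no hidden defaults: the
effective configuration is dumped into the report), runs the stages in
order, persists intermediate artifacts as TSV/JSON/GraphML, and writes a
report whose non-timestamp content is fully determined by the config hash
and seed.  The biogeographic section runs from the site table alone, so a
metadata-only configuration still produces a complete report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignments import (
    PruningPolicy,
    collapse_identical,
    prune_to_full_coverage,
    read_alignment,
    split_by_clade,
    clade_haplotype_report,
)
from .consensus import (
    EvidenceTable,
    PairEvidence,
    ReconciliationRules,
    SpeciesPartition,
    reconcile,
)
from .distances import DistanceSummary, barcode_gap, distance_matrix, summarize_distances
from .gmyc import gmyc_fit, gmyc_support, read_tree, upgma_tree
from .networks import ParsimonyConfig, build_networks, export_network, networks_to_partition
from .registry import (
    SpeciesMergeMap,
    cooccurrence_stats,
    load_site_table,
    rarefaction_curve,
    regional_summary,
    registry_totals,
    depth_profile,
)

log = logging.getLogger("specdelim.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "make_figures", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    sites: str
    output: str
    mito_alignment: str | None = None  # COI-like marker, fasta
    nuclear_alignment: str | None = None  # ITS2-like marker, fasta
    tree: str | None = None  # optional ultrametric tree (newick)
    connection_probability: float = 0.95
    fixed_limit: int | None = None
    support_cutoff: float = 0.9
    rules: ReconciliationRules = field(default_factory=ReconciliationRules)
    seed: int = 1
    merge: dict[str, str] | None = None  # clade -> species overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rules = ReconciliationRules(**raw.pop("rules", {}))
        cfg = cls(rules=rules, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.sites).exists():
            raise PipelineError(f"site table not found: {self.sites}")
        for attr in ("mito_alignment", "nuclear_alignment", "tree"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise PipelineError(f"{attr} not found: {val}")

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "rules"
        }
        out["rules"] = self.rules.__dict__.copy()
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _majority_clade(members) -> str:
    counts = Counter(m.rsplit("_", 1)[1] for m in members if "_" in m)
    return counts.most_common(1)[0][0] if counts else "?"


def _registry_stage(config: PipelineConfig, outdir: Path) -> dict:
    merge = SpeciesMergeMap(config.merge) if config.merge else SpeciesMergeMap()
    sites = load_site_table(config.sites)
    n_sites, n_specimens, dmin, dmax = registry_totals(sites)
    regions = regional_summary(sites, merge)
    multi_spm, multi_sp, max_sp = cooccurrence_stats(sites, merge)
    profile = depth_profile(sites, merge)
    summary = {
        "n_sites": n_sites,
        "n_specimens": n_specimens,
        "depth_min_m": dmin,
        "depth_max_m": dmax,
        "regions": {
            r: {
                "n_specimens": v["n_specimens"],
                "n_species": v["n_species"],
                "species": sorted(v["species"]),
            }
            for r, v in sorted(regions.items())
        },
        "n_multispecimen_sites": multi_spm,
        "n_multispecies_sites": multi_sp,
        "max_species_per_site": max_sp,
        "depth_profile": {
            sp: {r: list(rng) for r, rng in sorted(by_region.items())}
            for sp, by_region in sorted(profile.items())
        },
    }
    (outdir / "registry.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("registry: %d sites, %d specimens", n_sites, n_specimens)
    return summary


def _sequence_stage(config: PipelineConfig, outdir: Path) -> dict:
    out: dict = {}
    mito = read_alignment(config.mito_alignment, marker="mito")
    haps = collapse_identical(mito)
    out["mito_n_sequences"] = len(mito)
    out["mito_n_haplotypes"] = len(haps)

    pconf = ParsimonyConfig(
        connection_probability=config.connection_probability,
        fixed_limit=config.fixed_limit,
    )
    nets = build_networks(haps, pconf)
    out["mito_n_networks"] = len(nets)
    out["connection_limit"] = nets[0].connection_limit
    for i, net in enumerate(nets):
        export_network(net, outdir / f"network_{i}.graphml")
    partition = networks_to_partition(nets)
    ref_blocks: dict[int, set[str]] = {}
    for sid, k in partition.items():
        ref_blocks.setdefault(k, set()).add(sid)
    names = [_majority_clade(b) for b in ref_blocks.values()]
    # de-duplicate names deterministically
    seen: Counter = Counter()
    uniq = []
    for nm in names:
        seen[nm] += 1
        uniq.append(nm if seen[nm] == 1 else f"{nm}.{seen[nm]}")
    reference = SpeciesPartition(
        "TCS", "mito", [frozenset(b) for b in ref_blocks.values()], uniq
    )

    clades = split_by_clade(mito)
    pruned = {c: prune_to_full_coverage(a, PruningPolicy()) for c, a in clades.items()}
    report = clade_haplotype_report(pruned, clades)
    report.to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)

    dist_summary: DistanceSummary | None = None
    if len(clades) >= 2:
        dist_summary = summarize_distances(clades)
        dist_summary.to_frame().to_csv(outdir / "distances.tsv", sep="\t", index=False)
        mx_intra, mn_inter, gap = barcode_gap(dist_summary)
        out["barcode_gap"] = {
            "max_intra_pct": round(100 * mx_intra, 2),
            "min_inter_pct": round(100 * mn_inter, 2),
            "gap_exists": gap,
        }
    out["_reference"] = reference
    out["_dist_summary"] = dist_summary
    out["_haps"] = haps
    return out


def _gmyc_stage(config: PipelineConfig, outdir: Path, seq: dict) -> dict:
    if config.tree:
        tree = read_tree(config.tree)
    else:
        haps = seq["_haps"]
        reps = haps.representatives
        if len(reps) < 3:
            raise PipelineError("GMYC needs >= 3 unique haplotypes")
        tree = upgma_tree(distance_matrix(reps), reps.ids)
    fit = gmyc_fit(tree)
    support = gmyc_support(tree, fits=None, cutoff=config.support_cutoff)
    rows = ["entity\tmembers"]
    for i, ent in enumerate(fit.entities):
        rows.append(f"{i}\t{';'.join(sorted(ent))}")
    (outdir / "gmyc_entities.tsv").write_text("\n".join(rows) + "\n")
    return {
        "n_entities": fit.n_entities,
        "n_entities_at_cutoff": support.n_entities,
        "lnL_null": round(fit.lnL_null, 4),
        "lnL_alt": round(fit.lnL_alt, 4),
        "LR": round(fit.LR, 4),
        "p_value": round(fit.p_value, 6),
        "threshold_time": fit.threshold_time,
        "_fit": fit,
        "_tree": tree,
    }


def _consensus_stage(config: PipelineConfig, outdir: Path, seq: dict, gmyc: dict) -> dict:
    reference: SpeciesPartition = seq["_reference"]
    others = []
    fit = gmyc.get("_fit")
    haps = seq["_haps"]
    membership = haps.membership()
    if fit is not None:
        # entities are over haplotype representatives; expand to members
        rep_members = {m[0]: m for _, m in
                       ((s, mm) for s, mm in haps.haplotypes)}
        blocks = []
        for ent in fit.entities:
            members: set[str] = set()
            for rep in ent:
                members.update(rep_members.get(rep, [rep]))
            blocks.append(frozenset(members))
        others.append(SpeciesPartition("GMYC", "mito", blocks))

    shares_nuclear: dict[frozenset, bool] = {}
    if config.nuclear_alignment:
        nuc = read_alignment(config.nuclear_alignment, marker="nuclear")
        nuc_haps = collapse_identical(nuc)
        label_of = {}
        for name, block in zip(reference.names, reference.blocks):
            for sid in block:
                label_of[sid] = name
        for _, members in nuc_haps.haplotypes:
            labels = {label_of.get(m) for m in members} - {None}
            for a in labels:
                for b in labels:
                    if a < b:
                        shares_nuclear[frozenset((a, b))] = True

    dist = seq.get("_dist_summary")
    pairs = {}
    n_spec = {name: len(block) for name, block in zip(reference.names, reference.blocks)}
    for key, shared in shares_nuclear.items():
        a, b = sorted(key)
        ev_min = None
        if dist is not None and tuple(sorted((a, b), key=str)) in dist.inter:
            ev_min = round(100 * dist.pair(a, b)[0], 2)
        pairs[key] = PairEvidence(shares_nuclear_haplotype=shared, coi_min_inter=ev_min)
    if dist is not None:
        for key in list(dist.inter):
            fkey = frozenset(key)
            if fkey not in pairs and len(fkey) == 2:
                pairs[fkey] = PairEvidence(
                    coi_min_inter=round(100 * dist.inter[key][0], 2)
                )
    mx_intra = seq.get("barcode_gap", {}).get("max_intra_pct")
    evidence = EvidenceTable(
        pairs=pairs,
        n_specimens=n_spec,
        coi_max_intra_pooled=mx_intra,
        connection_limit=seq.get("connection_limit"),
    )
    result = reconcile(reference, others, evidence, config.rules)
    (outdir / "consensus.json").write_text(
        json.dumps(result.to_dict(), indent=1, sort_keys=True)
    )
    return {
        "n_species": result.n_species,
        "lower_bound": result.lower_bound,
        "upper_bound": result.upper_bound,
        "n_decisions": len(result.decisions),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to
    ``<output>/report.json``)."""
    config.validate()
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    stage = "registry"
    try:
        report["registry"] = _registry_stage(config, outdir)
        if config.mito_alignment:
            stage = "sequences"
            seq = _sequence_stage(config, outdir)
            report["sequences"] = {
                k: v for k, v in seq.items() if not k.startswith("_")
            }
            stage = "gmyc"
            gm = _gmyc_stage(config, outdir, seq)
            report["gmyc"] = {k: v for k, v in gm.items() if not k.startswith("_")}
            stage = "consensus"
            report["consensus"] = _consensus_stage(config, outdir, seq, gm)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", outdir / "report.json")
    return report


def make_figures(report: dict, outdir) -> list[Path]:
    """Depth histogram (log depth scale), per-region rarefaction curves and
    species-composition tables from a pipeline report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    reg = report["registry"]

    fig, ax = plt.subplots(figsize=(6, 4))
    depths = []
    for sp, by_region in reg["depth_profile"].items():
        for r, (lo, hi) in by_region.items():
            depths.append((lo + hi) / 2.0)
    if depths:
        ax.hist(depths, bins=20)
        ax.set_xscale("log")
        ax.set_xlabel("depth (m, log scale)")
        ax.set_ylabel("species-region records")
        path = outdir / "depth_distribution.svg"
        fig.savefig(path)
        produced.append(path)
    plt.close(fig)

    for region, info in reg["regions"].items():
        path = outdir / f"composition_{region.replace(' ', '_')}.tsv"
        lines = ["species"] + info["species"]
        path.write_text("\n".join(lines) + "\n")
        produced.append(path)
    return produced


def rarefaction_figure(specimen_species_by_region: dict[str, list[str]], outdir) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    for region, labels in sorted(specimen_species_by_region.items()):
        if not labels:
            continue
        curve = rarefaction_curve(labels)
        ax.plot([n for n, _ in curve], [s for _, s in curve], label=region)
    ax.set_xlabel("specimens sampled")
    ax.set_ylabel("expected species")
    ax.legend(fontsize=6)
    path = outdir / "rarefaction.svg"
    fig.savefig(path)
    plt.close(fig)
    return path
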