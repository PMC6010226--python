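"""Coalescent synthesizer: multi-species, multi-marker test data.

Generates data with the statistical structure the delimitation pipeline
assumes: a Yule species tree; within- and between-species genealogies from
the multispecies Kingman coalescent (via msprime); strict-clock sequence
evolution (HKY or JC, via dendropy's discrete-character simulator) at the
mitochondrial barcode rate of 2.2% pairwise divergence per My; an
indel-bearing nuclear-like marker; and specimen metadata spread over ten
biogeographic regions with overlapping species ranges and depths, so that
sympatry statistics are non-trivial.

Units and conventions
---------------------
Time is measured in My; the strict clock is ``rate`` substitutions per
site per My per lineage (default 0.011, i.e. 2.2%/My between a pair of
lineages).  ``theta`` is the expected within-species pairwise p-distance
(nucleotide diversity per site); the corresponding haploid effective size
is  N = theta / (2 * rate)  My.  The mitochondrial marker uses N/4
(haploid, maternally inherited).  Sequence ids follow the survey's
``extractionID_clade`` convention so every downstream module parses them.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import msprime
import numpy as np
from dendropy.model.discrete import Hky85, Jc69, simulate_discrete_chars

from .alignments import MarkerAlignment, write_alignment

__all__ = [
    "ClockModel",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_species_tree",
    "calibrated_species_tree",
    "simulate_gene_trees",
    "evolve_sequences",
    "simulate_dataset",
    "REGION_LABELS",
]

REGION_LABELS = (
    "Kattegat",
    "Skagerrak",
    "North Sea",
    "Irish Sea Celtic Sea",
    "Norwegian coast and shelf",
    "Norwegian Sea",
    "Barents Sea",
    "Arctic Ocean",
    "Greenland Sea",
    "South of Iceland",
)


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock with a log-normal rate prior.

    The default prior (log mean -4.466, log sd 0.075 on substitutions/site/
    My) has median 0.0115, i.e. about 2.3% pairwise divergence per My, and
    a 95% interval spanning 2.0-2.6% divergence per My.
    """

    rate: float = 0.011  # substitutions/site/My per lineage
    log_mean: float = -4.466
    log_sd: float = 0.075

    def prior_interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        lo = float(np.exp(self.log_mean - z * self.log_sd))
        hi = float(np.exp(self.log_mean + z * self.log_sd))
        return 2 * lo, 2 * hi  # pairwise divergence per My


@dataclass
class SimulationConfig:
    K: int = 5
    yule_rate: float = 0.3  # speciations per lineage per My
    theta: float = 0.008  # expected within-species pairwise p-distance
    n_per_species: int = 8
    coi_length: int = 658
    its2_length: int = 360
    clock: ClockModel = field(default_factory=ClockModel)
    kappa: float = 4.0  # HKY transition/transversion rate ratio
    indel_rate: float = 0.002  # events per site per My (nuclear marker)
    indel_mean_length: float = 3.0
    mito_ne_ratio: float = 0.25
    min_split_my: float | None = 1.0  # species age floor (clear barcode gap)
    sympatry_weight: float = 0.5  # weight of a species' home region
    seed: int = 1

    def __post_init__(self) -> None:
        if self.K < 1 or self.theta <= 0 or self.coi_length < 1 or self.its2_length < 1:
            raise ValueError("invalid simulation config")


@dataclass
class SyntheticDataset:
    true_partition: dict[str, str]  # specimen id -> species label
    alignments: dict[str, MarkerAlignment]
    sites: list[dict]
    gene_trees: dict[str, str]  # marker -> newick (My units)
    species_tree: str  # newick (My units)
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for marker, aln in self.alignments.items():
            write_alignment(aln, out / f"{marker.lower()}.fasta")
        import csv

        with open(out / "sites.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.sites[0]))
            writer.writeheader()
            writer.writerows(self.sites)
        for marker, nwk in self.gene_trees.items():
            (out / f"{marker.lower()}_genetree.nwk").write_text(nwk + "\n")
        (out / "species_tree.nwk").write_text(self.species_tree + "\n")
        (out / "truth.json").write_text(
            json.dumps(self.true_partition, indent=1, sort_keys=True)
        )


def simulate_species_tree(
    K: int,
    yule_rate: float,
    seed: int | np.random.Generator,
    duration: float | None = None,
) -> tuple[str, list[float]]:
    """Yule (pure-birth) species tree.

    With ``K`` given, splits accumulate until K lineages exist and the tips
    are extended to the present by one more exponential waiting time.  With
    ``duration`` given instead, the process runs for a fixed time and K is
    random (lineage count grows as exp(yule_rate * t) in expectation).

    Returns (newick with branch lengths in My, split ages before present).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is not None:
        t, k = 0.0, 1
        while True:
            t += rng.exponential(1.0 / (yule_rate * k))
            if t > duration:
                break
            k += 1
        K = k

    if K == 1:
        stem = rng.exponential(1.0 / yule_rate)
        return f"sp1:{stem:.12f};", []

    # forward-time splits: waiting time Exp(k * rate) while k lineages
    split_times = []
    t = 0.0
    for k in range(1, K):
        t += rng.exponential(1.0 / (yule_rate * k))
        split_times.append(t)
    t_end = split_times[-1] + rng.exponential(1.0 / (yule_rate * K))

    # build topology: at each split a uniformly chosen lineage bifurcates
    class _N:
        __slots__ = ("label", "time", "children")

        def __init__(self, label, time):
            self.label, self.time, self.children = label, time, None

    root = _N(None, 0.0)
    active = [root]
    for st in split_times:
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.time = st
        node.children = (_N(None, st), _N(None, st))
        active.extend(node.children)
    for i, node in enumerate(active):
        node.label = f"sp{i + 1}"
        node.time = t_end

    def newick(node, parent_time):
        if node.children is None:
            return f"{node.label}:{node.time - parent_time:.12f}"
        inner = ",".join(newick(c, node.time) for c in node.children)
        return f"({inner}):{node.time - parent_time:.12f}"

    inner = ",".join(newick(c, root.time) for c in root.children)
    ages = [t_end - st for st in split_times]  # before present
    return f"({inner});", ages


def calibrated_species_tree(
    K: int,
    yule_rate: float,
    seed: int | np.random.Generator,
    min_split_my: float | None = None,
) -> tuple[str, list[float]]:
    """Yule species tree, optionally rescaled so the shallowest split is at
    least ``min_split_my`` My old (emulating a clear barcode gap)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    newick, ages = simulate_species_tree(K, yule_rate, rng)
    if min_split_my is not None and ages and min(ages) < min_split_my:
        factor = min_split_my / min(ages)
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        # restore exact ultrametricity after float scaling
        depth = {}
        for nd in tree.preorder_node_iter():
            depth[nd] = (0.0 if nd.parent_node is None
                         else depth[nd.parent_node] + (nd.edge.length or 0.0))
        max_depth = max(depth[lf] for lf in tree.leaf_node_iter())
        for lf in tree.leaf_node_iter():
            lf.edge.length += max_depth - depth[lf]
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
        ages = [a * factor for a in ages]
    return newick, ages


def _demography(
    species_newick: str, ne: float, K: int
) -> msprime.Demography:
    if K == 1:
        demo = msprime.Demography()
        demo.add_population(name="sp1", initial_size=ne)
        return demo
    return msprime.Demography.from_species_tree(species_newick, initial_size=ne)


def simulate_gene_trees(
    species_newick: str,
    theta: float,
    n_per_species: int | dict[str, int],
    seed: int,
    clock: ClockModel | None = None,
    markers: dict[str, float] | None = None,
) -> dict[str, tuple[str, dict[str, str]]]:
    """One independent coalescent gene tree per marker, embedded in the
    species tree.

    ``markers`` maps marker name -> relative effective size (1.0 nuclear,
    0.25 mitochondrial by default).  Returns per marker (newick in My,
    mapping specimen id -> species label).  Specimen ids are
    ``<number>_<species index>`` so clade suffixes parse downstream.
    """
    clock = clock or ClockModel()
    markers = markers or {"COI": 0.25, "ITS2": 1.0}
    K = species_newick.count("sp")
    names = [f"sp{i + 1}" for i in range(K)]
    if isinstance(n_per_species, int):
        n_per_species = {name: n_per_species for name in names}
    ne_nuclear = theta / (2.0 * clock.rate)  # E[pairwise dist] = theta
    out: dict[str, tuple[str, dict[str, str]]] = {}
    rng = np.random.default_rng(seed)
    for marker, ratio in sorted(markers.items()):
        demo = _demography(species_newick, ne_nuclear * ratio, K)
        for pop in demo.populations:
            pop.initial_size = ne_nuclear * ratio
        ts = msprime.sim_ancestry(
            samples={name: n_per_species[name] for name in names},
            demography=demo,
            ploidy=1,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        tree = ts.first()
        pop_of = {}
        labels = {}
        counter = 1000
        mapping = {}
        for u in ts.samples():
            pop_name = demo.populations[ts.node(u).population].name
            sp_index = int(pop_name[2:])
            sid = f"{counter}_{sp_index}"
            counter += 1
            labels[u] = sid
            mapping[sid] = pop_name
            pop_of[u] = pop_name
        nwk = tree.as_newick(node_labels=labels)
        out[marker] = (nwk, mapping)
    return out


def _overlay_indels(
    tree: dendropy.Tree,
    tip_seqs: dict[str, list[str]],
    length: int,
    indel_rate: float,
    mean_length: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Place indel events on branches; all tips below an event share it.

    Deletions remove a run of ancestral columns from the subtree; insertions
    add columns (i.i.d. bases, invariant afterwards) present only in the
    subtree.  Output is gap-padded to a true alignment.
    """
    # master column list: (sort key tuple) -> per-tip presence handled via masks
    columns: list[tuple[float, int]] = [(float(i), 0) for i in range(length)]
    present: dict[str, set[int]] = {}  # tip -> set of column indices (into `columns`)
    inserted_base: dict[int, str] = {}
    bases = "ACGT"

    def descend(node, mask: set[int]):
        mask = set(mask)
        edge = node.edge.length or 0.0
        n_events = rng.poisson(indel_rate * length * edge) if edge > 0 else 0
        for _ in range(n_events):
            size = int(rng.geometric(1.0 / mean_length))
            if rng.random() < 0.5 and mask:  # deletion
                cols = sorted(mask)
                start = int(rng.integers(len(cols)))
                for c in cols[start : start + size]:
                    mask.discard(c)
            else:  # insertion
                anchor = float(rng.uniform(0, length))
                for k in range(size):
                    columns.append((anchor, len(columns)))
                    idx = len(columns) - 1
                    inserted_base[idx] = bases[int(rng.integers(4))]
                    mask.add(idx)
        if node.is_leaf():
            present[node.taxon.label] = mask
        else:
            for child in node.child_nodes():
                descend(child, mask)

    root_mask = set(range(length))
    for child in tree.seed_node.child_nodes():
        descend(child, root_mask)
    if not present:  # single-node tree
        for lf in tree.leaf_node_iter():
            present[lf.taxon.label] = root_mask

    order = sorted(range(len(columns)), key=lambda i: columns[i])
    out = {}
    for tip, seq in tip_seqs.items():
        mask = present.get(tip, root_mask)
        row = []
        for idx in order:
            if idx not in mask:
                row.append("-")
            elif idx < length:
                row.append(seq[idx])
            else:
                row.append(inserted_base[idx])
        out[tip] = "".join(row)
    return out


def evolve_sequences(
    gene_tree_newick: str,
    length: int,
    clock: ClockModel | None = None,
    model: str = "hky",
    kappa: float = 4.0,
    indel_rate: float = 0.0,
    indel_mean_length: float = 3.0,
    seed: int = 1,
    marker: str = "marker",
) -> MarkerAlignment:
    """Strict-clock sequence evolution along a gene tree (branch lengths in
    My); site-independent HKY or JC substitutions, optional indel overlay."""
    clock = clock or ClockModel()
    tree = dendropy.Tree.get(data=gene_tree_newick, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(seed)
    py_rng = random.Random(int(rng.integers(1, 2**31 - 1)))
    char_model = Jc69() if model == "jc" else Hky85(kappa=kappa)
    matrix = simulate_discrete_chars(
        length, tree, char_model, mutation_rate=clock.rate, rng=py_rng
    )
    tip_seqs = {
        taxon.label: list(matrix[taxon].symbols_as_string().upper().replace("U", "T"))
        for taxon in matrix
    }
    if indel_rate > 0:
        # indel clock also runs in My on the same tree
        seqs = _overlay_indels(
            tree, tip_seqs, length, indel_rate, indel_mean_length, rng
        )
    else:
        seqs = {tip: "".join(seq) for tip, seq in tip_seqs.items()}
    ids = sorted(seqs)
    return MarkerAlignment(marker, [(sid, seqs[sid]) for sid in ids])


def _synthetic_sites(
    partition: dict[str, str],
    K: int,
    sympatry_weight: float,
    rng: np.random.Generator,
) -> list[dict]:
    """Specimen metadata: species-specific regional weights with overlap,
    log-spaced overlapping depth bands, specimens grouped into sites."""
    n_regions = len(REGION_LABELS)
    weights = {}
    centers = np.geomspace(20, 3000, K)
    for s in range(K):
        w = np.full(n_regions, (1.0 - sympatry_weight - 0.3) / (n_regions - 3))
        home = s % n_regions
        w[home] = sympatry_weight
        w[(home + 1) % n_regions] = 0.2
        w[(home + 2) % n_regions] = 0.1
        weights[f"sp{s + 1}"] = w / w.sum()

    by_region: dict[str, list[tuple[str, str]]] = {r: [] for r in REGION_LABELS}
    for sid, sp in sorted(partition.items()):
        region = REGION_LABELS[int(rng.choice(n_regions, p=weights[sp]))]
        by_region[region].append((sid, sp))

    sites = []
    k = 0
    for region in REGION_LABELS:
        pool = by_region[region]
        i = 0
        while i < len(pool):
            size = int(rng.integers(1, 9))
            group = pool[i : i + size]
            i += size
            k += 1
            species = sorted({sp for _, sp in group})
            cs = [centers[int(sp[2:]) - 1] for sp in species]
            lo = max(8.0, min(cs) / 2.5)
            hi = min(4380.0, max(cs) * 2.5)
            sites.append(
                {
                    "site_id": f"SYN{k}",
                    "region": region,
                    "locality": "-",
                    "sample_size": len(group),
                    "clades": ";".join(sorted({sp[2:] for sp in species})),
                    "latitude": round(float(rng.uniform(53, 89)), 5),
                    "longitude": round(float(rng.uniform(-28, 131)), 5),
                    "depth_min": round(lo, 1),
                    "depth_max": round(hi, 1),
                    "date": "2020-01-01",
                    "habitat": "-",
                    "gear": "-",
                    "specimens": ";".join(sid for sid, _ in group),
                }
            )
    return sites


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Full synthetic bundle: two markers, site table, true partition."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    sp_newick, ages = calibrated_species_tree(
        config.K, config.yule_rate, rng, config.min_split_my
    )
    gt = simulate_gene_trees(
        sp_newick,
        config.theta,
        config.n_per_species,
        seed=int(rng.integers(1, 2**31 - 1)),
        clock=config.clock,
        markers={"COI": config.mito_ne_ratio, "ITS2": 1.0},
    )
    alignments = {}
    gene_trees = {}
    partition: dict[str, str] = {}
    for marker, (nwk, mapping) in gt.items():
        gene_trees[marker] = nwk
        length = config.coi_length if marker == "COI" else config.its2_length
        indel = 0.0 if marker == "COI" else config.indel_rate
        alignments[marker] = evolve_sequences(
            nwk,
            length,
            clock=config.clock,
            kappa=config.kappa,
            indel_rate=indel,
            indel_mean_length=config.indel_mean_length,
            seed=int(rng.integers(1, 2**31 - 1)),
            marker=marker,
        )
        partition.update(mapping)
    sites = _synthetic_sites(partition, config.K, config.sympatry_weight, rng)
    return SyntheticDataset(
        true_partition=partition,
        alignments=alignments,
        sites=sites,
        gene_trees=gene_trees,
        species_tree=sp_newick,
        config=config,
    )
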