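"""Multi-marker consensus: reconciling method/marker partitions into final
species hypotheses.

The reference partition is the mitochondrial (COI) statistical-parsimony
network partition; alternative partitions (GMYC per marker, nuclear
networks, posterior samples) either agree with a reference block, split it
(less inclusive) or merge blocks (more inclusive).  Expert reconciliation
is codified as an ordered, parameterized rule set producing an audited
decision per conflicting pair:

- R2  lump a pair that shares a nuclear haplotype when both sides are
      under-sampled and the mitochondrial divergence between them is
      within pooled intraspecific variation;
- R3  reject a split of a reference block proposed by a single method when
      the subgroup is within the parsimony connection limit and has no
      nuclear support;
- R4  keep a nuclear-connected pair separate when the sides share no
      nuclear haplotype and both are well sampled, or when nuclear indel
      events support the separation, or when the mitochondrial divergence
      is large;
- R5  flag a pair as uncertain when either side is severely under-sampled
      (these pairs generate the spread between the lower and upper species
      count bounds).

The undersampled flag (R5) is evaluated before the bare distance clause of
R4: a large mitochondrial distance resting on one or two specimens is
treated as tentative, matching how sparse lineages are judged in practice.
Replaying the decision log against the reference partition reconstructs
the final partition exactly (audit completeness).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ConsensusError",
    "SpeciesPartition",
    "PairEvidence",
    "SplitProposal",
    "EvidenceTable",
    "ReconciliationRules",
    "Decision",
    "ConsensusResult",
    "agreement_code",
    "posterior_partition_frequencies",
    "reconcile",
    "replay_decisions",
]


class ConsensusError(ValueError):
    pass


@dataclass
class SpeciesPartition:
    """A species partition produced by one method on one marker."""

    method: str  # e.g. TCS, GMYC, STACEY-posterior, consensus
    marker: str  # e.g. COI, ITS2x, ITS2s, combined
    blocks: list[frozenset[str]]
    names: list[str] | None = None  # optional block labels (clades)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if seen & b:
                raise ConsensusError("partition blocks overlap")
            seen |= b
        if self.names is not None and len(self.names) != len(self.blocks):
            raise ConsensusError("names do not match blocks")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def block_of(self, name: str) -> frozenset[str]:
        if self.names is None:
            raise ConsensusError("partition has no block names")
        return self.blocks[self.names.index(name)]

    def restricted(self, universe: frozenset[str]) -> list[frozenset[str]]:
        out = [b & universe for b in self.blocks]
        return [b for b in out if b]


def agreement_code(
    reference: SpeciesPartition, other: SpeciesPartition
) -> dict[frozenset[str], str]:
    """Per reference block: 'identical', 'finer' (split across blocks of
    ``other``) or 'coarser' (merged with other reference blocks).

    Both partitions are restricted to their shared specimen universe.  A
    block that is simultaneously split and merged is coded 'coarser' (some
    part joined foreign material — the more inclusive reading).
    """
    shared = reference.universe & other.universe
    if not shared:
        raise ConsensusError("no shared specimens between partitions")
    other_blocks = other.restricted(shared)
    codes: dict[frozenset[str], str] = {}
    for block in reference.restricted(shared):
        hits = [b for b in other_blocks if b & block]
        if len(hits) == 1 and hits[0] == block:
            codes[block] = "identical"
        elif all(b <= block for b in hits):
            codes[block] = "finer"
        else:
            codes[block] = "coarser"
    return codes


def _canonical(blocks: Iterable[frozenset[str]]) -> tuple[tuple[str, ...], ...]:
    return tuple(sorted(tuple(sorted(b)) for b in blocks))


def posterior_partition_frequencies(
    samples: Sequence[Iterable[frozenset[str]]],
) -> list[tuple[tuple[tuple[str, ...], ...], float]]:
    """Relative frequencies of distinct partitions in a posterior sample
    (order-invariant; frequencies sum to 1)."""
    if not samples:
        raise ConsensusError("no posterior samples")
    counts = Counter(_canonical(s) for s in samples)
    total = sum(counts.values())
    return sorted(
        ((part, n / total) for part, n in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )


@dataclass(frozen=True)
class PairEvidence:
    """Evidence bearing on whether two reference clades are one species."""

    shares_nuclear_haplotype: bool = False
    coi_min_inter: float | None = None  # percent
    indel_support: bool = False


@dataclass(frozen=True)
class SplitProposal:
    """A within-block split proposed by one or more methods."""

    block_name: str
    subgroup: frozenset[str]
    proposers: tuple[str, ...]
    steps: int | None = None  # mutational steps to the rest of the block
    nuclear_support: bool = False


@dataclass
class EvidenceTable:
    pairs: dict[frozenset[str], PairEvidence]
    n_specimens: dict[str, int]
    coi_max_intra_pooled: float | None = None  # percent
    connection_limit: int | None = None
    splits: list[SplitProposal] = field(default_factory=list)

    def pair(self, a: str, b: str) -> PairEvidence:
        return self.pairs.get(frozenset((a, b)), PairEvidence())


@dataclass(frozen=True)
class ReconciliationRules:
    well_sampled_n: int = 10
    lump_if_shared_nuclear_and_coi_below: float = 4.0  # percent
    keep_separate_if_coi_above: float = 8.0  # percent
    undersampled_flag_n: int = 3

    def __post_init__(self) -> None:
        if not (
            self.lump_if_shared_nuclear_and_coi_below
            < self.keep_separate_if_coi_above
        ):
            raise ConsensusError("lump threshold must be below keep threshold")


@dataclass(frozen=True)
class Decision:
    subject: tuple[str, ...]  # clade pair, or (block,) for splits
    action: str  # lump | keep | flag-uncertain | reject-split | flag-split
    rule: str
    evidence: str


@dataclass
class ConsensusResult:
    final_partition: SpeciesPartition
    n_species: int
    lower_bound: int
    upper_bound: int
    decisions: list[Decision]

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "species": {
                name: sorted(block)
                for name, block in zip(
                    self.final_partition.names or [], self.final_partition.blocks
                )
            },
            "decisions": [
                {
                    "subject": list(d.subject),
                    "action": d.action,
                    "rule": d.rule,
                    "evidence": d.evidence,
                }
                for d in self.decisions
            ],
        }


def _merge_candidates(
    reference: SpeciesPartition, others: Sequence[SpeciesPartition]
) -> list[frozenset[str]]:
    """Unordered clade-label pairs joined by at least one other partition."""
    assert reference.names is not None
    label_of: dict[str, str] = {}
    for name, block in zip(reference.names, reference.blocks):
        for sid in block:
            label_of[sid] = name
    pairs: set[frozenset[str]] = set()
    for part in others:
        for block in part.blocks:
            labels = {label_of[sid] for sid in block if sid in label_of}
            for a, b in combinations(sorted(labels), 2):
                pairs.add(frozenset((a, b)))
    return sorted(pairs, key=sorted)


def _sort_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def reconcile(
    reference: SpeciesPartition,
    others: Sequence[SpeciesPartition],
    evidence: EvidenceTable,
    rules: ReconciliationRules | None = None,
) -> ConsensusResult:
    """Apply the reconciliation rules to the reference (mitochondrial
    network) partition and the alternative partitions; every departure from
    the reference is logged as a :class:`Decision`."""
    rules = rules or ReconciliationRules()
    if reference.names is None:
        raise ConsensusError("reference partition must carry clade names")
    decisions: list[Decision] = []
    lumps: list[frozenset[str]] = []
    flagged_pairs: list[frozenset[str]] = []

    for pair in _merge_candidates(reference, others):
        a, b = sorted(pair, key=_sort_key)
        ev = evidence.pair(a, b)
        na = evidence.n_specimens.get(a, 0)
        nb = evidence.n_specimens.get(b, 0)
        well = rules.well_sampled_n
        if (
            ev.shares_nuclear_haplotype
            and na < well
            and nb < well
            and ev.coi_min_inter is not None
            and ev.coi_min_inter < rules.lump_if_shared_nuclear_and_coi_below
        ):
            lumps.append(pair)
            decisions.append(
                Decision(
                    (a, b),
                    "lump",
                    "R2",
                    f"shared nuclear haplotype; n={na},{nb} both under-sampled; "
                    f"COI min inter {ev.coi_min_inter}% within pooled "
                    f"intraspecific variation "
                    f"(max {evidence.coi_max_intra_pooled}%)",
                )
            )
        elif not ev.shares_nuclear_haplotype and na >= well and nb >= well:
            decisions.append(
                Decision(
                    (a, b),
                    "keep",
                    "R4",
                    f"no shared nuclear haplotypes; well sampled (n={na},{nb})",
                )
            )
        elif ev.indel_support:
            decisions.append(
                Decision(
                    (a, b), "keep", "R4",
                    "nuclear indel events support separation",
                )
            )
        elif min(na, nb) < rules.undersampled_flag_n:
            flagged_pairs.append(pair)
            decisions.append(
                Decision(
                    (a, b),
                    "flag-uncertain",
                    "R5",
                    f"n={na},{nb}: side below undersampled threshold "
                    f"({rules.undersampled_flag_n})",
                )
            )
        elif (
            ev.coi_min_inter is not None
            and ev.coi_min_inter >= rules.keep_separate_if_coi_above
        ):
            decisions.append(
                Decision(
                    (a, b),
                    "keep",
                    "R4",
                    f"COI min inter {ev.coi_min_inter}% >= "
                    f"{rules.keep_separate_if_coi_above}%",
                )
            )
        else:
            decisions.append(
                Decision(
                    (a, b), "keep", "R1",
                    "no lump rule fired; reference block retained",
                )
            )

    flagged_splits = 0
    for prop in evidence.splits:
        single_method = len(set(prop.proposers)) == 1
        within_limit = (
            prop.steps is not None
            and evidence.connection_limit is not None
            and prop.steps <= evidence.connection_limit
        )
        if single_method and within_limit and not prop.nuclear_support:
            decisions.append(
                Decision(
                    (prop.block_name,),
                    "reject-split",
                    "R3",
                    f"single method ({prop.proposers[0]}); {prop.steps} steps "
                    f"within connection limit {evidence.connection_limit}; "
                    "no nuclear support",
                )
            )
        else:
            flagged_splits += 1
            decisions.append(
                Decision(
                    (prop.block_name,),
                    "flag-split",
                    "R3",
                    f"split by {','.join(prop.proposers)} not dismissible",
                )
            )

    final = replay_decisions(reference, decisions)
    n_species = len(final.blocks)

    # bounds: flagged lump pairs shrink transitively; flagged splits add
    uf = _UnionFind({n for p in flagged_pairs for n in p} )
    for p in flagged_pairs:
        a, b = tuple(p)
        uf.union(a, b)
    potential_merges = sum(
        len([x for x in group]) - 1
        for group in _groups(uf).values()
    ) if flagged_pairs else 0
    return ConsensusResult(
        final_partition=final,
        n_species=n_species,
        lower_bound=n_species - potential_merges,
        upper_bound=n_species + flagged_splits,
        decisions=decisions,
    )


def _groups(uf: "_UnionFind") -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for x in uf.parent:
        groups.setdefault(uf.find(x), []).append(x)
    return groups


def replay_decisions(
    reference: SpeciesPartition, decisions: Sequence[Decision]
) -> SpeciesPartition:
    """Reconstruct the final partition from the reference plus the decision
    log (only 'lump' actions alter the partition with default rules)."""
    if reference.names is None:
        raise ConsensusError("reference partition must carry clade names")
    uf = _UnionFind(reference.names)
    for d in decisions:
        if d.action == "lump":
            uf.union(*d.subject[:2])
    merged: dict[str, list[str]] = {}
    for name in reference.names:
        merged.setdefault(uf.find(name), []).append(name)
    blocks, names = [], []
    for group in sorted(merged.values(), key=lambda g: _sort_key(sorted(g, key=_sort_key)[0])):
        members: set[str] = set()
        for name in group:
            members |= reference.block_of(name)
        blocks.append(frozenset(members))
        names.append("/".join(sorted(group, key=_sort_key)))
    return SpeciesPartition("consensus", "combined", blocks, names)
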