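"""Published delimitation evidence for the North East Atlantic
*Terebellides* survey, assembled from its printed tables.

The survey's per-specimen data are sequence downloads and are not packaged;
what IS printed — per-clade sequence coverage, the disagreements between
delimitation methods, and the distance evidence used to adjudicate them —
is encoded here so the consensus engine can be run and checked against the
published outcome (27 final species, with a plausible range of 25-27).

Specimen ids here are synthetic placeholders (``c<clade>_<k>``); per-clade
counts and subset sizes (COI-sequenced, ITS2-sequenced, both) match the
printed coverage table exactly, which is all the consensus logic consumes.
"""

from __future__ import annotations

from .consensus import (
    EvidenceTable,
    PairEvidence,
    SpeciesPartition,
    SplitProposal,
)

__all__ = [
    "CLADE_COVERAGE",
    "study_partitions",
    "study_evidence",
    "stacey_posterior_samples",
]

#: clade -> (n_specimens, n_COI, n_ITS2, n_both)
CLADE_COVERAGE: dict[str, tuple[int, int, int, int]] = {
    "1": (82, 63, 63, 44), "2": (36, 32, 28, 24), "3": (57, 50, 55, 48),
    "4": (14, 14, 13, 13), "5": (19, 19, 18, 18), "6": (36, 33, 25, 22),
    "7": (12, 12, 6, 6), "8": (41, 40, 29, 28), "9": (3, 2, 2, 1),
    "10": (12, 12, 7, 7), "11": (5, 5, 3, 3), "12": (23, 23, 17, 17),
    "13": (27, 26, 25, 24), "14": (20, 18, 19, 17), "15": (18, 15, 16, 13),
    "16": (62, 55, 50, 43), "17": (1, 1, 1, 1), "18": (3, 3, 2, 2),
    "19": (1, 1, 1, 1), "20": (2, 2, 2, 2), "21": (18, 18, 2, 2),
    "22": (1, 1, 1, 1), "23": (1, 1, 1, 1), "24": (6, 5, 4, 3),
    "25": (4, 4, 3, 3), "26": (3, 1, 3, 1), "27": (1, 1, 1, 1),
    "28": (5, 5, 5, 5),
}

_CLADES = sorted(CLADE_COVERAGE, key=int)


def _ids(clade: str) -> list[str]:
    n = CLADE_COVERAGE[clade][0]
    return [f"c{clade}_{k + 1}" for k in range(n)]


def _coi_ids(clade: str) -> list[str]:
    return _ids(clade)[: CLADE_COVERAGE[clade][1]]


def _its2_ids(clade: str) -> list[str]:
    n, n_coi, n_its2, n_both = CLADE_COVERAGE[clade]
    ids = _ids(clade)
    return ids[:n_both] + ids[n_coi : n_coi + (n_its2 - n_both)]


def _partition(method, marker, id_sets, merge_groups):
    """Blocks = clades, except clades listed together in a merge group."""
    merged_into = {}
    for group in merge_groups:
        for c in group:
            merged_into[c] = "/".join(sorted(group, key=int))
    blocks: dict[str, set[str]] = {}
    for c in _CLADES:
        key = merged_into.get(c, c)
        blocks.setdefault(key, set()).update(id_sets[c])
    names = sorted(blocks, key=lambda k: int(k.split("/")[0]))
    return SpeciesPartition(
        method, marker, [frozenset(blocks[k]) for k in names], names
    )


def study_partitions() -> dict[str, SpeciesPartition]:
    """The method/marker partitions of the survey's delimitation figure.

    Keys: reference (TCS on COI: the 28 networks), and the alternative
    columns with their published merges/splits.
    """
    coi = {c: _coi_ids(c) for c in _CLADES}
    its2 = {c: _its2_ids(c) for c in _CLADES}

    parts = {
        "TCS-COI": _partition("TCS", "COI", coi, []),
        "TCS-ITS2x": _partition(
            "TCS", "ITS2x", its2, [("20", "28"), ("5", "16"), ("4", "26", "27")]
        ),
        "TCS-ITS2s": _partition(
            "TCS", "ITS2s", its2,
            [("20", "28"), ("5", "16"), ("4", "26", "27"), ("12", "13")],
        ),
        "GMYC-ITS2x": _partition(
            "GMYC", "ITS2x", its2, [("20", "28"), ("5", "16"), ("4", "26", "27")]
        ),
        "GMYC-ITS2s": _partition(
            "GMYC", "ITS2s", its2, [("20", "21", "28"), ("4", "26", "27")]
        ),
    }

    # GMYC on COI: clades 20+28 joined, and a six-specimen subgroup of
    # clade 8 proposed as a separate entity (28 putative species in total).
    gmyc_coi = _partition("GMYC", "COI", coi, [("20", "28")])
    blocks, names = list(gmyc_coi.blocks), list(gmyc_coi.names)
    i8 = names.index("8")
    subgroup = frozenset(sorted(blocks[i8])[:6])
    blocks[i8] = blocks[i8] - subgroup
    blocks.insert(i8 + 1, subgroup)
    names.insert(i8 + 1, "8b")
    parts["GMYC-COI"] = SpeciesPartition("GMYC", "COI", blocks, names)
    return parts


def gmyc_coi_subgroup() -> frozenset[str]:
    parts = study_partitions()
    return parts["GMYC-COI"].block_of("8b")


def study_evidence() -> EvidenceTable:
    """Pairwise and split evidence from the printed distance tables and
    the delimitation results."""
    pairs = {
        frozenset(("20", "28")): PairEvidence(
            shares_nuclear_haplotype=True, coi_min_inter=2.6
        ),
        frozenset(("12", "13")): PairEvidence(
            coi_min_inter=8.2, indel_support=True
        ),
        frozenset(("5", "16")): PairEvidence(
            coi_min_inter=12.3, indel_support=True
        ),
        frozenset(("20", "21")): PairEvidence(
            coi_min_inter=12.0, indel_support=True
        ),
        frozenset(("21", "28")): PairEvidence(
            coi_min_inter=12.1, indel_support=True
        ),
        frozenset(("4", "26")): PairEvidence(coi_min_inter=9.9),
        frozenset(("4", "27")): PairEvidence(coi_min_inter=11.1),
        frozenset(("26", "27")): PairEvidence(coi_min_inter=13.3),
    }
    return EvidenceTable(
        pairs=pairs,
        n_specimens={c: CLADE_COVERAGE[c][0] for c in _CLADES},
        coi_max_intra_pooled=3.4,
        connection_limit=13,
        splits=[
            SplitProposal(
                block_name="8",
                subgroup=gmyc_coi_subgroup(),
                proposers=("GMYC-COI",),
                steps=7,
                nuclear_support=False,
            )
        ],
    )


def stacey_posterior_samples(
    n_total: int = 1000, n_lumped: int = 12
) -> list[list[frozenset[str]]]:
    """Constructed posterior partition samples mirroring the survey's
    multispecies-coalescent summary: most samples recover all 28 clades,
    a small fraction lumps clades 20 and 28."""
    both = {c: frozenset(_ids(c)[: CLADE_COVERAGE[c][3]]) for c in _CLADES}
    full = [both[c] for c in _CLADES]
    lumped = [both[c] for c in _CLADES if c not in ("20", "28")]
    lumped.append(both["20"] | both["28"])
    return [full] * (n_total - n_lumped) + [lumped] * n_lumped
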