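"""Alignment handling and haplotype collapsing.

Reads pre-aligned marker matrices (FASTA/NEXUS), extracts per-clade
sub-alignments (sequence ids carry an ``extractionID_clade`` suffix),
enforces equal data coverage by pruning flanking columns with terminal
missing data, and collapses identical sequences into unique haplotypes.

Internally coordinates are 0-based half-open; reports print 1-based
lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC",
    "TERMINAL_MISSING",
    "AlignmentError",
    "MarkerAlignment",
    "PruningPolicy",
    "HaplotypeSet",
    "read_alignment",
    "write_alignment",
    "extract_clade",
    "split_by_clade",
    "prune_to_full_coverage",
    "collapse_identical",
    "clade_haplotype_report",
]

#: Accepted alignment symbols: nucleotides, ambiguity codes, gap, missing.
IUPAC = set("ACGTRYSWKMBDHVN-?")
#: Symbols treated as missing when pruning terminal columns.  Ambiguity
#: codes other than N are real (partially informative) base calls and are
#: not trimmed.
TERMINAL_MISSING = set("-?N")
DETERMINATE = set("ACGT")


class AlignmentError(ValueError):
    pass


@dataclass
class MarkerAlignment:
    """An aligned nucleotide matrix for one marker."""

    marker: str
    rows: list[tuple[str, str]]  # ordered (sequence_id, sequence)

    def __post_init__(self) -> None:
        if not self.rows:
            return
        length = len(self.rows[0][1])
        for sid, seq in self.rows:
            if len(seq) != length:
                raise AlignmentError(f"ragged alignment at {sid!r}")
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        bad = set("".join(s for _, s in self.rows)) - IUPAC
        if bad:
            raise AlignmentError(f"non-IUPAC symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def sequence(self, sid: str) -> str:
        for s, seq in self.rows:
            if s == sid:
                return seq
        raise KeyError(sid)

    def subset(self, ids: Iterable[str]) -> "MarkerAlignment":
        keep = set(ids)
        return MarkerAlignment(
            self.marker, [(s, q) for s, q in self.rows if s in keep]
        )


@dataclass
class PruningPolicy:
    """How to equalize per-sequence coverage before haplotype counting.

    ``removed_ids`` are dropped before any pruning (the published per-clade
    removal lists).  ``mode``:

    - ``prune_flanks`` (default): replay the removals, then trim flanks.
    - ``drop_short``: drop the ``max_removals`` sequences with the least
      determinate data, then trim flanks.
    - ``auto``: try every removal subset of the shortest sequences up to
      ``max_removals`` and keep the outcome with the most haplotypes
      (ties: fewer removals, then lexicographic id order).
    """

    removed_ids: tuple[str, ...] = ()
    mode: str = "prune_flanks"
    max_removals: int = 3


@dataclass
class HaplotypeSet:
    """Unique haplotypes with their member sequence ids."""

    marker: str
    haplotypes: list[tuple[str, list[str]]]  # (representative sequence, members)
    source_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def representatives(self) -> MarkerAlignment:
        return MarkerAlignment(
            self.marker,
            [(members[0], seq) for seq, members in self.haplotypes],
        )

    def membership(self) -> dict[str, int]:
        """sequence id -> haplotype index."""
        out = {}
        for i, (_, members) in enumerate(self.haplotypes):
            for m in members:
                out[m] = i
        return out


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path, fmt: str = "fasta", marker: str = "marker") -> MarkerAlignment:
    """Read an aligned FASTA or NEXUS file (sequential or interleaved)."""
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(str(exc)) from exc
    return MarkerAlignment(
        marker, [(rec.id, _normalize(str(rec.seq))) for rec in msa]
    )


def write_alignment(aln: MarkerAlignment, path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="",
                  annotations={"molecule_type": "DNA"})
        for sid, seq in aln.rows
    ]
    msa = MultipleSeqAlignment(records)
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sid, seq in aln.rows:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    else:
        AlignIO.write(msa, str(path), fmt)


def clade_of(sequence_id: str) -> str | None:
    """Clade label parsed from an ``extractionID_clade`` sequence id."""
    if "_" not in sequence_id:
        return None
    return sequence_id.rsplit("_", 1)[1]


def extract_clade(aln: MarkerAlignment, clade: str) -> MarkerAlignment:
    """Rows whose id suffix equals ``clade``, order preserved."""
    rows = [(s, q) for s, q in aln.rows if clade_of(s) == str(clade)]
    if not rows:
        warnings.warn(f"no sequences for clade {clade!r}", stacklevel=2)
    return MarkerAlignment(aln.marker, rows)


def split_by_clade(aln: MarkerAlignment) -> dict[str, MarkerAlignment]:
    clades: dict[str, list[tuple[str, str]]] = {}
    for sid, seq in aln.rows:
        clades.setdefault(clade_of(sid) or "?", []).append((sid, seq))
    return {c: MarkerAlignment(aln.marker, rows) for c, rows in clades.items()}


def _trim_window(rows: Sequence[tuple[str, str]]) -> tuple[int, int]:
    """Widest [start, stop) window whose terminal columns are determinate
    (no gap/?/N) in every row."""
    length = len(rows[0][1])
    start, stop = 0, length
    while start < stop and any(q[start] in TERMINAL_MISSING for _, q in rows):
        start += 1
    while stop > start and any(q[stop - 1] in TERMINAL_MISSING for _, q in rows):
        stop -= 1
    return start, stop


def _apply_window(aln: MarkerAlignment, drop: set[str]) -> MarkerAlignment:
    rows = [(s, q) for s, q in aln.rows if s not in drop]
    if not rows:
        raise AlignmentError("all sequences removed")
    start, stop = _trim_window(rows)
    if start >= stop:
        raise AlignmentError("pruned to zero columns")
    return MarkerAlignment(aln.marker, [(s, q[start:stop]) for s, q in rows])


def _determinate_count(seq: str) -> int:
    return sum(1 for ch in seq if ch in DETERMINATE)


def prune_to_full_coverage(
    aln: MarkerAlignment, policy: PruningPolicy | None = None
) -> MarkerAlignment:
    """Equalize coverage: drop listed sequences, then trim flanking columns
    in which any retained sequence has terminal missing data.  Interior
    columns are untouched."""
    policy = policy or PruningPolicy()
    unknown = set(policy.removed_ids) - set(aln.ids)
    if unknown:
        raise AlignmentError(f"removed_ids not in alignment: {sorted(unknown)}")
    if policy.mode == "prune_flanks":
        return _apply_window(aln, set(policy.removed_ids))
    if policy.mode == "drop_short":
        by_len = sorted(aln.ids, key=lambda s: (_determinate_count(aln.sequence(s)), s))
        drop = set(policy.removed_ids) | set(by_len[: policy.max_removals])
        return _apply_window(aln, drop)
    if policy.mode == "auto":
        base_drop = set(policy.removed_ids)
        shortest = sorted(
            aln.ids, key=lambda s: (_determinate_count(aln.sequence(s)), s)
        )[: max(policy.max_removals * 2, policy.max_removals)]
        best = None
        for k in range(policy.max_removals + 1):
            for extra in combinations(shortest, k):
                try:
                    pruned = _apply_window(aln, base_drop | set(extra))
                except AlignmentError:
                    continue
                n_hap = len(collapse_identical(pruned))
                key = (-n_hap, k, tuple(sorted(extra)))
                if best is None or key < best[0]:
                    best = (key, pruned)
        if best is None:
            raise AlignmentError("pruned to zero columns")
        return best[1]
    raise AlignmentError(f"unknown pruning mode {policy.mode!r}")


def collapse_identical(
    aln: MarkerAlignment, treat_missing_as_wildcard: bool = False
) -> HaplotypeSet:
    """Collapse rows into unique haplotypes.

    Default identity rule: exact symbol match at every column, gap and
    missing treated as ordinary symbols (uniqhaplo behaviour).  With
    ``treat_missing_as_wildcard`` a row joins the first previously seen
    haplotype it is compatible with (non-ACGT symbols match anything);
    this greedy rule is order-dependent and off by default.
    """
    haplotypes: list[tuple[str, list[str]]] = []
    index: dict[str, int] = {}
    for sid, seq in aln.rows:
        if not treat_missing_as_wildcard:
            i = index.get(seq)
            if i is None:
                index[seq] = len(haplotypes)
                haplotypes.append((seq, [sid]))
            else:
                haplotypes[i][1].append(sid)
        else:
            for i, (rep, members) in enumerate(haplotypes):
                if all(
                    a == b or a not in DETERMINATE or b not in DETERMINATE
                    for a, b in zip(rep, seq)
                ):
                    members.append(sid)
                    break
            else:
                haplotypes.append((seq, [sid]))
    return HaplotypeSet(aln.marker, haplotypes, source_ids=aln.ids)


def clade_haplotype_report(
    pruned: dict[str, MarkerAlignment],
    original: dict[str, MarkerAlignment] | None = None,
) -> pd.DataFrame:
    """Per-clade table: specimens, original/pruned alignment length, and
    haplotype count (the layout of the published haplotype summaries)."""
    rows = []
    for clade in sorted(pruned, key=lambda c: (len(c), c)):
        aln = pruned[clade]
        rows.append(
            {
                "clade": clade,
                "n_specimens": len(aln),
                "original_length": (
                    original[clade].length if original and clade in original else None
                ),
                "pruned_length": aln.length,
                "n_haplotypes": len(collapse_identical(aln)),
            }
        )
    return pd.DataFrame(rows)
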