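"""Uncorrected p-distances and intra/interspecific divergence summaries.

Distances are proportions of differing sites among pairwise-comparable
columns: gaps, '?' and every IUPAC ambiguity code are uninformative and
excluded per pair (pairwise deletion).  Summaries report, per clade, the
intraspecific range and, per clade pair, the interspecific min/max, plus
each clade's nearest neighbour (the clade minimizing the between-clade
minimum) — the layout of the published distance tables.  Internally all
values are fractions; reports print percentages rounded to 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .alignments import MarkerAlignment

__all__ = [
    "DistanceConfig",
    "DistanceSummary",
    "DistanceError",
    "p_distance",
    "distance_matrix",
    "summarize_distances",
    "barcode_gap",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISS = 255


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceConfig:
    gap_policy: str = "pairwise_delete"
    scale: float = 1.0  # distances are fractions in [0, 1]

    def __post_init__(self) -> None:
        if self.gap_policy != "pairwise_delete":
            raise DistanceError("only pairwise_delete is implemented")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(ch, _MISS) for ch in seq], dtype=np.uint8)


def _encode_alignment(aln: MarkerAlignment) -> np.ndarray:
    return np.vstack([_encode(seq) for _, seq in aln.rows])


def p_distance(seq_a: str, seq_b: str, config: DistanceConfig | None = None) -> float:
    """Uncorrected p-distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences differ in length")
    a, b = _encode(seq_a), _encode(seq_b)
    comparable = (a != _MISS) & (b != _MISS)
    n = int(comparable.sum())
    if n == 0:
        raise DistanceError("no comparable columns")
    return float((a[comparable] != b[comparable]).sum()) / n


def distance_matrix(aln: MarkerAlignment) -> np.ndarray:
    """Symmetric pairwise p-distance matrix (pairwise deletion)."""
    enc = _encode_alignment(aln)
    n = enc.shape[0]
    dist = np.zeros((n, n))
    ok = enc != _MISS
    for i in range(n):
        comp = ok[i] & ok[i + 1 :]
        counts = comp.sum(axis=1)
        if np.any(counts == 0):
            j = int(np.argmax(counts == 0)) + i + 1
            raise DistanceError(
                f"no comparable columns between rows {i} and {j}"
            )
        diff = ((enc[i] != enc[i + 1 :]) & comp).sum(axis=1)
        dist[i, i + 1 :] = diff / counts
        dist[i + 1 :, i] = dist[i, i + 1 :]
    return dist


@dataclass
class DistanceSummary:
    """Intra/inter divergence extremes with nearest-neighbour annotation."""

    intra: dict[str, tuple[float, float] | None]  # None: singleton clade (NA)
    inter: dict[tuple[str, str], tuple[float, float]]  # unordered pairs, key sorted
    nearest: dict[str, str]
    nearest_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    farthest: dict[str, str] = field(default_factory=dict)
    farthest_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def pair(self, a: str, b: str) -> tuple[float, float]:
        return self.inter[tuple(sorted((a, b), key=str))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade in sorted(self.intra, key=lambda c: (len(c), c)):
            intra = self.intra[clade]
            fmt = lambda rng: f"{100 * rng[0]:.1f}-{100 * rng[1]:.1f}"
            rows.append(
                {
                    "clade": clade,
                    "intra_pct": "NA" if intra is None else fmt(intra),
                    "min_inter_pct": fmt(self.nearest_range[clade]),
                    "nearest": self.nearest[clade],
                    "max_inter_pct": fmt(self.farthest_range[clade]),
                    "farthest": self.farthest[clade],
                }
            )
        return pd.DataFrame(rows)


def summarize_distances(
    clade_alignments: Mapping[str, MarkerAlignment],
    config: DistanceConfig | None = None,
) -> DistanceSummary:
    """Intra- and interspecific distance extremes over per-clade alignments.

    All sequences must come from one shared alignment (equal lengths).
    Nearest neighbour of clade c = argmin over d≠c of min cross-pair
    distance; its reported range is (min, max) of the cross distances to
    that neighbour only, reproducing the published "min–max (clade)" cells.
    """
    clades = sorted(clade_alignments, key=lambda c: (len(c), c))
    if len(clades) < 2:
        raise DistanceError("need >=2 clades")
    enc = {c: _encode_alignment(clade_alignments[c]) for c in clades}

    def _cross(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        lo, hi = np.inf, -np.inf
        okb = b != _MISS
        for row in a:
            comp = (row != _MISS) & okb
            counts = comp.sum(axis=1)
            if np.any(counts == 0):
                raise DistanceError("no comparable columns in cross pair")
            d = ((row != b) & comp).sum(axis=1) / counts
            lo, hi = min(lo, float(d.min())), max(hi, float(d.max()))
        return lo, hi

    intra: dict[str, tuple[float, float] | None] = {}
    for c in clades:
        a = enc[c]
        if a.shape[0] < 2:
            intra[c] = None
            continue
        vals = []
        okm = a != _MISS
        for i in range(a.shape[0] - 1):
            comp = okm[i] & okm[i + 1 :]
            counts = comp.sum(axis=1)
            if np.any(counts == 0):
                raise DistanceError(f"no comparable columns within clade {c}")
            vals.append(((a[i] != a[i + 1 :]) & comp).sum(axis=1) / counts)
        flat = np.concatenate(vals)
        intra[c] = (float(flat.min()), float(flat.max()))

    inter: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in combinations(clades, 2):
        inter[tuple(sorted((a, b), key=str))] = _cross(enc[a], enc[b])

    nearest, nearest_range, farthest, farthest_range = {}, {}, {}, {}
    for c in clades:
        others = [d for d in clades if d != c]
        key = lambda d: inter[tuple(sorted((c, d), key=str))]
        nn = min(others, key=lambda d: (key(d)[0], d))
        ff = max(others, key=lambda d: (key(d)[1], d))
        nearest[c], nearest_range[c] = nn, key(nn)
        farthest[c], farthest_range[c] = ff, key(ff)
    return DistanceSummary(intra, inter, nearest, nearest_range, farthest, farthest_range)


def barcode_gap(summary: DistanceSummary) -> tuple[float, float, bool]:
    """(max intraspecific, min interspecific, gap exists) over the summary."""
    intra_vals = [rng[1] for rng in summary.intra.values() if rng is not None]
    if not summary.inter:
        raise DistanceError("need >=2 clades")
    max_intra = max(intra_vals) if intra_vals else 0.0
    min_inter = min(rng[0] for rng in summary.inter.values())
    return max_intra, min_inter, min_inter > max_intra
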