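"""Pairwise sequence distances: Kimura 2-parameter and p-distance.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions
and corrects the observed proportions for multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the transition and transversion proportions over the sites
where both sequences carry an unambiguous base (pairwise deletion).  Pairs
whose overlap falls below a minimum site count, or that are saturated
(log arguments <= 0), carry an explicit *undefined* marker: they are stored
as NaN with a defined-mask, never silently treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import Library, SpecimenRecord

#: Minimum overlapping unambiguous sites for a distance to be defined.
DEFAULT_MIN_OVERLAP = 100

# A/C/G/T -> 0..3; every other character (gap, N, IUPAC ambiguity) -> 4.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
# purine flag for transition detection (A, G purines; C, T pyrimidines)
_IS_PURINE = np.array([True, False, True, False, False])


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_library(library: Library) -> np.ndarray:
    """Stack a library into an (n_records, alignment_length) code matrix."""
    if not library.aligned:
        raise ValueError(
            "library is not aligned; align sequences (equal lengths) first"
        )
    return np.vstack([encode_sequence(r.sequence) for r in library])


@dataclass(frozen=True)
class SitePatternCounts:
    """Shared-site tallies between two aligned sequences."""

    valid_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if min(self.valid_sites, self.transitions, self.transversions) < 0:
            raise ValueError("negative site count")
        if self.transitions + self.transversions > self.valid_sites:
            raise ValueError("more differences than valid sites")


def count_site_patterns(a: SpecimenRecord, b: SpecimenRecord) -> SitePatternCounts:
    """Count valid sites, transitions and transversions for one pair.

    Only columns where both sequences have an unambiguous A/C/G/T count;
    A<->G and C<->T differences are transitions, all others transversions.
    """
    if len(a.sequence) != len(b.sequence):
        raise ValueError(
            f"sequences {a.specimen_id!r} and {b.specimen_id!r} have unequal lengths"
        )
    xa = encode_sequence(a.sequence)
    xb = encode_sequence(b.sequence)
    valid = (xa < 4) & (xb < 4)
    diff = valid & (xa != xb)
    ts = diff & (_IS_PURINE[xa] == _IS_PURINE[xb])
    return SitePatternCounts(
        valid_sites=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def kimura2p(
    counts: SitePatternCounts, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """K2P distance from site-pattern counts; NaN marks an undefined pair.

    Undefined when the overlap is below ``min_overlap`` or the pair is
    saturated (1 - 2P - Q <= 0 or 1 - 2Q <= 0, outside the log domain).
    """
    n = counts.valid_sites
    if n < min_overlap:
        return math.nan
    p = counts.transitions / n
    q = counts.transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def p_distance(
    counts: SitePatternCounts, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Uncorrected proportion of differing sites; NaN when overlap too low."""
    if counts.valid_sites < min_overlap:
        return math.nan
    return (counts.transitions + counts.transversions) / counts.valid_sites


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an undefined-pair mask.

    ``values[i, j]`` is a proportion (unitless); undefined pairs hold NaN
    and ``defined[i, j]`` is False.  ``n_sites`` records the pairwise
    overlap used for each entry.
    """

    ids: list[str]
    model: str
    values: np.ndarray
    defined: np.ndarray
    n_sites: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        self.index = {sid: i for i, sid in enumerate(self.ids)}

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int((~self.defined[iu]).sum())

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        idx = np.array([self.index[i] for i in ids], dtype=int)
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            model=self.model,
            values=self.values[np.ix_(idx, idx)],
            defined=self.defined[np.ix_(idx, idx)],
            n_sites=self.n_sites[np.ix_(idx, idx)],
        )


def build_distance_matrix(
    library: Library,
    model: str = "K2P",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs distance matrix under K2P or p-distance.

    Pairwise deletion: each pair uses only the columns where both carry an
    unambiguous base.  Row-blocked numpy comparison keeps this O(n^2 * L)
    with small constants.
    """
    model = model.upper() if model.lower() != "p" else "p"
    if model not in ("K2P", "p"):
        raise ValueError(f"unknown distance model: {model!r}")
    codes = encode_library(library)
    n = codes.shape[0]
    valid_any = codes < 4
    is_purine = _IS_PURINE[codes]

    nsites = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        block = slice(i + 1, n)
        valid = valid_any[i] & valid_any[block]
        diff = valid & (codes[i] != codes[block])
        ts_blk = diff & (is_purine[i] == is_purine[block])
        nsites[i, block] = valid.sum(axis=1)
        ts[i, block] = ts_blk.sum(axis=1)
        tv[i, block] = diff.sum(axis=1) - ts[i, block]

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(nsites > 0, nsites, 1)
        P = ts / denom
        Q = tv / denom
        if model == "K2P":
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            dist = -0.5 * np.log(np.where(w1 > 0, w1, np.nan)) - 0.25 * np.log(
                np.where(w2 > 0, w2, np.nan)
            )
        else:
            dist = P + Q

    defined = (nsites >= min_overlap) & np.isfinite(dist)
    dist = np.where(defined, dist, np.nan)

    # symmetrise the upper triangle
    iu = np.triu_indices(n, k=1)
    full = np.zeros((n, n))
    full[iu] = dist[iu]
    full = full + full.T
    full[~(defined | defined.T)] = np.nan
    np.fill_diagonal(full, 0.0)
    defined_full = defined | defined.T
    np.fill_diagonal(defined_full, True)
    nsites_full = nsites + nsites.T

    return DistanceMatrix(
        ids=list(library.ids),
        model=model,
        values=full,
        defined=defined_full,
        n_sites=nsites_full,
    )


def write_long_form(matrix: DistanceMatrix, path: str | Path) -> None:
    """Export as long-form TSV: id1, id2, distance, n_sites (upper triangle)."""
    rows = []
    n = len(matrix.ids)
    for i in range(n - 1):
        for j in range(i + 1, n):
            rows.append(
                {
                    "id1": matrix.ids[i],
                    "id2": matrix.ids[j],
                    "distance": matrix.values[i, j],
                    "n_sites": matrix.n_sites[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phylip_lower(matrix: DistanceMatrix, path: str | Path) -> None:
    """Export as a PHYLIP-style lower-triangular plain-text matrix."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, sid in enumerate(matrix.ids):
            vals = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(i))
            fh.write(f"{sid:<12s} {vals}".rstrip() + "\n")
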