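"""Barcode-gap statistics and identification-success analysis.

A species shows a *barcode gap* when its maximum intraspecific divergence
is smaller than its distance to the nearest heterospecific individual
(nearest-neighbor, NN, distance).  Identification *failure* is defined
strictly as haplotype sharing: a species fails if and only if at least one
of its haplotypes also occurs in another species.  Species whose NN
distance falls below a reporting threshold (default 2%) but that retain
unique haplotypes are counted separately, not failed.

The module also produces the dataset-level summaries: pooled intraspecific
and NN distance means/ranges (with a deep-split exclusion variant),
specimens-per-species and haplotypes-per-species tallies, and histogram
counts of the intra- and NN-distance distributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, encode_sequence
from .io_formats import Library

logger = logging.getLogger("barcodegap")


@dataclass
class GapConfig:
    """Thresholds for gap-analysis reporting.

    deep_split_exclusion: intraspecific distances above this (default 10%)
        are treated as likely overlooked species and excluded from the
        filtered intraspecific mean.
    identification_threshold_report: NN distances below this (default 2%)
        are counted as "shallow" in reports (informational only).
    histogram_bin_width: bin width for distance histograms (default 1%).
    """

    deep_split_exclusion: float = 0.10
    identification_threshold_report: float = 0.02
    histogram_bin_width: float = 0.01

    def __post_init__(self) -> None:
        for name in ("deep_split_exclusion", "identification_threshold_report",
                     "histogram_bin_width"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SpeciesGapSummary:
    """Per-species barcode-gap statistics."""

    species: str
    n_specimens: int
    n_haplotypes: int
    max_intra: Optional[float]  # None when n == 1
    mean_intra: Optional[float]
    nn_distance: float
    nn_species: str
    shares_haplotype_with: frozenset[str] = field(default_factory=frozenset)

    @property
    def has_gap(self) -> bool:
        """True when max intraspecific distance < NN distance.

        Singletons (undefined max_intra) have a gap by convention whenever
        their NN distance is positive.
        """
        if self.max_intra is None:
            return self.nn_distance > 0.0
        return self.max_intra < self.nn_distance


def _haplotype_compatible(
    sa: str, sb: str, ambiguity_tolerance: bool
) -> bool:
    """Decide whether two aligned sequences represent one haplotype.

    Strict mode (tolerance off): exact string equality over the common
    covered interval (between the first and last non-gap character of
    each).  With ambiguity tolerance on, columns where either sequence is
    ambiguous are skipped, i.e. only unambiguous conflicts separate
    haplotypes.
    """
    xa = encode_sequence(sa)
    xb = encode_sequence(sb)
    if ambiguity_tolerance:
        both = (xa < 4) & (xb < 4)
        return bool(np.all(xa[both] == xb[both]))
    ga = np.flatnonzero(np.frombuffer(sa.encode(), np.uint8) != ord("-"))
    gb = np.flatnonzero(np.frombuffer(sb.encode(), np.uint8) != ord("-"))
    if ga.size == 0 or gb.size == 0:
        return False
    lo, hi = max(ga[0], gb[0]), min(ga[-1], gb[-1])
    if hi < lo:
        return False
    return sa[lo : hi + 1] == sb[lo : hi + 1]


def collapse_haplotypes(
    library: Library, ambiguity_tolerance: bool = False
) -> dict[str, list[tuple[str, str]]]:
    """Group specimens into haplotypes.

    Returns a map haplotype_label -> list of (specimen_id, species).
    Labels are the lexicographically smallest member specimen id.  The
    pairwise compatibility relation is closed transitively (connected
    components), so a partition is always returned.
    """
    if not library.aligned:
        raise ValueError("haplotype collapsing requires an aligned library")
    records = library.records
    n = len(records)

    # fast path: identical strings always share a haplotype
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.sequence.upper(), []).append(i)
    reps = list(groups.values())

    parent = list(range(len(reps)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # pair phase only needed when gaps/ambiguities can bridge groups
    needs_pairs = any(
        set(seq) - set("ACGT") for seq in groups
    )
    if needs_pairs and len(reps) > 1:
        seqs = [records[g[0]].sequence.upper() for g in reps]
        for a, b in itertools.combinations(range(len(reps)), 2):
            if _haplotype_compatible(seqs[a], seqs[b], ambiguity_tolerance):
                union(a, b)

    clusters: dict[int, list[int]] = {}
    for gi, members in enumerate(reps):
        clusters.setdefault(find(gi), []).extend(members)

    out: dict[str, list[tuple[str, str]]] = {}
    for members in clusters.values():
        pairs = sorted(
            (records[i].specimen_id, records[i].species) for i in members
        )
        out[pairs[0][0]] = pairs
    return out


def species_haplotype_counts(
    haplotypes: dict[str, list[tuple[str, str]]]
) -> dict[str, int]:
    """Number of distinct haplotypes observed per species."""
    counts: dict[str, set[str]] = {}
    for label, members in haplotypes.items():
        for _sid, sp in members:
            counts.setdefault(sp, set()).add(label)
    return {sp: len(labels) for sp, labels in counts.items()}


def haplotype_sharing_map(
    haplotypes: dict[str, list[tuple[str, str]]]
) -> dict[str, set[str]]:
    """For each species, the set of other species it shares a haplotype with."""
    sharing: dict[str, set[str]] = {}
    for members in haplotypes.values():
        species = {sp for _sid, sp in members if sp}
        if len(species) > 1:
            for sp in species:
                sharing.setdefault(sp, set()).update(species - {sp})
    return sharing


def species_gap_summary(
    matrix: DistanceMatrix,
    library: Library,
    haplotypes: Optional[dict[str, list[tuple[str, str]]]] = None,
) -> list[SpeciesGapSummary]:
    """Per-species max/mean intraspecific distance and NN distance.

    NN distance is the minimum distance from any individual of the species
    to any heterospecific individual (nearest-neighbor semantics, not
    centroid distances); ties in the NN species break to the
    lexicographically smallest name.  Undefined distances are excluded
    from every min/mean with a logged count.
    """
    unlabeled = [r.specimen_id for r in library if not r.species]
    if unlabeled:
        raise ValueError(f"specimens without species label: {unlabeled[:5]}")
    by_species = library.by_species()
    if len(by_species) < 2:
        raise ValueError("gap analysis needs at least two species")

    if haplotypes is None:
        haplotypes = collapse_haplotypes(library)
    hap_counts = species_haplotype_counts(haplotypes)
    sharing = haplotype_sharing_map(haplotypes)

    idx = matrix.index
    indices = {sp: np.array([idx[r.specimen_id] for r in recs])
               for sp, recs in by_species.items()}
    all_species = sorted(by_species)
    species_of_col = np.empty(len(matrix.ids), dtype=object)
    for sp, ix in indices.items():
        species_of_col[ix] = sp

    n_undef_skipped = 0
    summaries = []
    for sp in all_species:
        own = indices[sp]
        rows = matrix.values[own]
        # intraspecific pairs
        if len(own) >= 2:
            sub = matrix.values[np.ix_(own, own)]
            iu = np.triu_indices(len(own), k=1)
            intra = sub[iu]
            n_undef_skipped += int(np.isnan(intra).sum())
            intra = intra[~np.isnan(intra)]
            max_intra = float(intra.max()) if intra.size else None
            mean_intra = float(intra.mean()) if intra.size else None
        else:
            max_intra = mean_intra = None
        # nearest heterospecific individual
        mask_other = np.ones(len(matrix.ids), dtype=bool)
        mask_other[own] = False
        cross = rows[:, mask_other]
        other_species = species_of_col[mask_other]
        finite = ~np.isnan(cross)
        n_undef_skipped += int((~finite).sum())
        if not finite.any():
            raise ValueError(f"species {sp!r} has no defined heterospecific distance")
        nn_distance = float(np.nanmin(cross))
        hit_cols = np.unique(np.where(np.isclose(cross, nn_distance) & finite)[1])
        nn_species = min(str(other_species[c]) for c in hit_cols)
        summaries.append(
            SpeciesGapSummary(
                species=sp,
                n_specimens=len(own),
                n_haplotypes=hap_counts.get(sp, 1),
                max_intra=max_intra,
                mean_intra=mean_intra,
                nn_distance=nn_distance,
                nn_species=nn_species,
                shares_haplotype_with=frozenset(sharing.get(sp, set())),
            )
        )
    if n_undef_skipped:
        logger.info("gap analysis skipped %d undefined distance entries",
                    n_undef_skipped)
    return summaries


def identification_success(
    summaries: list[SpeciesGapSummary],
    haplotypes: Optional[dict[str, list[tuple[str, str]]]] = None,
    threshold_report: float = 0.02,
) -> dict:
    """Identification-success report under the haplotype-sharing criterion.

    A species fails iff it shares at least one haplotype with another
    species.  The report groups failing species into sharing components
    (pairs, trios, ...), and separately counts species whose NN distance
    is below ``threshold_report`` despite unique haplotypes.
    """
    if not summaries:
        raise ValueError("no species summaries")
    sharing = {s.species: set(s.shares_haplotype_with) for s in summaries}
    if haplotypes is not None:
        for sp, others in haplotype_sharing_map(haplotypes).items():
            sharing.setdefault(sp, set()).update(others)

    failing = sorted(sp for sp, others in sharing.items() if others)
    # connected components of the sharing graph
    components: list[list[str]] = []
    seen: set[str] = set()
    for sp in failing:
        if sp in seen:
            continue
        comp, stack = [], [sp]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(sharing.get(cur, ()))
        components.append(sorted(comp))

    s_total = len(summaries)
    n_fail = len(failing)
    n_success = s_total - n_fail
    shallow = sorted(
        s.species
        for s in summaries
        if not sharing.get(s.species) and s.nn_distance < threshold_report
    )
    return {
        "n_species": s_total,
        "n_failing": n_fail,
        "n_success": n_success,
        "success_percent": 100.0 * n_success / s_total,
        "failing_species": failing,
        "sharing_components": components,
        "n_shallow_divergence": len(shallow),
        "shallow_divergence_species": shallow,
    }


def _tally_table(counts_per_species: dict[str, int], max_row: int = 10) -> pd.DataFrame:
    """Species tally by count (1, 2, ..., max_row, >max_row) with percentages.

    Cumulative percentages are computed from unrounded values; rounding
    happens only at the report layer.
    """
    s_total = len(counts_per_species)
    rows = []
    values = sorted(counts_per_species.values())
    for k in range(1, max_row + 1):
        c = sum(1 for v in values if v == k)
        rows.append({"count": str(k), "n_species": c})
    c_over = sum(1 for v in values if v > max_row)
    rows.append({"count": f">{max_row}", "n_species": c_over})
    df = pd.DataFrame(rows)
    df["percent"] = 100.0 * df["n_species"] / s_total
    df["cumulative_percent"] = df["percent"].cumsum()
    return df


def tally_by_sample_size(summaries: list[SpeciesGapSummary]) -> pd.DataFrame:
    return _tally_table({s.species: s.n_specimens for s in summaries})


def tally_by_haplotypes(summaries: list[SpeciesGapSummary]) -> pd.DataFrame:
    return _tally_table({s.species: s.n_haplotypes for s in summaries})


def distance_histograms(
    summaries: list[SpeciesGapSummary],
    matrix: DistanceMatrix,
    library: Library,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Histogram counts of intraspecific pair distances and per-species NN.

    Mirrors the classic within/between species distance histogram: black
    bars (intraspecific, all conspecific pairs pooled) vs white bars
    (per-species nearest-neighbor distance).
    """
    intra = pooled_intraspecific_distances(matrix, library)
    nn = np.array([s.nn_distance for s in summaries])
    top = max(intra.max() if intra.size else 0.0, nn.max() if nn.size else 0.0)
    n_bins = max(1, int(math.ceil(top / bin_width + 1e-9)))
    edges = np.arange(0, n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(intra, bins=edges)
    nn_counts, _ = np.histogram(nn, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "intra_count": intra_counts,
            "nn_count": nn_counts,
        }
    )


def pooled_intraspecific_distances(
    matrix: DistanceMatrix, library: Library
) -> np.ndarray:
    """All defined conspecific pair distances, pooled across species."""
    idx = matrix.index
    out = []
    for _sp, recs in library.by_species().items():
        ix = np.array([idx[r.specimen_id] for r in recs])
        if len(ix) < 2:
            continue
        sub = matrix.values[np.ix_(ix, ix)]
        iu = np.triu_indices(len(ix), k=1)
        vals = sub[iu]
        out.append(vals[~np.isnan(vals)])
    return np.concatenate(out) if out else np.array([])


def dataset_summary(
    summaries: list[SpeciesGapSummary],
    matrix: DistanceMatrix,
    library: Library,
    config: Optional[GapConfig] = None,
) -> dict:
    """Dataset-level aggregate report.

    Pooled intraspecific mean/range (plus the per-species-mean variant and
    the deep-split-filtered mean), NN distance mean/range, tallies by
    sample size and by haplotype count, histogram counts, and the count of
    species below the NN reporting threshold.
    """
    if config is None:
        config = GapConfig()
    intra = pooled_intraspecific_distances(matrix, library)
    nn = np.array([s.nn_distance for s in summaries])

    # exclude species whose max_intra exceeds the deep-split threshold
    deep = {s.species for s in summaries
            if s.max_intra is not None and s.max_intra > config.deep_split_exclusion}
    if deep:
        shallow_lib = library.subset_species(set(library.species_names) - deep)
        intra_filtered = pooled_intraspecific_distances(matrix, shallow_lib)
    else:
        intra_filtered = intra

    per_species_means = np.array(
        [s.mean_intra for s in summaries if s.mean_intra is not None]
    )

    def _stats(x: np.ndarray) -> dict:
        if x.size == 0:
            return {"mean": None, "min": None, "max": None, "n": 0}
        return {"mean": float(x.mean()), "min": float(x.min()),
                "max": float(x.max()), "n": int(x.size)}

    return {
        "intraspecific": _stats(intra),
        "intraspecific_filtered": _stats(intra_filtered),
        "intraspecific_per_species_mean": _stats(per_species_means),
        "nearest_neighbor": _stats(nn),
        "n_deep_split_species": len(deep),
        "deep_split_species": sorted(deep),
        "n_species_nn_below_threshold": int(
            (nn < config.identification_threshold_report).sum()
        ),
        "n_species_with_gap": sum(1 for s in summaries if s.has_gap),
        "tally_by_sample_size": tally_by_sample_size(summaries),
        "tally_by_haplotypes": tally_by_haplotypes(summaries),
        "histogram": distance_histograms(
            summaries, matrix, library, config.histogram_bin_width
        ),
        "n_undefined_pairs": matrix.n_undefined_pairs,
    }


def summaries_to_frame(summaries: list[SpeciesGapSummary]) -> pd.DataFrame:
    """Per-species summary as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "species": s.species,
            "n_specimens": s.n_specimens,
            "n_haplotypes": s.n_haplotypes,
            "max_intra": s.max_intra,
            "mean_intra": s.mean_intra,
            "nn_distance": s.nn_distance,
            "nn_species": s.nn_species,
            "has_gap": s.has_gap,
            "shares_with": ";".join(sorted(s.shares_haplotype_with)),
        }
        for s in summaries
    )
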