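"""Haplotype collapsing, per-species gap summaries, identification success
and the dataset-level tallies."""

import itertools
import math

import numpy as np
import pytest

from barcodegap.distances import (
    DistanceMatrix,
    build_distance_matrix,
    count_site_patterns,
    kimura2p,
)
from barcodegap.gap_analysis import (
    GapConfig,
    SpeciesGapSummary,
    collapse_haplotypes,
    dataset_summary,
    identification_success,
    species_gap_summary,
    tally_by_sample_size,
)
from barcodegap.io_formats import Library, SpecimenRecord


def rec(seq, sid, species=""):
    return SpecimenRecord(specimen_id=sid, sequence=seq, species=species)


class TestCollapseHaplotypes:
    def test_identical_and_distinct(self):
        lib = Library(
            records=[rec("ACGT", "a"), rec("ACGT", "b"), rec("ACGA", "c")],
            aligned=True,
        )
        haps = collapse_haplotypes(lib)
        groups = sorted(sorted(s for s, _ in v) for v in haps.values())
        assert groups == [["a", "b"], ["c"]]

    def test_ambiguity_tolerance_modes(self):
        lib = Library(records=[rec("ACGT", "a"), rec("ACGN", "b")], aligned=True)
        assert len(collapse_haplotypes(lib, ambiguity_tolerance=True)) == 1
        assert len(collapse_haplotypes(lib, ambiguity_tolerance=False)) == 2

    def test_strict_mode_trims_terminal_gaps(self):
        # same haplotype over the shared covered interval
        lib = Library(records=[rec("-CGTA", "a"), rec("ACGT-", "b")], aligned=True)
        assert len(collapse_haplotypes(lib)) == 1


def _transit(seq, positions):
    """Apply transitions (A<->G, C<->T) at the given positions."""
    swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def _mini_library():
    """Two species of 2, one singleton; handmade moderate distances."""
    base = ("ACGT" * 75)  # 300 sites
    a1 = base
    a2 = _transit(base, [299])  # one transition
    b1 = _transit(base, range(0, 90, 2))  # 45 substitutions (~15%)
    b2 = _transit(b1, [299])
    c = _transit(base, range(100, 190, 2))
    return Library(
        records=[
            rec(a1, "a1", "Alpha sp"),
            rec(a2, "a2", "Alpha sp"),
            rec(b1, "b1", "Beta sp"),
            rec(b2, "b2", "Beta sp"),
            rec(c, "c1", "Gamma sp"),
        ],
        aligned=True,
    )


class TestSpeciesGapSummary:
    def test_matches_brute_force_oracle(self, small_library):
        matrix = build_distance_matrix(small_library)
        summaries = {s.species: s for s in species_gap_summary(matrix, small_library)}
        recs = small_library.records
        for sp, summary in summaries.items():
            own = [r for r in recs if r.species == sp]
            other = [r for r in recs if r.species != sp]
            intra = [
                kimura2p(count_site_patterns(x, y))
                for x, y in itertools.combinations(own, 2)
            ]
            intra = [d for d in intra if not math.isnan(d)]
            if intra:
                assert summary.max_intra == pytest.approx(max(intra))
                assert summary.mean_intra == pytest.approx(np.mean(intra))
            else:
                assert summary.max_intra is None
            nn = min(
                kimura2p(count_site_patterns(x, y))
                for x in own
                for y in other
                if not math.isnan(kimura2p(count_site_patterns(x, y)))
            )
            assert summary.nn_distance == pytest.approx(nn)

    def test_gap_flags_and_nn_species(self):
        lib = _mini_library()
        matrix = build_distance_matrix(lib)
        summaries = {s.species: s for s in species_gap_summary(matrix, lib)}
        alpha = summaries["Alpha sp"]
        assert alpha.n_specimens == 2 and alpha.n_haplotypes == 2
        assert alpha.max_intra == pytest.approx(
            kimura2p(count_site_patterns(lib.records[0], lib.records[1]))
        )
        assert alpha.max_intra < 0.01 < alpha.nn_distance
        assert alpha.has_gap
        gamma = summaries["Gamma sp"]
        assert gamma.max_intra is None  # singleton
        assert gamma.has_gap  # by convention when NN > 0

    def test_shared_haplotype_gives_zero_nn_and_no_gap(self):
        seq = "ACGT" * 75
        lib = Library(
            records=[
                rec(seq, "x1", "X sp"), rec(seq, "x2", "X sp"),
                rec(seq, "y1", "Y sp"),
            ],
            aligned=True,
        )
        summaries = {s.species: s for s in
                     species_gap_summary(build_distance_matrix(lib), lib)}
        assert summaries["X sp"].nn_distance == 0.0
        assert not summaries["X sp"].has_gap
        assert summaries["Y sp"].shares_haplotype_with == {"X sp"}

    def test_single_species_raises(self):
        lib = Library(records=[rec("ACGT" * 75, "a", "A sp")], aligned=True)
        with pytest.raises(ValueError, match="two species"):
            species_gap_summary(build_distance_matrix(lib), lib)

    def test_adding_species_never_increases_nn(self, clean_library, clean_matrix):
        library, _ = clean_library
        species = library.species_names
        sub = library.subset_species(species[:20])
        base = {s.species: s.nn_distance for s in species_gap_summary(
            clean_matrix.submatrix(sub.ids), sub)}
        bigger = library.subset_species(species[:30])
        grown = {s.species: s.nn_distance for s in species_gap_summary(
            clean_matrix.submatrix(bigger.ids), bigger)}
        for sp, nn in base.items():
            assert grown[sp] <= nn + 1e-15


def _summary(species, n=1, n_hap=1, nn=0.1, shares=()):
    return SpeciesGapSummary(
        species=species, n_specimens=n, n_haplotypes=n_hap,
        max_intra=None if n == 1 else 0.004, mean_intra=None if n == 1 else 0.003,
        nn_distance=nn, nn_species="other", shares_haplotype_with=frozenset(shares),
    )


class TestIdentificationSuccess:
    def test_survey_scale_arithmetic(self):
        # 1872 species of which 31 share haplotypes (14 pairs + one trio)
        summaries = []
        k = 0
        for pair in range(14):
            a, b = f"P{pair}a", f"P{pair}b"
            summaries += [_summary(a, shares=[b]), _summary(b, shares=[a])]
            k += 2
        trio = ["Ta", "Tb", "Tc"]
        for sp in trio:
            summaries.append(_summary(sp, shares=set(trio) - {sp}))
        k += 3
        summaries += [_summary(f"S{i}") for i in range(1872 - k)]
        report = identification_success(summaries)
        assert report["n_species"] == 1872
        assert report["n_failing"] == 31
        assert report["n_success"] == 1841
        assert round(report["success_percent"], 1) == 98.3
        sizes = sorted(len(c) for c in report["sharing_components"])
        assert sizes == [2] * 14 + [3]

    def test_no_sharing_is_full_success(self):
        report = identification_success([_summary("A"), _summary("B")])
        assert report["success_percent"] == 100.0
        assert report["sharing_components"] == []

    def test_shallow_divergence_counted_separately(self):
        summaries = [_summary("A", nn=0.015), _summary("B", nn=0.5),
                     _summary("C", nn=0.019, shares=["B"])]
        report = identification_success(summaries)
        # C fails by sharing; A is shallow but not failing
        assert report["n_failing"] == 1
        assert report["shallow_divergence_species"] == ["A"]


class TestDatasetSummary:
    def test_tally_percentages_match_survey_table(self):
        counts = {1: 562, 2: 427, 3: 331, 4: 219, 5: 171,
                  6: 98, 7: 35, 8: 15, 9: 2, 10: 2, 12: 10}
        summaries = []
        i = 0
        for size, n_species in counts.items():
            for _ in range(n_species):
                summaries.append(_summary(f"S{i}", n=size, n_hap=1))
                i += 1
        tally = tally_by_sample_size(summaries)
        assert tally["n_species"].sum() == 1872
        assert round(tally.loc[0, "percent"], 2) == 30.02
        assert round(tally.loc[1, "cumulative_percent"], 2) == 52.83
        assert tally.loc[len(tally) - 1, "cumulative_percent"] == pytest.approx(100.0)
        assert tally["cumulative_percent"].is_monotonic_increasing

    def test_deep_split_exclusion_filters_mean(self):
        # two intraspecific pairs: 0.005 and 0.16; exclusion at 0.10
        ids = ["a1", "a2", "b1", "b2", "c1"]
        v = np.zeros((5, 5))
        pairs = {(0, 1): 0.005, (2, 3): 0.16}
        for (i, j), d in pairs.items():
            v[i, j] = v[j, i] = d
        v[v == 0] = 0.2
        np.fill_diagonal(v, 0.0)
        matrix = DistanceMatrix(ids=ids, model="K2P", values=v,
                                defined=np.ones((5, 5), bool),
                                n_sites=np.full((5, 5), 600))
        lib = Library(records=[
            rec("ACGT" * 75, "a1", "A sp"), rec("ACGT" * 75, "a2", "A sp"),
            rec("ACGT" * 75, "b1", "B sp"), rec("ACGT" * 75, "b2", "B sp"),
            rec("ACGT" * 75, "c1", "C sp")], aligned=True)
        summaries = species_gap_summary(matrix, lib)
        report = dataset_summary(summaries, matrix, lib, GapConfig())
        assert report["intraspecific"]["mean"] == pytest.approx((0.005 + 0.16) / 2)
        assert report["intraspecific_filtered"]["mean"] == pytest.approx(0.005)
        assert report["n_deep_split_species"] == 1
        hist = report["histogram"]
        assert hist["intra_count"].sum() == 2
        assert hist["nn_count"].sum() == len(summaries)
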