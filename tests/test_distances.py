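import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeval import (
    LocusAlignment,
    barcoding_gap,
    distance_matrix,
    k2p,
    partition_distances,
)
from barcodeval.distances import UndefinedDistanceError


def k2p_closed_form(p, q):
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p("ACGTACGTAC", "ACGTACGTAC") == 0.0

    @pytest.mark.parametrize(
        "a,b,p,q",
        [
            ("AAAAAAAAAA", "GAAAAAAAAA", 0.1, 0.0),   # one transition / 10
            ("AAAAAAAAAA", "TAAAAAAAAA", 0.0, 0.1),   # one transversion / 10
            ("AAAAAAAAAA", "GATAAAAAAA", 0.1, 0.1),
            ("ACGTACGTACGTACGTACGT", "GCGTGCGTACGTACGTACGT", 0.1, 0.0),
        ],
    )
    def test_matches_closed_form(self, a, b, p, q):
        assert k2p(a, b) == pytest.approx(k2p_closed_form(p, q), abs=1e-9)

    def test_pairwise_deletion_drops_gap_columns(self):
        # gap column dropped: 1 transition over 9 retained sites
        d = k2p("A-AAAAAAAA", "AAAAAAAAAG")
        assert d == pytest.approx(k2p_closed_form(1 / 9, 0), abs=1e-12)

    def test_n_columns_also_dropped(self):
        assert k2p("ANAAAAAAAA", "AAAAAAAAAA") == 0.0

    def test_saturation_reported_as_nan_not_clamped(self):
        # all sites transversions: Q = 1, log argument negative
        assert math.isnan(k2p("AAAA", "TTTT"))

    def test_no_comparable_sites_raises(self):
        with pytest.raises(UndefinedDistanceError):
            k2p("NNNN", "ACGT")

    @given(st.integers(0, 5), st.integers(0, 5), st.integers(20, 60))
    @settings(max_examples=50, deadline=None)
    def test_depends_only_on_p_q_and_site_count(self, n_ts, n_tv, extra):
        # distance is a function of (P, Q) only: two different sequence
        # pairs realising the same proportions agree exactly
        L = n_ts + n_tv + extra
        a1 = "A" * L
        b1 = "G" * n_ts + "T" * n_tv + "A" * extra
        a2 = "C" * L
        b2 = "T" * n_ts + "G" * n_tv + "C" * extra
        p, q = n_ts / L, n_tv / L
        if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
            assert math.isnan(k2p(a1, b1)) and math.isnan(k2p(a2, b2))
        else:
            assert k2p(a1, b1) == pytest.approx(k2p(a2, b2), abs=1e-12)
            assert k2p(a1, b1) == pytest.approx(k2p_closed_form(p, q), abs=1e-12)

    def test_symmetric(self):
        a, b = "ACGTACGTAC", "ATGTACGAAC"
        assert k2p(a, b) == k2p(b, a)

    def test_monotone_in_p_at_fixed_q(self):
        L = 100
        prev = -1.0
        for n_ts in range(0, 20, 4):
            b = "G" * n_ts + "T" * 5 + "A" * (L - n_ts - 5)
            d = k2p("A" * L, b)
            assert d > prev
            prev = d


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        aln = LocusAlignment("l", [(f"s{i}", "ACGTACGTAC") for i in range(3)])
        m = distance_matrix(aln)
        assert np.allclose(m.values, 0.0)

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(42)
        rows = [
            (f"s{i}", "".join(rng.choice(list("ACGT-N"), p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04], size=60)))
            for i in range(10)
        ]
        aln = LocusAlignment("l", rows)
        m = distance_matrix(aln)
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert m.values[i, j] == 0.0
                    continue
                expect = k2p(rows[i][1], rows[j][1])
                got = m.values[i, j]
                if math.isnan(expect):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_symmetric_zero_diagonal(self, preset_dataset):
        ds, _ = preset_dataset
        m = distance_matrix(ds.loci["its2"])
        assert np.array_equal(m.values, m.values.T) or np.allclose(
            m.values, m.values.T, equal_nan=True
        )
        assert np.all(np.diag(m.values) == 0)


class TestPartitionAndGap:
    @pytest.fixture()
    def labelled_matrix(self):
        # species sizes (3, 2): 3 + 1 intra pairs, 6 inter pairs;
        # sequences are light mutants of one base so no pair saturates
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=40)
        rows = []
        for i in range(5):
            seq = base.copy()
            sites = rng.choice(40, size=4, replace=False)
            seq[sites] = rng.choice(list("ACGT"), size=4)
            rows.append((f"s{i}", "".join(seq)))
        labels = {"s0": "X", "s1": "X", "s2": "X", "s3": "Y", "s4": "Y"}
        return distance_matrix(LocusAlignment("l", rows)), labels

    def test_pair_counts(self, labelled_matrix):
        m, labels = labelled_matrix
        intra, inter = partition_distances(m, labels)
        assert len(intra) == 4
        assert len(inter) == 6

    def test_single_species_has_no_inter(self):
        aln = LocusAlignment("l", [("a", "ACGT"), ("b", "ACTT")])
        m = distance_matrix(aln)
        intra, inter = partition_distances(m, {"a": "X", "b": "X"})
        assert inter == [] and len(intra) == 1

    def test_all_singletons_have_no_intra(self):
        aln = LocusAlignment("l", [("a", "ACGT"), ("b", "ACTT")])
        m = distance_matrix(aln)
        intra, inter = partition_distances(m, {"a": "X", "b": "Y"})
        assert intra == [] and len(inter) == 1

    def test_unlabeled_id_raises(self, labelled_matrix):
        m, labels = labelled_matrix
        with pytest.raises(ValueError):
            partition_distances(m, {"s0": "X"})

    def test_gap_report_on_separated_species(self, clean_dataset):
        ds, _ = clean_dataset
        m = distance_matrix(ds.loci["coi"])
        labels = {s.specimen_id: s.species_label for s in ds.specimens}
        rep = barcoding_gap(m, labels)
        assert rep.mean_inter > rep.mean_intra > 0
        assert rep.ratio == pytest.approx(rep.mean_inter / rep.mean_intra)
        assert rep.intra_hist.sum() + rep.inter_hist.sum() == 140 * 139 // 2
        for sp, entry in rep.per_species.items():
            assert entry["gap"] == pytest.approx(entry["min_inter"] - entry["max_intra"])
        assert rep.global_gap == pytest.approx(
            min(e["gap"] for e in rep.per_species.values())
        )

    def test_gap_positive_iff_supports_disjoint(self):
        # two tight clusters separated by 8 transitions -> positive gap
        rows = [
            ("a1", "A" * 40), ("a2", "A" * 39 + "G"),
            ("b1", "G" * 8 + "A" * 32), ("b2", "G" * 8 + "A" * 31 + "G"),
        ]
        m = distance_matrix(LocusAlignment("l", rows))
        rep = barcoding_gap(m, {"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"})
        assert rep.positive_gap
        assert rep.global_gap > 0
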