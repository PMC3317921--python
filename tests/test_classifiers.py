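import math

import numpy as np
import pytest

from barcodeval import (
    LocusAlignment,
    ReferenceLibrary,
    assign_bcm,
    assign_bp,
    assign_md,
    bcm_threshold,
    encode_onehot,
    k2p,
    train_bp,
)


def random_library(rng, n_refs=10, n_species=3, length=40):
    rows, labels = [], []
    for i in range(n_refs):
        rows.append((f"r{i}", "".join(rng.choice(list("ACGT"), size=length))))
        labels.append(f"sp{i % n_species}")
    return ReferenceLibrary(LocusAlignment("l", rows), labels)


class TestMinimumDistance:
    def test_identical_reference_assigned_at_distance_zero(self):
        lib = ReferenceLibrary(
            LocusAlignment("l", [("r1", "ACGTACGTAC"), ("r2", "TTTTTTTTTT")]),
            ["X", "Y"],
        )
        a = assign_md("ACGTACGTAC", lib)
        assert a.status == "assigned" and a.predicted_species == "X"
        assert a.best_distance == 0.0

    def test_exact_tie_across_species_is_ambiguous(self):
        lib = ReferenceLibrary(
            LocusAlignment("l", [("r1", "AAAAAAAAAA"), ("r2", "AAAAAAAAAA")]),
            ["X", "Y"],
        )
        a = assign_md("AAAAAAAAAG", lib)
        assert a.status == "ambiguous" and a.predicted_species is None

    def test_all_missing_query_unidentified(self):
        lib = ReferenceLibrary(
            LocusAlignment("l", [("r1", "ACGT"), ("r2", "TTTT")]), ["X", "Y"]
        )
        assert assign_md("NNNN", lib).status == "unidentified"

    def test_agrees_with_exhaustive_nearest_neighbour_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            lib = random_library(rng, n_refs=n, n_species=int(rng.integers(2, 5)))
            query = "".join(rng.choice(list("ACGT"), size=40))
            a = assign_md(query, lib)
            dists = [k2p(query, seq) for _, seq in lib.alignment.rows]
            if np.all(np.isnan(dists)):  # every pair saturated
                assert a.status == "unidentified"
                continue
            best = np.nanmin(dists)
            tied = {lib.labels[i] for i, d in enumerate(dists) if d <= best + 1e-12}
            if len(tied) == 1:
                assert a.status == "assigned"
                assert a.predicted_species == tied.pop()
                assert a.best_distance == pytest.approx(best, abs=1e-12)
            else:
                assert a.status == "ambiguous"


class TestBestCloseMatch:
    def test_threshold_is_linear_interpolated_95th_percentile(self):
        # hand-built distance multiset: 100 intraspecific distances
        # 0.01, 0.02, ..., 1.00 -> 95th percentile 0.9505
        from types import SimpleNamespace

        labels = ["X"] * 5 + ["Y"] * 10 + ["Z"] * 10  # 10+45+45 = 100 intra pairs
        n = len(labels)
        m = np.full((n, n), 5.0)  # inter distances: ignored by the threshold
        np.fill_diagonal(m, 0.0)
        values = iter(np.arange(1, 101) / 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] == labels[j]:
                    m[i, j] = m[j, i] = next(values)
        lib = SimpleNamespace(labels=labels, distances=lambda: SimpleNamespace(values=m))
        assert bcm_threshold(lib) == pytest.approx(0.9505, abs=1e-12)

    def test_degenerate_distributions(self):
        rows = [("a1", "ACGTACGTAC"), ("a2", "ACGTACGTAC"), ("b1", "TTTTTTTTTT")]
        lib = ReferenceLibrary(LocusAlignment("l", rows), ["X", "X", "Y"])
        # single intra pair at distance 0 -> threshold 0
        assert bcm_threshold(lib) == 0.0

    def test_no_intraspecific_pairs_errors(self):
        rows = [("a", "ACGTACGTAC"), ("b", "TTTTTTTTTT")]
        lib = ReferenceLibrary(LocusAlignment("l", rows), ["X", "Y"])
        with pytest.raises(ValueError):
            bcm_threshold(lib)

    def test_beyond_threshold_unidentified(self):
        lib = ReferenceLibrary(
            LocusAlignment("l", [("r1", "A" * 20), ("r2", "T" * 20)]), ["X", "Y"]
        )
        a = assign_bcm("A" * 14 + "G" * 6, lib, threshold=0.05)
        assert a.status == "unidentified" and a.predicted_species is None

    def test_within_threshold_assigned(self):
        lib = ReferenceLibrary(
            LocusAlignment("l", [("r1", "A" * 20), ("r2", "T" * 20)]), ["X", "Y"]
        )
        a = assign_bcm("A" * 20, lib, threshold=0.05)
        assert a.status == "assigned" and a.predicted_species == "X"

    def test_infinite_threshold_matches_md_on_assigned(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            lib = random_library(rng, n_refs=int(rng.integers(4, 15)))
            query = "".join(rng.choice(list("ACGT"), size=40))
            md = assign_md(query, lib)
            bcm = assign_bcm(query, lib, threshold=math.inf)
            if md.status == "assigned" and bcm.status == "assigned":
                assert md.predicted_species == bcm.predicted_species

    def test_threshold_monotone_under_added_high_distance(self):
        base = list(np.linspace(0.001, 0.02, 25))
        t0 = float(np.quantile(base, 0.95))
        t1 = float(np.quantile(base + [0.5], 0.95))
        assert t1 >= t0


class TestOneHot:
    def test_basic_encoding(self):
        out = encode_onehot(["AC"])
        assert out.tolist() == [[1, 0, 0, 0, 0, 1, 0, 0]]

    def test_gap_and_n_encode_all_zero(self):
        assert encode_onehot(["N-"]).sum() == 0

    def test_shape(self):
        out = encode_onehot(["ACGT", "TTTT", "NNNN"])
        assert out.shape == (3, 16)


@pytest.fixture(scope="module")
def separable_library():
    # two species, 20 diagnostic sites plus shared background
    rng = np.random.default_rng(3)
    bg = "".join(rng.choice(list("ACGT"), size=40))
    rows, labels = [], []
    for i in range(10):
        noise = lambda s: "".join(
            c if rng.random() > 0.02 else str(rng.choice(list("ACGT")))
            for c in s
        )
        rows.append((f"x{i}", noise("A" * 20 + bg)))
        labels.append("X")
        rows.append((f"y{i}", noise("T" * 20 + bg)))
        labels.append("Y")
    return ReferenceLibrary(LocusAlignment("l", rows), labels)


class TestBP:
    def test_training_reaches_perfect_accuracy_on_separable_data(self, separable_library):
        model = train_bp(separable_library, seed=1, max_epochs=3000)
        hits = sum(
            assign_bp(model, seq).predicted_species == lab
            for (_, seq), lab in zip(
                separable_library.alignment.rows, separable_library.labels
            )
        )
        assert hits == len(separable_library.labels)

    def test_same_seed_bitwise_identical(self, separable_library):
        m1 = train_bp(separable_library, seed=7, max_epochs=200)
        m2 = train_bp(separable_library, seed=7, max_epochs=200)
        assert np.array_equal(m1.w_hidden, m2.w_hidden)
        assert np.array_equal(m1.w_out, m2.w_out)
        assert m1.final_error == m2.final_error

    def test_infinite_goal_stops_immediately(self, separable_library):
        model = train_bp(separable_library, goal=math.inf, seed=0)
        assert model.epochs == 0 and model.converged

    def test_all_missing_query_is_ambiguous_or_uniform(self, separable_library):
        model = train_bp(separable_library, seed=1, max_epochs=500)
        a = assign_bp(model, "N" * 60)
        scores = np.array(list(a.score_vector.values()))
        # zero input drives both outputs through identical bias paths
        assert a.status == "ambiguous" or np.ptp(scores) < 0.2

    def test_prediction_is_argmax_of_scores(self, separable_library):
        model = train_bp(separable_library, seed=2, max_epochs=500)
        _, seq = separable_library.alignment.rows[0]
        a = assign_bp(model, seq)
        best = max(a.score_vector, key=a.score_vector.get)
        assert a.predicted_species == best

    def test_length_mismatch_errors(self, separable_library):
        model = train_bp(separable_library, seed=0, max_epochs=10)
        with pytest.raises(ValueError):
            assign_bp(model, "ACGT")
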