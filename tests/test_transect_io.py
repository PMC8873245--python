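import numpy as np
import pandas as pd
import pytest

from otolith_tracer.transect_io import (
    DEFAULT_REGISTRY,
    ElementRegistry,
    extract_edge_signature,
    filter_elements,
    read_sites,
    read_transects,
    write_transects,
)

from conftest import make_transect


class TestRegistry:
    def test_default_elements(self):
        assert DEFAULT_REGISTRY.symbols == ["Li", "B", "Mg", "P", "K", "Mn", "Rb", "Sr", "Ba"]
        assert DEFAULT_REGISTRY.mass_of("Ba") == 138

    def test_duplicate_symbol_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ElementRegistry((("Sr", 88), ("Sr", 87)))

    def test_bad_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ElementRegistry((("Sr", -1),))


class TestReadTransects:
    def test_toy_wide_round_trip(self):
        df = pd.DataFrame(
            {
                "fish_id": ["a"] * 3,
                "site_id": ["s"] * 3,
                "position_um": [1.0, 2.0, 3.0],
                "Sr": [0.1, 0.2, 0.3],
            }
        )
        transects, rejected = read_transects(df)
        assert len(transects) == 1
        assert transects[0].n_points == 3
        assert len(rejected) == 0
        np.testing.assert_array_equal(transects[0].positions, [1, 2, 3])

    def test_unsorted_positions_reordered(self):
        df = pd.DataFrame(
            {
                "fish_id": ["a"] * 3,
                "position_um": [3.0, 1.0, 2.0],
                "Sr": [0.3, 0.1, 0.2],
            }
        )
        (t,), _ = read_transects(df)
        np.testing.assert_array_equal(t.positions, [1, 2, 3])
        np.testing.assert_allclose(t.concentrations[:, 0], [0.1, 0.2, 0.3])

    def test_long_format_two_fish_interleaved(self):
        # oracle: hand-partitioned long table, fish a has 2 positions, b has 3
        rows = []
        for fish, positions in [("a", [1, 2]), ("b", [1, 2, 3])]:
            for p in positions:
                for el, v in [("Sr", 0.1 * p), ("Rb", 0.01 * p)]:
                    rows.append(
                        {"fish_id": fish, "site_id": "s", "position_um": p,
                         "element": el, "value": v}
                    )
        df = pd.DataFrame(rows).sample(frac=1, random_state=0)  # interleave
        transects, _ = read_transects(df)
        by_id = {t.fish_id: t for t in transects}
        assert set(by_id) == {"a", "b"}
        assert by_id["a"].n_points == 2
        assert by_id["b"].n_points == 3
        np.testing.assert_allclose(
            by_id["b"].concentrations[:, by_id["b"].element_index("Sr")],
            [0.1, 0.2, 0.3],
        )

    def test_duplicate_position_names_fish(self):
        df = pd.DataFrame(
            {"fish_id": ["a", "a"], "position_um": [1.0, 1.0], "Sr": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="'a'"):
            read_transects(df)

    def test_unknown_element_lists_registry(self):
        df = pd.DataFrame(
            {"fish_id": ["a"], "position_um": [1.0], "Xx": [0.1]}
        )
        with pytest.raises(ValueError, match="Xx"):
            read_transects(df)

    def test_unparseable_rows_rejected_with_report(self):
        df = pd.DataFrame(
            {
                "fish_id": ["a", "a", "a"],
                "position_um": [1.0, 2.0, 3.0],
                "Sr": [0.1, "oops", 0.3],
            }
        )
        (t,), rejected = read_transects(df)
        assert t.n_points == 2
        assert len(rejected) == 1
        assert rejected["reason"].iloc[0] == "unparseable numeric value"

    def test_write_read_round_trip_bit_exact(self, tmp_path, small_cohort):
        path = tmp_path / "t.csv"
        write_transects(small_cohort.transects, path)
        back, rejected = read_transects(path)
        assert len(rejected) == 0
        orig = {t.fish_id: t for t in small_cohort.transects}
        for t in back:
            o = orig[t.fish_id]
            np.testing.assert_array_equal(t.positions, o.positions)
            np.testing.assert_array_equal(t.concentrations, o.concentrations)
            np.testing.assert_array_equal(t.below_dl, o.below_dl)

    def test_tsv_sniffing(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("fish_id\tposition_um\tSr\na\t1.0\t0.1\na\t2.0\t0.2\n")
        (t,), _ = read_transects(path)
        assert t.n_points == 2


class TestFilterElements:
    @staticmethod
    def _cohort_with_flags(n_below: int, n_total: int = 100):
        values = np.ones((n_total, 2))
        flags = np.zeros((n_total, 2), dtype=bool)
        flags[:n_below, 0] = True  # element E0 partially below DL
        return [make_transect(values, elements=["E0", "E1"], below_dl=flags)]

    def test_boundary_26_of_100_excluded(self):
        retained, report = filter_elements(self._cohort_with_flags(26))
        assert retained == ["E1"]
        assert report.loc[report.element == "E0", "excluded"].item()

    def test_boundary_25_of_100_retained(self):
        retained, _ = filter_elements(self._cohort_with_flags(25))
        assert retained == ["E0", "E1"]

    def test_zero_flags_retained(self):
        retained, _ = filter_elements(self._cohort_with_flags(0))
        assert retained == ["E0", "E1"]

    def test_all_excluded_raises(self):
        values = np.ones((4, 1))
        flags = np.ones((4, 1), dtype=bool)
        cohort = [make_transect(values, elements=["E0"], below_dl=flags)]
        with pytest.raises(ValueError, match="all elements"):
            filter_elements(cohort)

    def test_idempotent_and_fish_order_independent(self, small_cohort):
        transects = list(small_cohort.transects)
        retained1, _ = filter_elements(transects)
        retained2, _ = filter_elements(transects[::-1])
        assert retained1 == retained2
        restricted = [t.restrict_elements(retained1) for t in transects]
        retained3, _ = filter_elements(restricted)
        assert retained3 == retained1


class TestEdgeSignature:
    def test_constant_transect(self):
        t = make_transect(np.full((11, 2), 5.0), elements=["Sr", "Rb"])
        sig = extract_edge_signature(t)
        np.testing.assert_allclose(sig.fingerprint, 5.0)

    def test_hand_averaged_window(self):
        # positions 0..10, surface at 10; values = position; window covers
        # distances 2..7 -> positions 3..8 -> mean 5.5
        values = np.arange(11, dtype=float).reshape(-1, 1)
        t = make_transect(values, elements=["Sr"])
        sig = extract_edge_signature(t)
        assert sig.n_points == 6
        np.testing.assert_allclose(sig.fingerprint, [5.5])

    def test_sub_2um_points_never_included(self):
        values = np.arange(11, dtype=float).reshape(-1, 1)
        t = make_transect(values, elements=["Sr"])
        sig = extract_edge_signature(t)
        contaminated = values.copy()
        contaminated[-2:] = 1e6  # closer than 2 um to the surface
        t2 = make_transect(contaminated, elements=["Sr"])
        np.testing.assert_allclose(
            extract_edge_signature(t2).fingerprint, sig.fingerprint
        )

    def test_partial_window(self):
        # only 4 points deep: distances 0..3, window [2,7] catches 2 points
        values = np.arange(4, dtype=float).reshape(-1, 1)
        t = make_transect(values, elements=["Sr"])
        sig = extract_edge_signature(t)
        assert sig.n_points == 2
        np.testing.assert_allclose(sig.fingerprint, [0.5])

    def test_no_points_in_window_errors(self):
        t = make_transect(np.ones((2, 1)), positions=[0.0, 0.5], elements=["Sr"], fish_id="fx")
        with pytest.raises(ValueError, match="fx"):
            extract_edge_signature(t)

    def test_mean_invariant_to_window_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.random((11, 1))
        t = make_transect(values, elements=["Sr"])
        sig = extract_edge_signature(t)
        perm = values.copy()
        perm[3:9, 0] = rng.permutation(perm[3:9, 0])  # shuffle in-window points
        t2 = make_transect(perm, elements=["Sr"])
        np.testing.assert_allclose(
            extract_edge_signature(t2).fingerprint, sig.fingerprint
        )


class TestSites:
    def test_read_sites(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text(
            "site_id,river_system,section,habitat,river_km\n"
            "A,R,estuary,estuary,0\nB,R,upper,upper river,80\n"
        )
        sites = read_sites(path)
        assert sites["B"].river_km == 80.0

    def test_duplicate_site_rejected(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text(
            "site_id,river_system,section,habitat,river_km\n"
            "A,R,estuary,estuary,0\nA,R,upper,upper river,80\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_sites(path)
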