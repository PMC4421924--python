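"""Data model, file round-trips, fixture checksums and episode expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from crcapture import (
    CaptureHistory,
    CellCounts,
    CovariateTable,
    EpisodeMap,
    breast_episode_map,
    colorectal_episode_map,
    expand_episodes,
    fixture_checksums,
    load_fixture,
    read_capture_history,
    read_cell_counts,
    to_capture_history,
    to_cell_counts,
    validate_fixture,
    write_cell_counts,
)
from crcapture.capture_data import CaptureDataError, age_band
from crcapture.synthetic import SimulationScenario, simulate


class TestCaptureHistory:
    def test_rejects_all_zero_row(self):
        with pytest.raises(CaptureDataError, match="row 1"):
            CaptureHistory(np.array([[1, 0], [0, 0]]), ("A", "B"))

    def test_rejects_non_binary(self):
        with pytest.raises(CaptureDataError, match="0 or 1"):
            CaptureHistory(np.array([[1, 2]]), ("A", "B"))

    def test_shape_accessors(self):
        h = CaptureHistory(np.array([[1, 0, 1], [0, 1, 0]]), ("A", "B", "C"))
        assert (h.n, h.T) == (2, 3)


class TestReadCaptureHistory:
    def test_transcribes_rows(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("id,A,B,C\n1,1,1,1\n2,1,1,0\n3,1,0,0\n")
        h = read_capture_history(p, ["A", "B", "C"])
        assert (h.n, h.T) == (3, 3)
        cc = to_cell_counts(h)
        assert cc.counts == {"111": 1, "110": 1, "100": 1}

    def test_missing_column(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("id,A,B\n1,1,0\n")
        with pytest.raises(CaptureDataError, match="missing source columns"):
            read_capture_history(p, ["A", "B", "C"])

    def test_non_binary_value(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("id,A,B\n1,1,0\n2,2,0\n")
        with pytest.raises(CaptureDataError, match="non-binary"):
            read_capture_history(p, ["A", "B"])

    def test_all_zero_row_named(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("id,A,B\n1,1,0\n2,0,0\n")
        with pytest.raises(CaptureDataError, match="row 1"):
            read_capture_history(p, ["A", "B"])

    def test_write_read_round_trip(self, tmp_path):
        sc = SimulationScenario(N_true=60, T=3, mu=0.4, alpha=(0.5, 0.0, -0.5))
        h = simulate(sc, seed=3).observed
        p = tmp_path / "sim.csv"
        h.write_csv(p)
        back = read_capture_history(p, list(h.episode_labels))
        assert np.array_equal(back.matrix, h.matrix)


class TestCellCounts:
    def test_direct_counting(self):
        h = CaptureHistory(np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]]), "ABC")
        assert to_cell_counts(h).counts == {"110": 2, "011": 1}

    def test_rejects_all_zero_pattern(self):
        with pytest.raises(CaptureDataError, match="unobservable"):
            CellCounts(("A", "B"), {"00": 3})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(
            np.int8, st.tuples(st.integers(1, 25), st.integers(1, 4)),
            elements=st.integers(0, 1),
        ).filter(lambda m: (m.sum(axis=1) > 0).all())
    )
    def test_round_trip_is_lossless(self, m):
        h = CaptureHistory(m, tuple(f"S{i}" for i in range(m.shape[1])))
        cc = to_cell_counts(h)
        assert cc.total == h.n
        back = to_cell_counts(to_capture_history(cc))
        assert back.counts == cc.counts

    def test_cell_csv_round_trip(self, tmp_path, breast_cells):
        p = tmp_path / "cells.csv"
        write_cell_counts(breast_cells, p)
        back = read_cell_counts(p)
        assert back.labels == breast_cells.labels
        assert back.counts == breast_cells.counts


class TestFixtures:
    @pytest.mark.parametrize("name", ["breast", "colorectal"])
    def test_checksums_pass(self, name):
        cells = load_fixture(name)
        report = validate_fixture(cells, fixture_checksums(name))
        assert report.passed, report.failures

    def test_breast_marginals(self, breast_cells):
        assert breast_cells.total == 787
        assert breast_cells.source_total("HR") == 729
        assert breast_cells.count_by_breadth(2, exact=True) == 470
        assert breast_cells.counts["111"] == 108

    def test_colorectal_marginals(self, colorectal_cells):
        assert colorectal_cells.total == 512
        assert colorectal_cells.source_total("HR") == 481
        assert colorectal_cells.count_by_breadth(2) == 337
        assert colorectal_cells.counts["111"] == 41

    def test_perturbed_count_fails_named_checksum(self, breast_cells):
        counts = dict(breast_cells.counts)
        counts["111"] += 1
        bad = CellCounts(breast_cells.labels, counts)
        report = validate_fixture(bad, fixture_checksums("breast"))
        assert not report.passed
        assert any("all 3 sources" in f for f in report.failures)
        assert any("total" in f for f in report.failures)


def _table(rows, sources=("HR", "MTM", "CSP")):
    return CovariateTable(pd.DataFrame(rows), sources)


class TestExpandEpisodes:
    def _covariate_table(self, n=40, seed=1):
        truth = simulate(
            SimulationScenario(
                N_true=n, T=3, mu=1.0,
                covariate_effects={"metastasis": {"MTM": 1.0}, "screening": {"CSP": 1.0}},
                covariate_prevalence={"metastasis": 0.3, "screening": 0.5},
                source_labels=("HR", "MTM", "CSP"),
            ),
            seed=seed,
        )
        return truth.observed_covariate_table()

    def test_colorectal_map_has_24_episodes(self):
        assert colorectal_episode_map().total_episodes == 24

    def test_breast_map_has_21_episodes(self):
        assert breast_episode_map().total_episodes == 21

    def test_expanded_rows_keep_every_individual(self):
        ct = self._covariate_table()
        for em in (breast_episode_map(), colorectal_episode_map()):
            h = expand_episodes(ct, em)
            assert h.n == ct.n
            assert h.T == em.total_episodes
            assert (h.matrix.sum(axis=1) >= 1).all()

    def test_age_band_episode_matches_manual_mask(self):
        ct = self._covariate_table()
        h = expand_episodes(ct, colorectal_episode_map())
        j = colorectal_episode_map().labels().index("MTM:age_band=60-64")
        manual = (ct.data["MTM"].to_numpy() == 1) & (
            ct.data["age_band"].to_numpy() == "60-64"
        )
        assert np.array_equal(h.matrix[:, j].astype(bool), manual)

    def test_identity_expansion_reproduces_source_matrix(self):
        ct = self._covariate_table()
        em = EpisodeMap((("HR", None, None), ("MTM", None, None), ("CSP", None, None)))
        h = expand_episodes(ct, em)
        assert np.array_equal(h.matrix, ct.capture_history().matrix)

    def test_unknown_level_rejected(self):
        ct = self._covariate_table()
        em = EpisodeMap((("HR", None, None), ("HR", "age_band", "45-49")))
        with pytest.raises(CaptureDataError, match="outside declared levels"):
            expand_episodes(ct, em)

    def test_out_of_range_age_rejected(self):
        with pytest.raises(CaptureDataError, match="outside the declared range"):
            age_band(49)

    def test_missing_covariate_value_rejected(self):
        df = pd.DataFrame({"HR": [1, 1], "MTM": [0, 1], "metastasis": [1, 2]})
        with pytest.raises(CaptureDataError, match="outside declared levels"):
            CovariateTable(df, ("HR", "MTM"), {"metastasis": (0, 1)})
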