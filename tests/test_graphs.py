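"""Time-series loading, correlation, and threshold binarization."""

import numpy as np
import networkx as nx
import pytest

from fractalconn.exceptions import (
    AllRoisDeadError,
    DeadRoiError,
    EmptyInputError,
    NonNumericCellError,
    RaggedRowsError,
)
from fractalconn.graphs import (
    CorrelationMatrix,
    RoiTimeSeriesSet,
    correlation_matrix,
    drop_dead_rois,
    load_timeseries,
    read_graph,
    threshold_binarize,
    write_graph,
)


def _write(tmp_path, text, name="ts.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadTimeseries:
    def test_wellformed_shape(self, tmp_path, rng):
        data = rng.standard_normal((150, 20))
        lines = ["\t".join(f"r{i}" for i in range(20))]
        lines += ["\t".join(f"{v:.6f}" for v in row) for row in data]
        ts = load_timeseries(_write(tmp_path, "\n".join(lines) + "\n"))
        assert ts.samples.shape == (150, 20)
        assert ts.roi_labels == [f"r{i}" for i in range(20)]

    def test_nonnumeric_cell_named(self, tmp_path):
        p = _write(tmp_path, "a\tb\n1.0\t2.0\n3.0\toops\n")
        with pytest.raises(NonNumericCellError, match=r"row 3.*'b'"):
            load_timeseries(p)

    def test_ragged_rows(self, tmp_path):
        p = _write(tmp_path, "a\tb\n1.0\t2.0\n3.0\n")
        with pytest.raises(RaggedRowsError, match="row 3"):
            load_timeseries(p)

    def test_empty_file(self, tmp_path):
        with pytest.raises(EmptyInputError):
            load_timeseries(_write(tmp_path, ""))
        with pytest.raises(EmptyInputError):
            load_timeseries(_write(tmp_path, "a\tb\n"))

    def test_csv_dialect(self, tmp_path):
        ts = load_timeseries(_write(tmp_path, "a,b\n1,2\n3,4\n", "x.csv"))
        assert ts.samples.shape == (2, 2)


class TestDropDeadRois:
    def _ts(self, samples, labels):
        return RoiTimeSeriesSet("s", "c", samples, labels)

    def test_all_zero_column_removed(self, rng):
        x = rng.standard_normal((20, 10))
        x[:, 4] = 0.0
        out = drop_dead_rois(self._ts(x, [f"r{i}" for i in range(10)]))
        assert out.n_rois == 9
        assert out.removed_rois == ["r4"]
        assert out.roi_labels == [f"r{i}" for i in range(10) if i != 4]

    def test_constant_nonzero_column_removed(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 1] = 7.5
        out = drop_dead_rois(self._ts(x, ["a", "b", "c"]))
        assert out.removed_rois == ["b"]

    def test_identity_when_all_alive(self, rng):
        x = rng.standard_normal((20, 5))
        ts = self._ts(x, list("abcde"))
        assert drop_dead_rois(ts) is ts

    def test_all_dead_is_error(self):
        with pytest.raises(AllRoisDeadError):
            drop_dead_rois(self._ts(np.zeros((10, 4)), list("abcd")))


class TestCorrelationMatrix:
    def test_duplicate_and_flipped_columns(self, rng):
        base = rng.standard_normal(30)
        x = np.column_stack([base, base, -base])
        m = correlation_matrix(RoiTimeSeriesSet("s", "c", x, ["a", "b", "c"]))
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(m.values) == 0.0)

    def test_hand_computed_pearson(self):
        # direct sum-formula values, computed independently
        x = np.array(
            [[1.0, 2.0, 5.0], [2.0, 1.0, 3.0], [3.0, 4.0, 2.0], [5.0, 3.0, 1.0]]
        )
        m = correlation_matrix(RoiTimeSeriesSet("s", "c", x, ["A", "B", "C"]))
        assert m.values[0, 1] == pytest.approx(0.5291502622129182)
        assert m.values[0, 2] == pytest.approx(-0.9428571428571428)
        assert m.values[1, 2] == pytest.approx(-0.5291502622129182)

    def test_zero_variance_column_directs_to_dropper(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10)
        with pytest.raises(DeadRoiError, match="drop_dead_rois"):
            correlation_matrix(RoiTimeSeriesSet("s", "c", x, ["a", "b"]))

    def test_too_few_timepoints(self, rng):
        x = rng.standard_normal((2, 3))
        with pytest.raises(ValueError):
            correlation_matrix(RoiTimeSeriesSet("s", "c", x, ["a", "b", "c"]))


def _corr_from_upper(n, entries):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = entries
    m = m + m.T
    return CorrelationMatrix(values=m, roi_labels=[f"r{i}" for i in range(n)])


class TestThresholdBinarize:
    def test_exact_edge_count_at_95(self, rng):
        n = 1000
        vals = rng.uniform(0.01, 0.99, size=n * (n - 1) // 2)
        g = threshold_binarize(_corr_from_upper(n, vals), percentile=95.0)
        assert g.number_of_edges() == 24_975

    def test_toy_matrix_percentile_75(self):
        m = _corr_from_upper(4, [0.9, 0.8, -0.7, 0.1, 0.2, 0.3])
        g = threshold_binarize(m, percentile=75.0)
        assert g.number_of_edges() == 1
        assert g.has_edge("r0", "r1")

    def test_percentile_zero_all_positive_gives_complete_graph(self, rng):
        n = 12
        vals = rng.uniform(0.05, 0.95, size=n * (n - 1) // 2)
        g = threshold_binarize(_corr_from_upper(n, vals), percentile=0.0)
        assert g.number_of_edges() == n * (n - 1) // 2

    def test_negative_survivors_discarded(self):
        m = _corr_from_upper(4, [0.9, -0.8, -0.7, 0.1, 0.2, 0.3])
        g = threshold_binarize(m, percentile=50.0)
        # rank keeps 3: {0.9, 0.3, 0.2}; none negative here
        assert g.number_of_edges() == 3
        m2 = _corr_from_upper(4, [-0.9, -0.8, -0.7, -0.1, -0.2, -0.3])
        with pytest.warns(UserWarning):
            g2 = threshold_binarize(m2, percentile=50.0)
        assert g2.number_of_edges() == 0

    def test_edge_count_rule_on_random_inputs(self, rng):
        for n in (10, 25, 40):
            vals = rng.uniform(-1, 1, size=n * (n - 1) // 2)
            q = float(rng.uniform(40, 95))
            keep = int(np.floor((1 - q / 100) * vals.size))
            ranked = np.sort(vals)[::-1][:keep]
            expected = int((ranked >= 0).sum())
            g = threshold_binarize(_corr_from_upper(n, vals), percentile=q)
            assert g.number_of_edges() == expected

    def test_invariant_under_roi_permutation(self, rng):
        n = 15
        vals = rng.uniform(-1, 1, size=n * (n - 1) // 2)
        m = _corr_from_upper(n, vals)
        g = threshold_binarize(m, percentile=80.0)
        perm = rng.permutation(n)
        labels = [m.roi_labels[i] for i in perm]
        m2 = CorrelationMatrix(
            values=m.values[np.ix_(perm, perm)], roi_labels=labels
        )
        g2 = threshold_binarize(m2, percentile=80.0)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in g2.edges}

    def test_rejects_bad_percentile(self):
        m = _corr_from_upper(3, [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            threshold_binarize(m, percentile=100.0)


class TestGraphIO:
    @pytest.mark.parametrize("suffix", [".mtx", ".tsv"])
    def test_roundtrip_identity(self, tmp_path, suffix):
        g = nx.gnp_random_graph(30, 0.2, seed=42)
        g = nx.relabel_nodes(g, {i: f"roi{i:03d}" for i in g.nodes})
        path = tmp_path / f"g{suffix}"
        write_graph(g, path)
        back = read_graph(path)
        assert list(back.nodes) == list(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
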