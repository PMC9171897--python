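"""Trace extraction, elution fitting and cosine-linked cluster assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trace
from mosquant.feature_extraction import (
    MS1Map,
    extract_traces,
    fit_elution_profile,
    link_cluster,
    trace_cosine,
)
from mosquant.isotope_model import IsotopeEnvelope, pair_positions


def _map_with_peaks(rts, peak_lists):
    mzs, ints = [], []
    for peaks in peak_lists:
        arr = np.array(sorted(peaks)) if peaks else np.empty((0, 2))
        arr = np.atleast_2d(arr)
        mzs.append(arr[:, 0] if arr.size else np.array([]))
        ints.append(arr[:, 1] if arr.size else np.array([]))
    return MS1Map(retention_times=np.asarray(rts, float), mz_arrays=mzs,
                  intensity_arrays=ints, run_id="test")


@pytest.fixture
def simple_geometry():
    env = IsotopeEnvelope(np.array([1.0, 0.0, 0.0, 0.0]), 998.98545)
    return pair_positions(env, 2)


class TestMzXMLReader:
    def _write(self, tmp_path, scan_attrs='centroided="1"'):
        import base64
        import struct

        peaks = base64.b64encode(
            struct.pack(">4f", 400.5, 1000.0, 401.0, 2000.0)
        ).decode()
        text = f"""<?xml version="1.0"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
 <msRun scanCount="2">
  <scan num="1" msLevel="1" retentionTime="PT60S" peaksCount="2" {scan_attrs}>
   <peaks precision="32" byteOrder="network" compressionType="none">{peaks}</peaks>
  </scan>
  <scan num="2" msLevel="2" retentionTime="PT61S" peaksCount="2" {scan_attrs}>
   <peaks precision="32" byteOrder="network" compressionType="none">{peaks}</peaks>
  </scan>
 </msRun>
</mzXML>"""
        p = tmp_path / "run.mzXML"
        p.write_text(text)
        return p

    def test_reads_ms1_only_and_converts_units(self, tmp_path):
        m = MS1Map.from_mzxml(str(self._write(tmp_path)), run_id="r")
        assert len(m) == 1  # the MS2 scan is skipped
        assert m.retention_times[0] == pytest.approx(1.0)  # 60 s -> minutes
        np.testing.assert_allclose(m.mz_arrays[0], [400.5, 401.0])
        np.testing.assert_allclose(m.intensity_arrays[0], [1000.0, 2000.0])

    def test_rejects_profile_scans(self, tmp_path):
        p = self._write(tmp_path, scan_attrs='centroided="0"')
        with pytest.raises(ValueError, match="centroided"):
            MS1Map.from_mzxml(str(p))


class TestExtractTraces:
    def test_exact_match_retrieval(self, simple_geometry):
        mz0 = simple_geometry.light_mz[0]
        rts = [1.0, 1.1, 1.2, 1.3, 1.4]
        m = _map_with_peaks(rts, [[(mz0, 100.0 + i)] for i in range(5)])
        traces = extract_traces(m, simple_geometry, rt_center=1.2, rt_halfwidth=0.5)
        np.testing.assert_allclose(traces["light"][0].intensities,
                                   [100, 101, 102, 103, 104])

    def test_peak_outside_tolerance_excluded(self, simple_geometry):
        mz0 = simple_geometry.light_mz[0]
        off = mz0 * 2 * 10e-6  # twice the ppm tolerance
        m = _map_with_peaks([1.0], [[(mz0 + off, 500.0)]])
        traces = extract_traces(m, simple_geometry, 1.0, 0.5, ppm_tol=10.0)
        assert traces["light"][0].intensities[0] == 0.0

    def test_most_intense_peak_wins(self, simple_geometry):
        mz0 = simple_geometry.light_mz[0]
        d = mz0 * 5e-6
        m = _map_with_peaks([1.0], [[(mz0 - d, 300.0), (mz0 + d, 800.0)]])
        traces = extract_traces(m, simple_geometry, 1.0, 0.5)
        assert traces["light"][0].intensities[0] == 800.0

    def test_empty_window_flagged_not_raised(self, simple_geometry):
        m = _map_with_peaks([10.0], [[(500.0, 1.0)]])
        traces = extract_traces(m, simple_geometry, rt_center=1.0, rt_halfwidth=0.5)
        assert len(traces["light"][0].intensities) == 0
        assert not traces["light"][0].valid

    def test_deterministic(self, simple_geometry):
        mz0 = simple_geometry.light_mz[0]
        m = _map_with_peaks([1.0, 1.1], [[(mz0, 5.0)], [(mz0, 7.0)]])
        a = extract_traces(m, simple_geometry, 1.05, 0.5)
        b = extract_traces(m, simple_geometry, 1.05, 0.5)
        np.testing.assert_array_equal(a["light"][0].intensities,
                                      b["light"][0].intensities)


class TestElutionFit:
    def test_recovers_noiseless_gaussian(self):
        t = np.linspace(29.5, 30.5, 20)
        y = 1e6 * np.exp(-0.5 * ((t - 30.0) / 0.1) ** 2)
        fit = fit_elution_profile(make_trace(y, rts=t), rt_predicted=30.0)
        assert fit.valid
        assert fit.n_components == 1
        assert fit.means[fit.selected] == pytest.approx(30.0, abs=0.01)

    def test_selects_component_nearest_prediction(self):
        t = np.linspace(0, 4, 80)
        y = 1e5 * np.exp(-0.5 * ((t - 1.0) / 0.1) ** 2) + 2e5 * np.exp(
            -0.5 * ((t - 3.0) / 0.1) ** 2
        )
        fit = fit_elution_profile(make_trace(y, rts=t), max_components=3,
                                  rt_predicted=1.0)
        assert fit.valid
        assert fit.means[fit.selected] == pytest.approx(1.0, abs=0.05)

    def test_too_few_points_invalid(self):
        fit = fit_elution_profile(make_trace([0, 0, 5.0, 3.0, 0, 0]))
        assert not fit.valid
        assert "nonzero" in fit.reason

    def test_multiplicative_noise_median_error(self, rng):
        """Median |mu_hat - mu| < 0.02 min under 5% multiplicative noise."""
        t = np.linspace(29.0, 31.0, 40)
        clean = 1e6 * np.exp(-0.5 * ((t - 30.0) / 0.1) ** 2)
        errors = []
        for _ in range(50):
            y = clean * np.exp(rng.normal(0, 0.05, len(t)))
            fit = fit_elution_profile(make_trace(y, rts=t), rt_predicted=30.0)
            assert fit.valid
            errors.append(abs(fit.means[fit.selected] - 30.0))
        assert np.median(errors) < 0.02


class TestTraceCosine:
    def test_identity_orthogonality_scale(self):
        a = make_trace([1, 2, 3, 0, 0])
        b = make_trace([0, 0, 0, 4, 5])
        assert trace_cosine(a, a) == pytest.approx(1.0)
        assert trace_cosine(a, b) == 0.0
        assert trace_cosine(a, make_trace([3, 6, 9, 0, 0])) == pytest.approx(1.0)

    def test_all_zero_gives_zero(self):
        assert trace_cosine(make_trace([0, 0, 0]), make_trace([1, 2, 3])) == 0.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            trace_cosine(make_trace([1, 2]), make_trace([1, 2, 3]))

    @settings(max_examples=30, deadline=None)
    @given(
        v=st.lists(st.floats(0, 1e6), min_size=3, max_size=12),
        w=st.lists(st.floats(0, 1e6), min_size=3, max_size=12),
    )
    def test_symmetric_and_bounded(self, v, w):
        n = min(len(v), len(w))
        a, b = make_trace(v[:n]), make_trace(w[:n])
        c = trace_cosine(a, b)
        assert 0.0 <= c <= 1.0
        assert c == pytest.approx(trace_cosine(b, a))


class TestLinkCluster:
    def _traces_with_cosines(self, cosines):
        """Build traces whose adjacent cosine similarities are approximately
        the requested values (two-scan vectors at controlled angles)."""
        traces = [make_trace([1.0, 0.0], index=0)]
        angle = 0.0
        for i, c in enumerate(cosines, start=1):
            angle += np.arccos(np.clip(c, 0, 1))
            traces.append(
                make_trace([np.cos(angle), np.sin(angle)], index=i)
            )
        return traces

    def test_chain_breaks_at_first_failure(self):
        traces = self._traces_with_cosines([0.99, 0.95, 0.4, 0.97])
        cluster = link_cluster(traces, threshold=0.6)
        assert cluster.indices() == [0, 1, 2]

    def test_threshold_inclusive(self):
        traces = self._traces_with_cosines([0.61, 0.61, 0.61])
        cluster = link_cluster(traces, threshold=0.6)
        assert len(cluster) == 4
        assert all(c >= 0.6 for c in cluster.cosines)

    def test_immediate_break_keeps_first_only(self):
        traces = self._traces_with_cosines([0.2])
        cluster = link_cluster(traces, threshold=0.6)
        assert cluster.indices() == [0]

    def test_coeluting_species_high_cosines(self, noiseless_single_run):
        """Noiseless co-eluting light/heavy species: all within-species
        adjacent cosines exceed 0.95."""
        from mosquant.isotope_model import composition_from_sequence, isotope_envelope

        truth, run, ms1, _ = noiseless_single_run
        for row in truth.peptides.itertuples(index=False):
            comp = composition_from_sequence(row.sequence, {"met_sulfoxide_16O"})
            geom = pair_positions(isotope_envelope(comp), int(row.charge))
            traces = extract_traces(ms1, geom, row.rt_mu, 0.3)
            for species in ("light", "heavy"):
                ts = traces[species]
                if ts[0].nonzero_scans() == 0:
                    continue  # pure opposite-species peptide
                for a, b in zip(ts[:-1], ts[1:]):
                    if b.nonzero_scans() == 0:
                        break
                    assert trace_cosine(a, b) > 0.95
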