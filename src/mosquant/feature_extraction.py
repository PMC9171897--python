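"""Extraction of per-isotopologue chromatographic traces from centroided MS1
maps, Gaussian elution-profile fitting, and cosine-linked isotopologue
cluster assembly."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .isotope_model import PairGeometry

__all__ = [
    "MS1Map",
    "IsotopologueTrace",
    "ElutionFit",
    "FeatureCluster",
    "extract_traces",
    "fit_elution_profile",
    "trace_cosine",
    "link_cluster",
]


@dataclass
class MS1Map:
    """Ordered centroided MS1 scans: retention times (min) and per-scan
    (m/z, intensity) arrays sorted by m/z."""

    retention_times: np.ndarray
    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    run_id: str = ""

    def __post_init__(self):
        rt = np.asarray(self.retention_times, dtype=float)
        if rt.size and np.any(np.diff(rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        self.retention_times = rt

    def __len__(self) -> int:
        return len(self.retention_times)

    @classmethod
    def from_mzml(cls, path: str, run_id: str | None = None) -> "MS1Map":
        """Read MS1 scans from an mzML file (centroided input required)."""
        from ._mz_readers import read_mzml

        rts, mzs, ints = read_mzml(path)
        return cls._assemble(rts, mzs, ints, run_id or str(path))

    @classmethod
    def from_mzxml(cls, path: str, run_id: str | None = None) -> "MS1Map":
        from ._mz_readers import read_mzxml

        rts, mzs, ints = read_mzxml(path)
        return cls._assemble(rts, mzs, ints, run_id or str(path))

    @classmethod
    def _assemble(cls, rts, mzs, ints, run_id):
        sorted_mz, sorted_int = [], []
        for mz, it in zip(mzs, ints):
            order = np.argsort(mz)
            sorted_mz.append(mz[order])
            sorted_int.append(it[order])
        order = np.argsort(rts)
        return cls(
            retention_times=np.asarray(rts)[order],
            mz_arrays=[sorted_mz[i] for i in order],
            intensity_arrays=[sorted_int[i] for i in order],
            run_id=run_id,
        )


@dataclass
class IsotopologueTrace:
    """Per-scan intensities of one isotopologue over the extraction window."""

    index: int
    retention_times: np.ndarray
    intensities: np.ndarray
    target_mz: float
    ppm_tol: float
    valid: bool = True

    def nonzero_scans(self) -> int:
        return int(np.count_nonzero(self.intensities))


@dataclass
class ElutionFit:
    """Result of fitting 1..max Gaussian components to a trace."""

    n_components: int
    means: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray
    selected: int
    goodness: float
    valid: bool = True
    reason: str = ""

    @property
    def rt_bounds(self) -> tuple[float, float]:
        """+-3 sigma window of the selected component."""
        mu = self.means[self.selected]
        s = self.widths[self.selected]
        return (mu - 3 * s, mu + 3 * s)


@dataclass
class FeatureCluster:
    """Cosine-linked contiguous isotopologue traces for one labeled species."""

    species: str
    traces: list[IsotopologueTrace]
    cosines: list[float]

    def indices(self) -> list[int]:
        return [t.index for t in self.traces]

    def __len__(self) -> int:
        return len(self.traces)


def extract_traces(
    ms1: MS1Map,
    geometry: PairGeometry,
    rt_center: float,
    rt_halfwidth: float,
    ppm_tol: float = 10.0,
) -> dict[str, list[IsotopologueTrace]]:
    """Extract light- and heavy-species isotopologue traces around
    ``rt_center`` within ``ppm_tol``.

    Per scan, the most intense centroid within the tolerance of each target
    m/z is taken; scans with no match contribute zero intensity.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    lo = rt_center - rt_halfwidth
    hi = rt_center + rt_halfwidth
    sel = np.nonzero((ms1.retention_times >= lo) & (ms1.retention_times <= hi))[0]
    rts = ms1.retention_times[sel]
    out: dict[str, list[IsotopologueTrace]] = {}
    for species, targets in (("light", geometry.light_mz), ("heavy", geometry.heavy_mz)):
        traces = []
        for k, mz0 in enumerate(targets):
            tol = mz0 * ppm_tol * 1e-6
            inten = np.zeros(len(sel))
            for j, si in enumerate(sel):
                mz = ms1.mz_arrays[si]
                i0 = bisect.bisect_left(mz, mz0 - tol)
                i1 = bisect.bisect_right(mz, mz0 + tol)
                if i1 > i0:
                    inten[j] = ms1.intensity_arrays[si][i0:i1].max()
            traces.append(
                IsotopologueTrace(
                    index=k,
                    retention_times=rts,
                    intensities=inten,
                    target_mz=float(mz0),
                    ppm_tol=ppm_tol,
                    valid=len(sel) > 0,
                )
            )
        out[species] = traces
    return out


def _gauss_mix(t, *params):
    y = np.zeros_like(t, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, s = params[i : i + 3]
        y = y + a * np.exp(-0.5 * ((t - mu) / s) ** 2)
    return y


def fit_elution_profile(
    trace: IsotopologueTrace,
    max_components: int = 3,
    rt_predicted: float | None = None,
) -> ElutionFit:
    """Fit 1..``max_components`` Gaussian elution components to a trace by
    least squares, selecting the component count by BIC and, among the
    components, the one whose mean is nearest ``rt_predicted``.
    """
    t = trace.retention_times
    y = trace.intensities
    if trace.nonzero_scans() < 5:
        return ElutionFit(0, np.array([]), np.array([]), np.array([]), -1,
                          np.inf, valid=False, reason="fewer than 5 nonzero scans")
    if rt_predicted is None:
        rt_predicted = float(t[np.argmax(y)])
    span = max(t[-1] - t[0], 1e-3)
    m = len(t)
    best = None
    best_bic = np.inf
    prev: list[float] = []
    residual = y.astype(float)
    for n in range(1, max_components + 1):
        # seed the added component at the current residual maximum
        j = int(np.argmax(residual))
        p0 = prev + [max(float(residual[j]), 1e-6), float(t[j]), span / 10]
        lower = [0.0, t[0] - span, 1e-4] * n
        upper = [np.inf, t[-1] + span, span] * n
        try:
            popt, _ = curve_fit(
                _gauss_mix, t, y, p0=p0, bounds=(lower, upper), maxfev=5000
            )
        except (RuntimeError, ValueError):
            break
        pred = _gauss_mix(t, *popt)
        rss = float(np.sum((y - pred) ** 2))
        bic = m * np.log(max(rss / m, 1e-300)) + 3 * n * np.log(m)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = popt
        prev = list(popt)
        residual = np.maximum(y - pred, 0.0)
    if best is None:
        return ElutionFit(0, np.array([]), np.array([]), np.array([]), -1,
                          np.inf, valid=False, reason="optimizer failed to converge")
    n = len(best) // 3
    amps = np.array(best[0::3])
    means = np.array(best[1::3])
    widths = np.array(best[2::3])
    selected = int(np.argmin(np.abs(means - rt_predicted)))
    return ElutionFit(
        n_components=n,
        means=means,
        widths=widths,
        amplitudes=amps,
        selected=selected,
        goodness=best_bic,
    )


def trace_cosine(a: IsotopologueTrace, b: IsotopologueTrace) -> float:
    """Cosine similarity of two traces on the same scan grid (0 if either is
    all-zero)."""
    if len(a.retention_times) != len(b.retention_times) or (
        len(a.retention_times)
        and not np.allclose(a.retention_times, b.retention_times)
    ):
        raise ValueError("traces are on different scan grids")
    na = np.linalg.norm(a.intensities)
    nb = np.linalg.norm(b.intensities)
    if na == 0 or nb == 0:
        return 0.0
    c = float(np.dot(a.intensities, b.intensities) / (na * nb))
    return min(max(c, 0.0), 1.0)


def link_cluster(
    traces: list[IsotopologueTrace], species: str = "", threshold: float = 0.6
) -> FeatureCluster:
    """Keep the maximal prefix of isotopologue traces in which every adjacent
    pair has cosine similarity >= ``threshold`` (inclusive)."""
    if not traces:
        return FeatureCluster(species=species, traces=[], cosines=[])
    kept = [traces[0]]
    cosines: list[float] = []
    for nxt in traces[1:]:
        c = trace_cosine(kept[-1], nxt)
        if c >= threshold:
            kept.append(nxt)
            cosines.append(c)
        else:
            break
    if not kept[0].valid or kept[0].nonzero_scans() == 0:
        return FeatureCluster(species=species, traces=[], cosines=[])
    return FeatureCluster(species=species, traces=kept, cosines=cosines)
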