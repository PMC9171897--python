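"""Light/heavy ratio estimation for one peptide pair in one run.

The light channel sums the first two light-species isotopologues, which the
heavy species cannot contaminate under the +2-position label shift; the
heavy channel sums all heavy-species isotopologue positions, which the light
species' M+2, M+3, ... peaks do contaminate. The raw per-scan channel slope
is therefore corrected by inverting the 2x2 envelope mixing model before the
L/(L+H) oxidation stoichiometry is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .feature_extraction import FeatureCluster
from .isotope_model import IsotopeEnvelope, MixingCoefficients, mixing_coefficients

__all__ = [
    "PairQuant",
    "estimate_raw_slope",
    "correct_overlap",
    "compute_mos",
    "quantify_pair",
]

#: default light-channel isotopologue indices (uncontaminated by the heavy species)
LIGHT_CHANNEL = (0, 1)

R2_THRESHOLD = 0.8
MIN_POINTS = 5


@dataclass
class PairQuant:
    peptide: str
    run: str
    light_sums: np.ndarray
    heavy_sums: np.ndarray
    slope: float
    r_squared: float
    corrected_ratio: float
    mos: float
    valid: bool
    reason: str = ""


def estimate_raw_slope(
    light_cluster: FeatureCluster,
    heavy_cluster: FeatureCluster,
    bounds: tuple[float, float] | None = None,
    light_channel: tuple[int, ...] = LIGHT_CHANNEL,
) -> tuple[float, float, np.ndarray, np.ndarray, int]:
    """Per-scan channel sums and the OLS slope of light on heavy.

    Returns ``(slope, r_squared, light_sums, heavy_sums, n_points)`` where
    ``n_points`` counts scans with both channel sums positive. The light
    channel sums only the accepted traces whose index is in
    ``light_channel``; the heavy channel sums every accepted heavy trace.
    """
    if not light_cluster.traces or not heavy_cluster.traces:
        raise ValueError("both clusters must be nonempty")
    rts = light_cluster.traces[0].retention_times
    mask = np.ones(len(rts), dtype=bool)
    if bounds is not None:
        mask = (rts >= bounds[0]) & (rts <= bounds[1])
    light = np.zeros(int(mask.sum()))
    for tr in light_cluster.traces:
        if tr.index in light_channel:
            light += tr.intensities[mask]
    heavy = np.zeros(int(mask.sum()))
    for tr in heavy_cluster.traces:
        heavy += tr.intensities[mask]
    n_points = int(np.count_nonzero((light > 0) & (heavy > 0)))
    if len(light) < 2 or np.var(heavy) == 0:
        return 0.0, 0.0, light, heavy, n_points
    slope, intercept = np.polyfit(heavy, light, 1)
    pred = slope * heavy + intercept
    ss_res = float(np.sum((light - pred) ** 2))
    ss_tot = float(np.sum((light - light.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(max(min(r2, 1.0), 0.0)), light, heavy, n_points


def correct_overlap(raw_slope: float, coeffs: MixingCoefficients) -> float:
    """Invert the 2x2 channel-mixing model for the true L/H ratio.

    With observed channel ratio r = (wLL*L + wLH*H) / (wHL*L + wHH*H),
    the true ratio is rho = (r*wHH - wLH) / (wLL - r*wHL), clamped to
    [0, inf); a vanishing denominator is the pure-light limit (rho -> inf).
    """
    if raw_slope < 0:
        raw_slope = 0.0
    w = coeffs
    det = (
        w.light_channel_weight_L * w.heavy_channel_weight_H
        - w.light_channel_weight_H * w.heavy_channel_weight_L
    )
    if abs(det) < 1e-15:
        raise ValueError("singular channel mixing (degenerate channels)")
    num = raw_slope * w.heavy_channel_weight_H - w.light_channel_weight_H
    den = w.light_channel_weight_L - raw_slope * w.heavy_channel_weight_L
    if den <= 1e-12 * max(w.light_channel_weight_L, 1e-30):
        return np.inf
    return max(num / den, 0.0)


def compute_mos(corrected_ratio: float) -> float:
    """Methionine oxidation stoichiometry MOS = r / (1 + r) = L/(L+H)."""
    if corrected_ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if np.isinf(corrected_ratio):
        return 1.0
    return corrected_ratio / (1.0 + corrected_ratio)


def quantify_pair(
    peptide: str,
    run: str,
    light_cluster: FeatureCluster,
    heavy_cluster: FeatureCluster,
    envelope: IsotopeEnvelope,
    bounds: tuple[float, float] | None = None,
    r2_threshold: float = R2_THRESHOLD,
    min_points: int = MIN_POINTS,
    light_channel: tuple[int, ...] = LIGHT_CHANNEL,
) -> PairQuant:
    """Full per-run quantification: channel sums, slope, R2 gate, overlap
    correction and MOS.

    The mixing coefficients are computed from the peptide's own envelope
    using the isotopologue index sets actually accepted into each cluster,
    so a cosine-truncated cluster keeps the correction consistent with the
    summed signal.
    """
    invalid = lambda reason: PairQuant(
        peptide, run, np.array([]), np.array([]), 0.0, 0.0, 0.0, 0.0, False, reason
    )
    if not light_cluster.traces or not heavy_cluster.traces:
        return invalid("empty cluster")
    light_idx = frozenset(i for i in light_cluster.indices() if i in light_channel)
    heavy_idx = frozenset(i + 2 for i in heavy_cluster.indices())
    if not light_idx:
        return invalid("no uncontaminated light isotopologues")
    slope, r2, lsum, hsum, n = estimate_raw_slope(
        light_cluster, heavy_cluster, bounds, light_channel
    )
    coeffs = mixing_coefficients(envelope, light_idx, heavy_idx)
    try:
        ratio = correct_overlap(slope, coeffs)
    except ValueError:
        return invalid("singular channel mixing")
    mos = compute_mos(ratio)
    if n < min_points:
        return PairQuant(peptide, run, lsum, hsum, slope, r2, ratio, mos, False,
                         "insufficient points")
    if r2 < r2_threshold:
        return PairQuant(peptide, run, lsum, hsum, slope, r2, ratio, mos, False,
                         "r_squared below threshold")
    return PairQuant(peptide, run, lsum, hsum, slope, r2, ratio, mos, True, "")
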