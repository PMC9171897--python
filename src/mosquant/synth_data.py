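"""Ground-truthed synthetic experiments for the 16O/18O blocking workflow.

The simulator emulates the measurement physics end to end: for every
peptide a light (in vivo, 16O) and heavy (blocked, 18O) sulfoxide species
share one natural-abundance isotope envelope, offset by ~2 Da; the signal
split between them is the run-level mixed light fraction
``t + (1 - t) * MOS_true`` (carrier-proteome titration mixing); species are
laid down as Gaussian elution profiles over a centroided MS1 scan grid with
lognormal multiplicative noise, an additive baseline, and optional reagent
isotopic impurity (a heavy label of purity p < 1 deposits a fraction 1 - p
of the blocked signal in the light species). Centroids closer than the
resolution limit are merged, which is what makes the light M+2.. peaks and
the heavy envelope genuinely overlap, as they do on an Orbitrap at 120k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_extraction import MS1Map
from .isotope_model import (
    composition_from_sequence,
    isotope_envelope,
    pair_positions,
)
from .titration import TitrationDesign, DESIGN_COLUMNS

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "SimulatedExperiment",
    "generate_peptide_set",
    "build_design",
    "make_ground_truth",
    "simulate_ms1_run",
    "simulate_experiment",
]

_AA_POOL = "ADEFGHILNPQSTVWY"  # no M, C, K, R: Met/Cys placed explicitly, K/R terminal

#: resolution-limited centroid merge tolerance (Da); 2x13C vs 18O label
#: mismatch (2.5 mDa) falls below it, so those peaks coalesce
MERGE_TOL = 0.005


@dataclass
class NoiseSpec:
    """Run-level noise: lognormal multiplicative sigma, mean additive
    baseline per centroid, and count of random spurious centroids per scan."""

    multiplicative_sigma: float = 0.01
    baseline: float = 0.0
    n_noise_peaks: int = 0


@dataclass
class GroundTruth:
    """Complete description of a simulated experiment."""

    peptides: pd.DataFrame        # sequence, charge, mos_true, rt_mu, rt_sigma, abundance
    design: TitrationDesign
    noise: NoiseSpec
    heavy_purity: float = 1.0
    seed: int = 0
    rt_start: float = 0.0
    rt_end: float = 2.0
    scan_interval: float = 1.0 / 60.0   # minutes (1 s cycle time)
    envelope_k: int = 6


@dataclass
class SimulatedExperiment:
    truth: GroundTruth
    ms1_maps: dict[str, MS1Map]
    evidence: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write mzML per run plus evidence/design/truth TSVs and a JSON
        parameter sidecar; returns the file map."""
        from .cli_io import write_mzml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for run, ms1 in self.ms1_maps.items():
            p = outdir / f"{run}.mzML"
            write_mzml(ms1, p)
            files[run] = str(p)
        self.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
        self.truth.design.table.to_csv(outdir / "design.tsv", sep="\t", index=False)
        self.truth.peptides.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        sidecar = {
            "seed": self.truth.seed,
            "heavy_purity": self.truth.heavy_purity,
            "noise": self.truth.noise.__dict__,
            "rt_start": self.truth.rt_start,
            "rt_end": self.truth.rt_end,
            "scan_interval": self.truth.scan_interval,
            "envelope_k": self.truth.envelope_k,
        }
        (outdir / "params.json").write_text(json.dumps(sidecar, indent=1))
        files.update(
            evidence=str(outdir / "evidence.tsv"),
            design=str(outdir / "design.tsv"),
            truth=str(outdir / "truth.tsv"),
            params=str(outdir / "params.json"),
        )
        return files


def generate_peptide_set(
    n: int,
    seed: int,
    require_single_met: bool = True,
    exclude_cys: bool = True,
) -> list[str]:
    """Deterministic tryptic-like peptide sequences: length 8-25, C-terminal
    K/R, exactly one Met when required, Cys-free when excluded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if require_single_met and not exclude_cys:
        pool = _AA_POOL + "C"
    else:
        pool = _AA_POOL
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        length = int(rng.integers(8, 26))
        body = list(rng.choice(list(pool), size=length - 1))
        if require_single_met:
            body[int(rng.integers(0, length - 1))] = "M"
        seq = "".join(body) + ("K" if rng.random() < 0.5 else "R")
        if seq in seen:
            continue
        seen.add(seq)
        out.append(seq)
    return out


def build_design(
    t_points: tuple[float, ...] = (0.10, 0.25),
    n_technical: int = 2,
    n_biological: int = 3,
    age_groups: tuple[str, ...] = ("young", "old"),
) -> TitrationDesign:
    """The full factorial run design: by default 2 titration points x 2
    technical x 3 biological replicates per age group = 12 runs per group."""
    rows = []
    for age in age_groups:
        for b in range(1, n_biological + 1):
            for t in t_points:
                for r in range(1, n_technical + 1):
                    run = f"{age}_b{b}_t{int(round(t * 100))}_r{r}"
                    rows.append((run, t, r, b, age))
    return TitrationDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def _draw_mos(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """In vivo MOS truth values: a named regime, a constant, or an array."""
    if isinstance(spec, str):
        if spec == "zero":
            return np.zeros(n)
        if spec == "default":
            # bulk near a few percent with an oxidation-prone upper tail
            vals = np.exp(rng.normal(np.log(0.04), 0.5, size=n))
            tail = rng.random(n) < 0.10
            vals[tail] = rng.uniform(0.15, 0.5, size=int(tail.sum()))
            return np.clip(vals, 0.0, 0.95)
        raise ValueError(f"unknown MOS spec: {spec!r}")
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError("MOS array must have one value per peptide")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("MOS truths must lie in [0, 1]")
    return arr


def make_ground_truth(
    n_peptides: int,
    mos: object = "default",
    design: TitrationDesign | None = None,
    noise: NoiseSpec | None = None,
    heavy_purity: float = 1.0,
    seed: int = 0,
    rt_start: float = 0.0,
    rt_end: float = 2.0,
    rt_sigma: float = 0.03,
    scan_interval: float = 1.0 / 60.0,
) -> GroundTruth:
    """Build a reproducible truth table: peptides with spread-out elution
    centers, per-peptide charge 2-3 and abundance, plus the run design."""
    rng = np.random.default_rng(seed)
    seqs = generate_peptide_set(n_peptides, seed=seed)
    margin = 4 * rt_sigma + 2 * scan_interval
    centers = np.linspace(rt_start + margin, rt_end - margin, n_peptides)
    centers = centers + rng.uniform(-0.2, 0.2, n_peptides) * scan_interval
    peptides = pd.DataFrame(
        {
            "sequence": seqs,
            "charge": rng.integers(2, 4, size=n_peptides),
            "mos_true": _draw_mos(mos, n_peptides, rng),
            "rt_mu": centers,
            "rt_sigma": np.full(n_peptides, rt_sigma),
            "abundance": np.exp(rng.normal(np.log(1e7), 0.5, size=n_peptides)),
        }
    )
    return GroundTruth(
        peptides=peptides,
        design=design or build_design(),
        noise=noise or NoiseSpec(),
        heavy_purity=heavy_purity,
        seed=seed,
        rt_start=rt_start,
        rt_end=rt_end,
        scan_interval=scan_interval,
    )


def _merge_centroids(mz: np.ndarray, inten: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge centroids closer than ``tol`` into intensity-weighted peaks."""
    if len(mz) == 0:
        return mz, inten
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    group = np.zeros(len(mz), dtype=int)
    group[1:] = np.cumsum(np.diff(mz) >= tol)
    n = group[-1] + 1
    tot = np.bincount(group, weights=inten, minlength=n)
    wmz = np.bincount(group, weights=inten * mz, minlength=n)
    with np.errstate(invalid="ignore"):
        mmz = np.where(tot > 0, wmz / np.maximum(tot, 1e-300), 0.0)
    keep = tot > 0
    return mmz[keep], tot[keep]


def simulate_ms1_run(
    truth: GroundTruth,
    run_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[MS1Map, pd.DataFrame]:
    """One centroided MS1 run plus its peptide-evidence rows.

    Species intensities split by the mixed light fraction
    ``f = t + (1 - t) * MOS_true`` of the run's titration point, further
    redistributed by the heavy-label purity, then sampled on the scan grid
    with the configured noise and centroid merging.
    """
    drow = truth.design.table[truth.design.table["run"].astype(str) == run_id]
    if len(drow) != 1:
        raise ValueError(f"run {run_id!r} not in the design")
    t_frac = float(drow["t"].iloc[0])
    if rng is None:
        run_index = truth.design.runs().index(run_id)
        rng = np.random.default_rng([truth.seed, run_index])

    rts = np.arange(truth.rt_start, truth.rt_end + 1e-12, truth.scan_interval)
    per_scan_mz: list[list[float]] = [[] for _ in rts]
    per_scan_int: list[list[float]] = [[] for _ in rts]

    env_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    evid_rows = []
    p = truth.heavy_purity
    for row in truth.peptides.itertuples(index=False):
        key = (row.sequence, int(row.charge))
        if key not in env_cache:
            comp = composition_from_sequence(row.sequence, {"met_sulfoxide_16O"})
            env = isotope_envelope(comp, K=truth.envelope_k)
            geom = pair_positions(env, int(row.charge))
            env_cache[key] = (env.abundances, geom.light_mz, geom.heavy_mz)
        abund, light_mz, heavy_mz = env_cache[key]
        f = t_frac + (1.0 - t_frac) * float(row.mos_true)
        light_eff = f + (1.0 - f) * (1.0 - p)
        heavy_eff = (1.0 - f) * p
        gauss = np.exp(-0.5 * ((rts - row.rt_mu) / row.rt_sigma) ** 2)
        for si in np.nonzero(gauss > 1e-6)[0]:
            g = row.abundance * gauss[si]
            for k, a in enumerate(abund):
                if a <= 0:
                    continue
                if light_eff > 0:
                    per_scan_mz[si].append(light_mz[k])
                    per_scan_int[si].append(g * light_eff * a)
                if heavy_eff > 0:
                    per_scan_mz[si].append(heavy_mz[k])
                    per_scan_int[si].append(g * heavy_eff * a)
        evid_rows.append(
            {
                "Sequence": row.sequence,
                "Modifications": "met_sulfoxide",
                "Charge": int(row.charge),
                "m/z": float(light_mz[0]),
                "Retention time": float(row.rt_mu),
                "Retention length": float(6 * row.rt_sigma),
                "Raw file": run_id,
                "Score": 100.0,
            }
        )

    mz_arrays, int_arrays = [], []
    ns = truth.noise
    for si in range(len(rts)):
        mz = np.asarray(per_scan_mz[si])
        it = np.asarray(per_scan_int[si])
        if ns.multiplicative_sigma > 0 and len(it):
            it = it * np.exp(rng.normal(0.0, ns.multiplicative_sigma, size=len(it)))
        if ns.baseline > 0 and len(it):
            it = it + rng.exponential(ns.baseline, size=len(it))
        if ns.n_noise_peaks > 0:
            nm = rng.uniform(300.0, 1500.0, size=ns.n_noise_peaks)
            ni = rng.exponential(ns.baseline or 1e3, size=ns.n_noise_peaks)
            mz = np.concatenate([mz, nm])
            it = np.concatenate([it, ni])
        mz, it = _merge_centroids(mz, it, MERGE_TOL)
        mz_arrays.append(mz)
        int_arrays.append(it)

    ms1 = MS1Map(
        retention_times=rts, mz_arrays=mz_arrays, intensity_arrays=int_arrays,
        run_id=run_id,
    )
    return ms1, pd.DataFrame(evid_rows)


def simulate_experiment(
    n_peptides: int = 50,
    mos: object = "default",
    design: TitrationDesign | None = None,
    noise: NoiseSpec | None = None,
    heavy_purity: float = 1.0,
    seed: int = 0,
    **truth_kwargs,
) -> SimulatedExperiment:
    """Simulate every run of a design (default: the 24-run, two-age-group
    titration layout) and collect MS1 maps, evidence and truth."""
    truth = make_ground_truth(
        n_peptides, mos=mos, design=design, noise=noise,
        heavy_purity=heavy_purity, seed=seed, **truth_kwargs,
    )
    maps: dict[str, MS1Map] = {}
    evid = []
    for run in truth.design.runs():
        ms1, ev = simulate_ms1_run(truth, run)
        maps[run] = ms1
        evid.append(ev)
    return SimulatedExperiment(
        truth=truth, ms1_maps=maps, evidence=pd.concat(evid, ignore_index=True)
    )
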