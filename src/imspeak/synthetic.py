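"""Synthetic two-class MCC-IMS cohorts with ground truth.

Real breath-volatilome cohorts pair a patient group with healthy
controls, each subject contributing one 2-D intensity grid containing a
reactant-ion band, a few dozen analyte peaks at positions that jitter
from subject to subject, occasional missed peaks, and detector noise.
The generator emulates exactly that: every measurement is

    RIP band + Σ present peaks (axis-aligned 2-D Gaussians, optionally
    retention-tailed) at jittered positions + Gaussian noise, clamped at 0

with a subset of peaks ("differential") whose intensity is multiplied by
an effect size in the case group.  The per-measurement peak count
(defaults: 20 shared + 5 differential) sits inside the 10–60 range
observed on real devices.  Everything is deterministic given the seed,
and the realised truth (positions, presence, apex amplitudes) is
returned for recall/precision scoring of any pipeline stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CASE, CONTROL, Measurement, PeakList
from .peakcluster import ClusterResult

__all__ = ["CohortSpec", "GroundTruth", "MatchStats", "generate_cohort", "truth_match"]


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Grid and physical scales default to a desk-scale approximation of a
    real device: 600 retention rows over 0–300 s and 400 drift columns
    over 1/K0 0.4–1.0 Vs/cm².  Amplitudes are log-normal with median
    ~20× the noise standard deviation.
    """

    n_case: int = 30
    n_control: int = 30
    n_rt: int = 600
    n_ik0: int = 400
    rt_range_s: tuple[float, float] = (0.0, 300.0)
    ik0_range: tuple[float, float] = (0.4, 1.0)
    n_shared_peaks: int = 20
    n_diff_peaks: int = 5
    amplitude_mu: float = float(np.log(20.0))
    amplitude_sigma: float = 0.4
    effect_size: float = 2.0
    jitter_sd_rt: float = 1.0
    jitter_sd_ik0: float = 0.001
    dropout: float = 0.1
    peak_sd_rt: float = 3.0
    peak_sd_ik0: float = 0.005
    rt_tailing: float = 0.0
    rip_column_fraction: float = 0.12
    rip_amplitude: float = 50.0
    rip_sd: float = 0.005
    noise_sd: float = 1.0
    min_separation: float = 8.0  # in units of peak sd, between true positions
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        for sd in (self.peak_sd_rt, self.peak_sd_ik0, self.jitter_sd_rt, self.jitter_sd_ik0):
            if sd <= 0:
                raise ValueError("standard deviations must be > 0")
        if self.n_rt < 2 or self.n_ik0 < 2:
            raise ValueError("grid must have at least 2 cells per axis")
        if self.rt_tailing < 0:
            raise ValueError("rt_tailing must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_shared_peaks + self.n_diff_peaks

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        rt = np.linspace(*self.rt_range_s, self.n_rt)
        ik0 = np.linspace(*self.ik0_range, self.n_ik0)
        return rt, ik0


@dataclass
class GroundTruth:
    """True analyte features and their per-measurement realisations.

    ``features`` has one row per analyte (feature_id, rt, ik0,
    differential, base_amplitude); ``realized`` one row per (measurement,
    feature) with the drawn presence, jittered position and apex
    amplitude.  Grid cell sizes are carried along so detection
    tolerances can be expressed in cells.
    """

    features: pd.DataFrame
    realized: pd.DataFrame
    cell_rt: float
    cell_ik0: float
    labels: dict[str, int] = field(default_factory=dict)

    def feature_positions(self) -> np.ndarray:
        return self.features[["rt", "ik0"]].to_numpy(dtype=float)

    def realized_positions(self, measurement_id: str) -> np.ndarray:
        sub = self.realized[
            (self.realized["measurement_id"] == measurement_id) & self.realized["present"]
        ]
        return sub[["rt", "ik0"]].to_numpy(dtype=float)


def _tailed_profile(t: np.ndarray, mu: float, sd: float, tau: float) -> np.ndarray:
    """Unit-apex retention profile: Gaussian, or exponentially modified
    Gaussian when the tailing constant tau > 0."""
    if tau <= 0:
        return np.exp(-0.5 * ((t - mu) / sd) ** 2)
    from scipy.stats import exponnorm

    k = tau / sd
    prof = exponnorm.pdf(t, K=k, loc=mu, scale=sd)
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def _sample_positions(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """True analyte positions: uniform in the usable area, rejected until
    pairwise separation (in peak-sd units) exceeds spec.min_separation,
    clear of the grid margins and of the RIP band."""
    rt_lo, rt_hi = spec.rt_range_s
    ik_lo, ik_hi = spec.ik0_range
    m_rt = 5 * spec.peak_sd_rt + 4 * spec.jitter_sd_rt
    m_ik = 5 * spec.peak_sd_ik0 + 4 * spec.jitter_sd_ik0
    rip_pos = ik_lo + spec.rip_column_fraction * (ik_hi - ik_lo)
    rip_clear = rip_pos + 6 * spec.rip_sd

    pos: list[tuple[float, float]] = []
    attempts = 0
    while len(pos) < spec.n_features:
        attempts += 1
        if attempts > 200 * spec.n_features:
            raise RuntimeError("could not place peaks with the requested separation")
        rt = rng.uniform(rt_lo + m_rt, rt_hi - m_rt)
        ik = rng.uniform(max(ik_lo + m_ik, rip_clear + m_ik), ik_hi - m_ik)
        ok = all(
            np.hypot((rt - r0) / spec.peak_sd_rt, (ik - k0) / spec.peak_sd_ik0)
            >= spec.min_separation
            for r0, k0 in pos
        )
        if ok:
            pos.append((rt, ik))
    return np.array(pos)


def generate_cohort(spec: CohortSpec) -> tuple[list[Measurement], GroundTruth, dict[str, int]]:
    """Generate a labelled two-class cohort of measurements with truth.

    Deterministic given ``spec.seed``.  Differential peaks have their
    amplitude multiplied by ``spec.effect_size`` in the case group only;
    presence is an independent Bernoulli(1 − dropout) draw per
    (measurement, feature).
    """
    rng = np.random.default_rng(spec.seed)
    rt_axis, ik0_axis = spec.axes()
    cell_rt = float(rt_axis[1] - rt_axis[0])
    cell_ik0 = float(ik0_axis[1] - ik0_axis[0])

    positions = _sample_positions(spec, rng)
    min_sep_cells = np.inf
    if len(positions) > 1:
        diff = positions[:, None, :] - positions[None, :, :]
        cells = np.hypot(diff[..., 0] / cell_rt, diff[..., 1] / cell_ik0)
        np.fill_diagonal(cells, np.inf)
        min_sep_cells = cells.min()
    if min_sep_cells < 3:
        warnings.warn(
            f"true peaks only {min_sep_cells:.1f} grid cells apart; "
            "pickers may not resolve them",
            RuntimeWarning,
        )

    differential = np.zeros(spec.n_features, dtype=bool)
    differential[spec.n_shared_peaks :] = True
    base_amp = np.exp(rng.normal(spec.amplitude_mu, spec.amplitude_sigma, spec.n_features))

    features = pd.DataFrame(
        {
            "feature_id": [f"T{j:03d}" for j in range(spec.n_features)],
            "rt": positions[:, 0],
            "ik0": positions[:, 1],
            "differential": differential,
            "base_amplitude": base_amp,
        }
    )

    rip_pos = spec.ik0_range[0] + spec.rip_column_fraction * np.ptp(spec.ik0_range)
    rip_profile = spec.rip_amplitude * np.exp(-0.5 * ((ik0_axis - rip_pos) / spec.rip_sd) ** 2)

    sample_ids = [f"case_{i:03d}" for i in range(spec.n_case)] + [
        f"ctrl_{i:03d}" for i in range(spec.n_control)
    ]
    labels = {mid: 1 if mid.startswith("case") else 0 for mid in sample_ids}

    measurements: list[Measurement] = []
    realized_rows = []
    for mid in sample_ids:
        is_case = labels[mid] == 1
        grid = np.tile(rip_profile, (spec.n_rt, 1))
        present = rng.random(spec.n_features) >= spec.dropout
        jit_rt = rng.normal(0.0, spec.jitter_sd_rt, spec.n_features)
        jit_ik = rng.normal(0.0, spec.jitter_sd_ik0, spec.n_features)
        # mild per-measurement biological variation on top of the base amplitude
        amp_var = np.exp(rng.normal(0.0, 0.2, spec.n_features))
        for j in range(spec.n_features):
            amp = base_amp[j] * amp_var[j]
            if differential[j] and is_case:
                amp *= spec.effect_size
            rt0 = positions[j, 0] + jit_rt[j]
            ik0_0 = positions[j, 1] + jit_ik[j]
            realized_rows.append(
                {
                    "measurement_id": mid,
                    "feature_id": features["feature_id"][j],
                    "present": bool(present[j]),
                    "rt": rt0,
                    "ik0": ik0_0,
                    "amplitude": amp,
                }
            )
            if not present[j]:
                continue
            # separable full-grid rendering: two 1-D profiles, one outer product
            prof_rt = _tailed_profile(rt_axis, rt0, spec.peak_sd_rt, spec.rt_tailing)
            prof_ik = np.exp(-0.5 * ((ik0_axis - ik0_0) / spec.peak_sd_ik0) ** 2)
            grid += amp * prof_rt[:, None] * prof_ik[None, :]
        if spec.noise_sd > 0:
            grid += rng.normal(0.0, spec.noise_sd, grid.shape)
        np.clip(grid, 0.0, None, out=grid)
        measurements.append(
            Measurement(
                sample_id=mid,
                rt_axis=rt_axis,
                ik0_axis=ik0_axis,
                intensity=grid,
                label=CASE if is_case else CONTROL,
            )
        )

    truth = GroundTruth(
        features=features,
        realized=pd.DataFrame(realized_rows),
        cell_rt=cell_rt,
        cell_ik0=cell_ik0,
        labels=labels,
    )
    return measurements, truth, labels


# ---------------------------------------------------------------------------
# Truth matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchStats:
    """Greedy one-to-one matching summary.

    ``rmse`` is over the matched pairs' elliptical distances (1.0 = one
    full tolerance).  With no detections, precision is reported as 1.0
    and ``zero_support`` is set — there were no false positives, but the
    value carries no evidence.
    """

    recall: float
    precision: float
    rmse: float
    n_true: int
    n_detected: int
    n_matched: int
    zero_support: bool = False


def _positions_of(detected) -> np.ndarray:
    if isinstance(detected, PeakList):
        return detected.positions()
    if isinstance(detected, ClusterResult):
        return np.array([(c.rt, c.ik0) for c in detected.consensus], float).reshape(-1, 2)
    return np.asarray(detected, dtype=float).reshape(-1, 2)


def truth_match(
    detected,
    truth,
    rt_tol: float,
    ik0_tol: float,
    radius: float = 1.0,
) -> MatchStats:
    """Score detections against true positions by greedy matching.

    ``detected`` may be a PeakList, a ClusterResult, or an (n, 2) array
    of (rt, ik0); ``truth`` an (m, 2) array of true positions.  Pairs
    are matched one-to-one in order of ascending elliptical distance
    d = sqrt((Δrt/rt_tol)² + (Δik0/ik0_tol)²); a pair counts when
    d ≤ radius.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    det = _positions_of(detected)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    n_det, n_true = det.shape[0], tru.shape[0]
    if n_det == 0:
        return MatchStats(
            recall=0.0 if n_true else 1.0,
            precision=1.0,
            rmse=0.0,
            n_true=n_true,
            n_detected=0,
            n_matched=0,
            zero_support=True,
        )
    if n_true == 0:
        return MatchStats(0.0, 0.0, 0.0, 0, n_det, 0)

    d = np.hypot(
        (det[:, None, 0] - tru[None, :, 0]) / rt_tol,
        (det[:, None, 1] - tru[None, :, 1]) / ik0_tol,
    )
    pairs = [(d[i, j], i, j) for i in range(n_det) for j in range(n_true) if d[i, j] <= radius]
    pairs.sort()
    used_det: set[int] = set()
    used_true: set[int] = set()
    dists = []
    for dist, i, j in pairs:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        dists.append(dist)
    n_matched = len(dists)
    return MatchStats(
        recall=n_matched / n_true,
        precision=n_matched / n_det,
        rmse=float(np.sqrt(np.mean(np.square(dists)))) if dists else 0.0,
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
    )
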