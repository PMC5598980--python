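"""Automated peak picking on single MCC-IMS measurements.

Three pickers, all returning a :class:`~imspeak.core_data.PeakList`:

``pick_lm``
    Local maxima: grid cells strictly exceeding their eight neighbours
    and a pre-specified intensity threshold; nearby candidates are
    merged by weighted cluster editing and each merged group is
    represented by its highest-intensity cell.
``pick_sgltr``
    Savitzky-Golay Laplace-operator filter thresholding regions: the
    (negated) Laplacian is estimated by SG second-derivative filters in
    both directions; connected regions where both the curvature response
    and the intensity exceed their noise levels yield one peak each.
``pick_pdsa``
    Peak detection by slope analysis: an online method scanning drift
    spectra row by row, keeping sliding-window segments whose intensity
    sum is a local maximum above noise, then chaining overlapping
    segments across neighbouring retention times.

Pickers run on a preprocessed grid; ``pick_measurement`` wires the
standard chain (RIP compensation → smoothing → picking) with the
reactant-ion band masked from candidacy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter

from .core_data import Measurement, Peak, PeakList
from .peakcluster import partition_weight_matrix
from .preprocess import compensate_rip, estimate_noise, smooth_savgol

__all__ = ["PickerParams", "pick_lm", "pick_sgltr", "pick_pdsa", "pick_measurement", "PICKERS"]

PICKERS = ("lm", "sgltr", "pdsa")


@dataclass
class PickerParams:
    """Tunable parameters for the three pickers.

    ``lm_threshold=None`` means "use the measurement's estimated noise
    level".  All windows are in grid cells and must be odd ≥ 3.
    """

    lm_threshold: float | None = None
    lm_join_radius: int = 3
    sgltr_window: int = 9
    sgltr_order: int = 2
    sgltr_noise_factor: float = 3.0
    pdsa_segment_window: int = 5
    pdsa_noise_factor: float = 3.0
    pdsa_min_overlap_fraction: float = 0.5
    sgltr_min_region_cells: int = 5
    rel_floor: float = 0.01
    smooth_window: int = 5
    smooth_order: int = 2
    rip_enabled: bool = True
    rip_band_fraction: float = 0.5
    noise_k: float = 3.0

    def __post_init__(self) -> None:
        for w in (self.sgltr_window, self.pdsa_segment_window, self.smooth_window):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"windows must be odd and >= 3, got {w}")
        if not 0.0 <= self.pdsa_min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must be in [0, 1]")


def _column_mask(m: Measurement, exclude_cols) -> np.ndarray:
    """Boolean mask of columns eligible for candidacy (True = usable).

    ``exclude_cols`` is either an inclusive (lo, hi) column range or a
    boolean array marking excluded columns.
    """
    mask = np.ones(m.ik0_axis.size, dtype=bool)
    if exclude_cols is None:
        return mask
    if isinstance(exclude_cols, tuple):
        lo, hi = exclude_cols
        mask[lo : hi + 1] = False
    else:
        mask[np.asarray(exclude_cols, dtype=bool)] = False
    return mask


def _make_peak(m: Measurement, r: int, c: int, bbox_cells=None) -> Peak:
    bbox = None
    if bbox_cells is not None:
        r0, r1, c0, c1 = bbox_cells
        bbox = (float(m.rt_axis[r0]), float(m.rt_axis[r1]),
                float(m.ik0_axis[c0]), float(m.ik0_axis[c1]))
    return Peak(
        measurement_id=m.sample_id,
        rt=float(m.rt_axis[r]),
        ik0=float(m.ik0_axis[c]),
        intensity=float(m.intensity[r, c]),
        bbox=bbox,
    )


# ---------------------------------------------------------------------------
# Local maxima
# ---------------------------------------------------------------------------

_NEIGHBOUR_FOOTPRINT = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)


def pick_lm(
    m: Measurement,
    threshold: float = 0.0,
    join_radius: int = 3,
    exclude_cols: tuple[int, int] | None = None,
    exact_limit: int = 12,
) -> PeakList:
    """Local-maxima picking with cluster-editing candidate merging.

    A cell is a candidate when its intensity strictly exceeds the
    threshold and all eight neighbours (exact-tie plateaus yield no
    candidate).  Candidates within ``join_radius`` grid cells (Chebyshev)
    belong to the same underlying peak and are merged by weighted
    cluster editing; each clique's position and intensity come from its
    highest-intensity cell.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = m.intensity
    neigh_max = ndimage.maximum_filter(x, footprint=_NEIGHBOUR_FOOTPRINT, mode="nearest")
    cand = (x > threshold) & (x > neigh_max)
    cand[:, ~_column_mask(m, exclude_cols)] = False
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        return PeakList(measurement_id=m.sample_id, peaks=[])

    # similarity = join_radius - Chebyshev cell distance (positive = same peak)
    pts = np.column_stack([rows, cols]).astype(float)
    cheb = np.max(np.abs(pts[:, None, :] - pts[None, :, :]), axis=2)
    W = float(join_radius) - cheb
    np.fill_diagonal(W, 0.0)

    peaks = []
    for clique in partition_weight_matrix(W, exact_limit=exact_limit):
        best = max(clique, key=lambda i: (x[rows[i], cols[i]], -rows[i], -cols[i]))
        peaks.append(_make_peak(m, rows[best], cols[best]))
    peaks.sort(key=lambda p: (p.rt, p.ik0))
    return PeakList(measurement_id=m.sample_id, peaks=peaks)


# ---------------------------------------------------------------------------
# SGLTR
# ---------------------------------------------------------------------------


def sgltr_response(m: Measurement, window: int = 9, order: int = 2) -> np.ndarray:
    """Negated SG-filtered Laplacian of the intensity grid (cell units).

    The Laplace operator (sum of unmixed second derivatives along
    retention and drift) is approximated by Savitzky-Golay
    second-derivative filters; the sign is flipped so that peak apices —
    where both second derivatives are strongly negative — give a large
    positive curvature response.
    """
    if order < 2:
        raise ValueError("SGLTR needs polynomial order >= 2 for second derivatives")
    if window < 3 or window % 2 == 0 or order >= window:
        raise ValueError(f"invalid SG window/order ({window}, {order})")
    d2_rt = savgol_filter(m.intensity, window, order, deriv=2, axis=0, mode="nearest")
    d2_ik0 = savgol_filter(m.intensity, window, order, deriv=2, axis=1, mode="nearest")
    return -(d2_rt + d2_ik0)


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def pick_sgltr(
    m: Measurement,
    window: int = 9,
    order: int = 2,
    noise_factor: float = 3.0,
    exclude_cols: tuple[int, int] | None = None,
    min_region_cells: int = 5,
    rel_floor: float = 0.01,
) -> PeakList:
    """High-curvature-region picking.

    Peak regions are 8-connected components of cells whose curvature
    response and intensity both exceed their respective noise levels
    (median + k·MAD).  Each region yields one peak at its
    maximum-intensity cell, with the region's bounding box attached.

    Two guards keep the method sane at extreme dynamic range: the noise
    levels are floored at ``rel_floor`` of the respective grid maximum
    (a noise-free grid would otherwise have level 0, promoting float
    crumbs in far tails), and regions smaller than ``min_region_cells``
    are discarded — a genuine smoothed peak always covers several cells.
    """
    resp = sgltr_response(m, window, order)
    level_resp = max(estimate_noise(resp, k=noise_factor).noise_level(),
                     rel_floor * float(resp.max(initial=0.0)))
    level_int = max(estimate_noise(m.intensity, k=noise_factor).noise_level(),
                    rel_floor * float(m.intensity.max(initial=0.0)))
    hot = (resp > level_resp) & (m.intensity > level_int)
    hot[:, ~_column_mask(m, exclude_cols)] = False
    labels, n_regions = ndimage.label(hot, structure=_EIGHT_CONN)
    if n_regions == 0:
        return PeakList(measurement_id=m.sample_id, peaks=[])

    peaks = []
    for sl_r, sl_c in ndimage.find_objects(labels):
        region = labels[sl_r, sl_c] > 0
        if int(region.sum()) < min_region_cells:
            continue
        sub = np.where(region, m.intensity[sl_r, sl_c], -np.inf)
        r_loc, c_loc = np.unravel_index(np.argmax(sub), sub.shape)
        r, c = sl_r.start + r_loc, sl_c.start + c_loc
        bbox_cells = (sl_r.start, sl_r.stop - 1, sl_c.start, sl_c.stop - 1)
        peaks.append(_make_peak(m, r, c, bbox_cells))
    peaks.sort(key=lambda p: (p.rt, p.ik0))
    return PeakList(measurement_id=m.sample_id, peaks=peaks)


# ---------------------------------------------------------------------------
# PDSA
# ---------------------------------------------------------------------------


def _row_segments(row: np.ndarray, L: int, min_score: float) -> list[tuple[int, float]]:
    """Start indices and scores of kept segments in one drift spectrum.

    Window sums are scored over all start positions; a window is a
    segment when its score is a strict local maximum over start shifts
    of ±1 and exceeds ``min_score``.  Overlapping segments are resolved
    by keeping the higher-scoring one.
    """
    n = row.size
    if L > n:
        raise ValueError(f"segment window {L} exceeds row length {n}")
    scores = np.convolve(row, np.ones(L), mode="valid")  # scores[j] = sum(row[j:j+L])
    left = np.empty_like(scores)
    right = np.empty_like(scores)
    left[0], left[1:] = -np.inf, scores[:-1]
    right[-1], right[:-1] = -np.inf, scores[1:]
    # plateau tie-break: keep the leftmost of equal-score neighbours, so a
    # peak apex falling exactly between two columns still yields a segment
    is_seg = (scores > left) & (scores >= right) & (scores > min_score)
    starts = np.nonzero(is_seg)[0]
    # discard overlaps: greedy by descending score, ties by start index
    kept: list[tuple[int, float]] = []
    for j in sorted(starts, key=lambda j: (-scores[j], j)):
        if all(abs(j - k) >= L for k, _ in kept):
            kept.append((int(j), float(scores[j])))
    kept.sort()
    return kept


def pick_pdsa(
    m: Measurement,
    segment_window: int = 5,
    noise_factor: float = 3.0,
    min_overlap_fraction: float = 0.5,
    exclude_cols: tuple[int, int] | None = None,
    rel_floor: float = 0.01,
) -> PeakList:
    """Slope-analysis picking: per-spectrum segments chained across rows.

    Each retention-time row is scanned with a sliding window of
    ``segment_window`` cells; locally-maximal window sums above
    ``segment_window ×`` the noise level become segments, overlapping
    segments within a row are discarded in favour of the higher score,
    and segments in adjacent rows whose drift intervals overlap by at
    least ``min_overlap_fraction`` of the window are chained into one
    peak.  The peak sits at the chain's maximum-intensity cell; its
    bounding box is the union of the member segments.

    The per-cell level is floored at ``rel_floor`` of the grid maximum
    so that a noise-free grid (estimated noise level 0) does not chain
    unrelated peaks through their vanishing tails.
    """
    x = m.intensity.copy()
    x[:, ~_column_mask(m, exclude_cols)] = 0.0
    level = max(estimate_noise(m.intensity, k=noise_factor).noise_level(),
                rel_floor * float(m.intensity.max(initial=0.0)))
    min_score = segment_window * level
    L = segment_window

    # collect segments per row
    seg_row: list[int] = []
    seg_start: list[int] = []
    by_row: dict[int, list[int]] = {}
    for r in range(x.shape[0]):
        for j, _ in _row_segments(x[r], L, min_score):
            by_row.setdefault(r, []).append(len(seg_row))
            seg_row.append(r)
            seg_start.append(j)
    n_seg = len(seg_row)
    if n_seg == 0:
        return PeakList(measurement_id=m.sample_id, peaks=[])

    # chain segments in adjacent rows with sufficient drift overlap
    parent = list(range(n_seg))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    min_overlap = min_overlap_fraction * L
    for r, idxs in by_row.items():
        for s in idxs:
            for t in by_row.get(r + 1, ()):
                overlap = L - abs(seg_start[s] - seg_start[t])
                if overlap >= min_overlap:
                    ra, rb = find(s), find(t)
                    if ra != rb:
                        parent[rb] = ra

    chains: dict[int, list[int]] = {}
    for s in range(n_seg):
        chains.setdefault(find(s), []).append(s)

    peaks = []
    for members in chains.values():
        best_val, best_cell = -np.inf, None
        r_lo = min(seg_row[s] for s in members)
        r_hi = max(seg_row[s] for s in members)
        c_lo = min(seg_start[s] for s in members)
        c_hi = max(seg_start[s] + L - 1 for s in members)
        for s in members:
            r, j = seg_row[s], seg_start[s]
            row_slice = x[r, j : j + L]
            c_loc = int(np.argmax(row_slice))
            if row_slice[c_loc] > best_val:
                best_val, best_cell = float(row_slice[c_loc]), (r, j + c_loc)
        peaks.append(_make_peak(m, *best_cell, bbox_cells=(r_lo, r_hi, c_lo, c_hi)))
    peaks.sort(key=lambda p: (p.rt, p.ik0))
    return PeakList(measurement_id=m.sample_id, peaks=peaks)


# ---------------------------------------------------------------------------
# Standard pipeline entry point
# ---------------------------------------------------------------------------


def pick_measurement(m: Measurement, method: str, params: PickerParams | None = None) -> PeakList:
    """RIP-compensate, smooth, and pick peaks with the chosen method.

    The reactant-ion band is located on the raw grid and its columns are
    masked from candidacy — the RIP is an instrument artifact, not an
    analyte.  ``method`` is one of ``"lm"``, ``"sgltr"``, ``"pdsa"``.
    """
    params = params or PickerParams()
    work = compensate_rip(m, params.rip_band_fraction) if params.rip_enabled else m
    if params.smooth_window:
        work = smooth_savgol(work, params.smooth_window, params.smooth_order)
        # smoothing can leave tiny negatives near clamped zeros
        work = work.with_intensity(np.clip(work.intensity, 0.0, None))

    band = None
    if params.rip_enabled:
        # any column whose median still rises above the noise floor carries
        # retention-invariant (RIP) structure: analyte peaks occupy too few
        # rows to move a column median, so this catches band residues and
        # uncompensated RIP tails alike
        level = max(estimate_noise(work.intensity, k=params.noise_k).noise_level(),
                    params.rel_floor * float(work.intensity.max(initial=0.0)))
        rip_cols = np.median(work.intensity, axis=0) > level
        if rip_cols.any():
            band = rip_cols

    if method == "lm":
        thr = params.lm_threshold
        if thr is None:
            thr = max(estimate_noise(work.intensity, k=params.noise_k).noise_level(),
                      params.rel_floor * float(work.intensity.max(initial=0.0)))
        return pick_lm(work, threshold=thr, join_radius=params.lm_join_radius,
                       exclude_cols=band)
    if method == "sgltr":
        return pick_sgltr(work, params.sgltr_window, params.sgltr_order,
                          params.sgltr_noise_factor, exclude_cols=band,
                          min_region_cells=params.sgltr_min_region_cells,
                          rel_floor=params.rel_floor)
    if method == "pdsa":
        return pick_pdsa(work, params.pdsa_segment_window, params.pdsa_noise_factor,
                         params.pdsa_min_overlap_fraction, exclude_cols=band,
                         rel_floor=params.rel_floor)
    raise ValueError(f"unknown picker {method!r}; expected one of {PICKERS}")
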