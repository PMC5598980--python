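"""Build the classification feature matrix from consensus peaks.

Each consensus peak is a feature; its intensity for a given measurement
is taken from that measurement's detected peak closest to the consensus
location, provided the peak lies within an assignment radius in
normalised coordinates.  Measurements without a matching peak get 0 —
the absence of a detected signal is treated as zero analyte response.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core_data import ConsensusPeak, FeatureMatrix, PeakList
from .peakcluster import Scaling

__all__ = ["build_feature_matrix"]


def build_feature_matrix(
    consensus: Sequence[ConsensusPeak],
    peaklists: Sequence[PeakList],
    labels: Mapping[str, int],
    assign_radius: float = 1.0,
    scaling: Scaling = Scaling(),
) -> FeatureMatrix:
    """Measurements × consensus-peaks intensity table.

    Entry (i, j) is the intensity of the peak in measurement i nearest
    to consensus j when their normalised distance is at most
    ``assign_radius``, else 0.  A single peak may supply several
    features only if it is the nearest for each of them.

    ``labels`` maps measurement id → binary class (1 = case).
    """
    if not consensus:
        raise ValueError("consensus list must be non-empty")
    if assign_radius <= 0:
        raise ValueError("assign_radius must be > 0")
    mids = [pl.measurement_id for pl in peaklists]
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate measurement ids in peak lists")
    missing = [mid for mid in mids if mid not in labels]
    if missing:
        raise ValueError(f"measurements without labels: {missing}")

    cons_rt = np.array([c.rt for c in consensus])
    cons_ik0 = np.array([c.ik0 for c in consensus])
    values = np.zeros((len(peaklists), len(consensus)))
    for i, pl in enumerate(peaklists):
        if len(pl) == 0:
            continue
        rt = np.array([p.rt for p in pl.peaks])
        ik0 = np.array([p.ik0 for p in pl.peaks])
        inten = np.array([p.intensity for p in pl.peaks])
        # (n_peaks, n_consensus) normalised distances
        d = scaling.distance(rt[:, None], ik0[:, None], cons_rt[None, :], cons_ik0[None, :])
        nearest = np.argmin(d, axis=0)
        within = d[nearest, np.arange(len(consensus))] <= assign_radius
        values[i, within] = inten[nearest[within]]

    return FeatureMatrix(
        measurement_ids=list(mids),
        feature_ids=[c.feature_id for c in consensus],
        values=values,
        labels=np.array([labels[mid] for mid in mids], dtype=int),
    )
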