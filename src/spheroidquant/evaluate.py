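"""Recovery evaluation of the pipeline against simulator ground truth.

The segmentation works per slice while the truth lives in 3D, so scoring
needs a visibility convention: a truth cell is *expected to be found* on
its nearest slice when its center lies within ``visible_dz_um`` of that
plane (default 3.5 µm ≈ 60% of a nucleus radius; nuclei further from the
plane present too small and dim a cross-section to be segmentable by
design). Detections are matched to truth cells on the same slice within
``match_radius_um`` in-plane.

- recall = matched expected-visible cells / expected-visible cells
- precision = detections matched to *any* nearby truth cell (within the
  looser ``tolerated_dz_um``) / all detections; cells beyond the
  visibility cut can still legitimately be detected (a nucleus at 2σ_z ≈
  10 µm off-plane still presents ~15% of its peak cross-section, enough
  for a local adaptive threshold), so they count for precision but are
  not demanded for recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import NucleusRecord
from .synthetic import GroundTruth, SimParams

DEFAULT_VISIBLE_DZ_UM = 3.5
DEFAULT_TOLERATED_DZ_UM = 10.0
DEFAULT_MATCH_RADIUS_UM = 10.0


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_truth_visible: int
    n_detected: int
    n_matched: int


def score_recovery(truth: GroundTruth, params: SimParams,
                   nuclei: list[NucleusRecord], *,
                   visible_dz_um: float = DEFAULT_VISIBLE_DZ_UM,
                   tolerated_dz_um: float = DEFAULT_TOLERATED_DZ_UM,
                   match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
                   ) -> RecoveryScore:
    """Match detections to truth cells per slice and score precision/recall.

    Apoptotic truth cells are excluded (they are rendered as fragment
    clusters, not nuclei, and are scored by the apoptosis detector
    instead).
    """
    xy = params.calibration.xy_size
    z_planes = params.slice_z_positions()
    cells = truth.cells[truth.cells["state"] != "apoptotic"]
    dz = np.abs(cells["z_um"].to_numpy()[:, None] - z_planes[None, :])
    nearest = dz.argmin(axis=1)
    min_dz = dz.min(axis=1)

    n_matched_truth = 0
    n_visible = 0
    n_det_matched = 0
    n_det = len(nuclei)

    for s in range(len(z_planes)):
        det = [n for n in nuclei if n.slice_index == s]
        det_um = np.array([[n.centroid[0] * xy, n.centroid[1] * xy]
                           for n in det]).reshape(-1, 2)
        on_slice = cells[nearest == s]
        vis = on_slice[min_dz[nearest == s] <= visible_dz_um]
        # for precision: any cell close enough to *this* plane can cause a
        # legitimate detection here, whichever plane is its nearest
        tol = cells[dz[:, s] <= tolerated_dz_um]
        n_visible += len(vis)
        if len(det) == 0:
            continue
        tree = cKDTree(det_um)
        if len(vis):
            vis_um = np.column_stack([vis["row_px"] * xy, vis["col_px"] * xy])
            dist, _ = tree.query(vis_um)
            n_matched_truth += int((dist <= match_radius_um).sum())
        if len(tol):
            tol_um = np.column_stack([tol["row_px"] * xy, tol["col_px"] * xy])
            truth_tree = cKDTree(tol_um)
            dist, _ = truth_tree.query(det_um)
            n_det_matched += int((dist <= match_radius_um).sum())

    precision = n_det_matched / n_det if n_det else 0.0
    recall = n_matched_truth / n_visible if n_visible else 0.0
    return RecoveryScore(precision=precision, recall=recall,
                         n_truth_visible=n_visible, n_detected=n_det,
                         n_matched=n_matched_truth)
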