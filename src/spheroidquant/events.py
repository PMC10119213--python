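"""Event quantification: apoptotic fragmentation, mitosis annotations,
per-zone count/frequency tables and the two-group comparison.

Apoptosis is read out from nuclear fragmentation of the chromatin
reporter: sub-nucleus objects with calibrated area 3–25 µm² that cluster
within a 20 µm linking distance (single linkage, ≥ 2 members) form one
apoptotic event, standing for one dead cell. Mitoses are ingested from
manual annotations (condensed, bright figures are counted by eye in this
assay). Group comparisons use a Mann–Whitney U test with an exact
enumeration branch for small samples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .calibration import PixelCalibration
from .image_io import AnnotationTable
from .segmentation import FragmentCandidate, NucleusRecord
from .zones import QuadrantSelection, ZoneMap

logger = logging.getLogger("spheroidquant")

FRAGMENT_AREA_MIN = 3.0   # µm²
FRAGMENT_AREA_MAX = 25.0  # µm²


@dataclass
class ApoptosisEvent:
    """A cluster of nuclear fragments standing for one dead cell."""

    id: int
    slice_index: int
    center: tuple  # (row, col) px
    member_ids: list
    zone: str = "unassigned"


def detect_apoptosis(fragment_candidates: list[FragmentCandidate],
                     calibration: PixelCalibration, *,
                     cluster_radius_um: float = 20.0,
                     min_fragments: int = 2) -> list[ApoptosisEvent]:
    """Cluster in-band fragments into apoptotic events, per slice.

    Candidates with 3 µm² ≤ area ≤ 25 µm² are single-linkage clustered
    with the 20 µm linking distance; clusters with at least
    ``min_fragments`` members become events centered at the mean member
    centroid. Each fragment belongs to at most one event.
    """
    in_band = [f for f in fragment_candidates
               if FRAGMENT_AREA_MIN <= f.area_um2 <= FRAGMENT_AREA_MAX]
    events: list[ApoptosisEvent] = []
    next_id = 1
    for slice_index in sorted({f.slice_index for f in in_band}):
        frags = [f for f in in_band if f.slice_index == slice_index]
        coords = np.array([f.centroid for f in frags]) * calibration.xy_size
        if len(frags) == 1:
            continue
        z = linkage(pdist(coords), method="single")
        assignments = fcluster(z, t=cluster_radius_um, criterion="distance")
        for cluster_id in np.unique(assignments):
            members = [f for f, a in zip(frags, assignments) if a == cluster_id]
            if len(members) < min_fragments:
                continue
            center = tuple(np.mean([f.centroid for f in members], axis=0))
            events.append(ApoptosisEvent(
                id=next_id, slice_index=slice_index, center=center,
                member_ids=[f.id for f in members]))
            next_id += 1
    return events


def assign_event_zones(events: list[ApoptosisEvent], zone_map: ZoneMap,
                       quadrant: QuadrantSelection | None = None, *,
                       restrict_invasion_to_quadrant: bool = False,
                       ) -> list[ApoptosisEvent]:
    """Zone of an event = zone label at its center pixel (same quadrant
    rule as nuclei, applied uniformly)."""
    for ev in events:
        zone = zone_map.zone_at(*ev.center)
        if (restrict_invasion_to_quadrant and quadrant is not None
                and zone == "invasion"
                and not bool(quadrant.contains(ev.center[0], ev.center[1]))):
            zone = "unassigned"
        ev.zone = zone
    return events


def death_frequency(events: list[ApoptosisEvent],
                    nuclei: list[NucleusRecord], zone: str) -> float:
    """events / (events + intact nuclei) in the zone; one event = one dead
    cell. Returns 0 (with a warning) when the zone is empty."""
    n_events = sum(1 for e in events if e.zone == zone)
    n_nuclei = sum(1 for n in nuclei if n.zone == zone)
    if n_events + n_nuclei == 0:
        logger.warning("death_frequency: no events or nuclei in zone %r", zone)
        return 0.0
    return n_events / (n_events + n_nuclei)


def ingest_mitoses(annotations: AnnotationTable, zone_map: ZoneMap,
                   nuclei: list[NucleusRecord],
                   calibration: PixelCalibration, *,
                   dedup_radius_um: float = 5.0) -> dict:
    """Assign manual mitosis annotations to zones and compute frequencies.

    Rows outside the image are rejected with a warning; duplicate
    annotations within 5 µm on the same slice collapse to one. Frequency
    per zone = mitoses / (mitoses + nuclei).
    """
    h, w = zone_map.labels.shape
    rows = annotations.rows
    kept: list[tuple[int, float, float]] = []
    for rec in rows.itertuples():
        if not (0 <= rec.row < h and 0 <= rec.col < w):
            logger.warning("mitosis annotation at (%s, %s) outside image; rejected",
                           rec.row, rec.col)
            continue
        dup = False
        for s, r, c in kept:
            if s == rec.slice and math.hypot(r - rec.row, c - rec.col) \
                    * calibration.xy_size <= dedup_radius_um:
                logger.warning("duplicate mitosis annotation within %.0f µm "
                               "collapsed", dedup_radius_um)
                dup = True
                break
        if not dup:
            kept.append((int(rec.slice), float(rec.row), float(rec.col)))

    counts: dict[str, int] = {}
    for _, r, c in kept:
        zone = zone_map.zone_at(r, c)
        counts[zone] = counts.get(zone, 0) + 1
    frequencies = {}
    zones = set(counts) | {n.zone for n in nuclei}
    for zone in zones:
        m = counts.get(zone, 0)
        n = sum(1 for rec in nuclei if rec.zone == zone)
        frequencies[zone] = m / (m + n) if (m + n) else 0.0
    return {"counts": counts, "frequencies": frequencies,
            "n_annotations_kept": len(kept)}


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class QuantResult:
    """Per-zone readouts of one specimen/time point."""

    nuclei: list = field(default_factory=list)
    events: list = field(default_factory=list)
    mitoses: dict = field(default_factory=dict)
    per_slice_zone_counts: pd.DataFrame | None = None
    zone_totals: dict = field(default_factory=dict)
    zone_mean_per_slice: dict = field(default_factory=dict)
    death_frequencies: dict = field(default_factory=dict)
    mitosis_frequencies: dict = field(default_factory=dict)
    invasion_max_distance_um: float = 0.0
    invasion_p95_distance_um: float = 0.0
    time_label: str = ""
    snr_profile: object = None
    metadata: dict = field(default_factory=dict)

    def nuclei_table(self) -> pd.DataFrame:
        cols = ["id", "slice", "centroid_row", "centroid_col", "area_um2",
                "mean_intensity", "zone", "radial_distance_um", "state"]
        rows = [{
            "id": n.id, "slice": n.slice_index,
            "centroid_row": n.centroid[0], "centroid_col": n.centroid[1],
            "area_um2": n.area_um2, "mean_intensity": n.mean_intensity,
            "zone": n.zone, "radial_distance_um": n.radial_distance_um,
            "state": n.state,
        } for n in self.nuclei]
        return pd.DataFrame(rows, columns=cols)

    def zone_summary_table(self) -> pd.DataFrame:
        zones = ("core", "rim", "invasion")
        rows = []
        for z in zones:
            rows.append({
                "zone": z,
                "nucleus_count": self.zone_totals.get(z, 0),
                "mean_per_slice": self.zone_mean_per_slice.get(z, 0.0),
                "apoptosis_events": sum(1 for e in self.events if e.zone == z),
                "death_frequency": self.death_frequencies.get(z, 0.0),
                "mitosis_count": self.mitoses.get("counts", {}).get(z, 0),
                "mitosis_frequency": self.mitosis_frequencies.get(z, 0.0),
            })
        return pd.DataFrame(rows)


def summarize(nuclei: list[NucleusRecord], events: list[ApoptosisEvent],
              mitoses: dict | None, zone_map: ZoneMap,
              quadrant: QuadrantSelection | None,
              calibration: PixelCalibration, *, n_slices: int | None = None,
              time_label: str = "", metadata: dict | None = None) -> QuantResult:
    """Fill the per-zone count/frequency tables for one specimen.

    The invasion summary reports the maximum and the 95th-percentile
    radial distance of invasion-zone nuclei (the "how far have cells
    disseminated" readout).
    """
    zones = ("core", "rim", "invasion")
    slices = sorted({n.slice_index for n in nuclei}) or [0]
    if n_slices is None:
        n_slices = len(slices)
    per_slice = [{"slice": s,
                  **{z: sum(1 for n in nuclei
                            if n.slice_index == s and n.zone == z)
                     for z in zones}}
                 for s in slices]
    per_slice_df = pd.DataFrame(per_slice, columns=["slice", *zones])
    totals = {z: int(sum(1 for n in nuclei if n.zone == z)) for z in zones}
    mean_per_slice = {z: totals[z] / n_slices if n_slices else 0.0 for z in zones}
    death = {z: death_frequency(events, nuclei, z) if
             (totals[z] or any(e.zone == z for e in events)) else 0.0
             for z in zones}
    mito_freq = (mitoses or {}).get("frequencies", {})

    inv_dist = np.array([n.radial_distance_um for n in nuclei
                         if n.zone == "invasion"
                         and np.isfinite(n.radial_distance_um)])
    return QuantResult(
        nuclei=nuclei, events=events, mitoses=mitoses or {},
        per_slice_zone_counts=per_slice_df, zone_totals=totals,
        zone_mean_per_slice=mean_per_slice, death_frequencies=death,
        mitosis_frequencies={z: mito_freq.get(z, 0.0) for z in zones},
        invasion_max_distance_um=float(inv_dist.max()) if len(inv_dist) else 0.0,
        invasion_p95_distance_um=float(np.percentile(inv_dist, 95))
        if len(inv_dist) else 0.0,
        time_label=time_label, metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    group_labels: tuple
    values_a: list
    values_b: list
    u_statistic: float
    p_value: float
    method: str


EXACT_ENUMERATION_LIMIT = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(group_a, group_b, *, labels: tuple = ("a", "b"),
                 ) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    Exact branch (n₁ + n₂ ≤ 12): full enumeration of which pooled
    mid-ranks go to group A; p = fraction of assignments whose U deviates
    from n₁n₂/2 at least as much as the observed U. Larger samples use
    the normal approximation with tie correction and continuity
    correction. U is reported for group A.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = ranks[list(combo)].sum()
            u = r - n1 * (n1 + 1) / 2.0
            if abs(u - mid) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact enumeration"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            from scipy.stats import norm
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            p = 2.0 * norm.sf(max(z, 0.0))
        p = min(p, 1.0)
        method = "normal approximation (tie-corrected)"
    return ComparisonResult(group_labels=labels, values_a=a.tolist(),
                            values_b=b.tolist(), u_statistic=float(u_obs),
                            p_value=float(p), method=method)
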