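"""Dimer-interface detection, clustering, labelling and crystal comparison.

A dimer observation is summarized by a binary residue–residue contact map
δ_ij (residue *i* of protomer A against residue *j* of protomer B, contact
iff the backbone-bead minimum-image distance is strictly below the cutoff,
default 8 Å).  A pair is *dimeric* once at least ``min_residues`` residues
on each protomer participate in cross-contacts, sustained over a
persistence window.  Interfaces are clustered by k-means under the
Frobenius-norm distance — with the protomer-swap (transpose) orientation
minimized per member for homodimers — and labelled by the TM helices
contributing at least ``min_involved`` involved residues per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory import BeadTrajectory, align_to_reference, minimum_image_displacement

__all__ = [
    "ContactMap",
    "DimerEvent",
    "InterfaceCluster",
    "CrystalDimer",
    "compute_contact_map",
    "detect_dimer_events",
    "interface_dissimilarity",
    "cluster_interfaces",
    "auto_cluster",
    "label_cluster",
    "format_interface_label",
    "crystal_rmsd",
    "load_crystal_dimer",
    "events_to_frame",
]

HELIX_ORDER = {f"TM{i}": i for i in range(1, 8)} | {"H8": 8}


@dataclass
class ContactMap:
    """Binary inter-protomer contact map for one dimer observation."""

    matrix: np.ndarray  # (n_res_A, n_res_B) in {0,1}
    pair: tuple[int, int] = (0, 1)
    observation_id: int = 0
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("contact map must be a matrix")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("contact-map entries must be 0/1")


@dataclass
class DimerEvent:
    """First sustained association of a protomer pair in one trajectory."""

    trajectory_id: str
    time: float  # ns
    pair: tuple[int, int]
    cluster: int | None = None
    label: str | None = None


@dataclass
class InterfaceCluster:
    """A k-means cluster of contact maps with marginal contact profiles.

    ``marginal_a``/``marginal_b`` hold, per residue of each side, the
    fraction of member maps in which that residue carries at least one
    cross-contact (in [0, 1]; used for labelling by majority).  The
    centroid is the member-averaged real-valued contact map, whose row and
    column sums give the mean contact *count* per residue.
    """

    cluster_id: int
    members: list[int]  # observation ids
    centroid: np.ndarray
    marginal_a: np.ndarray  # per residue of side A
    marginal_b: np.ndarray  # per residue of side B
    label: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def contact_count_a(self) -> np.ndarray:
        """Mean number of contacts per side-A residue over members."""
        return self.centroid.sum(axis=1)

    @property
    def contact_count_b(self) -> np.ndarray:
        return self.centroid.sum(axis=0)


@dataclass
class CrystalDimer:
    """Backbone coordinates of two chains of a crystallographic dimer."""

    name: str
    chain_a: np.ndarray  # (n, 3), Å
    chain_b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.chain_a) == 0 or len(self.chain_b) == 0:
            raise ValueError("both chains must be non-empty")


def compute_contact_map(
    protA: np.ndarray,
    protB: np.ndarray,
    box: np.ndarray | None,
    cutoff: float = 8.0,
    pair: tuple[int, int] = (0, 1),
    observation_id: int = 0,
    time: float = 0.0,
) -> ContactMap:
    """δ_ij = 1 iff the minimum-image residue-bead distance is < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.asarray(protA, dtype=float)
    B = np.asarray(protB, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("empty protomer")
    if box is None:
        d = B[None, :, :] - A[:, None, :]
    else:
        d = minimum_image_displacement(A[:, None, :], B[None, :, :], np.asarray(box, dtype=float))
    dist = np.sqrt((d**2).sum(axis=-1))
    return ContactMap((dist < cutoff).astype(np.uint8), pair, observation_id, time)


def _pair_contact_matrix(traj: BeadTrajectory, frame: int, i: int, j: int, cutoff: float) -> np.ndarray:
    return compute_contact_map(
        traj.protomer_positions(i, frame), traj.protomer_positions(j, frame), traj.box[frame], cutoff
    ).matrix


def detect_dimer_events(
    traj: BeadTrajectory,
    cutoff: float = 8.0,
    min_residues: int = 10,
    min_persist_frames: int = 1,
    trajectory_id: str = "traj",
    prefilter_margin: float = 1.2,
) -> tuple[list[DimerEvent], list[ContactMap]]:
    """Detect first sustained dimerization events for every protomer pair.

    A frame *qualifies* for a pair when at least ``min_residues`` distinct
    residues on **each** protomer carry a cross-contact.  An event is the
    first frame of the first run of ``min_persist_frames`` consecutive
    qualifying frames; its representative contact map is the time-average
    over that window, binarized at 0.5.  Each unordered pair yields at most
    one event (association is treated as irreversible).
    """
    if min_residues < 1:
        raise ValueError("min_residues must be >= 1")
    n_prot = len(traj.topologies)
    if n_prot < 2:
        return [], []
    # pre-filter pairs by centroid distance to avoid n_res² work everywhere
    centroids = np.stack(
        [traj.positions[:, top.bead_indices, :].mean(axis=1) for top in traj.topologies], axis=1
    )  # (n_frames, n_prot, 3)
    radius = max(
        float(np.linalg.norm(traj.positions[0, top.bead_indices, :2] - centroids[0, p, :2], axis=1).max())
        for p, top in enumerate(traj.topologies)
    )
    reach = (2 * radius + cutoff) * prefilter_margin

    events: list[DimerEvent] = []
    maps: list[ContactMap] = []
    done: set[tuple[int, int]] = set()
    streak: dict[tuple[int, int], tuple[int, np.ndarray]] = {}  # pair -> (start_frame, map sum)
    for f in range(traj.n_frames):
        d = minimum_image_displacement(
            centroids[f, :, None, :2], centroids[f, None, :, :2], traj.box[f, :2]
        )
        cdist = np.hypot(d[..., 0], d[..., 1])
        for i in range(n_prot):
            for j in range(i + 1, n_prot):
                pair = (i, j)
                if pair in done:
                    continue
                qualifies = False
                m = None
                if cdist[i, j] < reach:
                    m = _pair_contact_matrix(traj, f, i, j, cutoff)
                    qualifies = (
                        int((m.any(axis=1)).sum()) >= min_residues
                        and int((m.any(axis=0)).sum()) >= min_residues
                    )
                if qualifies:
                    if pair in streak:
                        start, acc = streak[pair]
                        acc = acc + m
                    else:
                        start, acc = f, m.astype(float)
                    if f - start + 1 >= min_persist_frames:
                        rep = (acc / (f - start + 1) >= 0.5).astype(np.uint8)
                        oid = len(maps)
                        events.append(DimerEvent(trajectory_id, traj.times[start], pair))
                        maps.append(ContactMap(rep, pair, oid, traj.times[start]))
                        done.add(pair)
                        streak.pop(pair, None)
                    else:
                        streak[pair] = (start, acc)
                else:
                    streak.pop(pair, None)
    return events, maps


def interface_dissimilarity(k1: ContactMap | np.ndarray, k2: ContactMap | np.ndarray, homodimer: bool = False) -> float:
    """Frobenius distance between contact maps.

    In homodimer mode the minimum over the identity and protomer-swap
    (transpose) orientations is returned, reflecting the equivalence of a
    homodimer under exchange of its protomers.
    """
    m1 = k1.matrix if isinstance(k1, ContactMap) else np.asarray(k1)
    m2 = k2.matrix if isinstance(k2, ContactMap) else np.asarray(k2)
    if m1.shape != m2.shape and not (homodimer and m1.shape == m2.T.shape):
        raise ValueError("dimension mismatch")
    d_id = np.inf
    if m1.shape == m2.shape:
        d_id = float(np.linalg.norm(m1.astype(float) - m2.astype(float)))
    if not homodimer:
        return d_id
    d_sw = np.inf
    if m1.shape == m2.T.shape:
        d_sw = float(np.linalg.norm(m1.astype(float) - m2.T.astype(float)))
    return min(d_id, d_sw)


def _farthest_point_seeds(X: np.ndarray, k: int, homodimer: bool, rng: np.random.Generator) -> list[int]:
    """Deterministic farthest-point seeding; first seed drawn from rng."""
    n = X.shape[0]
    seeds = [int(rng.integers(n))]
    d_min = np.full(n, np.inf)
    while len(seeds) < k:
        last = X[seeds[-1]]
        for i in range(n):
            d = _member_distance(X[i], last, homodimer)[0]
            if d < d_min[i]:
                d_min[i] = d
        masked = d_min.copy()
        masked[seeds] = -np.inf
        seeds.append(int(np.argmax(masked)))
    return seeds


def _member_distance(m: np.ndarray, centroid: np.ndarray, homodimer: bool) -> tuple[float, bool]:
    """Distance of a map to a (real-valued) centroid; returns (d, swapped)."""
    d_id = float(np.linalg.norm(m - centroid))
    if not homodimer or m.shape != m.T.shape:
        return d_id, False
    d_sw = float(np.linalg.norm(m.T - centroid))
    if d_sw < d_id:  # ties broken toward the identity orientation
        return d_sw, True
    return d_id, False


def cluster_interfaces(
    maps: Sequence[ContactMap],
    k: int,
    homodimer: bool = False,
    seed: int = 0,
    max_iter: int = 200,
    objective_history: list[float] | None = None,
) -> tuple[list[InterfaceCluster], list[int]]:
    """Symmetrized k-means over contact maps under the Frobenius distance.

    Centroids are real-valued maps.  In homodimer mode every member enters
    assignment and centroid update in its distance-minimizing orientation
    (identity vs transpose), ties toward identity.  Initialization is
    farthest-point seeding from ``seed``.  Returns the clusters and the
    per-map cluster assignment.  ``objective_history``, if given, collects
    the within-cluster sum of squares after each assignment step.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(maps):
        raise ValueError("k exceeds the number of maps")
    X = np.stack([m.matrix.astype(float) for m in maps])
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    centroids = [X[i].copy() for i in _farthest_point_seeds(X, k, homodimer, rng)]
    assign = np.full(n, -1)
    swapped = np.zeros(n, dtype=bool)
    prev_obj = np.inf
    for _ in range(max_iter):
        # assignment step
        new_assign = np.empty(n, dtype=int)
        obj = 0.0
        for i in range(n):
            best = (np.inf, -1, False)
            for c, cen in enumerate(centroids):
                d, sw = _member_distance(X[i], cen, homodimer)
                if d < best[0]:
                    best = (d, c, sw)
            new_assign[i] = best[1]
            swapped[i] = best[2]
            obj += best[0] ** 2
        if objective_history is not None:
            objective_history.append(obj)
        if np.array_equal(new_assign, assign) or obj >= prev_obj - 1e-12:
            assign = new_assign
            break
        assign = new_assign
        prev_obj = obj
        # update step: members enter in their chosen orientation
        for c in range(k):
            idx = np.nonzero(assign == c)[0]
            if len(idx) == 0:
                continue
            stack = np.stack([X[i].T if swapped[i] else X[i] for i in idx])
            centroids[c] = stack.mean(axis=0)

    out: list[InterfaceCluster] = []
    remap: dict[int, int] = {}
    for c in range(k):
        idx = np.nonzero(assign == c)[0]
        if len(idx) == 0:
            continue
        stack = np.stack([X[i].T if swapped[i] else X[i] for i in idx])
        # marginal profile: per-residue fraction of members with >=1 contact
        out.append(
            InterfaceCluster(
                cluster_id=len(out),
                members=[maps[i].observation_id for i in idx],
                centroid=stack.mean(axis=0),
                marginal_a=stack.max(axis=2).mean(axis=0),
                marginal_b=stack.max(axis=1).mean(axis=0),
            )
        )
        remap[c] = out[-1].cluster_id
    assignment = [remap.get(int(a), -1) for a in assign]
    return out, assignment


def format_interface_label(helices_a: set[str], helices_b: set[str], homodimer: bool = False) -> str:
    """Render helix sets as ``"TM1,2/TM4,5"`` style labels.

    TM helices are merged into one comma-joined token (``TM1,2``); H8 is
    appended after the TMs.  In homodimer mode the two sides are put in a
    canonical (sorted) order so swap-equivalent labels compare equal.
    """

    def side(hs: set[str]) -> str:
        tms = sorted(int(h[2:]) for h in hs if h.startswith("TM"))
        parts = []
        if tms:
            parts.append("TM" + ",".join(str(t) for t in tms))
        if "H8" in hs:
            parts.append("H8")
        return ",".join(parts) if parts else "-"

    a, b = side(helices_a), side(helices_b)
    if homodimer and b < a:
        a, b = b, a
    return f"{a}/{b}"


def label_cluster(
    cluster: InterfaceCluster,
    tm_map_a: Mapping[int, str],
    tm_map_b: Mapping[int, str] | None = None,
    min_involved: int = 3,
    involvement_threshold: float = 0.5,
    homodimer: bool = False,
) -> str:
    """Label a cluster by the helices with ≥ ``min_involved`` involved residues.

    A residue is *involved* on a side when its marginal contact frequency
    δ(C) exceeds ``involvement_threshold`` (a majority of cluster members by
    default).  ``tm_map_a``/``tm_map_b`` map residue positions (array index
    into the marginal) to helix names.
    """
    if cluster.n_members < 1:
        raise ValueError("empty cluster")
    if min_involved < 1:
        raise ValueError("min_involved must be >= 1")
    tm_map_b = tm_map_b if tm_map_b is not None else tm_map_a

    def involved_helices(marginal: np.ndarray, tm_map: Mapping[int, str]) -> set[str]:
        counts: dict[str, int] = {}
        for r, val in enumerate(marginal):
            if val > involvement_threshold:
                h = tm_map.get(r, "loop")
                if h != "loop":
                    counts[h] = counts.get(h, 0) + 1
        return {h for h, c in counts.items() if c >= min_involved}

    return format_interface_label(
        involved_helices(cluster.marginal_a, tm_map_a),
        involved_helices(cluster.marginal_b, tm_map_b),
        homodimer=homodimer,
    )


def merge_clusters_by_label(
    clusters: list[InterfaceCluster], assignment: Sequence[int]
) -> tuple[list[InterfaceCluster], list[int]]:
    """Merge clusters that received identical labels (post-hoc)."""
    by_label: dict[str, InterfaceCluster] = {}
    remap: dict[int, int] = {}
    out: list[InterfaceCluster] = []
    for cl in clusters:
        key = cl.label if cl.label is not None else f"#{cl.cluster_id}"
        if key in by_label:
            tgt = by_label[key]
            w1, w2 = tgt.n_members, cl.n_members
            tgt.marginal_a = (tgt.marginal_a * w1 + cl.marginal_a * w2) / (w1 + w2)
            tgt.marginal_b = (tgt.marginal_b * w1 + cl.marginal_b * w2) / (w1 + w2)
            tgt.centroid = (tgt.centroid * w1 + cl.centroid * w2) / (w1 + w2)
            tgt.members.extend(cl.members)
            remap[cl.cluster_id] = tgt.cluster_id
        else:
            new = replace(cl, cluster_id=len(out), members=list(cl.members))
            by_label[key] = new
            remap[cl.cluster_id] = new.cluster_id
            out.append(new)
    return out, [remap.get(a, -1) for a in assignment]


def auto_cluster(
    maps: Sequence[ContactMap],
    tm_map_a: Mapping[int, str],
    tm_map_b: Mapping[int, str] | None = None,
    homodimer: bool = False,
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 12,
    min_involved: int = 3,
    involvement_threshold: float = 0.5,
) -> tuple[list[InterfaceCluster], list[int]]:
    """Cluster with automatic k: smallest k whose label set is stable at k+1.

    Scans k from ``k_min`` to ``k_max`` (capped at the number of maps),
    labels clusters, merges duplicate labels, and picks the smallest k whose
    merged label set equals that of k+1.  Falls back to the largest k tried.
    """
    k_hi = min(k_max, len(maps))
    k_lo = min(k_min, k_hi)
    results = {}
    labelsets = {}
    for k in range(k_lo, k_hi + 1):
        clusters, assign = cluster_interfaces(maps, k, homodimer=homodimer, seed=seed)
        for cl in clusters:
            cl.label = label_cluster(
                cl, tm_map_a, tm_map_b, min_involved, involvement_threshold, homodimer=homodimer
            )
        clusters, assign = merge_clusters_by_label(clusters, assign)
        results[k] = (clusters, assign)
        labelsets[k] = frozenset(cl.label for cl in clusters)
    for k in range(k_lo, k_hi):
        if labelsets[k] == labelsets[k + 1]:
            return results[k]
    return results[k_hi]


def events_to_frame(events: Sequence[DimerEvent]) -> pd.DataFrame:
    """Events as a tidy table (trajectory, time, pair, cluster, label)."""
    return pd.DataFrame(
        {
            "trajectory": [e.trajectory_id for e in events],
            "time_ns": [e.time for e in events],
            "protomer_a": [e.pair[0] for e in events],
            "protomer_b": [e.pair[1] for e in events],
            "cluster": [e.cluster for e in events],
            "label": [e.label for e in events],
        }
    )


def crystal_rmsd(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    crystal: CrystalDimer,
    heterodimer: bool = False,
) -> float:
    """Minimum backbone RMSD of a simulated dimer against a crystal dimer.

    Each simulated protomer is superposed independently onto its assigned
    crystal chain (ignoring internal monomer deformation); the transform
    from one protomer is then applied to the whole simulated dimer and the
    overall RMSD against the crystal is computed.  The reported value is the
    minimum over the anchoring protomer and — for homodimers — over the two
    chain assignments.
    """
    sim_a = np.asarray(sim_a, dtype=float)
    sim_b = np.asarray(sim_b, dtype=float)
    assignments = [((sim_a, crystal.chain_a), (sim_b, crystal.chain_b))]
    if not heterodimer:
        assignments.append(((sim_a, crystal.chain_b), (sim_b, crystal.chain_a)))
    best = np.inf
    for (s1, c1), (s2, c2) in assignments:
        if s1.shape != c1.shape or s2.shape != c2.shape:
            raise ValueError("no residue correspondence: chain lengths differ")
        for anchor_sim, anchor_cry in ((s1, c1), (s2, c2)):
            R, t, _ = align_to_reference(anchor_sim, anchor_cry)
            moved1 = s1 @ R.T + t
            moved2 = s2 @ R.T + t
            sq = np.concatenate(
                [np.sum((moved1 - c1) ** 2, axis=1), np.sum((moved2 - c2) ** 2, axis=1)]
            )
            best = min(best, float(np.sqrt(sq.mean())))
    return best


def load_crystal_dimer(
    pdb_path: str | Path,
    chain_ids: tuple[str, str],
    name: str | None = None,
    selection: str = "name CA",
) -> CrystalDimer:
    """Read two chains of backbone coordinates from a PDB file."""
    import MDAnalysis as mda  # deferred: heavy import

    u = mda.Universe(str(pdb_path))
    a = u.select_atoms(f"({selection}) and chainID {chain_ids[0]}").positions.copy()
    b = u.select_atoms(f"({selection}) and chainID {chain_ids[1]}").positions.copy()
    return CrystalDimer(name or Path(pdb_path).stem, a, b)
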