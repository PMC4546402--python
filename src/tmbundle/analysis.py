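"""Ensemble analysis: RMSD clustering, arrangement classification, distances.

Conformations are compared by C-alpha RMSD *without* superposition: the
membrane frame is physically fixed and the in-plane arrangement of the
helices is exactly what distinguishes conformations, so removing the
global rigid-body fit would erase the signal being clustered.  (An
optional superposed RMSD is available behind a flag.)

Clustering is agglomerative with complete linkage, cut at a height h:
this guarantees that no two members of a cluster differ by more than h
in RMSD.  Each cluster is represented by its centroid, the member with
the smallest summed RMSD to its co-members.

Arrangement types: viewed from the extracellular side (+z looking
down), the four helices (A = first helix, B = second, ...) are read
clockwise around their common centroid starting at A; the six distinct
cyclic orders are the arrangement labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, ClusterMixin

from .geometry import Ensemble, HelixSpec, principal_axis

UNCLASSIFIABLE = "unclassifiable"

#: Above this ensemble size exact hierarchical clustering is preceded by a
#: greedy leader pre-clustering pass at cutoff/2 (memory scales as n^2).
EXACT_CLUSTERING_LIMIT = 20_000


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def pairwise_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                  superpose: bool = False) -> float:
    """C-alpha RMSD between two equally-sized coordinate arrays (Angstrom).

    By default no superposition is applied (fixed membrane frame).  With
    ``superpose=True`` the optimal rigid superposition (Kabsch) is
    removed first.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a, b)
        b = rot.apply(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_matrix(coords: np.ndarray, superpose: bool = False) -> np.ndarray:
    """Condensed pairwise RMSD matrix over an (n, m, 3) coordinate stack."""
    coords = np.asarray(coords, float)
    n, m, _ = coords.shape
    if not superpose:
        return pdist(coords.reshape(n, -1)) / np.sqrt(m)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = pairwise_rmsd(coords[i], coords[j], superpose=True)
            k += 1
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteredEnsemble:
    """Result of cutting a complete-linkage RMSD dendrogram at ``cutoff``."""

    labels: np.ndarray  # cluster id per member, 0-based
    centroid_indices: np.ndarray  # member index of each cluster's centroid
    cutoff: float
    centroid_scores: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_indices)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


class RmsdClustering(ClusterMixin, BaseEstimator):
    """Complete-linkage hierarchical clustering on pairwise C-alpha RMSD.

    sklearn-style estimator: ``fit(X)`` takes an (n, m, 3) coordinate
    stack (or an :class:`~tmbundle.geometry.Ensemble`) and sets
    ``labels_``, ``centroid_indices_`` and ``n_clusters_``.  Above
    ``exact_limit`` members, a greedy leader pass at ``cutoff/2``
    pre-groups near-duplicates before the exact hierarchical step.
    """

    def __init__(self, cutoff: float = 2.0, superpose: bool = False,
                 exact_limit: int = EXACT_CLUSTERING_LIMIT):
        self.cutoff = cutoff
        self.superpose = superpose
        self.exact_limit = exact_limit

    def fit(self, X, y=None):
        coords = X.coords if isinstance(X, Ensemble) else np.asarray(X, float)
        if len(coords) == 0:
            raise ValueError("cannot cluster an empty ensemble")
        if len(coords) == 1:
            self.labels_ = np.zeros(1, dtype=int)
        elif len(coords) <= self.exact_limit:
            self.labels_ = self._exact_labels(coords)
        else:
            self.labels_ = self._two_stage_labels(coords)
        self.centroid_indices_ = _centroids(coords, self.labels_, self.superpose)
        self.n_clusters_ = len(self.centroid_indices_)
        return self

    def _exact_labels(self, coords):
        condensed = rmsd_matrix(coords, superpose=self.superpose)
        merge_tree = linkage(condensed, method="complete")
        return fcluster(merge_tree, t=self.cutoff, criterion="distance") - 1

    def _two_stage_labels(self, coords):
        # Greedy leader pass: assign each member to the first leader within
        # cutoff/2, then cluster the leaders hierarchically and combine.
        half = self.cutoff / 2.0
        leaders: list[int] = []
        assign = np.empty(len(coords), dtype=int)
        for i in range(len(coords)):
            for k, lead in enumerate(leaders):
                if pairwise_rmsd(coords[i], coords[lead], self.superpose) <= half:
                    assign[i] = k
                    break
            else:
                leaders.append(i)
                assign[i] = len(leaders) - 1
        leader_labels = self._exact_labels(coords[leaders]) \
            if len(leaders) > 1 else np.zeros(1, dtype=int)
        return leader_labels[assign]


def cluster(ensemble, cutoff: float = 2.0, superpose: bool = False) -> ClusteredEnsemble:
    """Cluster an ensemble at an RMSD cutoff (complete linkage).

    Returns cluster assignments and centroid representatives; when the
    ensemble carries scores, the centroids' scores are attached.
    """
    est = RmsdClustering(cutoff=cutoff, superpose=superpose).fit(ensemble)
    scores = None
    if isinstance(ensemble, Ensemble) and ensemble.scores is not None:
        scores = ensemble.scores[est.centroid_indices_]
    return ClusteredEnsemble(est.labels_, est.centroid_indices_, cutoff, scores)


def _centroids(coords, labels, superpose):
    """Per cluster, the member minimising summed RMSD to co-members
    (ties broken toward the lowest member index)."""
    out = []
    for cl in range(labels.max() + 1):
        members = np.flatnonzero(labels == cl)
        if len(members) == 1:
            out.append(members[0])
            continue
        sub = coords[members]
        d = squareform(rmsd_matrix(sub, superpose=superpose))
        out.append(members[int(np.argmin(d.sum(axis=1)))])
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Arrangement classification
# ---------------------------------------------------------------------------

def enumerate_arrangements(n_helices: int = 4) -> list:
    """All distinct clockwise cyclic orders starting at helix A."""
    letters = [chr(ord("A") + i) for i in range(n_helices)]
    return ["A" + "".join(p) for p in itertools.permutations(letters[1:])]


def classify_arrangement(midpoints_xy: np.ndarray, tol: float = 1e-6) -> str:
    """Arrangement label from in-plane helix midpoints (rows = A, B, C, D).

    Projects the helix midpoints onto the membrane plane, sorts them
    clockwise (as seen from +z, the extracellular side) around their
    centroid, and returns the cyclic order starting at A.  Degenerate
    geometry (coincident midpoints, or all midpoints collinear within
    tolerance) yields the explicit outcome ``"unclassifiable"``.
    """
    pts = np.asarray(midpoints_xy, float)[:, :2]
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) < tol:
                return UNCLASSIFIABLE
    centered = pts - pts.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[-1] < tol:
        return UNCLASSIFIABLE
    angles = np.arctan2(centered[:, 1], centered[:, 0])
    clockwise = np.argsort(-angles, kind="stable")
    order = list(clockwise)
    start = order.index(0)
    cyclic = order[start:] + order[:start]
    return "".join(chr(ord("A") + int(i)) for i in cyclic)


def classify_ensemble(ensemble: Ensemble, tol: float = 1e-6) -> np.ndarray:
    """Arrangement label per conformation of an ensemble."""
    mids = ensemble.midpoints()
    return np.array([classify_arrangement(m, tol=tol) for m in mids])


# ---------------------------------------------------------------------------
# Arrangement tables
# ---------------------------------------------------------------------------

@dataclass
class ArrangementTable:
    """Arrangement-type counts for all centroids and the top-K by score."""

    counts_all: dict
    counts_top: dict
    top_k: int

    def __post_init__(self):
        self.counts_all = dict(self.counts_all)
        self.counts_top = dict(self.counts_top)

    @property
    def n_total(self) -> int:
        return sum(self.counts_all.values())

    def top3_share_all(self) -> float:
        """Share (percent, 1 decimal) of the three most populated types."""
        return _top3_share(self.counts_all)

    def top3_share_top(self) -> float:
        return _top3_share(self.counts_top)

    def top3_count_top(self) -> int:
        """Members of the top-K ensemble in the three most populated types."""
        ranked = sorted(self.counts_top.values(), reverse=True)
        return int(sum(ranked[:3]))

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(self.counts_all, key=self.counts_all.get, reverse=True)
        return pd.DataFrame({
            "arrangement": labels,
            "count_all": [self.counts_all[l] for l in labels],
            f"count_top{self.top_k}": [self.counts_top.get(l, 0) for l in labels],
        })


def _top3_share(counts: dict) -> float:
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    ranked = sorted(counts.values(), reverse=True)
    return round(100.0 * sum(ranked[:3]) / total, 1)


def arrangement_table(labels: Sequence[str], scores: Sequence[float] | None = None,
                      top_k: int = 100) -> ArrangementTable:
    """Tabulate arrangement counts over all members and the top-K by score.

    Scores are energies: "top" means lowest.  When no scores are given
    the top-K column counts the first ``top_k`` members.
    """
    labels = np.asarray(labels)
    counts_all = {l: int(c) for l, c in zip(*np.unique(labels, return_counts=True))}
    if scores is not None:
        order = np.argsort(np.asarray(scores), kind="stable")
        top_labels = labels[order[:top_k]]
    else:
        top_labels = labels[:top_k]
    counts_top = {l: int(c) for l, c in zip(*np.unique(top_labels, return_counts=True))}
    return ArrangementTable(counts_all, counts_top, top_k)


# ---------------------------------------------------------------------------
# Distance statistics (proline kinks and N-termini)
# ---------------------------------------------------------------------------

def distance_stats(ensemble: Ensemble, labels: Sequence[str],
                   res_i: int = 85, helix_i: str = "TM2",
                   res_j: int = 231, helix_j: str = "TM3",
                   interval: tuple = (16.0, 20.0)) -> pd.DataFrame:
    """Per-arrangement distance statistics between two key residues.

    For each arrangement label: mean and SD of (i) the C-alpha distance
    between ``res_i`` (default Pro85 of TM2) and ``res_j`` (default
    Pro231 of TM3) and (ii) the distance between the two helices'
    N-terminal C-alphas, plus the fraction of conformations whose
    residue-residue distance falls inside ``interval``.
    """
    spec_map = {s.name: s for s in ensemble.specs}
    for name, res in ((helix_i, res_i), (helix_j, res_j)):
        if name not in spec_map:
            raise KeyError(f"helix {name} not in ensemble")
        spec_map[name].index_of(res)  # raises KeyError if absent
    sl = ensemble.slices
    ca_i = ensemble.coords[:, sl[helix_i]][:, spec_map[helix_i].index_of(res_i)]
    ca_j = ensemble.coords[:, sl[helix_j]][:, spec_map[helix_j].index_of(res_j)]
    res_d = np.linalg.norm(ca_i - ca_j, axis=1)

    # N-terminal C-alpha = first residue of each helix trace
    nt_i = ensemble.coords[:, sl[helix_i]][:, 0]
    nt_j = ensemble.coords[:, sl[helix_j]][:, 0]
    nt_d = np.linalg.norm(nt_i - nt_j, axis=1)

    labels = np.asarray(labels)
    rows = []
    for label in np.unique(labels):
        mask = labels == label
        lo, hi = interval
        inside = (res_d[mask] >= lo) & (res_d[mask] <= hi)
        rows.append({
            "arrangement": label,
            "n": int(mask.sum()),
            "res_pair_mean": float(res_d[mask].mean()),
            "res_pair_sd": float(res_d[mask].std(ddof=0)),
            "nterm_mean": float(nt_d[mask].mean()),
            "nterm_sd": float(nt_d[mask].std(ddof=0)),
            "frac_in_interval": float(inside.mean()),
        })
    return pd.DataFrame(rows).set_index("arrangement")


# ---------------------------------------------------------------------------
# Crossing angles
# ---------------------------------------------------------------------------

def crossing_angle(coords_i: np.ndarray, coords_j: np.ndarray) -> float:
    """Signed inter-helix crossing angle in degrees, range (-90, 90].

    Helix axes are fitted by principal components; axes are unsigned
    lines, so the angle is folded into (-90, 90] (an antiparallel
    untilted pair has crossing angle 0).  The sign is the handedness of
    the rotation from axis i to axis j about the line connecting the
    two helix midpoints (right-handed positive).
    """
    u = principal_axis(coords_i)
    v = principal_axis(coords_j)
    if u @ v < 0:
        v = -v
    cosang = np.clip(u @ v, -1.0, 1.0)
    magnitude = float(np.degrees(np.arccos(cosang)))
    if magnitude > 90.0:
        magnitude = 180.0 - magnitude
    connect = np.asarray(coords_j, float).mean(axis=0) - np.asarray(coords_i, float).mean(axis=0)
    norm = np.linalg.norm(connect)
    if norm < 1e-12 or magnitude < 1e-12:
        return 0.0 if magnitude < 1e-12 else magnitude
    sign = np.sign(np.cross(u, v) @ (connect / norm))
    if sign == 0:
        sign = 1.0
    return float(sign * magnitude)


def crossing_angle_filter(ensemble: Ensemble, max_abs_deg: float = 40.0,
                          pairs: Sequence[tuple] | None = None) -> np.ndarray:
    """Boolean mask of conformations whose helix-pair crossing angles are
    all within ``|angle| <= max_abs_deg``.

    ``pairs`` defaults to all helix pairs.  Applied as a hard filter at
    analysis time.
    """
    names = [s.name for s in ensemble.specs]
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    sl = ensemble.slices
    mask = np.ones(len(ensemble), dtype=bool)
    for k in range(len(ensemble)):
        for a, b in pairs:
            ang = crossing_angle(ensemble.coords[k, sl[a]], ensemble.coords[k, sl[b]])
            if abs(ang) > max_abs_deg:
                mask[k] = False
                break
    return mask
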