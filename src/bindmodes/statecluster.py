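"""Binding-mode clustering: features -> PCA -> K-means++ -> k selection.

The pipeline identifies recurring ligand binding arrangements in an MD
trajectory:

1. :func:`build_features` assembles a frames x descriptors matrix from
   ligand-residue center-of-mass distances plus three RMSD families
   (protein backbone, ligand, interacting residues), each column
   standardized to zero mean / unit standard deviation (population n
   denominator; constant columns are dropped with a warning).
2. :func:`pca_reduce` keeps the minimal number of principal components
   whose cumulative explained variance reaches the configured fraction
   (default 0.90).
3. :func:`kscan` runs K-means++ for k = 2..10 (best of ``n_init``
   restarts by within-cluster sum of squares) and scores every k with four
   internal validation indices: mean silhouette (SI), Dunn index (DI),
   Calinski-Harabasz pseudo-F (pSF) and the within sum of squares (WSS).
4. :func:`select_k` lets SI, DI and pSF vote for their argmax and WSS for
   its elbow (largest positive second difference); a k with at least 3 of
   the 4 votes wins.  If no k reaches 3 votes, the k with the most votes
   wins, ties broken toward smaller k (parsimony).
5. :func:`fit_model` produces per-frame labels, cluster weights W% (the
   percentage of frames per cluster, reported descending) and the centroid
   frame of each cluster: the sampled frame nearest (Euclidean, in reduced
   space) to the cluster mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .geometry import com_distance_series, rmsd_series
from .trajio import Trajectory, resolve_selection


class ClusterError(ValueError):
    """Raised for unusable clustering input."""


@dataclass
class FeatureMatrix:
    """Standardized frames x descriptors matrix with column provenance."""

    data: np.ndarray  # (n_frames, n_columns), standardized
    columns: list  # descriptor labels, e.g. "dist:ligand-Y473"
    means: np.ndarray  # raw per-column means
    sds: np.ndarray  # raw per-column population standard deviations
    dropped: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ReducedMatrix:
    """PCA scores retaining a target fraction of total variance."""

    scores: np.ndarray  # (n_frames, n_components)
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_fraction: float


@dataclass
class KScanTable:
    """Validation indices per candidate cluster count."""

    ks: np.ndarray
    si: np.ndarray
    di: np.ndarray
    psf: np.ndarray
    wss: np.ndarray
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "SI": self.si, "DI": self.di,
                             "pSF": self.psf, "WSS": self.wss})


@dataclass
class ClusterModel:
    """Fitted binding-mode model: labels, weights, centroid frames."""

    k: int
    labels: np.ndarray  # per sampled frame, relabeled by descending size
    weights: np.ndarray  # unrounded fractions, descending, sum 1
    w_percent: np.ndarray  # rounded integer W% per cluster, descending
    centroid_frames: np.ndarray  # frame index per cluster
    scan: KScanTable | None = None

    def summary(self) -> dict:
        return {
            "k": int(self.k),
            "w_percent": [int(w) for w in self.w_percent],
            "weights": [float(w) for w in self.weights],
            "centroid_frames": [int(c) for c in self.centroid_frames],
            "n_frames": int(len(self.labels)),
        }


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def standardize(raw: np.ndarray, columns: list) -> FeatureMatrix:
    """Zero-mean / unit-sd columns (population denominator).

    Constant columns carry no clustering information and would divide by
    zero; they are dropped and recorded.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ClusterError("feature matrix must be 2-D")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population (n) denominator
    keep = sds > 1e-12
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant feature column(s): {dropped}",
                      stacklevel=2)
    if not keep.any():
        raise ClusterError("all feature columns are constant; nothing to cluster")
    data = (raw[:, keep] - means[keep]) / sds[keep]
    return FeatureMatrix(
        data=data,
        columns=[c for c, k in zip(columns, keep) if k],
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )


def build_features(
    traj: Trajectory,
    ligand_selection: str = "ligand",
    distance_residues: list[int] | None = None,
    interacting_residues: list[int] | None = None,
    reference_frame: int = 0,
    backbone_selection: str = "backbone",
) -> FeatureMatrix:
    """Assemble the standardized descriptor matrix for mode clustering.

    Columns: one ligand-COM-to-residue-COM distance per residue in
    ``distance_residues``, plus backbone RMSD, ligand RMSD (fit on the
    backbone, measured without re-fitting) and the RMSD of the named
    ``interacting_residues`` — all relative to ``reference_frame`` (the
    initial frame by default).
    """
    distance_residues = distance_residues or []
    interacting_residues = interacting_residues or []
    columns: list[str] = []
    raw_cols: list[np.ndarray] = []
    lig = resolve_selection(traj, ligand_selection)
    for resid in distance_residues:
        res_sel = resolve_selection(traj, f"resid {resid}")
        series = com_distance_series(traj, lig, res_sel)
        columns.append(f"dist:ligand-resid{resid}")
        raw_cols.append(series.values)
    backbone = resolve_selection(traj, backbone_selection)
    raw_cols.append(rmsd_series(traj, backbone,
                                reference_frame=reference_frame).values)
    columns.append("rmsd:backbone")
    raw_cols.append(rmsd_series(traj, backbone, lig,
                                reference_frame=reference_frame).values)
    columns.append("rmsd:ligand")
    if interacting_residues:
        expr = "resid " + " ".join(str(r) for r in interacting_residues)
        inter = resolve_selection(traj, expr)
        raw_cols.append(rmsd_series(traj, backbone, inter,
                                    reference_frame=reference_frame).values)
        columns.append("rmsd:interacting")
    return standardize(np.column_stack(raw_cols), columns)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_reduce(fm: FeatureMatrix, variance_fraction: float = 0.90) -> ReducedMatrix:
    """Keep the minimal number of components reaching the variance target.

    The sign convention is fixed so each component's largest-magnitude
    loading is positive, making scores reproducible across runs.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ClusterError("variance fraction must be in (0, 1]")
    if fm.n_frames < 2:
        raise ClusterError("PCA needs at least 2 frames")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(fm.data)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_comp = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    n_comp = min(n_comp, len(evr))
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_comp):
        loading = pca.components_[j]
        lead = np.argmax(np.abs(loading))
        if loading[lead] < 0:
            scores[:, j] *= -1.0
    return ReducedMatrix(
        scores=scores[:, :n_comp],
        explained_variance_ratio=evr[:n_comp],
        n_components=n_comp,
        variance_fraction=variance_fraction,
    )


# ---------------------------------------------------------------------------
# Validation indices
# ---------------------------------------------------------------------------

def dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster point distance / max intra-cluster diameter."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusterError("Dunn index needs at least 2 clusters")
    from scipy.spatial.distance import cdist, pdist

    max_diam = 0.0
    for c in uniq:
        pts = x[labels == c]
        if len(pts) > 1:
            max_diam = max(max_diam, float(pdist(pts).max()))
    min_inter = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            min_inter = min(min_inter, float(cdist(x[labels == a], x[labels == b]).min()))
    if max_diam == 0.0:
        return np.inf
    return min_inter / max_diam


def wss(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Within-cluster sum of squared distances to assigned centroids."""
    return float(np.sum((x - centers[labels]) ** 2))


def _best_kmeans(x: np.ndarray, k: int, n_init: int, seed: int | None) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed)
    km.fit(x)
    return km


def kscan(
    rm: ReducedMatrix,
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 10,
    seed: int | None = 0,
) -> KScanTable:
    """Score K-means++ solutions for every k in [k_min, k_max]."""
    x = rm.scores
    n = len(x)
    if k_max > n:
        raise ClusterError(f"k_max={k_max} exceeds the {n} sampled frames")
    ks, si_v, di_v, psf_v, wss_v = [], [], [], [], []
    for k in range(k_min, k_max + 1):
        km = _best_kmeans(x, k, n_init, seed)
        labels = km.labels_
        ks.append(k)
        if len(np.unique(labels)) < 2 or k >= n:
            si_v.append(np.nan)
            psf_v.append(np.nan)
            di_v.append(np.nan)
        else:
            si_v.append(float(silhouette_score(x, labels)))
            psf_v.append(float(calinski_harabasz_score(x, labels)))
            di_v.append(dunn_index(x, labels))
        wss_v.append(wss(x, labels, km.cluster_centers_))
    return KScanTable(ks=np.array(ks), si=np.array(si_v), di=np.array(di_v),
                      psf=np.array(psf_v), wss=np.array(wss_v), seed=seed)


def wss_elbow(ks: np.ndarray, wss_values: np.ndarray) -> int:
    """Elbow k: the largest positive second difference of WSS vs k.

    With fewer than 3 scanned k values there is no curvature to measure;
    the smallest k is returned.
    """
    if len(ks) < 3:
        return int(ks[0])
    second = wss_values[:-2] - 2 * wss_values[1:-1] + wss_values[2:]
    return int(ks[1:-1][int(np.argmax(second))])


def select_k(scan: KScanTable) -> tuple[int, dict]:
    """Choose k by 3-of-4 convergence of the validation criteria.

    SI, DI and pSF each vote for their argmax k; WSS votes for the elbow.
    Any k with >= 3 votes wins; otherwise the k with the most votes,
    ties broken toward smaller k.  Returns ``(k, votes)`` where ``votes``
    maps each criterion name to the k it voted for.
    """
    if len(scan.ks) < 2:
        raise ClusterError("k selection needs a scan over at least 2 values of k")
    votes = {
        "SI": int(scan.ks[int(np.nanargmax(scan.si))]),
        "DI": int(scan.ks[int(np.nanargmax(scan.di))]),
        "pSF": int(scan.ks[int(np.nanargmax(scan.psf))]),
        "WSS": wss_elbow(scan.ks, scan.wss),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best_count = max(counts.values())
    candidates = sorted(k for k, c in counts.items() if c == best_count)
    if best_count >= 3:
        return candidates[0], votes
    # fallback: most votes, ties toward smaller k (parsimony)
    return candidates[0], votes


def fit_model(
    rm: ReducedMatrix,
    k: int,
    n_init: int = 10,
    seed: int | None = 0,
    scan: KScanTable | None = None,
) -> ClusterModel:
    """Fit the final model at the chosen k and derive weights + centroids.

    Clusters are relabeled by descending population so cluster 0 is always
    the most populated mode.  W% is the rounded percentage of frames per
    cluster; the exact fractions are kept for downstream energy weighting.
    """
    x = rm.scores
    for attempt in range(5):
        km = _best_kmeans(x, k, n_init, None if seed is None else seed + attempt)
        sizes = np.bincount(km.labels_, minlength=k)
        if sizes.min() > 0:
            break
        warnings.warn(f"empty cluster at k={k}; refitting with a new init",
                      stacklevel=2)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    new_labels = relabel[labels]
    fractions = sizes[order] / len(labels)
    centroid_frames = np.empty(k, dtype=int)
    for new_c, old_c in enumerate(order):
        mean = km.cluster_centers_[old_c]
        members = np.flatnonzero(labels == old_c)
        d2 = np.sum((x[members] - mean) ** 2, axis=1)
        centroid_frames[new_c] = members[int(np.argmin(d2))]
    return ClusterModel(
        k=k,
        labels=new_labels,
        weights=fractions,
        w_percent=np.rint(100.0 * fractions).astype(int),
        centroid_frames=centroid_frames,
        scan=scan,
    )


def cluster_pipeline(
    fm: FeatureMatrix,
    variance_fraction: float = 0.90,
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 10,
    seed: int | None = 0,
) -> ClusterModel:
    """features -> PCA -> k scan -> k vote -> fitted model, in one call."""
    rm = pca_reduce(fm, variance_fraction)
    scan = kscan(rm, k_min=k_min, k_max=min(k_max, fm.n_frames - 1),
                 n_init=n_init, seed=seed)
    k, _ = select_k(scan)
    return fit_model(rm, k, n_init=n_init, seed=seed, scan=scan)
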