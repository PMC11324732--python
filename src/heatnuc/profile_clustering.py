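"""Profile clustering of unassigned DAPs and mapping to "like" groups.

Proteins that the decision table leaves UNASSIGNED are clustered on
their condition profiles with Pearson correlation distance and complete
linkage; the number of clusters is chosen with the gap statistic, and
each cluster is mapped to a like-group (ELG, LLG, TLG, RLG or CG) by
similarity of its centroid to canonical profile templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quant_io import CONDITION_ORDER, AbundanceMatrix, SampleDesign

__all__ = [
    "condition_profiles",
    "log2fc_profiles",
    "pearson_distance",
    "Dendrogram",
    "complete_linkage",
    "cut_dendrogram",
    "GapStatisticResult",
    "gap_statistic",
    "TEMPLATES",
    "TEMPLATE_FAMILY",
    "assign_like_groups",
    "cluster_unassigned",
]

#: Canonical 4-condition templates (T22, H4, H24, R22) for like-group mapping.
TEMPLATES: dict[str, np.ndarray] = {
    "early": np.array([0.0, 1.0, 1.0, 0.0]),
    "early_persistent": np.array([0.0, 1.0, 1.0, 1.0]),
    "late": np.array([0.0, 0.0, 1.0, 0.0]),
    "late_persistent": np.array([0.0, 0.0, 1.0, 1.0]),
    "transient": np.array([0.0, 1.0, 0.0, 0.0]),
    "recovery": np.array([0.0, 0.0, 0.0, 1.0]),
    "continuous": np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0]),
}

TEMPLATE_FAMILY: dict[str, str] = {
    "early": "ELG",
    "early_persistent": "ELG",
    "late": "LLG",
    "late_persistent": "LLG",
    "transient": "TLG",
    "recovery": "RLG",
    "continuous": "CG",
}


def condition_profiles(
    m: AbundanceMatrix, design: SampleDesign, zscore: bool = True
) -> pd.DataFrame:
    """Per-protein 4-condition mean log2 abundance, z-standardized by row.

    Constant rows become all-zero; they are flagged via the returned
    frame's ``attrs['constant']`` list and excluded by the distance step.
    """
    if m.scale != "log2":
        raise ValueError("profiles require a log2 matrix")
    cols = {}
    for c in CONDITION_ORDER:
        ids = [s for s in design.samples_for(c) if s in m.data.columns]
        if not ids:
            raise ValueError(f"no samples for condition {c.value}")
        cols[c.value] = m.data[ids].mean(axis=1, skipna=True)
    prof = pd.DataFrame(cols)
    if zscore:
        mu = prof.mean(axis=1)
        sd = prof.std(axis=1, ddof=0)
        constant = sd == 0
        sd = sd.replace(0.0, 1.0)
        prof = prof.sub(mu, axis=0).div(sd, axis=0)
        prof.attrs["constant"] = list(prof.index[constant])
    else:
        prof.attrs["constant"] = []
    return prof


def log2fc_profiles(ct: pd.DataFrame) -> pd.DataFrame:
    """Alternative clustering space: the 6-vector of log2FC values C1..C6."""
    wide = ct.pivot(index="accession", columns="contrast", values="log2fc")
    wide.attrs["constant"] = list(wide.index[wide.std(axis=1, ddof=0) == 0])
    return wide


def pearson_distance(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """d(i,j) = 1 - Pearson r between profile rows; in [0, 2].

    Constant rows have undefined correlation; callers must exclude them
    first (:func:`condition_profiles` lists them in ``attrs``).
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two profiles")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant profile(s) at rows {bad.tolist()}; exclude first")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over n items."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    n: int

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.merges)


def complete_linkage(dist: np.ndarray) -> Dendrogram:
    """Complete-linkage agglomeration of a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    condensed = squareform(dist, checks=False)
    merges = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(merges=merges, n=dist.shape[0])


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Cut into k clusters; labels 1..k follow dendrogram leaf order."""
    if not (1 <= k <= dend.n):
        raise ValueError(f"k must be in [1, {dend.n}], got {k}")
    raw = hierarchy.fcluster(dend.merges, t=k, criterion="maxclust")
    # relabel so that cluster 1 is the first encountered in leaf order
    relabel: dict[int, int] = {}
    for leaf in dend.leaf_order():
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    return np.array([relabel[c] for c in raw], dtype=int)


def _within_dispersion(dist_sq: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (pairwise squared distances) / (2 n_r)."""
    w = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        block = dist_sq[np.ix_(idx, idx)]
        w += block.sum() / (2.0 * len(idx))
    return w


def _cluster_labels(x: np.ndarray, k: int) -> np.ndarray:
    d = pearson_distance(x)
    return cut_dendrogram(complete_linkage(d), k)


@dataclass
class GapStatisticResult:
    k_values: np.ndarray
    log_w: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    chosen_k: int
    B: int
    seed: int
    log_w_ref_mean: np.ndarray = field(default=None)  # type: ignore[assignment]


def gap_statistic(
    profiles: pd.DataFrame | np.ndarray,
    kmax: int = 12,
    B: int = 100,
    seed: int = 0,
) -> GapStatisticResult:
    """Gap statistic for the number of complete-linkage clusters.

    For each k the within-cluster dispersion W_k uses squared Pearson
    distances; B reference datasets are drawn uniformly over each
    feature's observed range.  Chosen k is the smallest with
    gap_k >= gap_{k+1} - se_{k+1} (first-SE-max rule).
    """
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    if kmax >= n:
        raise ValueError("kmax must be < number of profiles")
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, kmax + 1)

    def log_w_curve(data: np.ndarray) -> np.ndarray:
        d = pearson_distance(data)
        d_sq = d**2
        dend = complete_linkage(d)
        out = np.empty(len(ks))
        for i, k in enumerate(ks):
            labels = cut_dendrogram(dend, int(k))
            out[i] = np.log(max(_within_dispersion(d_sq, labels), 1e-300))
        return out

    log_w = log_w_curve(x)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1e-12)
    ref_curves = np.empty((B, len(ks)))
    for b in range(B):
        ref = lo + span * rng.random(size=x.shape)
        ref_curves[b] = log_w_curve(ref)
    ref_mean = ref_curves.mean(axis=0)
    gap = ref_mean - log_w
    sd = ref_curves.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / B)

    chosen = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            chosen = int(ks[i])
            break
    return GapStatisticResult(
        k_values=ks,
        log_w=log_w,
        gap=gap,
        se=se,
        chosen_k=chosen,
        B=B,
        seed=seed,
        log_w_ref_mean=ref_mean,
    )


def _is_monotone(v: np.ndarray) -> bool:
    dv = np.diff(v)
    return bool(np.all(dv >= 0) or np.all(dv <= 0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom)


def assign_like_groups(
    profiles: pd.DataFrame,
    labels: np.ndarray,
    tau: float = 0.8,
    templates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Map each cluster centroid to a like-group by template correlation.

    |r| is used so both orientations of a tendency match its template;
    centroids below ``tau`` that are monotone across conditions fall
    back to CG, otherwise they keep the best template's family with a
    ``low_confidence`` flag.
    """
    templates = templates or TEMPLATES
    rows = []
    for c in np.unique(labels):
        centroid = profiles.to_numpy()[labels == c].mean(axis=0)
        if np.ptp(centroid) == 0:
            raise ValueError(f"cluster {c} has a constant centroid")
        best_name, best_r = None, -np.inf
        for name, tmpl in templates.items():
            r = abs(_pearson(centroid, tmpl))
            if r > best_r:
                best_name, best_r = name, r
        family = TEMPLATE_FAMILY[best_name]
        low_conf = False
        if best_r < tau:
            if _is_monotone(centroid):
                family = "CG"
                best_name = "continuous"
            else:
                low_conf = True
        rows.append(
            {
                "cluster": int(c),
                "like_group": family,
                "best_template": best_name,
                "template_r": best_r,
                "low_confidence": low_conf,
                "size": int((labels == c).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("cluster", ignore_index=True)


def cluster_unassigned(
    profiles: pd.DataFrame,
    k: int | None = None,
    kmax: int = 12,
    B: int = 100,
    seed: int = 0,
    tau: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, GapStatisticResult | None]:
    """Distance -> linkage -> (gap-chosen) cut -> like-group assignment.

    Returns (per-protein cluster table, per-cluster like-group table,
    gap result or None when k was forced).  Constant profiles are
    excluded with a warning and reported with cluster 0.
    """
    constant = profiles.attrs.get("constant", [])
    work = profiles.drop(index=constant) if constant else profiles
    if constant:
        warnings.warn(f"excluded {len(constant)} constant profile(s) from clustering")
    if len(work) < 3:
        raise ValueError("need at least 3 non-constant profiles to cluster")
    gap_res = None
    if k is None:
        gap_res = gap_statistic(work, kmax=min(kmax, len(work) - 1), B=B, seed=seed)
        k = gap_res.chosen_k
    labels = _cluster_labels(work.to_numpy(dtype=float), int(k))
    members = pd.DataFrame({"accession": work.index, "cluster": labels})
    if constant:
        members = pd.concat(
            [members, pd.DataFrame({"accession": constant, "cluster": 0})],
            ignore_index=True,
        )
    like = assign_like_groups(work, labels, tau=tau)
    return members.sort_values("accession", ignore_index=True), like, gap_res
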