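"""Neighborhood-composition niche detection and cross-section alignment.

Each cell is summarized by the cell-type counts among its k nearest
neighbors; k-means on the (column-standardized) profiles yields niches per
section; niches are then matched across sections by Pearson correlation of
their cell-type compositions and average-linkage clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datatypes import SpatialCellMap


@dataclass
class NeighborhoodProfile:
    """Per-cell label counts among the k nearest neighbors (self excluded)."""

    section_id: str
    cell_ids: np.ndarray
    labels: np.ndarray  # each cell's own label
    catalog: List[str]
    counts: np.ndarray  # cells x len(catalog), rows sum to k
    k: int


def _knn_indices(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Deterministic k nearest neighbors, self excluded.

    Ties at the k-th distance break by cell index order (stable argsort on
    distance with index as implicit secondary key).  Brute force in chunks:
    exact, and cheap at section scale.
    """
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        for i in range(stop - start):
            d2[i, start + i] = np.inf  # exclude self
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        out[start:stop] = idx
    return out


def neighborhood_profiles(
    s: SpatialCellMap,
    k: int = 20,
    catalog: Optional[Sequence[str]] = None,
    restrict_labels: Optional[Sequence[str]] = None,
) -> NeighborhoodProfile:
    """Neighborhood label-count vector for every cell of one section.

    ``restrict_labels`` limits both the cells profiled and the neighbor
    pool to the given labels (supervised mode).
    """
    df = s.cells
    if restrict_labels is not None:
        df = df[df["label"].isin(set(restrict_labels))].reset_index(drop=True)
    labels = df["label"].to_numpy(dtype=object)
    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if catalog is None:
        catalog = sorted(pd.unique(labels))
    catalog = list(catalog)
    cat_idx = {c: i for i, c in enumerate(catalog)}
    nbr = _knn_indices(coords, k)
    lab_codes = np.array([cat_idx[l] for l in labels])
    counts = np.zeros((len(df), len(catalog)), dtype=np.int64)
    flat = lab_codes[nbr]  # cells x k
    for j in range(len(catalog)):
        counts[:, j] = (flat == j).sum(axis=1)
    return NeighborhoodProfile(
        section_id=s.section_id,
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        labels=labels,
        catalog=catalog,
        counts=counts,
        k=k,
    )


@dataclass
class NicheModel:
    """K-means niche assignment for one section."""

    section_id: str
    cell_ids: np.ndarray
    labels: np.ndarray  # member cells' own labels
    niche: np.ndarray  # 1..K per cell
    composition: pd.DataFrame  # niche x label proportions (member cells' own labels)
    K: int
    k: int
    seed: int
    standardized: bool


def fit_niches(
    p: NeighborhoodProfile,
    K: int = 4,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> NicheModel:
    """Cluster neighborhood profiles into K niches.

    Columns are z-scored across cells before k-means (zero-variance columns
    dropped) unless ``standardize=False``.  Niche composition is the label
    distribution of member cells' own labels.
    """
    X = p.counts.astype(float)
    if K > len(X):
        raise ValueError(f"K={K} exceeds n_cells={len(X)}")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all profile columns have zero variance")
        X = (X[:, keep] - mu[keep]) / sd[keep]
    km = KMeans(
        n_clusters=K,
        n_init=n_init,
        init="k-means++",
        tol=1e-6,
        max_iter=300,
        random_state=seed,
    ).fit(X)
    niche = km.labels_ + 1
    rows = []
    for nid in range(1, K + 1):
        member = p.labels[niche == nid]
        counts = pd.Series(member).value_counts()
        rows.append(counts.reindex(p.catalog).fillna(0.0) / max(len(member), 1))
    comp = pd.DataFrame(rows, index=pd.RangeIndex(1, K + 1, name="niche"))
    comp.columns = p.catalog
    return NicheModel(
        section_id=p.section_id,
        cell_ids=p.cell_ids,
        labels=p.labels,
        niche=niche,
        composition=comp,
        K=K,
        k=p.k,
        seed=seed,
        standardized=standardize,
    )


@dataclass
class NicheCorrespondence:
    """Cross-section niche matching by composition correlation."""

    profiles: pd.DataFrame  # (section, niche) x label
    correlation: pd.DataFrame  # (section, niche) x (section, niche)
    groups: pd.Series  # (section, niche) -> group id
    linkage: np.ndarray
    annotations: Dict[int, str]


def align_niches_across_sections(
    models: Sequence[NicheModel],
    n_groups: Optional[int] = None,
) -> NicheCorrespondence:
    """Group niches across sections by Pearson correlation of composition.

    Average-linkage hierarchical clustering on 1 - r, cut into
    ``n_groups`` groups (default: the per-section K).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 sections to align")
    if n_groups is None:
        n_groups = models[0].K
    cats = sorted({c for m in models for c in m.composition.columns})
    rows = {}
    for m in models:
        for nid in m.composition.index:
            rows[(m.section_id, int(nid))] = (
                m.composition.loc[nid].reindex(cats).fillna(0.0)
            )
    prof = pd.DataFrame(rows).T
    prof.index = pd.MultiIndex.from_tuples(prof.index, names=["section", "niche"])
    prof.columns = cats

    X = prof.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    if const.any():
        warnings.warn(f"{const.sum()} constant niche profiles; matched by nearest valid profile")
        # replace undefined correlations using the nearest (Euclidean) valid profile
        valid = np.flatnonzero(~const)
        for i in np.flatnonzero(const):
            d = ((X[valid] - X[i]) ** 2).sum(axis=1)
            proxy = valid[d.argmin()]
            R[i, :] = R[proxy, :]
            R[:, i] = R[:, proxy]
            R[i, i] = 1.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)

    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    grp = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    corr = pd.DataFrame(R, index=prof.index, columns=prof.index)
    groups = pd.Series(grp, index=prof.index, name="group")
    return NicheCorrespondence(
        profiles=prof, correlation=corr, groups=groups, linkage=Z, annotations={}
    )


def compare_niche_composition(
    corr: NicheCorrespondence,
    models: Sequence[NicheModel],
    group_a: int,
    group_b: int,
) -> pd.DataFrame:
    """Per-label Welch's t-test between two aligned niche groups.

    Each section contributes one composition vector per group (cells of the
    section's niches in that group, pooled).  Returns a DataFrame with the
    per-label t statistic, two-sided p, BH-adjusted p, per-group means and
    significance stars.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    cats = list(corr.profiles.columns)
    by_model = {m.section_id: m for m in models}

    def group_section_props(group: int) -> pd.DataFrame:
        rows = {}
        members = corr.groups[corr.groups == group].index
        by_sec: Dict[str, List[int]] = {}
        for sec, nid in members:
            by_sec.setdefault(sec, []).append(nid)
        for sec, nids in by_sec.items():
            m = by_model[sec]
            mask = np.isin(m.niche, nids)
            if not mask.any():
                continue
            member = m.labels[mask]
            counts = pd.Series(member).value_counts()
            rows[sec] = (counts.reindex(cats).fillna(0.0) / len(member))
        return pd.DataFrame(rows).T  # sections x labels

    a = group_section_props(group_a)
    b = group_section_props(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group must be represented in >= 2 sections")
    tstat, pval = stats.ttest_ind(
        a.to_numpy(), b.to_numpy(), axis=0, equal_var=False
    )
    pval = np.where(np.isnan(pval), 1.0, pval)
    p_bh = multipletests(pval, method="fdr_bh")[1]
    stars = np.select(
        [pval < 0.001, pval < 0.01, pval < 0.05], ["***", "**", "*"], default="ns"
    )
    return pd.DataFrame(
        {
            "t": tstat,
            "p": pval,
            "p_bh": p_bh,
            "stars": stars,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
        },
        index=pd.Index(cats, name="label"),
    )
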