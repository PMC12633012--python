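"""Colocalization statistics on spatial cell maps.

Symmetric mean nearest-neighbor distances between cell-type point sets
(with one-way ANOVA + Tukey HSD across sections), and same-label join
counts over distance-band neighbor graphs with analytic (random-labeling)
and permutation nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .datatypes import SpatialCellMap


@dataclass
class PairDistance:
    type_a: str
    type_b: str
    section_id: str
    d_ab: float  # mean over A-cells of distance to nearest B
    d_ba: float
    d_sym: float
    n_a: int
    n_b: int


def symmetric_mean_nn_distance(
    s: SpatialCellMap, type_a: str, type_b: str
) -> Optional[PairDistance]:
    """Average of the two directed mean nearest-neighbor distances (um)."""
    if type_a == type_b:
        raise ValueError("type_a and type_b must differ")
    coords = s.coords()
    labels = s.labels()
    a = coords[labels == type_a]
    b = coords[labels == type_b]
    if len(a) == 0 or len(b) == 0:
        warnings.warn(
            f"section {s.section_id}: missing {type_a if len(a) == 0 else type_b}"
        )
        return None
    d_ab = float(cKDTree(b).query(a, k=1)[0].mean())
    d_ba = float(cKDTree(a).query(b, k=1)[0].mean())
    return PairDistance(
        type_a=type_a,
        type_b=type_b,
        section_id=s.section_id,
        d_ab=d_ab,
        d_ba=d_ba,
        d_sym=0.5 * (d_ab + d_ba),
        n_a=len(a),
        n_b=len(b),
    )


def pair_distance_table(
    sections: Sequence[SpatialCellMap], pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """d_sym for every (pair, section); sections are the replicates."""
    rows = []
    for s in sections:
        for a, b in pairs:
            pd_ = symmetric_mean_nn_distance(s, a, b)
            if pd_ is None:
                continue
            rows.append(
                {
                    "pair": f"{a}|{b}",
                    "type_a": a,
                    "type_b": b,
                    "section_id": s.section_id,
                    "d_ab": pd_.d_ab,
                    "d_ba": pd_.d_ba,
                    "d_sym": pd_.d_sym,
                    "n_a": pd_.n_a,
                    "n_b": pd_.n_b,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # pair_1, pair_2, mean_diff, p_adj


def distance_anova_tukey(table: pd.DataFrame, value_col: str = "d_sym") -> AnovaTukeyResult:
    """One-way ANOVA of d_sym across type-pair groups, then Tukey HSD."""
    groups = [g[value_col].to_numpy(dtype=float) for _, g in table.groupby("pair", sort=True)]
    names = sorted(table["pair"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 type-pair groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations (sections)")
    f, p = stats.f_oneway(*groups)
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        f, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*groups)
    within_ss = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = float(np.mean(groups[i]) - np.mean(groups[j]))
            p_adj = float(hsd.pvalue[i, j])
            if within_ss == 0:  # zero residual variance: HSD undefined
                p_adj = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "pair_1": names[i],
                    "pair_2": names[j],
                    "mean_diff": diff,
                    "p_adj": p_adj,
                }
            )
    return AnovaTukeyResult(f_statistic=float(f), p_value=float(p), tukey=pd.DataFrame(rows))


@dataclass
class JoinCountResult:
    label: str
    radius: float
    n: int
    n_pos: int
    s0: float  # total binary weight sum (= 2 * n_edges)
    j_obs: int
    e_j: float
    sd_j: float
    z: float
    p: float
    null_method: str
    n_permutations: int = 0
    degenerate: bool = False


def combine_sections(
    sections: Sequence[SpatialCellMap], max_radius: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Concatenate sections into one field, offsetting y between sections.

    The offset is the running field height plus 10x the maximum radius, so
    no distance-band edge can cross sections.
    """
    pts = []
    labels = []
    y0 = 0.0
    for s in sections:
        c = s.coords().copy()
        ymin, ymax = c[:, 1].min(), c[:, 1].max()
        c[:, 1] += y0 - ymin
        y0 += (ymax - ymin) + 10.0 * max_radius
        pts.append(c)
        labels.append(s.labels())
    return np.vstack(pts), np.concatenate(labels)


def _joincount_moments(n: int, n1: int, s0: float, s1: float, s2: float) -> Tuple[float, float]:
    """Mean and variance of same-label join counts under random labeling.

    Nonfree-sampling moments (Cliff & Ord): J = 1/2 sum_ij w_ij x_i x_j.
    """

    def ff(m: int, k: int) -> float:  # falling factorial m^(k)
        out = 1.0
        for t in range(k):
            out *= m - t
        return out

    e_j = 0.5 * s0 * ff(n1, 2) / ff(n, 2)
    e_j2 = 0.25 * (
        s1 * ff(n1, 2) / ff(n, 2)
        + (s2 - 2.0 * s1) * ff(n1, 3) / ff(n, 3)
        + (s0 * s0 + s1 - s2) * ff(n1, 4) / ff(n, 4)
    )
    var = e_j2 - e_j * e_j
    return e_j, max(var, 0.0)


def joincount_profile(
    sections: Sequence[SpatialCellMap],
    label: str,
    radii: Sequence[float] = tuple(range(10, 31)),
    null: str = "analytic",
    n_perm: int = 999,
    seed: int = 0,
) -> List[JoinCountResult]:
    """Same-label join counts over distance bands (0, r].

    Sections are merged into one field with y offsets before the
    distance-band graph is built.  ``null='analytic'`` uses the
    random-labeling (nonfree sampling) moments and a normal two-sided p;
    ``null='permutation'`` shuffles labels over all cells in the field and
    uses the +1-corrected two-sided permutation p.
    """
    if null not in ("analytic", "permutation"):
        raise ValueError(f"unknown null {null!r}")
    radii = sorted(float(r) for r in radii)
    pts, labels = combine_sections(sections, max_radius=max(radii))
    x = (labels == label).astype(np.int64)
    n = len(x)
    n1 = int(x.sum())
    if n1 < 2:
        raise ValueError(f"fewer than 2 cells with label {label!r}")
    tree = cKDTree(pts)
    rng = np.random.default_rng(seed)
    results: List[JoinCountResult] = []
    for r in radii:
        pairs = tree.query_pairs(r, output_type="ndarray")  # i < j, d <= r
        # drop exactly coincident points' zero-distance pairs? band is (0, r]
        if len(pairs):
            d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
            pairs = pairs[d > 0]
        n_edges = len(pairs)
        if n_edges == 0:
            results.append(
                JoinCountResult(
                    label=label, radius=r, n=n, n_pos=n1, s0=0.0, j_obs=0,
                    e_j=0.0, sd_j=0.0, z=np.nan, p=1.0, null_method=null,
                    degenerate=True,
                )
            )
            continue
        j_obs = int((x[pairs[:, 0]] * x[pairs[:, 1]]).sum())
        s0 = 2.0 * n_edges
        s1 = 4.0 * n_edges  # sum (w_ij + w_ji)^2 over ordered pairs / ... binary symmetric
        deg = np.bincount(pairs.ravel(), minlength=n)
        s2 = float((4 * deg.astype(np.float64) ** 2).sum())
        if n1 == n or n1 == 0:
            results.append(
                JoinCountResult(
                    label=label, radius=r, n=n, n_pos=n1, s0=s0, j_obs=j_obs,
                    e_j=float(j_obs), sd_j=0.0, z=np.nan, p=1.0,
                    null_method=null, degenerate=True,
                )
            )
            continue
        if null == "analytic":
            e_j, var = _joincount_moments(n, n1, s0, s1, s2)
            sd = float(np.sqrt(var))
            if sd == 0:
                results.append(
                    JoinCountResult(
                        label=label, radius=r, n=n, n_pos=n1, s0=s0, j_obs=j_obs,
                        e_j=e_j, sd_j=0.0, z=np.nan, p=1.0, null_method=null,
                        degenerate=True,
                    )
                )
                continue
            z = (j_obs - e_j) / sd
            p = 2.0 * stats.norm.sf(abs(z))
            results.append(
                JoinCountResult(
                    label=label, radius=r, n=n, n_pos=n1, s0=s0, j_obs=j_obs,
                    e_j=e_j, sd_j=sd, z=float(z), p=float(min(p, 1.0)),
                    null_method="analytic",
                )
            )
        else:
            perm_j = np.empty(n_perm, dtype=np.int64)
            for b in range(n_perm):
                xp = rng.permutation(x)
                perm_j[b] = (xp[pairs[:, 0]] * xp[pairs[:, 1]]).sum()
            mu = float(perm_j.mean())
            sd = float(perm_j.std(ddof=1))
            z = (j_obs - mu) / sd if sd > 0 else np.nan
            extreme = int((np.abs(perm_j - mu) >= abs(j_obs - mu)).sum())
            p = (1.0 + extreme) / (n_perm + 1.0)
            results.append(
                JoinCountResult(
                    label=label, radius=r, n=n, n_pos=n1, s0=s0, j_obs=j_obs,
                    e_j=mu, sd_j=sd, z=float(z) if np.isfinite(z) else np.nan,
                    p=float(p), null_method="permutation", n_permutations=n_perm,
                    degenerate=sd == 0,
                )
            )
    return results


def joincount_table(results: Sequence[JoinCountResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
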