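"""Marker detection, gene signatures, binned-control module scoring.

Module scores follow the binned-control scheme: genes are binned by
dataset-average expression, each signature gene draws control genes from
its own bin, and the score is the signature mean minus the pooled-control
mean per cell.  With one bin and all non-signature genes as controls this
reduces exactly to a direct contrast, which the tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSignature, NormalizedMatrix, gene_mask

DEFAULT_EXCLUDE = (r"^MT-", r"^RPS", r"^RPL")


def _rank_sum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows), tie-corrected normal."""
    res = stats.mannwhitneyu(
        x_in, x_out, alternative="two-sided", method="asymptotic", axis=1
    )
    return np.asarray(res.pvalue)


def rank_markers(
    x: NormalizedMatrix,
    labels: Sequence[str],
    group1,
    group2,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Differential expression between two label groups.

    Only genes detected in at least ``min_pct`` of either group, with
    |log2 fold change| above ``min_logfc`` and not matching
    ``exclude_patterns`` are tested.  P-values are adjusted over the full
    gene universe (Bonferroni by default, ``adjust='bh'`` for
    Benjamini-Hochberg).

    Returns a DataFrame indexed by gene with columns
    ``log2fc, pct_in, pct_out, p, p_adjusted``, sorted by descending
    log2fc.
    """
    labels = np.asarray(labels, dtype=object)
    g1 = set([group1]) if isinstance(group1, str) else set(group1)
    g2 = set([group2]) if isinstance(group2, str) else set(group2)
    if g1 & g2:
        raise ValueError(f"groups overlap: {sorted(g1 & g2)}")
    m1 = np.isin(labels, list(g1))
    m2 = np.isin(labels, list(g2))
    if not m1.any() or not m2.any():
        raise ValueError("both groups must be non-empty")

    dense = x.dense()
    x1, x2 = dense[:, m1], dense[:, m2]
    pct_in = (x1 > 0).mean(axis=1)
    pct_out = (x2 > 0).mean(axis=1)
    eps = 1e-9
    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    log2fc = np.log2((mean1 + eps) / (mean2 + eps))

    excluded = gene_mask(x.genes, exclude_patterns) if exclude_patterns else np.zeros(
        x.n_genes, dtype=bool
    )
    testable = (
        ((pct_in >= min_pct) | (pct_out >= min_pct))
        & (np.abs(log2fc) > min_logfc)
        & ~excluded
    )
    idx = np.flatnonzero(testable)
    pvals = np.ones(len(idx))
    if len(idx):
        pvals = _rank_sum_pvalues(x1[idx], x2[idx])
    n_universe = x.n_genes
    if adjust == "bonferroni":
        p_adj = np.minimum(pvals * n_universe, 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(pvals, method="fdr_bh")[1] if len(idx) else pvals
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = pd.DataFrame(
        {
            "gene": x.genes[idx],
            "log2fc": log2fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p": pvals,
            "p_adjusted": p_adj,
        }
    ).set_index("gene")
    return out.sort_values("log2fc", ascending=False)


def rank_sum_pvalues_all_genes(
    x: NormalizedMatrix, labels: Sequence[str], group1, group2
) -> pd.Series:
    """Unfiltered per-gene rank-sum p-values (calibration checks)."""
    labels = np.asarray(labels, dtype=object)
    g1 = set([group1]) if isinstance(group1, str) else set(group1)
    g2 = set([group2]) if isinstance(group2, str) else set(group2)
    m1 = np.isin(labels, list(g1))
    m2 = np.isin(labels, list(g2))
    dense = x.dense()
    p = _rank_sum_pvalues(dense[:, m1], dense[:, m2])
    return pd.Series(p, index=x.genes)


def build_signature(
    markers: pd.DataFrame,
    top_n: int,
    direction: str = "up",
    name: Optional[str] = None,
) -> GeneSignature:
    """Top-N genes by |log2fc| in one direction; ties by p then gene ID."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(markers) == 0:
        raise ValueError("empty marker table")
    df = markers.copy()
    df = df[df["log2fc"] > 0] if direction == "up" else df[df["log2fc"] < 0]
    df = df.assign(_abs=df["log2fc"].abs(), _gene=df.index.astype(str))
    df = df.sort_values(["_abs", "p", "_gene"], ascending=[False, True, True])
    genes = df.index[:top_n].tolist()
    if len(genes) < top_n:
        warnings.warn(
            f"requested top {top_n} but only {len(genes)} genes available "
            f"({direction})"
        )
    return GeneSignature(name=name or f"sig_{direction}", genes=genes)


@dataclass
class ModuleScores:
    scores: pd.DataFrame  # cells x signatures
    n_bins: int
    n_controls: int
    seed: int


def score_modules(
    x: NormalizedMatrix,
    sigs: Sequence[GeneSignature],
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
    bin_reference: Optional[NormalizedMatrix] = None,
) -> ModuleScores:
    """Binned-control module scores per cell.

    Genes are cut into ``n_bins`` near-equal-size bins by rank of average
    expression (computed on ``bin_reference`` if given, else on ``x``).
    For each signature gene, ``n_controls`` controls are drawn uniformly
    without replacement from its bin, excluding signature genes; if a bin
    has fewer eligible genes than ``n_controls`` they are drawn with
    replacement (with a warning).  Controls are pooled with multiplicity.
    """
    ref = bin_reference if bin_reference is not None else x
    avg = np.asarray(ref.values.mean(axis=1)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=np.int64)
    # near-equal-size bins over the expression rank
    bins[order] = np.floor(np.arange(len(avg)) * n_bins / len(avg)).astype(np.int64)

    gidx = x.gene_index()
    dense = x.dense()
    rng = np.random.default_rng(seed)
    cols: Dict[str, np.ndarray] = {}
    for sig in sigs:
        present = [g for g in sig.genes if g in gidx]
        dropped = [g for g in sig.genes if g not in gidx]
        if dropped:
            warnings.warn(
                f"signature {sig.name!r}: dropping {len(dropped)} genes absent from data"
            )
        if not present:
            raise ValueError(f"signature {sig.name!r} has no genes in the data")
        mod_idx = np.array([gidx[g] for g in present])
        mod_set = set(mod_idx.tolist())
        control_pool: List[np.ndarray] = []
        short_bins = set()
        for gi in mod_idx:
            eligible = np.array(
                [j for j in np.flatnonzero(bins == bins[gi]) if j not in mod_set]
            )
            if len(eligible) == 0:
                raise ValueError(
                    f"signature {sig.name!r}: no eligible control genes in bin {bins[gi]}"
                )
            if len(eligible) < n_controls:
                short_bins.add(int(bins[gi]))
                control_pool.append(rng.choice(eligible, size=n_controls, replace=True))
            else:
                control_pool.append(rng.choice(eligible, size=n_controls, replace=False))
        if short_bins:
            warnings.warn(
                f"signature {sig.name!r}: bins {sorted(short_bins)} have fewer than "
                f"{n_controls} eligible controls; sampled with replacement"
            )
        controls = np.concatenate(control_pool)
        score = dense[mod_idx].mean(axis=0) - dense[controls].mean(axis=0)
        cols[sig.name] = score
    scores = pd.DataFrame(cols, index=pd.Index(x.cells, name="cell_id"))
    return ModuleScores(scores=scores, n_bins=n_bins, n_controls=n_controls, seed=seed)


def assign_at2_state(
    at2_cells,
    fmo5_sig: Optional[GeneSignature] = None,
    cftr_sig: Optional[GeneSignature] = None,
    mode: str = "score",
    tau: float = 0.0,
    min_counts: int = 2,
    scores: Optional[pd.DataFrame] = None,
    panel_counts: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Assign AT2 cells to FMO5+/CFTR+/Unassigned.

    score mode: ``scores`` is a cells x 2 frame of module scores for the
    two state signatures; the higher-scoring state wins when it exceeds
    ``tau``.  panel_counts mode: ``panel_counts`` is a cells x 2 frame of
    summed transcript counts over each state's panel genes; a state is
    positive at >= ``min_counts`` transcripts, both positive resolves to
    the larger count (exact tie -> Unassigned).
    """
    from .qc import CFTR, FMO5, UNASSIGNED

    if mode == "score":
        if scores is None:
            if fmo5_sig is None or cftr_sig is None:
                raise ValueError("score mode needs scores or both signatures")
            if len(fmo5_sig) == 0 or len(cftr_sig) == 0:
                raise ValueError("empty signature")
            if not isinstance(at2_cells, NormalizedMatrix):
                raise ValueError(
                    "score mode needs a NormalizedMatrix of AT2 cells or a scores frame"
                )
            scores = score_modules(at2_cells, [fmo5_sig, cftr_sig]).scores
        f = scores.iloc[:, 0].to_numpy(dtype=float)
        c = scores.iloc[:, 1].to_numpy(dtype=float)
        top = np.maximum(f, c)
        out = np.where(top > tau, np.where(f > c, FMO5, CFTR), UNASSIGNED)
        out = np.where((top > tau) & (f == c), UNASSIGNED, out)
        return pd.Series(out, index=scores.index, name="at2_state")
    if mode == "panel_counts":
        if panel_counts is None:
            raise ValueError("panel_counts mode requires a panel_counts frame")
        f = panel_counts.iloc[:, 0].to_numpy()
        c = panel_counts.iloc[:, 1].to_numpy()
        fpos = f >= min_counts
        cpos = c >= min_counts
        out = np.full(len(f), UNASSIGNED, dtype=object)
        out[fpos & ~cpos] = FMO5
        out[cpos & ~fpos] = CFTR
        both = fpos & cpos
        out[both & (f > c)] = FMO5
        out[both & (c > f)] = CFTR
        return pd.Series(out, index=panel_counts.index, name="at2_state")
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class MaturationSets:
    """Per cell type: genes switching on / off across maturation."""

    sets: Dict[str, Dict[str, GeneSignature]]  # type -> {"on": ..., "off": ...}

    def types(self) -> List[str]:
        return list(self.sets)


def build_maturation_sets(
    reference: NormalizedMatrix,
    stage_labels: Sequence[str],
    type_labels: Sequence[str],
    fetal_stage: str,
    top_n: int = 100,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
) -> MaturationSets:
    """On/off signatures per type: pooled postnatal vs fetal contrast."""
    stage_labels = np.asarray(stage_labels, dtype=object)
    type_labels = np.asarray(type_labels, dtype=object)
    if fetal_stage not in set(stage_labels):
        raise ValueError(f"fetal stage {fetal_stage!r} absent from reference")
    sets: Dict[str, Dict[str, GeneSignature]] = {}
    for t in pd.unique(type_labels):
        tmask = type_labels == t
        fet = tmask & (stage_labels == fetal_stage)
        post = tmask & (stage_labels != fetal_stage)
        if not fet.any() or not post.any():
            warnings.warn(f"type {t!r} missing a stage; skipped")
            continue
        sub = reference.subset_cells(tmask)
        grp = np.where(stage_labels[tmask] == fetal_stage, "fetal", "postnatal")
        mr = rank_markers(sub, grp, "postnatal", "fetal", min_pct=min_pct, min_logfc=min_logfc)
        if len(mr) == 0:
            warnings.warn(f"type {t!r}: no differential genes; skipped")
            continue
        on = build_signature(mr, top_n, "up", name=f"{t}_maturation_on")
        off = build_signature(mr, top_n, "down", name=f"{t}_maturation_off")
        sets[t] = {"on": on, "off": off}
    return MaturationSets(sets=sets)


def score_maturation(
    query: NormalizedMatrix,
    type_labels: Sequence[str],
    sets: MaturationSets,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
    bin_reference: Optional[NormalizedMatrix] = None,
) -> pd.DataFrame:
    """Per-cell on/off maturation scores using each cell's own type's sets."""
    type_labels = np.asarray(type_labels, dtype=object)
    on = np.full(query.n_cells, np.nan)
    off = np.full(query.n_cells, np.nan)
    for t in pd.unique(type_labels):
        if t not in sets.sets:
            warnings.warn(f"no maturation sets for type {t!r}; skipped")
            continue
        m = type_labels == t
        sub = query.subset_cells(m)
        ms = score_modules(
            sub,
            [sets.sets[t]["on"], sets.sets[t]["off"]],
            n_bins=n_bins,
            n_controls=n_controls,
            seed=seed,
            bin_reference=bin_reference,
        )
        on[m] = ms.scores.iloc[:, 0].to_numpy()
        off[m] = ms.scores.iloc[:, 1].to_numpy()
    return pd.DataFrame(
        {"cell_id": query.cells, "cell_type": type_labels, "on_score": on, "off_score": off}
    ).set_index("cell_id")


def assign_labels_nearest_centroid(
    query: NormalizedMatrix,
    centroids: pd.DataFrame,  # genes x types
    genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Label each cell by max Pearson correlation with a type centroid.

    Confidence is the top correlation minus the runner-up.  Ties break
    lexicographically by type name; all-constant cells are Unassigned.
    """
    from .qc import UNASSIGNED

    use = list(genes) if genes is not None else [g for g in centroids.index if g in set(query.genes)]
    gidx = query.gene_index()
    use = [g for g in use if g in gidx and g in centroids.index]
    if not use:
        raise ValueError("no shared genes between query and centroids")
    qi = np.array([gidx[g] for g in use])
    X = query.dense()[qi]  # genes x cells
    C = centroids.loc[use].to_numpy(dtype=float)  # genes x types
    types = sorted(centroids.columns.astype(str))
    C = centroids.loc[use, types].to_numpy(dtype=float)

    Xc = X - X.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(Cc, axis=0)
    valid_cell = xn > 0
    valid_type = cn > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Cc) / np.outer(np.where(xn > 0, xn, 1.0), np.where(cn > 0, cn, 1.0))
    R[:, ~valid_type] = -np.inf

    # lexicographic tie-break: argmax over columns already ordered by name
    best = R.argmax(axis=1)
    sortedR = np.sort(R, axis=1)
    top = sortedR[:, -1]
    runner = sortedR[:, -2] if R.shape[1] > 1 else np.full(len(best), -np.inf)
    labels = np.array(types, dtype=object)[best]
    conf = np.where(np.isfinite(runner), top - runner, np.inf)
    labels = np.where(valid_cell, labels, UNASSIGNED)
    conf = np.where(valid_cell, conf, 0.0)
    return pd.DataFrame(
        {"label": labels, "confidence": conf}, index=pd.Index(query.cells, name="cell_id")
    )
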