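"""QC filtering, normalization, specimen classification and composition.

Boundary semantics follow the printed thresholds literally: feature counts
are kept on a closed interval, molecule counts must strictly exceed the
minimum, and the mitochondrial/ribosomal fractions must be strictly below
their caps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import CountMatrix, NormalizedMatrix

FMO5 = "FMO5+"
CFTR = "CFTR+"
UNASSIGNED = "Unassigned"


@dataclass
class QCThresholds:
    min_features: int = 500
    max_features: int = 7500
    min_molecules: int = 1000  # exclusive
    max_frac_mito: float = 0.05  # exclusive
    max_frac_ribo: float = 0.075  # exclusive
    spatial_min_counts: int = 25  # "less than 25 ... excluded" => keep >= 25

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if min(self.min_features, self.min_molecules, self.spatial_min_counts) <= 0:
            raise ValueError("thresholds must be positive")


def apply_qc_filters(m: CountMatrix, t: QCThresholds = QCThresholds()) -> CountMatrix:
    """Retain cells passing all four per-cell QC predicates.

    Requires ``n_features``, ``n_molecules``, ``frac_mito``, ``frac_ribo``
    in ``cell_meta`` (computed from counts with default gene-name patterns
    if absent).
    """
    needed = ["n_features", "n_molecules", "frac_mito", "frac_ribo"]
    if any(c not in m.cell_meta.columns for c in needed):
        m = m.compute_qc_metrics()
    meta = m.cell_meta
    keep = (
        (meta["n_features"] >= t.min_features)
        & (meta["n_features"] <= t.max_features)
        & (meta["n_molecules"] > t.min_molecules)
        & (meta["frac_mito"] < t.max_frac_mito)
        & (meta["frac_ribo"] < t.max_frac_ribo)
    ).to_numpy()
    if not keep.any():
        warnings.warn("QC filter removed every cell")
    return m.subset_cells(keep)


def normalize_counts(m: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """value(g, c) = ln(1 + count(g, c) * scale / total(c))."""
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = m.cells[totals == 0][:5]
        raise ValueError(f"cells with zero total counts: {list(bad)}")
    x = m.counts.tocsc().astype(np.float64)
    # scale each column, then log1p on stored entries (zeros map to zero)
    x = x @ sp.diags(scale / totals)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        genes=m.genes,
        cells=m.cells,
        values=x.tocsr(),
        scale_factor=scale,
        cell_meta=m.cell_meta,
    )


@dataclass
class SpecimenGroup:
    """Specimen -> AT2-abundance class assignment."""

    classes: Dict[str, str]  # specimen -> class
    enrich_threshold: float = 0.65
    min_at2_cells: int = 50
    fmo5_fraction: Dict[str, float] = field(default_factory=dict)

    def specimens_in(self, cls: str):
        return [s for s, c in self.classes.items() if c == cls]


def classify_specimens_by_at2_state(
    cells: pd.DataFrame,
    enrich_threshold: float = 0.65,
    min_at2_cells: int = 50,
    specimen_col: str = "specimen",
    state_col: str = "at2_state",
) -> SpecimenGroup:
    """Classify specimens by the FMO5+ fraction among assigned AT2 cells.

    ``cells`` must contain one row per AT2 cell with its state label
    (FMO5+/CFTR+/Unassigned); rows of other cell types may be present and
    are ignored.
    """
    classes: Dict[str, str] = {}
    fracs: Dict[str, float] = {}
    for specimen, grp in cells.groupby(specimen_col, sort=True):
        st = grp[state_col]
        n_f = int((st == FMO5).sum())
        n_c = int((st == CFTR).sum())
        assigned = n_f + n_c
        if assigned < min_at2_cells or assigned == 0:
            classes[specimen] = "unclassified"
            continue
        p = n_f / assigned
        fracs[specimen] = p
        if p >= enrich_threshold:
            classes[specimen] = "FMO5_enriched"
        elif p <= 1.0 - enrich_threshold:
            classes[specimen] = "CFTR_enriched"
        else:
            classes[specimen] = "mixed"
    return SpecimenGroup(
        classes=classes,
        enrich_threshold=enrich_threshold,
        min_at2_cells=min_at2_cells,
        fmo5_fraction=fracs,
    )


@dataclass
class WeightedComposition:
    """Equal-weight-per-class composition summary."""

    weights: pd.Series  # per cell
    overall_proportions: pd.Series  # weighted type proportions, all classes pooled
    class_proportions: pd.DataFrame  # class x type
    class_shares: pd.DataFrame  # type x class, rows sum to 1
    n_classes: int


def weighted_composition(
    cells: pd.DataFrame,
    groups: SpecimenGroup,
    compartment: Optional[Sequence[str]] = None,
    type_col: str = "cell_type",
    specimen_col: str = "specimen",
) -> WeightedComposition:
    """Weight cells so each specimen class contributes equally.

    w(cell in class g) = 1 / (G * N_g) with N_g the class's cell count in
    the compartment.  Unclassified specimens are excluded.
    """
    df = cells.copy()
    df["_class"] = df[specimen_col].map(groups.classes)
    df = df[df["_class"].notna() & (df["_class"] != "unclassified")]
    if compartment is not None:
        df = df[df[type_col].isin(set(compartment))]
    class_sizes = df.groupby("_class").size()
    empty = [c for c in class_sizes.index if class_sizes[c] == 0]
    if empty:
        warnings.warn(f"dropping classes with no compartment cells: {empty}")
    class_sizes = class_sizes[class_sizes > 0]
    G = len(class_sizes)
    if G == 0:
        raise ValueError("no classes with cells in the requested compartment")
    w = df["_class"].map(lambda c: 1.0 / (G * class_sizes[c]))
    w.index = df.index

    tab = pd.crosstab(df["_class"], df[type_col])  # class x type counts
    class_props = tab.div(tab.sum(axis=1), axis=0)
    # weighted overall proportions: mean of class proportions (equal weights)
    overall = class_props.mean(axis=0)
    # per-type class shares: fraction of the type's total weight from each class
    wtab = tab.div(tab.sum(axis=1), axis=0)  # = class_props
    shares = wtab.div(wtab.sum(axis=0), axis=1).T  # type x class
    return WeightedComposition(
        weights=w,
        overall_proportions=overall,
        class_proportions=class_props,
        class_shares=shares,
        n_classes=G,
    )


def exact_weights(
    class_sizes: Dict[str, int],
) -> Dict[str, Fraction]:
    """Exact rational per-cell weight for each class (for invariant checks)."""
    G = len(class_sizes)
    return {c: Fraction(1, G * n) for c, n in class_sizes.items()}


def compare_composition(
    cells: pd.DataFrame,
    groups: SpecimenGroup,
    cell_type: str,
    group_a: str,
    group_b: str,
    type_col: str = "cell_type",
    specimen_col: str = "specimen",
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-specimen proportions of a type.

    Exact null distribution when combined n <= 20 without ties; normal
    approximation with continuity correction otherwise.  Returns
    (Mann-Whitney U statistic of group A, p-value).
    """

    def specimen_props(cls: str) -> np.ndarray:
        specs = groups.specimens_in(cls)
        out = []
        for s in specs:
            sub = cells[cells[specimen_col] == s]
            if len(sub) == 0:
                continue
            out.append((sub[type_col] == cell_type).mean())
        return np.array(out)

    a = specimen_props(group_a)
    b = specimen_props(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 specimens with cells")
    return wilcoxon_rank_sum(a, b)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def qpcr_relative_abundance(ct_target: float, ct_18s: float) -> float:
    """Expression in arbitrary units: 2^(18S Ct - target Ct) x 10,000."""
    return 2.0 ** (ct_18s - ct_target) * 10_000.0


def zscore_by_gene(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score assay values per gene (rows) across conditions, sample SD."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return values.sub(mu, axis=0).div(sd, axis=0)
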