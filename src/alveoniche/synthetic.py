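"""Seeded synthetic cohorts, staged developmental series and spatial sections.

The generator plants known structure — cell-type marker blocks, two mutually
exclusive AT2 transcriptional states whose per-specimen mixture varies across
three specimen classes, staged on/off developmental programs, and spatial
regions with distinct compositions — so every downstream method can be
checked against ground truth.

Counts follow a gamma-Poisson (negative binomial) model with a lognormal
per-cell library size; in the Poisson limit (``nb_dispersion=None``) counts
are drawn multinomially so per-cell totals equal the drawn library size
exactly.  All randomness descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configs give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, SpatialCellMap

AT2_TYPE = "AT2"
STATE_FMO5 = "FMO5+"
STATE_CFTR = "CFTR+"
SPECIMEN_CLASSES = ("FMO5_enriched", "CFTR_enriched", "mixed")

DEFAULT_CATALOG: Dict[str, float] = {
    "AT2": 0.25,
    "AT1": 0.12,
    "Transitional": 0.08,
    "AF_c1": 0.10,
    "AF_c2": 0.08,
    "AF_c3": 0.10,
    "Airway": 0.07,
    "Immune": 0.10,
    "Endothelial": 0.10,
}

DEFAULT_STATE_MIX: Dict[str, Tuple[float, float]] = {
    "FMO5_enriched": (24.0, 6.0),
    "CFTR_enriched": (6.0, 24.0),
    "mixed": (30.0, 30.0),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic multi-specimen snRNA-seq cohort."""

    n_specimens_per_class: int = 3
    cells_per_specimen: int = 500
    cell_type_catalog: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATALOG))
    at2_state_mix: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_MIX)
    )
    n_genes: int = 2000
    n_markers_per_type: int = 50
    marker_log_fold: float = 1.5
    libsize_lognormal: Tuple[float, float] = (8.5, 0.35)
    nb_dispersion: Optional[float] = 2.0  # None => Poisson/multinomial limit
    mito_gene_fraction: float = 0.01
    ribo_gene_fraction: float = 0.02
    mito_expr_share: float = 0.02
    ribo_expr_share: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens_per_class <= 0 or self.cells_per_specimen <= 0:
            raise ValueError("specimen and cell counts must be positive")
        if self.n_genes <= 0 or self.n_markers_per_type <= 0:
            raise ValueError("gene counts must be positive")
        total = sum(self.cell_type_catalog.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"baseline proportions sum to {total}, expected 1")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (or None for Poisson)")
        for cls, (a, b) in self.at2_state_mix.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {cls} must be positive")


@dataclass
class SpatialConfig:
    """Parameters of the synthetic multi-section spatial maps."""

    n_sections: int = 5
    cells_per_section: int = 3000
    region_layout: str = "segregated"  # or "salt_and_pepper"
    region_catalog: Optional[Dict[str, Dict[str, float]]] = None
    min_spacing_um: float = 5.0
    section_extent_um: Tuple[float, float] = (1000.0, 1000.0)
    patch_size_um: float = 100.0  # salt-and-pepper patch scale
    anchors_per_region: int = 3  # segregated Voronoi blob count
    panel_genes: Optional[List[str]] = None
    panel_mean_counts: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_layout not in ("segregated", "salt_and_pepper"):
            raise ValueError(f"unknown region_layout {self.region_layout!r}")
        if self.min_spacing_um <= 0:
            raise ValueError("min_spacing_um must be positive")
        if self.region_catalog is not None:
            for name, comp in self.region_catalog.items():
                s = sum(comp.values())
                if not math.isclose(s, 1.0, abs_tol=1e-6):
                    raise ValueError(f"region {name!r} composition sums to {s}, expected 1")


def default_region_catalog() -> Dict[str, Dict[str, float]]:
    """Four-region layout: bronchiolar, interstitial, two alveolar niches.

    Alveolar region 1 pairs the lipogenic AT2 state with AF_c1/AF_c2
    fibroblasts; alveolar region 2 pairs the inflammatory AT2 state with
    AF_c3.
    """
    return {
        "bronchiolar": {
            "Airway": 0.70,
            "Immune": 0.10,
            "Endothelial": 0.10,
            "AF_c1": 0.05,
            "AF_c2": 0.05,
        },
        "interstitial": {
            "Immune": 0.35,
            "Endothelial": 0.35,
            "AF_c1": 0.10,
            "AF_c2": 0.10,
            "Airway": 0.05,
            "AT1": 0.05,
        },
        "alveolar_1": {
            "AT2_FMO5": 0.30,
            "AF_c1": 0.20,
            "AF_c2": 0.15,
            "AT1": 0.15,
            "Transitional": 0.08,
            "Immune": 0.06,
            "Endothelial": 0.06,
        },
        "alveolar_2": {
            "AT2_CFTR": 0.30,
            "AF_c3": 0.35,
            "AT1": 0.15,
            "Transitional": 0.08,
            "Immune": 0.06,
            "Endothelial": 0.06,
        },
    }


@dataclass
class GroundTruth:
    """Planted truth: per-cell labels and per-gene program membership."""

    cell_truth: pd.DataFrame  # cell_id, specimen, specimen_class, cell_type, at2_state[, stage]
    gene_truth: pd.DataFrame  # gene, program
    region_truth: Optional[pd.DataFrame] = None  # cell_id, section_id, region

    def markers_of(self, cell_type: str) -> List[str]:
        m = self.gene_truth["program"] == f"marker:{cell_type}"
        return self.gene_truth.loc[m, "gene"].tolist()

    def state_genes(self, state: str) -> List[str]:
        key = {"FMO5+": "state_fmo5", "CFTR+": "state_cftr"}[state]
        m = self.gene_truth["program"] == key
        return self.gene_truth.loc[m, "gene"].tolist()

    def program_genes(self, program: str) -> List[str]:
        m = self.gene_truth["program"] == program
        return self.gene_truth.loc[m, "gene"].tolist()


class ExpressionModel:
    """Per-(type, state) expected gene proportions derived from a config.

    Gene universe layout (contiguous blocks): mitochondrial genes, ribosomal
    genes, then generic genes of which some are claimed by marker / state /
    maturation programs.  Baseline relative abundances are lognormal so that
    expression-level bins used by module scoring are well populated.
    """

    def __init__(self, config: CohortConfig):
        self.config = config
        cfg = config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE0]))
        n = cfg.n_genes
        n_mito = max(1, int(round(cfg.mito_gene_fraction * n)))
        n_ribo = max(1, int(round(cfg.ribo_gene_fraction * n)))
        genes = (
            [f"MT-{i+1:04d}" for i in range(n_mito)]
            + [f"RPS{i+1:04d}" for i in range(n_ribo)]
            + [f"G{i+1:05d}" for i in range(n - n_mito - n_ribo)]
        )
        self.genes = np.array(genes, dtype=object)
        self.n_mito, self.n_ribo = n_mito, n_ribo

        base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        # Rescale contiguous blocks so expected mito/ribo count shares are
        # controllable (QC fraction knobs).
        mito_sl = slice(0, n_mito)
        ribo_sl = slice(n_mito, n_mito + n_ribo)
        rest_sl = slice(n_mito + n_ribo, n)
        rest_share = 1.0 - cfg.mito_expr_share - cfg.ribo_expr_share
        base[mito_sl] *= cfg.mito_expr_share / base[mito_sl].sum()
        base[ribo_sl] *= cfg.ribo_expr_share / base[ribo_sl].sum()
        base[rest_sl] *= rest_share / base[rest_sl].sum()
        self.base = base

        types = list(cfg.cell_type_catalog)
        if AT2_TYPE not in types:
            raise ValueError(f"catalog must contain an {AT2_TYPE!r} type")
        n_programs = len(types) + 2  # per-type markers + two AT2 state sets
        needed = n_programs * cfg.n_markers_per_type
        avail = n - n_mito - n_ribo
        if needed > avail:
            raise ValueError(
                f"{needed} marker genes requested but only {avail} non-mito/ribo genes available"
            )
        pool = np.arange(n_mito + n_ribo, n)
        picked = rng.choice(pool, size=needed, replace=False)
        self.markers: Dict[str, np.ndarray] = {}
        k = cfg.n_markers_per_type
        for i, t in enumerate(types):
            self.markers[t] = np.sort(picked[i * k : (i + 1) * k])
        self.state_genes = {
            STATE_FMO5: np.sort(picked[len(types) * k : (len(types) + 1) * k]),
            STATE_CFTR: np.sort(picked[(len(types) + 1) * k : (len(types) + 2) * k]),
        }
        self.types = types
        self._claimed = set(picked.tolist())
        self._rng_for_programs = rng  # reused by maturation program allocation
        self.maturation: Dict[str, Dict[str, np.ndarray]] = {}

    def allocate_maturation_programs(self, program_size: int) -> None:
        """Claim disjoint on/off gene blocks per cell type (idempotent)."""
        if self.maturation:
            return
        cfg = self.config
        n = cfg.n_genes
        free = np.array(
            [i for i in range(self.n_mito + self.n_ribo, n) if i not in self._claimed]
        )
        needed = 2 * program_size * len(self.types)
        if needed > len(free):
            raise ValueError(
                f"maturation programs need {needed} genes, only {len(free)} unclaimed"
            )
        picked = self._rng_for_programs.choice(free, size=needed, replace=False)
        off = 0
        for t in self.types:
            on_idx = np.sort(picked[off : off + program_size])
            off_idx = np.sort(picked[off + program_size : off + 2 * program_size])
            self.maturation[t] = {"on": on_idx, "off": off_idx}
            self._claimed.update(on_idx.tolist())
            self._claimed.update(off_idx.tolist())
            off += 2 * program_size

    def mean_proportions(
        self,
        cell_type: str,
        at2_state: Optional[str] = None,
        stage_frac: Optional[float] = None,
        ramp_log_fold: float = 1.5,
    ) -> np.ndarray:
        """Normalized expected gene proportions for one cell phenotype.

        ``stage_frac`` in [0, 1] positions the cell on the fetal->mature ramp
        (0 = fetal); requires maturation programs to be allocated.
        """
        mu = self.base.copy()
        lf = math.exp(self.config.marker_log_fold)
        mu[self.markers[cell_type]] *= lf
        if cell_type == AT2_TYPE and at2_state in (STATE_FMO5, STATE_CFTR):
            mu[self.state_genes[at2_state]] *= lf
        if stage_frac is not None:
            prog = self.maturation[cell_type]
            mu[prog["on"]] *= math.exp(ramp_log_fold * stage_frac)
            mu[prog["off"]] *= math.exp(ramp_log_fold * (1.0 - stage_frac))
        return mu / mu.sum()

    def gene_truth_frame(self) -> pd.DataFrame:
        prog = np.full(self.config.n_genes, "neutral", dtype=object)
        prog[: self.n_mito] = "mito"
        prog[self.n_mito : self.n_mito + self.n_ribo] = "ribo"
        for t, idx in self.markers.items():
            prog[idx] = f"marker:{t}"
        prog[self.state_genes[STATE_FMO5]] = "state_fmo5"
        prog[self.state_genes[STATE_CFTR]] = "state_cftr"
        for t, d in self.maturation.items():
            prog[d["on"]] = f"maturation_on:{t}"
            prog[d["off"]] = f"maturation_off:{t}"
        return pd.DataFrame({"gene": self.genes, "program": prog})


def _sample_counts(
    rng: np.random.Generator,
    props: np.ndarray,
    libsize: int,
    dispersion: Optional[float],
) -> np.ndarray:
    """One cell's gene counts. Poisson mode conserves the library size."""
    if dispersion is None:
        return rng.multinomial(libsize, props)
    mean = props * libsize
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _draw_libsizes(rng: np.random.Generator, n: int, mu: float, sigma: float) -> np.ndarray:
    return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)


def generate_expression_cohort(
    config: CohortConfig,
) -> Tuple[CountMatrix, GroundTruth]:
    """Simulate a multi-specimen cohort with three AT2-abundance classes."""
    model = ExpressionModel(config)
    cfg = config
    classes = [c for c in SPECIMEN_CLASSES if c in cfg.at2_state_mix]
    type_names = model.types
    type_p = np.array([cfg.cell_type_catalog[t] for t in type_names])

    blocks: List[sp.csc_matrix] = []
    cell_ids: List[str] = []
    meta_rows: List[dict] = []
    ss = np.random.SeedSequence([cfg.seed, 0xC0])
    children = ss.spawn(len(classes) * cfg.n_specimens_per_class)
    si = 0
    for cls in classes:
        a, b = cfg.at2_state_mix[cls]
        for j in range(cfg.n_specimens_per_class):
            rng = np.random.default_rng(children[si])
            specimen = f"{cls}_{j+1:02d}"
            p_fmo5 = rng.beta(a, b)
            n = cfg.cells_per_specimen
            types = rng.choice(type_names, size=n, p=type_p)
            states = np.full(n, "", dtype=object)
            at2 = types == AT2_TYPE
            states[at2] = np.where(
                rng.random(at2.sum()) < p_fmo5, STATE_FMO5, STATE_CFTR
            )
            libs = _draw_libsizes(rng, n, *cfg.libsize_lognormal)
            mat = np.empty((n, cfg.n_genes), dtype=np.int64)
            prop_cache: Dict[Tuple[str, str], np.ndarray] = {}
            for i in range(n):
                key = (types[i], states[i])
                if key not in prop_cache:
                    prop_cache[key] = model.mean_proportions(
                        types[i], states[i] if states[i] else None
                    )
                mat[i] = _sample_counts(rng, prop_cache[key], libs[i], cfg.nb_dispersion)
            blocks.append(sp.csc_matrix(mat.T))
            for i in range(n):
                cid = f"{specimen}_c{i+1:05d}"
                cell_ids.append(cid)
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "specimen": specimen,
                        "specimen_class": cls,
                        "cell_type": types[i],
                        "at2_state": states[i],
                        "true_p_fmo5": p_fmo5,
                    }
                )
            si += 1

    counts = sp.hstack(blocks, format="csr")
    truth = pd.DataFrame(meta_rows).set_index("cell_id", drop=False)
    meta = truth[["specimen", "specimen_class"]].copy()
    cm = CountMatrix(
        genes=model.genes,
        cells=np.array(cell_ids, dtype=object),
        counts=counts,
        cell_meta=meta,
    ).compute_qc_metrics()
    gt = GroundTruth(
        cell_truth=truth.reset_index(drop=True), gene_truth=model.gene_truth_frame()
    )
    return cm, gt


def generate_maturation_series(
    config: CohortConfig,
    stages: Sequence[str] = ("fetal", "birth", "6mo", "2yr"),
    program_size: int = 100,
    ramp_log_fold: float = 1.5,
    n_arrest_specimens: int = 0,
    specimens_per_stage: int = 2,
) -> Tuple[CountMatrix, GroundTruth]:
    """Staged series: per-type "on" programs rise and "off" programs fall.

    ``n_arrest_specimens`` extra specimens carry the final stage label but
    their expression is frozen at the second stage (disease-arrest model).
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    model = ExpressionModel(config)
    model.allocate_maturation_programs(program_size)
    cfg = config
    type_names = model.types
    type_p = np.array([cfg.cell_type_catalog[t] for t in type_names])
    n_stages = len(stages)

    jobs: List[Tuple[str, str, float, bool]] = []  # specimen, stage, stage_frac, arrested
    for s_i, stage in enumerate(stages):
        frac = s_i / (n_stages - 1)
        for j in range(specimens_per_stage):
            jobs.append((f"{stage}_{j+1:02d}", stage, frac, False))
    arrest_frac = 1.0 / (n_stages - 1)  # second stage
    for j in range(n_arrest_specimens):
        jobs.append((f"arrest_{j+1:02d}", stages[-1], arrest_frac, True))

    ss = np.random.SeedSequence([cfg.seed, 0xA7])
    children = ss.spawn(len(jobs))
    blocks: List[sp.csc_matrix] = []
    cell_ids: List[str] = []
    meta_rows: List[dict] = []
    for (specimen, stage, frac, arrested), child in zip(jobs, children):
        rng = np.random.default_rng(child)
        n = cfg.cells_per_specimen
        types = rng.choice(type_names, size=n, p=type_p)
        states = np.full(n, "", dtype=object)
        at2 = types == AT2_TYPE
        states[at2] = np.where(rng.random(at2.sum()) < 0.5, STATE_FMO5, STATE_CFTR)
        libs = _draw_libsizes(rng, n, *cfg.libsize_lognormal)
        mat = np.empty((n, cfg.n_genes), dtype=np.int64)
        prop_cache: Dict[Tuple[str, str], np.ndarray] = {}
        for i in range(n):
            key = (types[i], states[i])
            if key not in prop_cache:
                prop_cache[key] = model.mean_proportions(
                    types[i],
                    states[i] if states[i] else None,
                    stage_frac=frac,
                    ramp_log_fold=ramp_log_fold,
                )
            mat[i] = _sample_counts(rng, prop_cache[key], libs[i], cfg.nb_dispersion)
        blocks.append(sp.csc_matrix(mat.T))
        for i in range(n):
            cid = f"{specimen}_c{i+1:05d}"
            cell_ids.append(cid)
            meta_rows.append(
                {
                    "cell_id": cid,
                    "specimen": specimen,
                    "stage": stage,
                    "cell_type": types[i],
                    "at2_state": states[i],
                    "arrested": arrested,
                }
            )

    counts = sp.hstack(blocks, format="csr")
    truth = pd.DataFrame(meta_rows)
    meta = truth.set_index("cell_id", drop=False)[["specimen", "stage", "cell_type"]]
    cm = CountMatrix(
        genes=model.genes,
        cells=np.array(cell_ids, dtype=object),
        counts=counts,
        cell_meta=meta,
    ).compute_qc_metrics()
    gt = GroundTruth(cell_truth=truth, gene_truth=model.gene_truth_frame())
    return cm, gt


# ---------------------------------------------------------------------------
# Spatial sections
# ---------------------------------------------------------------------------


def _hardcore_points(
    rng: np.random.Generator,
    n: int,
    extent: Tuple[float, float],
    spacing: float,
    max_attempts_factor: int = 200,
) -> np.ndarray:
    """Dart-throwing hard-core point process on a bucket grid."""
    w, h = extent
    cell = spacing
    nx, ny = int(w // cell) + 1, int(h // cell) + 1
    grid: Dict[Tuple[int, int], List[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = max_attempts_factor * n
    sp2 = spacing * spacing
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} points with spacing {spacing} in {extent} "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        p = rng.random(2) * (w, h)
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    d = pts[j] - p
                    if d[0] * d[0] + d[1] * d[1] < sp2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    return pts


def _assign_regions(
    rng: np.random.Generator,
    pts: np.ndarray,
    region_names: List[str],
    config: SpatialConfig,
) -> np.ndarray:
    if config.region_layout == "segregated":
        w, h = config.section_extent_um
        anchors = []
        owner = []
        for r_i, name in enumerate(region_names):
            a = rng.random((config.anchors_per_region, 2)) * (w, h)
            anchors.append(a)
            owner.extend([r_i] * len(a))
        anchors = np.vstack(anchors)
        owner = np.array(owner)
        d2 = ((pts[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        return np.array(region_names, dtype=object)[owner[d2.argmin(axis=1)]]
    # salt_and_pepper: independent region per grid patch
    w, h = config.section_extent_um
    ps = config.patch_size_um
    nx = int(np.ceil(w / ps))
    ny = int(np.ceil(h / ps))
    patch_region = rng.integers(0, len(region_names), size=(nx, ny))
    ix = np.minimum((pts[:, 0] // ps).astype(int), nx - 1)
    iy = np.minimum((pts[:, 1] // ps).astype(int), ny - 1)
    return np.array(region_names, dtype=object)[patch_region[ix, iy]]


def _spatial_label_props(
    model: ExpressionModel, label: str, panel_idx: np.ndarray
) -> np.ndarray:
    """Panel-restricted expected proportions for a spatial label.

    Labels ``AT2_FMO5`` / ``AT2_CFTR`` map to the AT2 type in each state.
    """
    if label == "AT2_FMO5":
        mu = model.mean_proportions(AT2_TYPE, STATE_FMO5)
    elif label == "AT2_CFTR":
        mu = model.mean_proportions(AT2_TYPE, STATE_CFTR)
    else:
        mu = model.mean_proportions(label)
    sub = mu[panel_idx]
    return sub / sub.sum()


def default_panel_genes(model: ExpressionModel, per_type: int = 10) -> List[str]:
    """Targeted panel: leading markers of each type plus AT2-state genes."""
    idx: List[int] = []
    for t in model.types:
        idx.extend(model.markers[t][:per_type].tolist())
    idx.extend(model.state_genes[STATE_FMO5][:per_type].tolist())
    idx.extend(model.state_genes[STATE_CFTR][:per_type].tolist())
    return [model.genes[i] for i in sorted(set(idx))]


def state_panel_genes(model: ExpressionModel, per_state: int = 10) -> Dict[str, List[str]]:
    return {
        STATE_FMO5: [model.genes[i] for i in model.state_genes[STATE_FMO5][:per_state]],
        STATE_CFTR: [model.genes[i] for i in model.state_genes[STATE_CFTR][:per_state]],
    }


def generate_spatial_sections(
    config: SpatialConfig,
    cohort_config: Optional[CohortConfig] = None,
) -> Tuple[List[SpatialCellMap], GroundTruth]:
    """Simulate spatial sections with planted regions and panel counts."""
    if config.cells_per_section <= 0:
        raise ValueError("cells_per_section must be positive")
    cohort_config = cohort_config or CohortConfig(seed=config.seed)
    model = ExpressionModel(cohort_config)
    catalog = (
        config.region_catalog if config.region_catalog is not None else default_region_catalog()
    )
    region_names = list(catalog)
    panel = (
        config.panel_genes
        if config.panel_genes is not None
        else default_panel_genes(model)
    )
    gidx = {g: i for i, g in enumerate(model.genes)}
    missing = [g for g in panel if g not in gidx]
    if missing:
        raise ValueError(f"panel genes not in gene universe: {missing[:5]}")
    panel_idx = np.array([gidx[g] for g in panel])

    sections: List[SpatialCellMap] = []
    region_rows: List[dict] = []
    ss = np.random.SeedSequence([config.seed, 0x5A])
    children = ss.spawn(config.n_sections)
    for s_i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sec = f"S{s_i+1}"
        pts = _hardcore_points(
            rng, config.cells_per_section, config.section_extent_um, config.min_spacing_um
        )
        regions = _assign_regions(rng, pts, region_names, config)
        labels = np.empty(len(pts), dtype=object)
        for name in region_names:
            m = regions == name
            comp = catalog[name]
            lab_names = list(comp)
            lab_p = np.array([comp[l] for l in lab_names], dtype=float)
            lab_p = lab_p / lab_p.sum()
            labels[m] = rng.choice(np.array(lab_names, dtype=object), size=m.sum(), p=lab_p)

        prop_cache: Dict[str, np.ndarray] = {}
        counts = np.empty((len(pts), len(panel)), dtype=np.int64)
        libs = np.maximum(
            1, rng.poisson(config.panel_mean_counts, size=len(pts))
        )
        for i in range(len(pts)):
            lab = labels[i]
            if lab not in prop_cache:
                prop_cache[lab] = _spatial_label_props(model, lab, panel_idx)
            counts[i] = rng.multinomial(libs[i], prop_cache[lab])

        cell_ids = [f"{sec}_c{i+1:05d}" for i in range(len(pts))]
        df = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "label": labels,
            }
        )
        sections.append(
            SpatialCellMap(
                section_id=sec,
                cells=df,
                panel_genes=np.array(panel, dtype=object),
                panel_counts=sp.csr_matrix(counts.T),
            )
        )
        for cid, reg in zip(cell_ids, regions):
            region_rows.append({"cell_id": cid, "section_id": sec, "region": reg})

    gt = GroundTruth(
        cell_truth=pd.DataFrame(
            {
                "cell_id": [r["cell_id"] for r in region_rows],
                "specimen": [r["section_id"] for r in region_rows],
            }
        ),
        gene_truth=model.gene_truth_frame(),
        region_truth=pd.DataFrame(region_rows),
    )
    return sections, gt
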