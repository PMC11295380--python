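"""Synthetic multi-patient HCC cohorts with known malignant-cell subtypes.

The generator emulates the statistical structure the downstream analysis
assumes: every tumor cell carries one of three expression programs
(metabolism / proliferation / EMT-stemness), each sample holds a roughly
stable proliferative fraction, and the remaining cells split between the
metabolism and EMT programs with the dominant side shared by all samples of
one patient. Counts follow a negative-binomial model with log-normal library
sizes, designated mitochondrial genes, and a configurable fraction of
low-quality cells placed deliberately on the wrong side of the QC thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import ConfigError, check_count, check_fraction, substream

SUBTYPES = ("metab", "prol", "emt")

# Marker symbols the scoring operations rely on; always present in the panel.
METAB_MARKERS = ("ARG1", "ALDOB")
PROL_MARKERS = ("TOP2A", "STMN1", "MKI67")
EMT_MARKERS = ("S100A6", "S100A11", "EPCAM", "CD24", "KRT19", "SOX9",
               "PROM1", "CD44", "THY1", "CD47")

# Cell-line mutation frequencies used as simulation defaults for the panel.
DEFAULT_MUTATION_RATES = {
    "TP53": {"metab": 5 / 9, "emt": 16 / 22},
    "CTNNB1": {"metab": 2 / 9, "emt": 2 / 22},
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic cohort generator.

    ``program_log_fc`` is the natural-log elevation of a program's marker
    genes in cells of that subtype. ``dominance_strength`` is the share of
    non-proliferative cells given to the patient's dominant terminal subtype
    (metab or emt); the rest go to the other one.
    """

    n_patients: int = 10
    samples_per_patient: int = 2
    cells_per_sample: int = 300
    n_genes: int = 1000
    n_marker_genes_per_program: int = 30
    program_log_fc: float = 2.0
    prol_fraction_mean: float = 0.2
    prol_fraction_kappa: float = 60.0
    dominance_strength: float = 0.85
    nb_dispersion: float = 2.0
    library_size_mean: int = 5000
    library_size_sigma: float = 0.3
    mito_gene_count: int = 10
    mito_fraction_mean: float = 0.05
    lowq_cell_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        check_count(self.n_patients, "n_patients")
        check_count(self.samples_per_patient, "samples_per_patient")
        check_count(self.cells_per_sample, "cells_per_sample")
        check_count(self.n_genes, "n_genes")
        check_count(self.n_marker_genes_per_program, "n_marker_genes_per_program",
                    minimum=len(EMT_MARKERS))
        check_count(self.library_size_mean, "library_size_mean")
        check_count(self.mito_gene_count, "mito_gene_count")
        check_fraction(self.prol_fraction_mean, "prol_fraction_mean",
                       lo_open=True, hi_open=True)
        check_fraction(self.dominance_strength, "dominance_strength",
                       lo=0.5, lo_open=True)
        check_fraction(self.lowq_cell_fraction, "lowq_cell_fraction")
        check_fraction(self.mito_fraction_mean, "mito_fraction_mean",
                       lo_open=True, hi_open=True)
        if self.program_log_fc < 0:
            raise ConfigError(f"program_log_fc must be >= 0; got {self.program_log_fc}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0; got {self.nb_dispersion}")
        if self.prol_fraction_kappa <= 0:
            raise ConfigError(f"prol_fraction_kappa must be > 0; got {self.prol_fraction_kappa}")
        need = 3 * self.n_marker_genes_per_program + self.mito_gene_count
        if need > self.n_genes:
            raise ConfigError(
                f"n_genes ({self.n_genes}) must cover 3 x n_marker_genes_per_program"
                f" + mito_gene_count ({need})")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    cell_subtype: pd.Series           # cell id -> {metab, prol, emt}
    sample_dominance: pd.Series       # sample id -> {metab, emt}
    sample_composition: pd.DataFrame  # sample x (metab, prol, emt), rows sum to 1
    program_genes: dict[str, list[str]]
    lowq_cells: pd.Index
    config_echo: SynthConfig


def _gene_panel(cfg: SynthConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    m = cfg.n_marker_genes_per_program
    programs = {
        "metab": list(METAB_MARKERS) + [f"METABG{i:03d}" for i in range(len(METAB_MARKERS), m)],
        "prol": list(PROL_MARKERS) + [f"PROLG{i:03d}" for i in range(len(PROL_MARKERS), m)],
        "emt": list(EMT_MARKERS) + [f"EMTG{i:03d}" for i in range(len(EMT_MARKERS), m)],
    }
    mito = [f"MT-SIM{i:02d}" for i in range(cfg.mito_gene_count)]
    n_fill = cfg.n_genes - 3 * m - cfg.mito_gene_count
    fillers = [f"GENE{i:05d}" for i in range(n_fill)]
    genes = programs["metab"] + programs["prol"] + programs["emt"] + fillers + mito
    return genes, programs, mito


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draw as a gamma-Poisson mixture (theta = size)."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def generate_cohort(cfg: SynthConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a multi-patient tumor-cell cohort with known subtype labels.

    Returns an AnnData of integer counts (cells x genes, sparse) whose ``obs``
    carries sample/patient assignments and QC covariates, plus the
    :class:`SyntheticTruth` needed for recovery tests.
    """
    genes, programs, mito_genes = _gene_panel(cfg)
    gene_index = pd.Index(genes)
    non_mito = ~gene_index.isin(mito_genes)

    rng_genes = substream(cfg.seed, "baseline")
    base_log_mean = rng_genes.normal(0.0, 1.0, size=cfg.n_genes)

    program_boost = {}
    for s in SUBTYPES:
        boost = np.zeros(cfg.n_genes)
        boost[gene_index.isin(programs[s])] = cfg.program_log_fc
        program_boost[s] = boost

    rng_dom = substream(cfg.seed, "dominance")
    rng_prol = substream(cfg.seed, "prol_fraction")
    rng_lab = substream(cfg.seed, "labels")
    rng_lib = substream(cfg.seed, "library")
    rng_mito = substream(cfg.seed, "mito")
    rng_lowq = substream(cfg.seed, "lowq")
    rng_counts = substream(cfg.seed, "counts")

    a, b = (cfg.prol_fraction_mean * cfg.prol_fraction_kappa,
            (1 - cfg.prol_fraction_mean) * cfg.prol_fraction_kappa)
    mito_a = 2.0
    mito_b = mito_a * (1 - cfg.mito_fraction_mean) / cfg.mito_fraction_mean

    rows = []
    labels_all: list[str] = []
    cell_ids: list[str] = []
    sample_ids: list[str] = []
    patient_ids: list[str] = []
    lowq_ids: list[str] = []
    dominance = {}
    composition = {}

    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        dom = "metab" if rng_dom.random() < 0.5 else "emt"
        other = "emt" if dom == "metab" else "metab"
        for s in range(cfg.samples_per_patient):
            sample = f"{patient}S{s + 1}"
            dominance[sample] = dom
            prol_frac = rng_prol.beta(a, b)
            probs = {
                "prol": prol_frac,
                dom: (1 - prol_frac) * cfg.dominance_strength,
                other: (1 - prol_frac) * (1 - cfg.dominance_strength),
            }
            p_vec = np.array([probs[t] for t in SUBTYPES])
            labels = rng_lab.choice(len(SUBTYPES), size=cfg.cells_per_sample, p=p_vec)
            labels = [SUBTYPES[i] for i in labels]
            counts = pd.Series(labels).value_counts()
            composition[sample] = [counts.get(t, 0) / cfg.cells_per_sample for t in SUBTYPES]

            lib = rng_lib.lognormal(np.log(cfg.library_size_mean),
                                    cfg.library_size_sigma,
                                    size=cfg.cells_per_sample)
            mito_frac = rng_mito.beta(mito_a, mito_b, size=cfg.cells_per_sample)
            is_lowq = rng_lowq.random(cfg.cells_per_sample) < cfg.lowq_cell_fraction
            # low-quality cells: shrunken library (few detected genes) or
            # inflated mitochondrial mass, one of the two QC failure modes
            lowq_mode = rng_lowq.random(cfg.cells_per_sample) < 0.5
            lib = np.where(is_lowq & lowq_mode, rng_lowq.uniform(80, 400, cfg.cells_per_sample), lib)
            mito_frac = np.where(is_lowq & ~lowq_mode,
                                 rng_lowq.uniform(0.20, 0.40, cfg.cells_per_sample), mito_frac)

            log_mu = np.stack([base_log_mean + program_boost[t] for t in labels])
            w = np.exp(log_mu)
            w[:, ~non_mito] = 0.0
            p_gene = w / w.sum(axis=1, keepdims=True)
            mean = p_gene * (lib * (1 - mito_frac))[:, None]
            mito_mean = (lib * mito_frac)[:, None] / cfg.mito_gene_count
            mean[:, ~non_mito] = mito_mean
            block = _nb_counts(rng_counts, mean, cfg.nb_dispersion)
            rows.append(sp.csr_matrix(block))

            ids = [f"{sample}C{i + 1:04d}" for i in range(cfg.cells_per_sample)]
            cell_ids.extend(ids)
            sample_ids.extend([sample] * cfg.cells_per_sample)
            patient_ids.extend([patient] * cfg.cells_per_sample)
            labels_all.extend(labels)
            lowq_ids.extend(np.asarray(ids)[is_lowq])

    X = sp.vstack(rows).astype(np.int64)
    obs = pd.DataFrame(
        {"sample_id": sample_ids, "patient_id": patient_ids, "cell_class": "tumor"},
        index=pd.Index(cell_ids, name="cell_id"))
    obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(X[:, ~non_mito].sum(axis=1)).ravel()
    obs["mito_fraction"] = np.divide(mito_counts, totals, out=np.zeros_like(totals),
                                     where=totals > 0)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_index.rename("gene")))

    truth = SyntheticTruth(
        cell_subtype=pd.Series(labels_all, index=obs.index, name="subtype"),
        sample_dominance=pd.Series(dominance, name="dominance"),
        sample_composition=pd.DataFrame.from_dict(
            composition, orient="index", columns=list(SUBTYPES)),
        program_genes={k: list(v) for k, v in programs.items()},
        lowq_cells=pd.Index(lowq_ids, name="cell_id"),
        config_echo=cfg,
    )
    return adata, truth


def generate_cellline_panel(
    cfg: SynthConfig,
    n_lines_per_subtype: int,
    mutation_rates: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk cell-line panel split between metab and EMT programs.

    Returns a genes x lines log-expression table and a line annotation table
    with the true subtype and per-gene mutation flags drawn at the given
    per-subtype rates (defaults follow published HCC cell-line frequencies).
    """
    check_count(n_lines_per_subtype, "n_lines_per_subtype")
    rates = mutation_rates or DEFAULT_MUTATION_RATES
    genes, programs, _ = _gene_panel(cfg)
    gene_index = pd.Index(genes)
    rng = substream(cfg.seed, "celllines")
    base = rng.normal(0.0, 1.0, size=cfg.n_genes)

    cols, records = {}, []
    for subtype in ("metab", "emt"):
        boost = np.zeros(cfg.n_genes)
        boost[gene_index.isin(programs[subtype])] = cfg.program_log_fc
        for i in range(n_lines_per_subtype):
            line = f"{subtype.upper()}_L{i + 1:02d}"
            cols[line] = base + boost + rng.normal(0.0, noise_sd, size=cfg.n_genes)
            rec = {"line_id": line, "subtype": subtype}
            for gene, by_subtype in rates.items():
                rec[gene] = bool(rng.random() < by_subtype[subtype])
            records.append(rec)
    expr = pd.DataFrame(cols, index=gene_index)
    annot = pd.DataFrame.from_records(records).set_index("line_id")
    return expr, annot


def generate_spots(
    cohort: tuple[ad.AnnData, SyntheticTruth],
    n_spots: int,
    seed: int,
    max_cells_per_spot: int = 10,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Aggregate 1-10 cells from single samples into pseudo-spots.

    Mimics spatial spots, each of which captures a handful of adjacent cells;
    spot counts are exact sums of the contributing cells' count rows.
    """
    adata, truth = cohort
    if adata.n_obs == 0:
        raise ValueError("cohort is empty")
    check_count(n_spots, "n_spots")
    rng = substream(seed, "spots")
    samples = np.asarray(sorted(adata.obs["sample_id"].unique()))
    X = sp.csr_matrix(adata.X)

    spot_rows, records = [], []
    for i in range(n_spots):
        sample = samples[rng.integers(len(samples))]
        pool = np.flatnonzero((adata.obs["sample_id"] == sample).to_numpy())
        k = int(rng.integers(1, min(max_cells_per_spot, len(pool)) + 1))
        members = rng.choice(pool, size=k, replace=False)
        spot_rows.append(X[members].sum(axis=0))
        member_ids = adata.obs_names[members].tolist()
        subtype_counts = truth.cell_subtype.loc[member_ids].value_counts()
        rec = {"spot_id": f"SPOT{i + 1:05d}", "sample_id": sample, "n_cells": k,
               "members": member_ids}
        for t in SUBTYPES:
            rec[f"frac_{t}"] = subtype_counts.get(t, 0) / k
        records.append(rec)

    spot_truth = pd.DataFrame.from_records(records).set_index("spot_id")
    spots = ad.AnnData(
        X=sp.csr_matrix(np.asarray(np.vstack(spot_rows))),
        obs=spot_truth[["sample_id", "n_cells"]].copy(),
        var=adata.var.copy())
    return spots, spot_truth


def save_cohort(path: str | Path, adata: ad.AnnData, truth: SyntheticTruth) -> None:
    """Write a cohort as a Matrix Market bundle plus ``truth.json``."""
    from .io import write_mtx_bundle

    path = Path(path)
    write_mtx_bundle(adata, path)
    payload = {
        "cell_subtype": truth.cell_subtype.to_dict(),
        "sample_dominance": truth.sample_dominance.to_dict(),
        "sample_composition": {s: list(map(float, row))
                               for s, row in truth.sample_composition.iterrows()},
        "program_genes": truth.program_genes,
        "lowq_cells": truth.lowq_cells.tolist(),
        "config": dataclasses.asdict(truth.config_echo),
    }
    (path / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads((Path(path) / "truth.json").read_text())
    comp = pd.DataFrame.from_dict(payload["sample_composition"], orient="index",
                                  columns=list(SUBTYPES))
    return SyntheticTruth(
        cell_subtype=pd.Series(payload["cell_subtype"], name="subtype"),
        sample_dominance=pd.Series(payload["sample_dominance"], name="dominance"),
        sample_composition=comp,
        program_genes=payload["program_genes"],
        lowq_cells=pd.Index(payload["lowq_cells"], name="cell_id"),
        config_echo=SynthConfig(**payload["config"]),
    )
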