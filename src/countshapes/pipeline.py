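"""End-to-end orchestration: filter -> KS gate -> GLM fits -> selection ->
per-condition calls -> differential-distribution comparison.

Per-gene work is independent; each gene's Monte-Carlo stream is seeded from
the master seed combined with a stable hash of the gene name, so results do
not depend on execution order or worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .datamodel import CellDesign, CountMatrix
from .dd import extract_structural_zeros, identify_switches
from .filtering import filter_genes_by_condition, intersect_conditions
from .glm import build_design, check_zero_inflation, fit_all_families
from .io import compute_library_sizes, drop_empty_cells, write_results
from .ks import DegenerateDataError, ks_test_mc, select_zinb_family
from .selection import assign_distribution, bic

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    counts_path: str = ""
    metadata_path: str = ""
    counts_format: str = "10x"  # 10x | table
    condition: str = "condition"
    covariates: list[str] = field(default_factory=list)
    min_fraction: float = 0.10
    ks_alpha: float = 0.01
    adequacy_alpha: float = 0.05
    n_boot: int = 999
    offset_base: str = "e"
    fast_zero_screen: bool = False
    seed: int = 0
    workers: int = 1
    output_dir: str = "countshapes_output"

    def __post_init__(self):
        for name in ("ks_alpha", "adequacy_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def gene_seed(master_seed: int, gene: str) -> int:
    """Stable per-gene seed independent of gene order."""
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(gene.encode())) % (2**31 - 1)


def _gate_one(gene, y, n_boot, seed):
    try:
        res = ks_test_mc(y, n_boot=n_boot, seed=seed)
        return gene, res.statistic, res.pvalue, None
    except DegenerateDataError as exc:
        return gene, np.nan, np.nan, str(exc)


def run_ks_gate(
    matrix: CountMatrix,
    design: CellDesign,
    genes: list[str],
    n_boot: int = 999,
    alpha: float = 0.01,
    seed: int = 0,
    workers: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo KS gate per gene within each condition, BH-adjusted
    within condition; returns the per-gene KS table."""
    col_of = {c: j for j, c in enumerate(matrix.cells)}
    frames = []
    for cond in design.conditions:
        idx = [col_of[c] for c in design.cells_in(cond) if c in col_of]
        jobs = [
            delayed(_gate_one)(
                g, matrix.counts[matrix.genes.index(g)][idx], n_boot,
                gene_seed(seed, f"{cond}:{g}"),
            )
            for g in genes
        ]
        results = Parallel(n_jobs=workers)(jobs)
        rows = pd.DataFrame(results, columns=["gene", "D", "p", "failure"])
        ok = rows[rows["failure"].isna()]
        retained, adj = select_zinb_family(
            dict(zip(ok["gene"], ok["p"])), alpha=alpha
        )
        retained = set(retained)
        rows["condition"] = cond
        rows["p_adj"] = rows["gene"].map(adj)
        rows["retained"] = rows["gene"].map(lambda g: g in retained)
        frames.append(rows)
    table = pd.concat(frames, ignore_index=True)
    return table[["gene", "condition", "D", "p", "p_adj", "retained", "failure"]]


def classify_genes(
    matrix: CountMatrix,
    design: CellDesign,
    genes: list[str],
    adequacy_alpha: float = 0.05,
    offset_base: str = "e",
    fast_zero_screen: bool = False,
    workers: int = 1,
):
    """Fit the four families and assign a distribution label per gene within
    each condition.  Returns (calls table, fit table, fits dict)."""
    col_of = {c: j for j, c in enumerate(matrix.cells)}
    fit_rows, call_rows = [], []
    fits_store = {}

    def _one(gene, y, spec):
        fits = fit_all_families(y, spec, fast_zero_screen=fast_zero_screen)
        call = assign_distribution(fits, y, gene=gene, alpha=adequacy_alpha)
        return gene, fits, call

    for cond in design.conditions:
        cells = [c for c in design.cells_in(cond) if c in col_of]
        idx = [col_of[c] for c in cells]
        spec = build_design(design, covariate_names=design.covariates,
                            cells=cells, offset_base=offset_base)
        jobs = [
            delayed(_one)(g, matrix.counts[matrix.genes.index(g)][idx], spec)
            for g in genes
        ]
        for gene, fits, call in Parallel(n_jobs=workers)(jobs):
            call.condition = cond
            for fam, fit in fits.items():
                if fit is None:
                    continue
                fit_rows.append({
                    "gene": gene, "condition": cond, "family": fam,
                    "loglik": fit.loglik, "k": fit.k,
                    "BIC": bic(fit.loglik, fit.k, fit.n),
                    "omega": fit.omega, "phi": fit.phi,
                    "converged": fit.converged,
                })
                fits_store[(gene, cond, fam)] = fit
            call_rows.append({
                "gene": gene, "condition": cond, "label": call.label,
                "BIC_P": call.bic_all.get("P"), "BIC_NB": call.bic_all.get("NB"),
                "BIC_ZIP": call.bic_all.get("ZIP"), "BIC_ZINB": call.bic_all.get("ZINB"),
                "dev_p": call.adequacy.deviance_p,
                "zi_lrt_p": call.adequacy.lrt_p,
                "omega_hat": call.omega_hat,
            })
    calls = pd.DataFrame(call_rows)
    fit_table = pd.DataFrame(fit_rows)
    return calls, fit_table, fits_store


def analyze(
    matrix: CountMatrix,
    design: CellDesign,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full framework in memory; returns the output tables."""
    config = config or RunConfig()
    if "library_size" not in design.table.columns:
        design = design.attach_library_sizes(compute_library_sizes(matrix))
    matrix, design = drop_empty_cells(matrix, design)
    design.validate_against(matrix)

    report = filter_genes_by_condition(matrix, design, config.min_fraction)
    common = intersect_conditions(report)
    log.info("%d genes pass the %.0f%% prevalence filter in every condition",
             len(common), 100 * config.min_fraction)

    ks_table = run_ks_gate(
        matrix, design, common, n_boot=config.n_boot, alpha=config.ks_alpha,
        seed=config.seed, workers=config.workers,
    )
    by_gene = ks_table.groupby("gene")["retained"].all()
    gated = [g for g in common if bool(by_gene.get(g, False))]
    log.info("%d/%d genes retained by the KS family gate", len(gated), len(common))

    calls, fit_table, fits_store = classify_genes(
        matrix, design, gated,
        adequacy_alpha=config.adequacy_alpha,
        offset_base=config.offset_base,
        fast_zero_screen=config.fast_zero_screen,
        workers=config.workers,
    )

    outputs = {
        "filter_report": report.to_frame(),
        "ks_table": ks_table,
        "fit_table": fit_table,
        "calls": calls,
    }
    if not calls.empty and calls["condition"].nunique() >= 2:
        outputs["dd_table"] = identify_switches(calls, "global")
        counts_by_gene = {
            g: matrix.counts[matrix.genes.index(g)] for g in calls["gene"].unique()
        }
        fits_by_call = {
            (row["gene"], row["condition"]): fits_store.get(
                (row["gene"], row["condition"], row["label"])
            )
            for _, row in calls.iterrows()
            if row["label"] not in ("FAILED",)
        }
        outputs["structural_zeros"] = extract_structural_zeros(
            calls, counts_by_gene, fits_by_call
        )
    return outputs


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file run: read inputs, analyze, write all tables plus a JSON
    run-metadata sidecar.  Outputs are written via a temporary suffix and
    renamed on completion."""
    from .io import read_cell_metadata, read_counts_10x, read_counts_table

    if config.counts_format == "10x":
        matrix = read_counts_10x(config.counts_path)
    else:
        matrix = read_counts_table(config.counts_path)
    design = read_cell_metadata(
        config.metadata_path, condition=config.condition, covariates=config.covariates
    )
    design = design.subset([c for c in matrix.cells if c in set(design.cells)])

    outputs = analyze(matrix, design, config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in outputs.items():
        if table is None or table.empty:
            continue
        final = outdir / f"{name}.tsv"
        tmp = outdir / f"{name}.tsv.tmp"
        write_results(table, tmp)
        os.replace(tmp, final)
    meta = {
        "tool": "countshapes",
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return outdir
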