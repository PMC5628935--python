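"""End-to-end orchestration of the discovery -> replication analysis.

``run_discovery`` sequences LOD-prevalence exclusion, whole-cohort quantile
normalization, below-LOD reset, per-contrast univariate screening, and
(optionally) double cross-validation with permutation significance.
``run_replication`` projects each replication sample independently onto the
discovery reference, resets censored cells, applies the CI-based
replication-validation rule, and evaluates the transferred sPLS-DA models
(error rate, ROC/AUC).  ``report`` writes delimited result tables whose
header comments carry the seed and a config hash so every run is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import model_selection as ms
from . import preprocess as pp
from .contrasts import contrast_samples, get_contrast
from .data_io import NPXMatrix, align_annotations, write_cv_results, write_results
from .univariate import run_univariate, validate_in_replication

__all__ = ["RunConfig", "DiscoveryBundle", "ReplicationBundle", "run_discovery", "run_replication", "report"]

log = logging.getLogger("splsero")


@dataclass
class RunConfig:
    contrasts: tuple = ("CD_vs_HC", "UC_vs_HC")
    fc_threshold: float = 1.2
    q_threshold: float = 0.05
    prevalence_threshold: float = 0.80
    evenness_alpha: float = 0.05
    component_grid: tuple = ms.DEFAULT_COMPONENT_GRID
    cutoff_grid: tuple = ms.DEFAULT_CUTOFF_GRID
    inner_folds: int = 7
    B: int = 40
    seed: int = 0
    run_cv: bool = True
    run_permutation: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class DiscoveryBundle:
    matrix: NPXMatrix                 # retained proteins, normalized, LOD-reset
    annotations: pd.DataFrame
    exclusion: pd.DataFrame
    reference: pp.ReferenceDistribution
    univariate: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    config: RunConfig = field(default_factory=RunConfig)


@dataclass
class ReplicationBundle:
    matrix: NPXMatrix
    annotations: pd.DataFrame
    validation: dict = field(default_factory=dict)
    transfer: dict = field(default_factory=dict)


def _cv_xy(matrix: NPXMatrix, annot: pd.DataFrame, name: str):
    contrast = get_contrast(name)
    ids_a, ids_b = contrast_samples(annot.loc[annot.index.intersection(matrix.sample_ids)], contrast)
    ids = list(ids_a) + list(ids_b)
    X = matrix.values.loc[ids]
    y = [contrast.label_a] * len(ids_a) + [contrast.label_b] * len(ids_b)
    return X, pd.array(y).to_numpy(), contrast


def run_discovery(matrix: NPXMatrix, annot: pd.DataFrame, config: RunConfig | None = None) -> DiscoveryBundle:
    """Preprocess the discovery cohort and run its per-contrast analyses."""
    config = config or RunConfig()
    annot = align_annotations(matrix, annot)
    log.info("discovery: %d samples x %d proteins", matrix.n_samples, matrix.n_proteins)

    exclusion = pp.detect_excludable_proteins(
        matrix, annot,
        prevalence_threshold=config.prevalence_threshold,
        evenness_alpha=config.evenness_alpha,
    )
    dropped = exclusion.index[exclusion["excluded"]].tolist()
    retained = matrix.drop_proteins(dropped)
    log.info("excluded %d protein(s) by LOD prevalence: %s", len(dropped), dropped)

    normalized, reference = pp.quantile_normalize(retained)
    processed = pp.reset_below_lod(normalized)
    log.info("quantile-normalized %d samples; reference length %d",
             processed.n_samples, len(reference))

    bundle = DiscoveryBundle(
        matrix=processed, annotations=annot, exclusion=exclusion,
        reference=reference, config=config,
    )
    for name in config.contrasts:
        bundle.univariate[name] = run_univariate(
            processed, annot, name,
            fc_threshold=config.fc_threshold, q_threshold=config.q_threshold,
        )
        n_sig = int(bundle.univariate[name]["significant"].sum())
        log.info("univariate %s: %d significant protein(s)", name, n_sig)
        if config.run_cv:
            X, y, _ = _cv_xy(processed, annot, name)
            cv = ms.double_cv(
                X, y,
                component_grid=config.component_grid,
                cutoff_grid=config.cutoff_grid,
                inner_folds=config.inner_folds,
                seed=config.seed,
                contrast=name,
            )
            bundle.cv[name] = cv
            log.info("double CV %s: LOO error %.3f over %d samples",
                     name, cv.loo_error_rate, cv.n_samples)
            if config.run_permutation:
                bundle.permutation[name] = ms.permutation_pvalue(
                    X, y, B=config.B, seed=config.seed, observed=cv,
                    component_grid=config.component_grid,
                    cutoff_grid=config.cutoff_grid,
                    inner_folds=config.inner_folds,
                    contrast=name,
                )
                log.info("permutation %s: p %s (B=%d)", name,
                         bundle.permutation[name].p_label, config.B)
    return bundle


def run_replication(
    matrix: NPXMatrix, annot: pd.DataFrame, discovery: DiscoveryBundle,
    config: RunConfig | None = None,
) -> ReplicationBundle:
    """Project the replication cohort and validate/transfer every contrast."""
    config = config or discovery.config
    annot = align_annotations(matrix, annot)
    matrix = matrix.drop_proteins(
        [p for p in matrix.protein_ids if p not in set(discovery.matrix.protein_ids)]
    )
    projected = pp.project_matrix(matrix, discovery.reference)
    processed = pp.reset_below_lod(projected)
    log.info("replication: projected %d samples onto discovery reference",
             processed.n_samples)

    bundle = ReplicationBundle(matrix=processed, annotations=annot)
    for name, disc_table in discovery.univariate.items():
        bundle.validation[name] = validate_in_replication(
            disc_table, processed, annot, name
        )
        v = bundle.validation[name]["validated"]
        log.info("validation %s: %d/%d validated", name,
                 int(v.sum()), int(v.notna().sum()))
    if config.run_cv:
        for name in discovery.cv:
            Xd, yd, contrast = _cv_xy(discovery.matrix, discovery.annotations, name)
            Xr, yr, _ = _cv_xy(processed, annot, name)
            bundle.transfer[name] = ms.transfer_evaluate(
                Xd, yd, Xr[Xd.columns], yr,
                positive_class=contrast.label_a,
                component_grid=config.component_grid,
                cutoff_grid=config.cutoff_grid,
                inner_folds=config.inner_folds,
                seed=config.seed,
                contrast=name,
            )
            t = bundle.transfer[name]
            log.info("transfer %s: error %.3f, AUC %.3f", name, t.error_rate, t.auc)
    return bundle


def report(
    discovery: DiscoveryBundle,
    replication: ReplicationBundle | None,
    outdir: str | Path,
) -> list[Path]:
    """Write result tables; every file header carries seed and config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = discovery.config
    stamp = f"seed={config.seed} config_hash={config.config_hash()}"
    written: list[Path] = []

    path = outdir / "protein_exclusion.tsv"
    write_cv_results(discovery.exclusion.reset_index(drop=True), path, stamp)
    written.append(path)

    for name, table in discovery.univariate.items():
        table = table.copy()
        if replication is not None and name in replication.validation:
            table = replication.validation[name]
        path = outdir / f"univariate_{name}.tsv"
        write_results(table, path, stamp)
        written.append(path)

    if {"CD_vs_HC", "UC_vs_HC"} <= set(discovery.univariate):
        sig_cd = set(
            discovery.univariate["CD_vs_HC"].query("significant")["protein_id"]
        )
        sig_uc = set(
            discovery.univariate["UC_vs_HC"].query("significant")["protein_id"]
        )
        venn = pd.DataFrame(
            {
                "set": ["CD_only", "UC_only", "shared"],
                "count": [
                    len(sig_cd - sig_uc),
                    len(sig_uc - sig_cd),
                    len(sig_cd & sig_uc),
                ],
            }
        )
        path = outdir / "venn_counts.tsv"
        write_cv_results(venn, path, stamp)
        written.append(path)

    if discovery.cv:
        rows = []
        for name, cv in discovery.cv.items():
            row = {"contrast": name, "loo_error_rate": cv.loo_error_rate,
                   "n_samples": cv.n_samples}
            if name in discovery.permutation:
                perm = discovery.permutation[name]
                row["permutation_p"] = perm.p_label
                row["B"] = perm.B
            rows.append(row)
        path = outdir / "double_cv_summary.tsv"
        write_cv_results(pd.DataFrame(rows), path, stamp)
        written.append(path)

    if replication is not None and replication.transfer:
        rows = []
        for name, t in replication.transfer.items():
            rows.append(
                {
                    "contrast": name,
                    "replication_error_rate": t.error_rate,
                    "auc": t.auc,
                    "positive_class": t.positive_class,
                    "n_components": t.n_components,
                    "vip_cutoff": t.cutoff,
                    "n_proteins": len(t.selected_proteins),
                }
            )
            roc_path = outdir / f"roc_{name}.tsv"
            write_cv_results(t.roc, roc_path, stamp)
            written.append(roc_path)
        path = outdir / "transfer_summary.tsv"
        write_cv_results(pd.DataFrame(rows), path, stamp)
        written.append(path)

    ref_path = outdir / "reference_distribution.tsv"
    discovery.reference.save(ref_path)
    written.append(ref_path)
    return written
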