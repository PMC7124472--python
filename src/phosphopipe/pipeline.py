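"""End-to-end driver: peptide records to per-strain contrast tables and
annotated phospho-sites.

Order of operations: remove decoys/contaminants, keep phospho-peptides,
log2-transform, drop peptides with more than one missing value in any
replicate triplet, calibrate the sibling error model, impute, quantile
normalize, fit the global linear model with a batch term, shrink variances
(empirical Bayes) and test the treated-vs-mock contrast per strain with
per-strain BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import diffstats, impute, mq_io, sitemap
from .impute import ErrorModel, SiblingPair
from .mq_io import LogIntensityMatrix, PeptideRecord


@dataclass
class PipelineResult:
    records: list[PeptideRecord]  # retained phospho records
    matrix: LogIntensityMatrix  # log2, after missingness filter
    retained_fraction: float
    sibling_pairs: list[SiblingPair]
    error_model: ErrorModel
    imputed: LogIntensityMatrix
    normalized: pd.DataFrame
    fit: diffstats.LinearFit
    prior: diffstats.EBayesPrior
    contrasts: pd.DataFrame  # all strains, per-strain BH families


def run_differential_analysis(
    records: Sequence[PeptideRecord],
    design: pd.DataFrame,
    seed: int,
    alpha: float = 0.05,
    min_sibling_obs: int = 30,
    max_missed_gap: int = 1,
    batch_column: str = "batch",
    scope: str = "every",
) -> PipelineResult:
    design = mq_io.validate_design(design)
    clean = mq_io.select_phospho(mq_io.filter_contaminants_decoys(records))
    matrix = mq_io.build_log2_matrix(clean, design)
    filt = impute.filter_by_missingness(matrix, scope=scope)
    retained_ids = set(filt.matrix.values.index)
    retained = [r for r in clean if r.peptide_id in retained_ids]
    pairs = impute.find_sibling_pairs(
        retained, max_missed_gap=max_missed_gap
    )
    model = impute.estimate_error_model(
        filt.matrix, pairs, min_obs=min_sibling_obs
    )
    imputed = impute.impute(filt.matrix, model, seed=seed)
    normalized = diffstats.quantile_normalize(imputed.values)
    X = diffstats.build_design_matrix(design, batch_column=batch_column)
    fit = diffstats.fit_linear_model(normalized, X)
    prior = diffstats.estimate_prior(fit.s2.to_numpy(), fit.df_resid)
    strains = list(dict.fromkeys(design["strain"]))
    contrasts = diffstats.run_contrasts(fit, prior, strains)
    return PipelineResult(
        records=retained,
        matrix=filt.matrix,
        retained_fraction=filt.retained_fraction,
        sibling_pairs=pairs,
        error_model=model,
        imputed=imputed,
        normalized=normalized,
        fit=fit,
        prior=prior,
        contrasts=contrasts,
    )


def annotate_sites(
    result: PipelineResult, proteome: Mapping[str, str]
) -> list[sitemap.PhosphoSiteAssignment]:
    """Map the retained phospho-peptides to de-duplicated, motif-annotated
    protein sites (best-localization representative per site)."""
    assignments = sitemap.map_sites(result.records, proteome)
    resolved = sitemap.resolve_best_isoform(assignments)
    return sitemap.annotate_windows(resolved, proteome)
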