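"""Sibling-peptide missing-value model for label-free phospho-proteomics.

MS1 missing values are missing-not-at-random: low-abundance species drop out
preferentially, and the value that went missing tends to sit slightly below
the mean of its two observed replicate siblings.  The model imputes a single
missing value within a replicate triplet as

    I_{P,S,i} = alpha_{P,S,i} + N(mu, sigma)

where ``alpha`` is the mean of the two observed replicates of peptide P in
sample S, and the Gaussian error term is calibrated on *sibling peptides*:
pairs where one sequence is an N- or C-terminal tryptic extension of the
other (a missed-cleavage variant) carrying the same modifications.  Because
trypsin efficiency should not depend on the biological condition, siblings
share an expression profile, so a fully observed sibling reveals what the
missing replicate of its partner would have looked like.

Peptides with two or three missing values in any replicate triplet are
excluded before imputation: with a single remaining observation the error of
the reconstruction grows enough to inflate false positives downstream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ContractError
from .mq_io import LogIntensityMatrix, PeptideRecord

logger = logging.getLogger(__name__)

_TRYPTIC = frozenset("KR")


@dataclass(frozen=True)
class SiblingPair:
    """A missed-cleavage pair: ``short`` extended N- or C-terminally to ``long``."""

    short_id: str
    long_id: str
    kind: Literal["N", "C"]  # side of the extension on the long peptide
    missed_gap: int  # extra missed cleavages of the long form


@dataclass
class ErrorModel:
    """Gaussian error term of the imputation model plus diagnostics."""

    mu: float
    sigma: float
    n_obs: int
    bias_t: float
    bias_p: float
    fallback: bool = False


def n_missed_cleavages(sequence: str) -> int:
    """Internal K/R count (Trypsin/P: every K/R except a C-terminal one cleaves)."""
    return sum(1 for c in sequence[:-1] if c in _TRYPTIC)


def _mods_key(mods) -> frozenset:
    return frozenset(mods)


def _shifted(mods, k: int) -> frozenset:
    return frozenset((name, pos + k) for name, pos in mods)


def find_sibling_pairs(
    records: Sequence[PeptideRecord],
    max_missed_gap: int = 1,
) -> list[SiblingPair]:
    """Enumerate sibling pairs among ``records``.

    A pair qualifies when the short sequence is a proper prefix (C-terminal
    extension) or suffix (N-terminal extension) of the long one, the junction
    falls after a K/R (tryptic), both map to the same leading protein, the
    modifications coincide on the shared residues and the extension segment
    is unmodified.  Each unordered pair is reported once.
    """
    by_seq: dict[tuple[str, str], list[PeptideRecord]] = {}
    for r in records:
        by_seq.setdefault((r.leading_protein, r.sequence), []).append(r)

    pairs: dict[frozenset, SiblingPair] = {}
    for long_rec in records:
        seq = long_rec.sequence
        cuts = [j for j, c in enumerate(seq[:-1]) if c in _TRYPTIC]
        for j in cuts:
            # C-terminal extension: candidate short = prefix ending at the cut
            prefix = seq[: j + 1]
            for short_rec in by_seq.get(
                (long_rec.leading_protein, prefix), ()
            ):
                gap = n_missed_cleavages(seq) - n_missed_cleavages(prefix)
                if not (1 <= gap <= max_missed_gap):
                    continue
                if _mods_key(short_rec.modifications) != _mods_key(
                    long_rec.modifications
                ):
                    continue
                _add_pair(pairs, short_rec, long_rec, "C", gap)
            # N-terminal extension: candidate short = suffix after the cut
            suffix = seq[j + 1:]
            shift = j + 1
            for short_rec in by_seq.get(
                (long_rec.leading_protein, suffix), ()
            ):
                gap = n_missed_cleavages(seq) - n_missed_cleavages(suffix)
                if not (1 <= gap <= max_missed_gap):
                    continue
                if _shifted(short_rec.modifications, shift) != _mods_key(
                    long_rec.modifications
                ):
                    continue
                _add_pair(pairs, short_rec, long_rec, "N", gap)
    return sorted(
        pairs.values(), key=lambda p: (p.short_id, p.long_id, p.kind)
    )


def _add_pair(pairs, short_rec, long_rec, kind, gap) -> None:
    if short_rec.peptide_id == long_rec.peptide_id:
        return
    key = frozenset((short_rec.peptide_id, long_rec.peptide_id))
    if key not in pairs:
        pairs[key] = SiblingPair(
            short_rec.peptide_id, long_rec.peptide_id, kind, gap
        )


# ---------------------------------------------------------------------------
# missingness filter


@dataclass
class FilterResult:
    matrix: LogIntensityMatrix
    triplet_mask: pd.DataFrame  # peptides x groups, count of missing (0..3)
    retained_fraction: float


def filter_by_missingness(
    matrix: LogIntensityMatrix,
    max_missing: int = 1,
    replicates: int = 3,
    scope: Literal["every", "any"] = "every",
) -> FilterResult:
    """Keep peptides whose replicate triplets have at most ``max_missing``
    missing values.

    ``scope='every'`` (default, strict reading) requires the condition in
    every (strain, treatment) group; ``'any'`` requires it in at least one.
    """
    groups = matrix.group_columns()
    for g, cols in groups.items():
        if len(cols) != replicates:
            raise ConfigError(
                f"group {g} has {len(cols)} replicates, expected {replicates}"
            )
    miss = matrix.values.isna()
    mask = pd.DataFrame(
        {"|".join(g): miss[cols].sum(axis=1) for g, cols in groups.items()},
        index=matrix.values.index,
    )
    if scope == "every":
        keep = (mask <= max_missing).all(axis=1)
    elif scope == "any":
        keep = (mask <= max_missing).any(axis=1)
    else:
        raise ConfigError(f"unknown scope {scope!r}")
    retained = LogIntensityMatrix(matrix.values.loc[keep], matrix.design)
    frac = float(keep.mean()) if len(keep) else 0.0
    return FilterResult(retained, mask, frac)


# ---------------------------------------------------------------------------
# error-model estimation


def sibling_differences(
    matrix: LogIntensityMatrix, pairs: Sequence[SiblingPair]
) -> np.ndarray:
    """Collect the calibration differences I_{P',S,i} - alpha_{P',S,i}.

    For every peptide P with exactly one missing value at replicate i in
    sample S whose sibling P' is fully observed in S, the difference between
    the sibling's value at i and the mean of the sibling's values at the two
    replicates where P was observed estimates the error the imputation of P
    would commit.  Both orientations of each pair contribute.
    """
    groups = list(matrix.group_columns().values())
    values = matrix.values
    diffs: list[float] = []
    for pair in pairs:
        for pid, sid in (
            (pair.short_id, pair.long_id),
            (pair.long_id, pair.short_id),
        ):
            if pid not in values.index or sid not in values.index:
                continue
            p_row = values.loc[pid]
            s_row = values.loc[sid]
            for cols in groups:
                p = p_row[cols].to_numpy()
                s = s_row[cols].to_numpy()
                p_miss = np.isnan(p)
                if p_miss.sum() != 1 or np.isnan(s).any():
                    continue
                i = int(np.argmax(p_miss))
                obs = [k for k in range(len(cols)) if k != i]
                diffs.append(float(s[i] - s[obs].mean()))
    return np.asarray(diffs)


def _median_triplet_sd(matrix: LogIntensityMatrix) -> float:
    sds = []
    for cols in matrix.group_columns().values():
        block = matrix.values[cols].to_numpy()
        complete = ~np.isnan(block).any(axis=1)
        if complete.any():
            sds.append(block[complete].std(axis=1, ddof=1))
    if not sds:
        return 0.0
    return float(np.median(np.concatenate(sds)))


def estimate_error_model(
    matrix: LogIntensityMatrix,
    pairs: Sequence[SiblingPair],
    min_obs: int = 30,
) -> ErrorModel:
    """Estimate (mu, sigma) of the imputation error term from sibling pairs.

    mu and sigma are the sample mean and standard deviation of all collected
    sibling differences; ``bias_t``/``bias_p`` report a one-sample two-sided
    t test of those differences against zero (a significantly negative mean
    indicates that missing values sit below their triplet mean).  With fewer
    than ``min_obs`` differences the model falls back to mu = 0 and sigma =
    the median within-triplet standard deviation, with a logged warning.
    """
    diffs = sibling_differences(matrix, pairs)
    n = len(diffs)
    if n < max(min_obs, 2):
        logger.warning(
            "only %d sibling differences (< %d); falling back to mu=0, "
            "sigma=median within-triplet sd",
            n,
            min_obs,
        )
        return ErrorModel(
            mu=0.0,
            sigma=_median_triplet_sd(matrix),
            n_obs=n,
            bias_t=float("nan"),
            bias_p=float("nan"),
            fallback=True,
        )
    mu = float(diffs.mean())
    sigma = float(diffs.std(ddof=1))
    if sigma == 0.0:
        bias_t = 0.0 if mu == 0.0 else float("inf") * np.sign(mu)
        bias_p = 1.0 if mu == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
        bias_t, bias_p = float(t), float(p)
    return ErrorModel(mu=mu, sigma=sigma, n_obs=n, bias_t=bias_t,
                      bias_p=bias_p)


# ---------------------------------------------------------------------------
# imputation


def _cell_rng(seed: int, peptide_id: str, run_id: str) -> np.random.Generator:
    # counter-based per-cell stream: draws depend only on (seed, peptide, run),
    # so subsetting rows never shifts other imputations
    ss = np.random.SeedSequence(
        [
            int(seed) & 0x7FFFFFFF,
            zlib.crc32(peptide_id.encode()),
            zlib.crc32(run_id.encode()),
        ]
    )
    return np.random.default_rng(ss)


def impute(
    matrix: LogIntensityMatrix, model: ErrorModel, seed: int
) -> LogIntensityMatrix:
    """Fill every single-missing triplet cell with alpha + N(mu, sigma).

    ``alpha`` is the mean of the two observed replicate values.  Observed
    cells are untouched (bit-identical).  A triplet with two or more missing
    values violates the filter contract and raises :class:`ContractError`.
    """
    out = matrix.values.copy()
    groups = matrix.group_columns()
    arr = out.to_numpy()
    col_index = {c: j for j, c in enumerate(out.columns)}
    for cols in groups.values():
        jj = [col_index[c] for c in cols]
        block = arr[:, jj]
        miss = np.isnan(block)
        counts = miss.sum(axis=1)
        if (counts > 1).any():
            bad = out.index[counts > 1][0]
            raise ContractError(
                f"peptide {bad!r} has >1 missing value in a triplet; "
                "run filter_by_missingness first"
            )
        for i in np.flatnonzero(counts == 1):
            k = int(np.argmax(miss[i]))
            obs = [m for m in range(len(jj)) if m != k]
            alpha = float(block[i, obs].mean())
            pid = str(out.index[i])
            run = cols[k]
            if model.sigma == 0.0:
                noise = model.mu
            else:
                noise = float(
                    _cell_rng(seed, pid, run).normal(model.mu, model.sigma)
                )
            arr[i, jj[k]] = alpha + noise
    out.iloc[:, :] = arr
    return LogIntensityMatrix(out, matrix.design)
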