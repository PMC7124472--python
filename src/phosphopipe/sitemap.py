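"""Phospho-site mapping, sequence windows, kinase consensus motifs,
logo-style binomial enrichment and cross-kinase overlap reports.

Phospho-peptides are located in their leading protein by exact substring
search; each phosphorylated residue becomes a (protein, 1-based position)
site.  When several peptides or positional isoforms report the same site,
the representative with the best localization score wins and the site is
listed once.  The sequence context is the 11-mer window from -5 to +5
around the phospho-acceptor, padded with ``_`` beyond the protein ends.

Consensus motifs of the basophilic AGC kinases are read off the window:
RxxS/T (R at -3), RRxS/T (R at -3 and -2, the classical PKA/Sch9 motif) and
RxRxxS/T (R at -5 and -3, the reported Ypk1 motif).  A padded ``_`` never
satisfies an R requirement.  Position-specific over/under-representation of
residues in a foreground site set against the background of all quantified
sites uses exact binomial tail probabilities, signed -log10(p) scores, in
the style of pLogo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MappingError
from .mq_io import PeptideRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_POSITIONS = tuple(range(-5, 6))  # index 5 is the phospho-acceptor
PAD = "_"


@dataclass(frozen=True)
class MotifFlags:
    """Arginine-anchor flags of an S/T window (R at -3 / -3,-2 / -5,-3)."""

    rxx: bool
    rrx: bool
    rxrxx: bool
    rxrrx: bool
    note: str = ""


@dataclass
class PhosphoSiteAssignment:
    protein: str
    position: int  # 1-based protein coordinate
    residue: str
    localization_score: float
    source_peptides: tuple[str, ...]
    window: str = ""
    flags: MotifFlags | None = None


def map_sites(
    records: Sequence[PeptideRecord], proteome: Mapping[str, str]
) -> list[PhosphoSiteAssignment]:
    """Map each phospho position of each peptide to a protein coordinate.

    The peptide is located at the first exact occurrence of its sequence in
    the leading protein; protein position = peptide start + phospho peptide
    position - 1 (both 1-based).
    """
    out = []
    for r in records:
        if r.n_phospho < 1:
            continue
        protein = proteome.get(r.leading_protein)
        if protein is None:
            raise MappingError(
                f"protein {r.leading_protein!r} of peptide "
                f"{r.peptide_id!r} not in proteome"
            )
        start0 = protein.find(r.sequence)
        if start0 < 0:
            raise MappingError(
                f"peptide {r.peptide_id!r} ({r.sequence}) not found in "
                f"{r.leading_protein!r}"
            )
        for pos in r.phospho_positions:
            out.append(
                PhosphoSiteAssignment(
                    protein=r.leading_protein,
                    position=start0 + pos,
                    residue=r.sequence[pos - 1],
                    localization_score=r.localization_score,
                    source_peptides=(r.peptide_id,),
                )
            )
    return out


def resolve_best_isoform(
    assignments: Sequence[PhosphoSiteAssignment],
) -> list[PhosphoSiteAssignment]:
    """Collapse duplicate (protein, position) entries to a single row.

    The representative is the assignment with the highest localization
    score (ties broken by lowest peptide id, deterministically); the merged
    row lists every contributing source peptide.
    """
    groups: dict[tuple[str, int], list[PhosphoSiteAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.protein, a.position), []).append(a)
    out = []
    for key in sorted(groups):
        members = groups[key]
        best = min(
            members,
            key=lambda a: (
                -(a.localization_score
                  if a.localization_score == a.localization_score else -1.0),
                min(a.source_peptides),
            ),
        )
        sources = tuple(
            sorted({p for a in members for p in a.source_peptides})
        )
        out.append(
            PhosphoSiteAssignment(
                protein=best.protein,
                position=best.position,
                residue=best.residue,
                localization_score=best.localization_score,
                source_peptides=sources,
                window=best.window,
                flags=best.flags,
            )
        )
    return out


def extract_window(
    proteome: Mapping[str, str], protein: str, position: int
) -> str:
    """11-mer context from -5 to +5 around ``position`` (1-based), padded
    with ``_`` where the window leaves the protein."""
    seq = proteome[protein]
    chars = []
    for off in WINDOW_POSITIONS:
        i = position - 1 + off
        chars.append(seq[i] if 0 <= i < len(seq) else PAD)
    return "".join(chars)


def classify_motifs(window: str) -> MotifFlags:
    """Read the arginine-anchor consensus flags off a -5..+5 window.

    The center must be S or T for any flag to be set; tyrosine (or any other
    center) yields all-false flags with a note.  ``_`` padding never counts
    as R.
    """
    if len(window) != 11:
        raise ValueError("window must be exactly 11 characters")
    center = window[5]
    if center not in "ST":
        return MotifFlags(False, False, False, False,
                          note=f"center {center!r} is not S/T")
    r3 = window[2] == "R"  # position -3
    r2 = window[3] == "R"  # position -2
    r5 = window[0] == "R"  # position -5
    rxx = r3
    rrx = r3 and r2
    rxrxx = r5 and r3
    return MotifFlags(rxx=rxx, rrx=rrx, rxrxx=rxrxx, rxrrx=rrx and rxrxx)


def annotate_windows(
    assignments: Sequence[PhosphoSiteAssignment],
    proteome: Mapping[str, str],
) -> list[PhosphoSiteAssignment]:
    """Attach windows and motif flags to site assignments (in place)."""
    for a in assignments:
        a.window = extract_window(proteome, a.protein, a.position)
        a.flags = classify_motifs(a.window)
    return list(assignments)


# ---------------------------------------------------------------------------
# foreground construction


def build_foreground(
    contrasts: pd.DataFrame,
    assignments: Sequence[PhosphoSiteAssignment],
    direction: Literal["hyper", "hypo", "union"],
    alpha: float = 0.05,
) -> set[tuple[str, int]]:
    """Sites of peptides significantly regulated in the given direction.

    A site inherits significance from any of its source peptides (union
    rule); ``hypo`` means logFC < 0 (reduced phosphorylation upon inhibitor
    treatment), ``hyper`` logFC > 0.
    """
    sig = contrasts[contrasts["p_adj"] < alpha]
    if direction == "hypo":
        sig = sig[sig["logFC"] < 0]
    elif direction == "hyper":
        sig = sig[sig["logFC"] > 0]
    elif direction != "union":
        raise ValueError(f"unknown direction {direction!r}")
    sig_ids = set(sig["peptide_id"])
    return {
        (a.protein, a.position)
        for a in assignments
        if sig_ids.intersection(a.source_peptides)
    }


# ---------------------------------------------------------------------------
# logo enrichment


@dataclass
class LogoMatrix:
    """Signed -log10 binomial tail scores per (residue, window position)."""

    scores: pd.DataFrame  # residues x positions (-5..-1, 1..5)
    n_foreground: int
    significance: float  # the score magnitude corresponding to alpha


def logo_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> LogoMatrix:
    """Position-specific residue enrichment of foreground windows against
    background frequencies, scored as signed -log10 exact binomial tails.

    For residue a at off-center position j with background frequency p0 and
    k of n foreground windows carrying a at j: over-representation uses
    P(X >= k), under-representation P(X <= k), X ~ Binomial(n, p0); the
    score is +(-log10 p) or -(-log10 p) respectively, and exactly 0 when
    k equals its expectation n*p0.  ``_`` pads are excluded from counts and
    from n at that position.
    """
    if not foreground:
        raise ValueError("empty foreground")
    positions = [p for p in WINDOW_POSITIONS if p != 0]
    scores = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=positions
    )
    for j, pos in zip([i for i in range(11) if i != 5], positions):
        bg_chars = [w[j] for w in background if w[j] != PAD]
        fg_chars = [w[j] for w in foreground if w[j] != PAD]
        n = len(fg_chars)
        if n == 0 or not bg_chars:
            continue
        bg_total = len(bg_chars)
        for aa in AMINO_ACIDS:
            p0 = sum(1 for c in bg_chars if c == aa) / bg_total
            k = sum(1 for c in fg_chars if c == aa)
            if p0 in (0.0, 1.0) or k == n * p0:
                scores.loc[aa, pos] = 0.0
                continue
            if k > n * p0:
                p = float(stats.binom.sf(k - 1, n, p0))
                scores.loc[aa, pos] = -np.log10(max(p, 1e-300))
            else:
                p = float(stats.binom.cdf(k, n, p0))
                scores.loc[aa, pos] = np.log10(max(p, 1e-300))
    m = len(positions) * len(AMINO_ACIDS)
    sig = -np.log10(alpha / m) if bonferroni else -np.log10(alpha)
    return LogoMatrix(scores=scores, n_foreground=len(foreground),
                      significance=float(sig))


# ---------------------------------------------------------------------------
# overlap and known-target reports


def overlap_sets(
    sets: Mapping[str, set],
    motif_filter: str | None = None,
    flags_by_item: Mapping[object, MotifFlags] | None = None,
) -> pd.DataFrame:
    """Venn-cell counts of named sets (every nonempty membership pattern).

    With ``motif_filter`` in {'rxx','rrx','rxrxx','rxrrx'} and a flag lookup,
    items are restricted to those carrying the motif.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two named sets")
    filtered = {}
    for name in names:
        items = sets[name]
        if motif_filter:
            if flags_by_item is None:
                raise ValueError("motif_filter requires flags_by_item")
            items = {
                x
                for x in items
                if x in flags_by_item
                and getattr(flags_by_item[x], motif_filter)
            }
        filtered[name] = set(items)
    universe = set().union(*filtered.values())
    cells: dict[tuple[bool, ...], int] = {}
    for item in universe:
        pattern = tuple(item in filtered[n] for n in names)
        cells[pattern] = cells.get(pattern, 0) + 1
    rows = []
    for pattern in sorted(cells, reverse=True):
        row = dict(zip(names, pattern))
        row["count"] = cells[pattern]
        rows.append(row)
    return pd.DataFrame(rows, columns=names + ["count"])


def crossref_known_targets(
    curated: pd.DataFrame,
    quantified_sites: set,
    significant_hypo: Mapping[str, set],
    proteome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tally curated kinase target sites against this study's site sets.

    ``curated`` has columns kinase, protein, position.  Per kinase the report
    counts known sites, those detected among the quantified sites, and those
    significantly hypo-phosphorylated upon inhibiting that kinase.  Rows
    naming a protein absent from the proteome are skipped with a warning.
    """
    rows = []
    for kinase, grp in curated.groupby("kinase", sort=False):
        n_known = 0
        n_detected = 0
        n_hypo = 0
        hypo = significant_hypo.get(kinase, set())
        for rec in grp.itertuples(index=False):
            if proteome is not None and rec.protein not in proteome:
                logger.warning(
                    "curated target %s %s%d: protein not in proteome; skipped",
                    kinase, rec.protein, rec.position,
                )
                continue
            n_known += 1
            site = (rec.protein, int(rec.position))
            if site in quantified_sites:
                n_detected += 1
                if site in hypo:
                    n_hypo += 1
        rows.append(
            {
                "kinase": kinase,
                "n_known": n_known,
                "n_detected": n_detected,
                "n_hypo_significant": n_hypo,
            }
        )
    return pd.DataFrame(rows)


def sites_table(
    assignments: Sequence[PhosphoSiteAssignment],
) -> pd.DataFrame:
    """Flat result table of resolved, annotated sites."""
    rows = []
    for a in assignments:
        f = a.flags or MotifFlags(False, False, False, False)
        rows.append(
            {
                "protein": a.protein,
                "position": a.position,
                "residue": a.residue,
                "localization_score": a.localization_score,
                "window": a.window,
                "rxx": f.rxx,
                "rrx": f.rrx,
                "rxrxx": f.rxrxx,
                "rxrrx": f.rxrrx,
                "source_peptides": ";".join(a.source_peptides),
            }
        )
    return pd.DataFrame(rows)
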