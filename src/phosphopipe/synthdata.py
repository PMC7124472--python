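"""Synthetic MaxQuant-style data with the statistical structure the
analysis assumes.

The generator builds a proteome from planned tryptic segments (interior
residues drawn from an 18-letter alphabet without K/R, a K/R terminal), so
an in-silico Trypsin/P digest recovers the planned peptides exactly.  Kinase
consensus contexts are planted at segment junctions: because trypsin cleaves
after every K and R, the arginine anchors of RRxS/T and RxRxxS/T motifs are
realized as short spacer segments and forced R terminals of the preceding
segment, exactly as basic motifs fragment in real tryptic digests.

Emitted per phospho-peptide: a log2 baseline intensity, a planted kinase
effect (applied only in the drug condition of the responsible strain, on
motif-bearing sites), a batch shift per replicate, Gaussian replicate noise,
and a missed-cleavage sibling for a configurable fraction of peptides
(longer siblings are dimmer, as in real MS1 data).  Missingness is
intensity-dependent (logistic in log2 intensity) with a small negative bias
of the values that go missing.

The bias is injected at the sibling-family level: when a flagged cell is
the single missing value of a member's replicate triplet, one shared draw
from N(mu_miss, sigma_miss) replaces the replicate deviation of *every*
family member at that (sample, replicate), anchored at each member's mean
of the other two replicates.  Triplets losing two or more values are
deleted without injection; the downstream filter discards them and neither
the calibration nor the imputation ever sees them.  This is what makes the bias recoverable: the calibration
procedure never sees the deleted value, only the fully observed sibling,
which must therefore carry the same deviation.  The deleted value itself
then follows the imputation model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import mq_io
from .errors import ConfigError
from .mq_io import (
    DEFAULT_STRAINS,
    PHOSPHO_MOD,
    LogIntensityMatrix,
    PeptideRecord,
    make_design,
)

INTERIOR_FREQS = {
    "A": 0.09, "C": 0.01, "D": 0.07, "E": 0.07, "F": 0.05, "G": 0.06,
    "H": 0.02, "I": 0.07, "L": 0.11, "M": 0.02, "N": 0.07, "P": 0.05,
    "Q": 0.04, "S": 0.10, "T": 0.06, "V": 0.06, "W": 0.01, "Y": 0.04,
}

MOTIF_CLASSES = ("plain", "rrx", "rxrxx", "rxrrx")


def _default_effects() -> dict[str, dict[str, float]]:
    rrx_kinase = {"rrx": -1.0, "rxrrx": -1.0}
    return {
        "wt_as": {},
        "pka_as": dict(rrx_kinase),
        "sch9_as": dict(rrx_kinase),
        "pka_sch9_as": dict(rrx_kinase),
        "ypk1_as": {"rxrxx": -1.0, "rxrrx": -1.0},
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the study's 30-run design."""

    n_proteins: int = 320
    segments_per_protein: int = 12
    segment_len: tuple[int, int] = (7, 14)
    residue_freqs: dict[str, float] = field(
        default_factory=lambda: dict(INTERIOR_FREQS)
    )
    p_terminal_r: float = 0.6
    phospho_fraction: float = 0.75
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"rrx": 0.06, "rxrxx": 0.06, "rxrrx": 0.01}
    )
    sibling_fraction: float = 0.35
    max_missed_cleavages: int = 2
    strains: tuple[str, ...] = DEFAULT_STRAINS
    replicates: int = 3
    effects: dict[str, dict[str, float]] = field(
        default_factory=_default_effects
    )
    baseline_mean: float = 23.0
    baseline_sd: float = 2.0
    sibling_offset: float = -1.5
    noise_sd: float = 0.25
    batch_shifts: tuple[float, ...] = (0.0, 0.3, -0.2)
    miss_slope: float = 0.8  # per log2 unit; missingness drops with intensity
    miss_intercept: float = 15.6
    mu_miss: float = -0.15
    sigma_miss: float = 0.4
    decoy_fraction: float = 0.01
    contaminant_fraction: float = 0.01

    def validate(self) -> None:
        for name in ("phospho_fraction", "sibling_fraction",
                     "decoy_fraction", "contaminant_fraction",
                     "p_terminal_r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.miss_slope < 0:
            raise ConfigError(
                "miss_slope must be >= 0 (missingness decreases with intensity)"
            )
        if sum(self.motif_mix.values()) > 1.0:
            raise ConfigError("motif_mix fractions exceed 1")
        if len(self.batch_shifts) != self.replicates:
            raise ConfigError("need one batch shift per replicate")
        if abs(sum(self.residue_freqs.values()) - 1.0) > 1e-6:
            raise ConfigError("residue frequencies must sum to 1")
        if set("KR") & set(self.residue_freqs):
            raise ConfigError("interior residue frequencies must exclude K/R")


def null_config(**overrides) -> SimConfig:
    """One unaffected strain, no planted effects: the false-positive setup."""
    cfg = SimConfig(
        n_proteins=250,
        strains=("wt_as",),
        effects={"wt_as": {}},
        **overrides,
    )
    return cfg


def small_config(**overrides) -> SimConfig:
    """A small single-strain dataset for repeated-simulation studies."""
    kwargs = dict(
        n_proteins=80,
        segments_per_protein=8,
        sibling_fraction=0.6,
        strains=("wt_as",),
        effects={"wt_as": {}},
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# proteome construction


@dataclass
class PlannedPeptide:
    peptide_id: str
    base_id: str  # id of the shortest family member
    protein: str
    start: int  # 1-based
    sequence: str
    phospho_pos: int | None  # 1-based in-peptide position
    motif_class: str | None
    site_position: int | None  # 1-based protein coordinate
    is_sibling: bool


@dataclass
class ProteomePlan:
    proteome: dict[str, str]
    peptides: list[PlannedPeptide]
    planted_sites: pd.DataFrame  # protein, position, residue, motif_class


def _draw_segment(rng, config: SimConfig) -> str:
    lo, hi = config.segment_len
    length = int(rng.integers(lo, hi + 1))
    letters = list(config.residue_freqs)
    probs = np.array(list(config.residue_freqs.values()))
    interior = rng.choice(letters, size=length - 1, p=probs)
    term = "R" if rng.random() < config.p_terminal_r else "K"
    return "".join(interior) + term


def generate_proteome(
    config: SimConfig, rng: np.random.Generator
) -> ProteomePlan:
    """Build random proteins from tryptic segments with planted motif
    contexts at recorded positions (deterministic under the generator)."""
    config.validate()
    classes = list(config.motif_mix)
    class_p = np.array([config.motif_mix[c] for c in classes])
    p_plain = 1.0 - class_p.sum()
    all_classes = classes + ["plain"]
    all_p = np.append(class_p, p_plain)

    proteome: dict[str, str] = {}
    peptides: list[PlannedPeptide] = []
    site_rows = []
    pep_counter = 0
    for ip in range(config.n_proteins):
        acc = f"SP{ip + 1:04d}"
        # plan main segments: phospho yes/no and motif class
        plan = []
        for k in range(config.segments_per_protein):
            if rng.random() < config.phospho_fraction:
                cls = str(rng.choice(all_classes, p=all_p))
                if cls != "plain" and k == 0:
                    cls = "plain"  # motif anchors need a preceding segment
            else:
                cls = None
            plan.append(cls)
        # build physical elements in order
        elements: list[tuple[str, str, int | None, str | None]] = []
        # (sequence, kind, phospho_pos, motif_class); kind in main/spacer
        main_seqs = []
        for k, cls in enumerate(plan):
            seq = _draw_segment(rng, config)
            if cls == "plain":
                pos = int(rng.integers(6, len(seq)))  # 1-based, not terminal
                res = "S" if rng.random() < 0.7 else "T"
                seq = seq[: pos - 1] + res + seq[pos:]
            elif cls in ("rrx", "rxrxx", "rxrrx"):
                res = "S" if rng.random() < 0.7 else "T"
                if cls == "rxrxx":
                    seq = seq[:2] + res + seq[3:]
                    pos = 3
                else:
                    seq = seq[:1] + res + seq[2:]
                    pos = 2
            else:
                pos = None
            main_seqs.append((seq, pos, cls))
        seqs_final = []
        for k, (seq, pos, cls) in enumerate(main_seqs):
            if (
                k + 1 < len(main_seqs)
                and main_seqs[k + 1][2] in ("rrx", "rxrxx", "rxrrx")
            ):
                seq = seq[:-1] + "R"  # next motif needs an R just upstream
            seqs_final.append((seq, pos, cls))
        letters = list(config.residue_freqs)
        probs = np.array(list(config.residue_freqs.values()))
        for k, (seq, pos, cls) in enumerate(seqs_final):
            if cls == "rrx":
                elements.append(("R", "spacer", None, None))
            elif cls == "rxrxx":
                y = str(rng.choice(letters, p=probs))
                elements.append((y + "R", "spacer", None, None))
            elif cls == "rxrrx":
                elements.append(("K", "spacer", None, None))
                elements.append(("R", "spacer", None, None))
                elements.append(("R", "spacer", None, None))
            elements.append((seq, "main", pos, cls))
        # concatenate and record coordinates
        offset = 0
        built: list[tuple[str, str, int | None, str | None, int]] = []
        for seq, kind, pos, cls in elements:
            built.append((seq, kind, pos, cls, offset + 1))
            offset += len(seq)
        proteome[acc] = "".join(b[0] for b in built)
        mains = [b for b in built if b[1] == "main"]
        for mi, (seq, _, pos, cls, start) in enumerate(mains):
            pep_counter += 1
            pid = f"pep{pep_counter:05d}"
            site = start + pos - 1 if pos is not None else None
            peptides.append(
                PlannedPeptide(
                    peptide_id=pid,
                    base_id=pid,
                    protein=acc,
                    start=start,
                    sequence=seq,
                    phospho_pos=pos,
                    motif_class=cls,
                    site_position=site,
                    is_sibling=False,
                )
            )
            if pos is not None:
                site_rows.append(
                    {
                        "protein": acc,
                        "position": site,
                        "residue": seq[pos - 1],
                        "motif_class": cls,
                    }
                )
        # siblings: extend a fraction of phospho mains by an adjacent
        # unmodified physical segment (missed-cleavage variant)
        main_indices = [i for i, b in enumerate(built) if b[1] == "main"]
        base_ids = {i: peptides[-len(mains) + j].peptide_id
                    for j, i in enumerate(main_indices)}
        for j, i in enumerate(main_indices):
            seq, _, pos, cls, start = built[i]
            if pos is None or rng.random() >= config.sibling_fraction:
                continue
            # the extension segment is emitted unmodified: a missed-cleavage
            # species carries its own modification state, so spanning a
            # neighboring phospho-capable segment without its phospho is a
            # legitimate sibling of the short form
            long_seq = None
            if i + 1 < len(built):
                ext = built[i + 1][0]
                if len(seq) + len(ext) <= 30:
                    long_seq = seq + ext
                    long_start, long_pos = start, pos
            if long_seq is None and i > 0:
                ext = built[i - 1][0]
                if len(seq) + len(ext) <= 30:
                    long_seq = ext + seq
                    long_start = built[i - 1][4]
                    long_pos = pos + len(ext)
            if long_seq is None:
                continue
            pep_counter += 1
            peptides.append(
                PlannedPeptide(
                    peptide_id=f"pep{pep_counter:05d}",
                    base_id=base_ids[i],
                    protein=acc,
                    start=long_start,
                    sequence=long_seq,
                    phospho_pos=long_pos,
                    motif_class=cls,
                    site_position=start + pos - 1,
                    is_sibling=True,
                )
            )
    planted = pd.DataFrame(
        site_rows, columns=["protein", "position", "residue", "motif_class"]
    )
    return ProteomePlan(proteome, peptides, planted)


# ---------------------------------------------------------------------------
# in-silico digestion


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 30,
) -> list[tuple[str, int, int]]:
    """Trypsin/P digest: cleave after every K/R (including before proline).

    Returns (peptide, 1-based start, missed cleavages) for every product
    with 0..``max_missed`` internal missed cleavages passing the length
    filter (pass ``min_len=1, max_len=None`` to disable it).
    """
    seq = sequence.upper()
    cuts = [0] + [i + 1 for i, c in enumerate(seq) if c in "KR"]
    if not cuts or cuts[-1] != len(seq):
        cuts.append(len(seq))
    out = []
    for a in range(len(cuts) - 1):
        for m in range(max_missed + 1):
            b = a + m + 1
            if b >= len(cuts):
                break
            pep = seq[cuts[a]: cuts[b]]
            if len(pep) < min_len:
                continue
            if max_len is not None and len(pep) > max_len:
                continue
            out.append((pep, cuts[a] + 1, m))
    return out


# ---------------------------------------------------------------------------
# intensities, missingness, emission


@dataclass
class SimDataset:
    """A complete simulated experiment plus its ground truth."""

    config: SimConfig
    seed: int
    design: pd.DataFrame
    proteome: dict[str, str]
    records: list[PeptideRecord]  # includes decoy/contaminant rows
    truth: pd.DataFrame  # one row per real peptide
    planted_sites: pd.DataFrame
    true_values: pd.DataFrame  # complete log2 matrix before the MNAR bias
    biased_values: pd.DataFrame  # after the family-level bias, pre-deletion
    observed: LogIntensityMatrix  # with NaN where values were deleted

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for row in self.truth.itertuples(index=False):
            fams.setdefault(row.base_id, []).append(row.peptide_id)
        return fams


def simulate_intensities(
    peptides: Sequence[PlannedPeptide],
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete true log2 matrix plus the per-peptide truth table."""
    run_ids = list(design["run_id"])
    n = len(peptides)
    baselines: dict[str, float] = {}
    rows = []
    values = np.empty((n, len(run_ids)))
    batch = np.array(
        [config.batch_shifts[r - 1] for r in design["replicate"]]
    )
    drug_mask = (design["treatment"] == "drug").to_numpy()
    strain_arr = design["strain"].to_numpy()
    for i, pep in enumerate(peptides):
        if pep.base_id not in baselines:
            baselines[pep.base_id] = float(
                rng.normal(config.baseline_mean, config.baseline_sd)
            )
        b = baselines[pep.base_id] + (
            config.sibling_offset if pep.is_sibling else 0.0
        )
        effects = {}
        for strain in config.strains:
            eff = 0.0
            if pep.motif_class is not None:
                eff = config.effects.get(strain, {}).get(pep.motif_class, 0.0)
            effects[strain] = eff
        eff_vec = np.array(
            [
                effects[s] if dm else 0.0
                for s, dm in zip(strain_arr, drug_mask)
            ]
        )
        values[i] = (
            b + batch + eff_vec
            + rng.normal(0.0, config.noise_sd, len(run_ids))
        )
        row = {
            "peptide_id": pep.peptide_id,
            "base_id": pep.base_id,
            "protein": pep.protein,
            "sequence": pep.sequence,
            "start": pep.start,
            "phospho_pos": pep.phospho_pos,
            "site_position": pep.site_position,
            "motif_class": pep.motif_class,
            "is_sibling": pep.is_sibling,
            "baseline": b,
        }
        for strain in config.strains:
            row[f"effect_{strain}"] = effects[strain]
        rows.append(row)
    true_values = pd.DataFrame(
        values,
        index=pd.Index([p.peptide_id for p in peptides], name="peptide_id"),
        columns=run_ids,
    )
    return true_values, pd.DataFrame(rows)


def apply_missingness(
    true_values: pd.DataFrame,
    design: pd.DataFrame,
    families: Mapping[str, Sequence[str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag cells missing with logistic(intercept - slope * intensity), inject
    the family-level negative bias at flagged replicates, and return
    (biased complete matrix, observed matrix with NaN at flagged cells)."""
    config.validate()
    arr = true_values.to_numpy().copy()
    p_miss = expit(config.miss_intercept - config.miss_slope * arr)
    flagged = rng.random(arr.shape) < p_miss
    row_index = {pid: i for i, pid in enumerate(true_values.index)}
    col_index = {c: j for j, c in enumerate(true_values.columns)}
    groups: dict[tuple[str, str], list[str]] = {}
    for run in design.sort_values("replicate", kind="mergesort").itertuples(
        index=False
    ):
        groups.setdefault((run.strain, run.treatment), []).append(run.run_id)
    for fam_members in families.values():
        ridx = [row_index[p] for p in fam_members if p in row_index]
        if not ridx:
            continue
        for cols in groups.values():
            jj = [col_index[c] for c in cols]
            fam_flags = flagged[np.ix_(ridx, jj)]
            if not fam_flags.any():
                continue
            base = arr[np.ix_(ridx, jj)].copy()
            # inject the shared deviation only for single-missing triplets:
            # those are the events the calibration and the imputation see;
            # triplets losing 2+ values are dropped by the filter anyway
            single = fam_flags.sum(axis=1) == 1
            for k in range(len(jj)):
                if not (fam_flags[:, k] & single).any():
                    continue
                delta = float(rng.normal(config.mu_miss, config.sigma_miss))
                others = [m for m in range(len(jj)) if m != k]
                arr[ridx, jj[k]] = base[:, others].mean(axis=1) + delta
    biased = pd.DataFrame(
        arr, index=true_values.index, columns=true_values.columns
    )
    observed = biased.where(~flagged)
    return biased, observed


def _random_sequence(rng, config: SimConfig, length: int) -> str:
    letters = list(config.residue_freqs)
    probs = np.array(list(config.residue_freqs.values()))
    body = "".join(rng.choice(letters, size=length - 1, p=probs))
    return body + ("R" if rng.random() < 0.5 else "K")


def _make_flagged_records(
    n: int, kind: str, design: pd.DataFrame, config: SimConfig, rng,
    start_counter: int,
) -> list[PeptideRecord]:
    out = []
    run_ids = list(design["run_id"])
    for i in range(n):
        seq = _random_sequence(rng, config, int(rng.integers(8, 21)))
        st_pos = [j + 1 for j, c in enumerate(seq) if c in "ST"]
        mods = ((PHOSPHO_MOD, st_pos[0]),) if st_pos else ()
        vals = np.exp2(rng.normal(config.baseline_mean, config.baseline_sd,
                                  len(run_ids)))
        out.append(
            PeptideRecord(
                peptide_id=f"{kind}{start_counter + i:04d}",
                sequence=seq,
                modifications=mods,
                n_phospho=len(mods),
                proteins=(),
                leading_protein="",
                localization_score=float("nan"),
                is_reverse=kind == "rev",
                is_contaminant=kind == "con",
                intensities={r: float(v) for r, v in zip(run_ids, vals)},
            )
        )
    return out


def simulate(config: SimConfig | None = None, seed: int = 0) -> SimDataset:
    """Run the full generator: proteome, peptides, intensities, missingness,
    decoys; byte-identical output for a given (config, seed)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    design = make_design(config.strains, replicates=config.replicates)
    plan = generate_proteome(config, rng)
    true_values, truth = simulate_intensities(
        plan.peptides, design, config, rng
    )
    families: dict[str, list[str]] = {}
    for pep in plan.peptides:
        families.setdefault(pep.base_id, []).append(pep.peptide_id)
    biased, observed_df = apply_missingness(
        true_values, design, families, config, rng
    )
    records = []
    for pep in plan.peptides:
        obs = observed_df.loc[pep.peptide_id]
        intensities = {
            run: (0.0 if np.isnan(v) else float(np.exp2(v)))
            for run, v in obs.items()
        }
        if pep.phospho_pos is not None:
            mods = ((PHOSPHO_MOD, pep.phospho_pos),)
            loc = float(rng.uniform(0.7, 1.0))
        else:
            mods = ()
            loc = float("nan")
        records.append(
            PeptideRecord(
                peptide_id=pep.peptide_id,
                sequence=pep.sequence,
                modifications=mods,
                n_phospho=len(mods),
                proteins=(pep.protein,),
                leading_protein=pep.protein,
                localization_score=loc,
                is_reverse=False,
                is_contaminant=False,
                intensities=intensities,
            )
        )
    n_real = len(records)
    n_decoy = int(round(config.decoy_fraction * n_real))
    n_con = int(round(config.contaminant_fraction * n_real))
    records += _make_flagged_records(n_decoy, "rev", design, config, rng, 1)
    records += _make_flagged_records(n_con, "con", design, config, rng, 1)
    observed = LogIntensityMatrix(observed_df, design)
    return SimDataset(
        config=config,
        seed=seed,
        design=design,
        proteome=plan.proteome,
        records=records,
        truth=truth,
        planted_sites=plan.planted_sites,
        true_values=true_values,
        biased_values=biased,
        observed=observed,
    )


def write_maxquant_like_tables(sim: SimDataset, outdir) -> dict[str, Path]:
    """Emit the peptide table, design, proteome FASTA and truth tables.

    Missing cells are serialized as raw intensity 0, the MaxQuant
    convention the reader converts back to missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "modification_specific_peptides.tsv",
        "design": outdir / "design.tsv",
        "proteome": outdir / "proteome.fasta",
        "truth_peptides": outdir / "truth_peptides.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "params": outdir / "sim_params.json",
    }
    mq_io.write_peptide_table(sim.records, sim.design, paths["peptides"])
    mq_io.write_design(sim.design, paths["design"])
    mq_io.write_proteome_fasta(sim.proteome, paths["proteome"])
    mq_io.write_results_tsv(sim.truth, paths["truth_peptides"])
    mq_io.write_results_tsv(sim.planted_sites, paths["truth_sites"])
    params = asdict(sim.config)
    params["seed"] = sim.seed
    paths["params"].write_text(json.dumps(params, indent=2, default=list))
    return paths
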