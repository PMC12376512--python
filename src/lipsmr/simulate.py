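"""Synthetic data with planted ground truth for every pipeline stage.

Three generators, all pure functions of (config, seed):

* ``generate_lipms_dataset`` — a protein database plus a LiP-MS peptide
  intensity table in which *target* proteins carry a planted protection
  signature (an up- and a down-shifted tryptic peptide at the same or
  adjacent sequence positions), *far decoys* carry opposite-direction
  shifts separated by more than the adjacency gap, *same-direction decoys*
  carry two co-located shifts in the same direction, and the rest are null.
* ``generate_smr_dataset`` — per-gene eQTL/GWAS summary statistics with an
  AR(1) LD structure under causal, null, or pleiotropic generative models.
* ``generate_assay_traces`` — toy glucose-tolerance and mito-stress OCR
  traces for the assay metrics.

Child random streams are derived per protein/gene from the top-level seed,
so enlarging a simulation never reshuffles previously generated units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import AMINO_ACIDS, digest_tryptic
from .intensities import PeptideIntensityTable
from .proteins import ProteinDB, ProteinRecord
from .screen import interval_gap

# -- LiP-MS -------------------------------------------------------------


@dataclass
class LipSimConfig:
    """Conditions for a synthetic LiP-MS screen.

    Defaults mirror the experimental design the screen is meant for: three
    biological replicates per treatment and log2 intensities with
    peptide-level noise. ``effect_delta`` is the planted log2 shift in the
    compound condition; ``adjacency_gap`` is the residue gap defining
    "same or adjacent" peptides for planted structure.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (70, 110)
    n_targets: int = 10
    n_far_decoys: int = 10
    n_same_direction_decoys: int = 0
    site_peptides: int = 4
    effect_delta: float = 2.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    missing_rate: float = 0.05
    min_pep_len: int = 7
    max_pep_len: int = 35
    missed_cleavages: int = 0
    adjacency_gap: int = 10
    baseline_range: tuple[float, float] = (18.0, 30.0)
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def validate(self) -> None:
        n_special = self.n_targets + self.n_far_decoys + self.n_same_direction_decoys
        if n_special > self.n_proteins:
            raise ValueError("planted classes exceed n_proteins")
        if self.effect_delta <= 0:
            raise ValueError("effect_delta must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")
        if self.min_pep_len > self.max_pep_len:
            raise ValueError("invalid peptide length window")
        if self.adjacency_gap < 0:
            raise ValueError("adjacency_gap must be >= 0")
        if self.site_peptides < 1:
            raise ValueError("site_peptides must be >= 1")


@dataclass
class LipTruthTable:
    """Planted ground truth: per-protein class and site, per-peptide
    planted direction and generating coordinates."""

    proteins: pd.DataFrame  # protein_id, cls, site_start, site_end
    peptides: pd.DataFrame  # peptide_id, protein_id, sequence, start, end, planted


def _random_protein(rng: np.random.Generator, cfg: LipSimConfig) -> str:
    length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    return "".join(rng.choice(list(cfg.alphabet), size=length))


def _adjacency_chains(
    peptides: list[tuple[str, int, int]], gap_max: int
) -> list[list[int]]:
    """Maximal runs of position-ordered peptide indices in which successive
    peptides are at most ``gap_max`` residues apart."""
    order = sorted(range(len(peptides)), key=lambda i: peptides[i][1])
    chains: list[list[int]] = []
    for i in order:
        if chains and (
            interval_gap(
                peptides[chains[-1][-1]][1],
                peptides[chains[-1][-1]][2],
                peptides[i][1],
                peptides[i][2],
            )
            <= gap_max
        ):
            chains[-1].append(i)
        else:
            chains.append([i])
    return chains


def _plant_site(
    peptides: list[tuple[str, int, int]],
    rng: np.random.Generator,
    cfg: LipSimConfig,
    cls: str,
) -> dict[int, str] | None:
    """Choose planted peptide indices and directions for one protein.

    target: a window of 2*site_peptides chain-adjacent peptides with
    alternating directions (so every neighbouring pair is an opposite-
    direction pair within the adjacency gap). same_direction_decoy: such a
    window with one direction throughout. far_decoy: site_peptides
    peptides at each end of the protein with all opposite-direction pairs
    separated by more than the adjacency gap. Returns None when the digest
    cannot support the class (caller redraws the sequence).
    """
    k = cfg.site_peptides
    if cls == "far_decoy":
        # two peptides per end suffice: the decoy challenges the adjacency
        # rule, not the significance test
        k = min(k, 2)
        order = sorted(range(len(peptides)), key=lambda i: peptides[i][1])
        if len(order) < 2 * k:
            return None
        head, tail = order[:k], order[-k:]
        sep = interval_gap(
            peptides[head[-1]][1],
            peptides[head[-1]][2],
            peptides[tail[0]][1],
            peptides[tail[0]][2],
        )
        if sep <= cfg.adjacency_gap:
            return None
        d_head, d_tail = ("up", "down") if rng.integers(2) == 0 else ("down", "up")
        return {**{i: d_head for i in head}, **{i: d_tail for i in tail}}

    window = 2 * k if cls == "target" else min(2 * k, max(2, k))
    chains = [c for c in _adjacency_chains(peptides, cfg.adjacency_gap) if len(c) >= window]
    if not chains:
        return None
    if cls == "target":
        # footprint covers the longest run of mutually adjacent peptides
        chain = max(chains, key=len)
    else:
        chain = chains[int(rng.integers(len(chains)))]
    if cls == "target":
        # the footprint spans the whole run of mutually adjacent peptides,
        # alternating directions so neighbours always conflict
        first = "up" if rng.integers(2) == 0 else "down"
        other = "down" if first == "up" else "up"
        return {i: (first if n % 2 == 0 else other) for n, i in enumerate(chain)}
    lo = int(rng.integers(len(chain) - window + 1))
    picked = chain[lo : lo + window]
    direction = "up" if rng.integers(2) == 0 else "down"
    return {i: direction for i in picked}


def generate_lipms_dataset(
    config: LipSimConfig,
) -> tuple[ProteinDB, PeptideIntensityTable, LipTruthTable]:
    """Simulate a full LiP-MS screen input with planted truth.

    Proteins are i.i.d. random sequences digested with trypsin; each
    peptide gets a baseline log2 intensity uniform over
    ``baseline_range`` and per-replicate Gaussian noise in both
    conditions; planted peptides additionally shift by ±``effect_delta``
    in the compound condition only. The returned intensity table is on the
    linear scale with missing values as NaN.
    """
    config.validate()
    cfg = config
    classes = (
        ["target"] * cfg.n_targets
        + ["far_decoy"] * cfg.n_far_decoys
        + ["same_direction_decoy"] * cfg.n_same_direction_decoys
    )
    classes += ["null"] * (cfg.n_proteins - len(classes))

    records: list[ProteinRecord] = []
    prot_rows, pep_rows = [], []
    intens_rows = []
    rep_cols = [
        f"intensity_{cond}_{r + 1}"
        for cond in ("vehicle", "compound")
        for r in range(cfg.n_replicates)
    ]

    for i, cls in enumerate(classes):
        rng = np.random.default_rng([cfg.seed, i])
        protein_id = f"P{i:04d}"
        # redraw until the sequence supports the planted structure
        planted: dict[int, str] = {}
        for _attempt in range(500):
            seq = _random_protein(rng, cfg)
            peptides = digest_tryptic(
                seq, cfg.missed_cleavages, cfg.min_pep_len, cfg.max_pep_len
            )
            if cls == "null":
                if peptides:
                    break
                continue
            site_plan = _plant_site(peptides, rng, cfg, cls)
            if site_plan is not None:
                planted = site_plan
                break
        else:
            raise RuntimeError(
                f"could not generate a sequence supporting class {cls!r}; "
                "widen length_range or relax the peptide length window"
            )

        records.append(ProteinRecord(protein_id, seq))
        site = (np.nan, np.nan)
        if planted:
            site = (
                min(peptides[i][1] for i in planted),
                max(peptides[i][2] for i in planted),
            )
        prot_rows.append(
            dict(protein_id=protein_id, cls=cls, site_start=site[0], site_end=site[1])
        )

        for j, (pep, start, end) in enumerate(peptides):
            peptide_id = f"{protein_id}_pep{j:03d}"
            direction = planted.get(j, "none")
            pep_rows.append(
                dict(
                    peptide_id=peptide_id,
                    protein_id=protein_id,
                    sequence=pep,
                    start=start,
                    end=end,
                    planted=direction,
                )
            )
            baseline = rng.uniform(*cfg.baseline_range)
            veh = baseline + rng.normal(0.0, cfg.noise_sd, cfg.n_replicates)
            cmp_ = baseline + rng.normal(0.0, cfg.noise_sd, cfg.n_replicates)
            if direction == "up":
                cmp_ = cmp_ + cfg.effect_delta
            elif direction == "down":
                cmp_ = cmp_ - cfg.effect_delta
            vals = np.concatenate([veh, cmp_])
            miss = rng.random(vals.size) < cfg.missing_rate
            lin = np.exp2(vals)
            lin[miss] = np.nan
            intens_rows.append(
                dict(peptide_id=peptide_id, sequence=pep, **dict(zip(rep_cols, lin)))
            )

    db = ProteinDB(records)
    table = PeptideIntensityTable(
        pd.DataFrame(intens_rows, columns=["peptide_id", "sequence", *rep_cols]),
        scale="linear",
    )
    truth = LipTruthTable(
        proteins=pd.DataFrame(prot_rows),
        peptides=pd.DataFrame(pep_rows),
    )
    _check_planted_structure(truth, cfg)
    return db, table, truth


def _check_planted_structure(truth: LipTruthTable, cfg: LipSimConfig) -> None:
    """Programmatic guarantee of the planted-structure invariants."""
    for rec in truth.proteins.itertuples(index=False):
        peps = truth.peptides[truth.peptides["protein_id"] == rec.protein_id]
        ups = peps[peps["planted"] == "up"]
        downs = peps[peps["planted"] == "down"]
        if rec.cls == "target":
            assert len(ups) >= 1 and len(downs) >= 1
            gaps = [
                interval_gap(u.start, u.end, d.start, d.end)
                for u in ups.itertuples()
                for d in downs.itertuples()
            ]
            assert min(gaps) <= cfg.adjacency_gap
        elif rec.cls == "far_decoy":
            assert len(ups) >= 1 and len(downs) >= 1
            gaps = [
                interval_gap(u.start, u.end, d.start, d.end)
                for u in ups.itertuples()
                for d in downs.itertuples()
            ]
            assert min(gaps) > cfg.adjacency_gap
        elif rec.cls == "same_direction_decoy":
            assert (len(ups) >= 2) != (len(downs) >= 2)
            assert len(ups) == 0 or len(downs) == 0
        else:
            assert len(ups) == 0 and len(downs) == 0


# -- SMR ----------------------------------------------------------------


@dataclass
class SmrSimConfig:
    """Conditions for simulated eQTL/GWAS summary statistics.

    Effective sample sizes default to the real resources this design
    emulates: a blood eQTL meta-analysis of ~31.7k individuals and a
    case-control GWAS totalling ~32.9k; on the standardized scale the
    summary-statistic standard errors are then 1/sqrt(n). The causal
    cis-eQTL explains b=0.15 sd per allele (|z| ~ 27). Pleiotropic loci add
    a second variant, ``pleio_offset`` SNPs from the causal eQTL, with a
    direct outcome effect ``pleio_effect`` whose sign opposes ``beta_xy``
    so the local Wald ratios disagree.
    """

    n_genes: int = 100
    m_snps: int = 30
    ld_rho: float = 0.6
    beta_xy: float = -0.1
    pleiotropy_frac: float = 0.0
    n_eqtl: int = 31684
    n_gwas: int = 32941
    b_causal: float = 0.15
    pleio_effect: float = 0.04
    pleio_offset: int = 2
    seed: int = 0

    def validate(self) -> None:
        if abs(self.ld_rho) >= 1:
            raise ValueError("|ld_rho| must be < 1")
        if self.m_snps < 5:
            raise ValueError("m_snps must be >= 5")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if self.n_eqtl < 2 or self.n_gwas < 2:
            raise ValueError("sample sizes must be >= 2")


def ar1_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix r_ij = rho^|i-j| (always PSD for |rho|<1)."""
    idx = np.arange(m)
    ld = rho ** np.abs(idx[:, None] - idx[None, :])
    if np.linalg.eigvalsh(ld).min() < -1e-8:
        raise ValueError("constructed LD matrix is not positive semidefinite")
    return ld


def generate_smr_dataset(
    config: SmrSimConfig,
) -> list[tuple[pd.DataFrame, np.ndarray, dict]]:
    """Per gene: a summary-statistic table, the LD matrix, and the truth.

    The causal eQTL sits at the middle SNP; marginal eQTL effects are its
    effect propagated through LD. Causal genes have GWAS effects
    ``beta_xy`` times the eQTL effects; pleiotropic genes additionally
    carry the second variant's direct outcome effect; null genes
    (``beta_xy = 0`` model) have outcome effects of pure noise. Estimation
    noise is LD-correlated, as for real summary statistics.

    The truth dict holds gene_id, model class, beta_xy, and the causal
    (and any pleiotropic) SNP index.
    """
    config.validate()
    cfg = config
    m = cfg.m_snps
    ld = ar1_ld(m, cfg.ld_rho)
    chol = np.linalg.cholesky(ld + 1e-12 * np.eye(m))
    se_x = 1.0 / np.sqrt(cfg.n_eqtl)
    se_y = 1.0 / np.sqrt(cfg.n_gwas)
    j = m // 2
    k = min(m - 1, j + cfg.pleio_offset)
    n_pleio = int(round(cfg.pleiotropy_frac * cfg.n_genes))

    out = []
    for g in range(cfg.n_genes):
        rng = np.random.default_rng([cfg.seed, g])
        model = "pleiotropic" if g < n_pleio else ("causal" if cfg.beta_xy != 0 else "null")
        b_x = cfg.b_causal * ld[:, j]
        b_y = cfg.beta_xy * b_x
        if model == "pleiotropic":
            b_y = b_y + cfg.pleio_effect * ld[:, k]
        bhat_x = b_x + se_x * (chol @ rng.standard_normal(m))
        bhat_y = b_y + se_y * (chol @ rng.standard_normal(m))
        locus = pd.DataFrame(
            {
                "snp_id": [f"rs{g:04d}_{s:03d}" for s in range(m)],
                "b_eqtl": bhat_x,
                "se_eqtl": se_x,
                "b_gwas": bhat_y,
                "se_gwas": se_y,
            }
        )
        truth = dict(
            gene_id=f"G{g:04d}",
            model=model,
            beta_xy=cfg.beta_xy,
            causal_index=j,
            pleio_index=k if model == "pleiotropic" else None,
        )
        out.append((locus, ld, truth))
    return out


# -- assay traces -------------------------------------------------------

OCR_PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")


@dataclass
class AssayParams:
    """Parameters for toy assay traces; see ``generate_assay_traces``."""

    times: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0, 120.0)
    baseline: float = 6.0
    peak: float = 18.0
    decay: float = 0.03
    noise_sd: float = 0.0
    phase_means: dict = field(
        default_factory=lambda: {
            "baseline": 100.0,
            "oligomycin": 40.0,
            "fccp": 150.0,
            "rot_aa": 20.0,
        }
    )
    n_per_phase: int = 3


def generate_assay_traces(kind: str, params: AssayParams, seed: int = 0) -> pd.DataFrame:
    """Toy assay traces.

    ``kind="gtt"`` returns columns (time, value): glucose rising from
    baseline to a peak at the first post-injection time then decaying
    exponentially back. ``kind="ocr"`` returns columns (time, value,
    phase) with the four mito-stress phases in injection order
    baseline -> oligomycin -> FCCP -> rotenone/antimycin A.
    """
    rng = np.random.default_rng(seed)
    if kind == "gtt":
        t = np.asarray(params.times, float)
        value = params.baseline + (params.peak - params.baseline) * np.where(
            t <= 0, 0.0, np.exp(-params.decay * np.maximum(t - params.times[1], 0.0))
        ) * np.where(t < params.times[1], t / max(params.times[1], 1e-9), 1.0)
        value = value + rng.normal(0.0, params.noise_sd, t.size)
        return pd.DataFrame({"time": t, "value": value})
    if kind == "ocr":
        times, values, phases = [], [], []
        tick = 0.0
        for phase in OCR_PHASES:
            mean = params.phase_means[phase]
            for _ in range(params.n_per_phase):
                times.append(tick)
                values.append(mean + rng.normal(0.0, params.noise_sd))
                phases.append(phase)
                tick += 6.5
        return pd.DataFrame({"time": times, "value": values, "phase": phases})
    raise ValueError(f"unknown assay kind {kind!r}")
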