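"""Summary-data-based Mendelian randomization with the HEIDI pleiotropy test.

Per gene, the exposure is expression (eQTL summary statistics) and the
outcome is disease risk (GWAS summary statistics on the log-odds scale).
The causal effect is estimated at the top cis-eQTL as the Wald ratio
``b_smr = b_gwas / b_eqtl``; its test statistic is

    T_smr = z_eqtl^2 * z_gwas^2 / (z_eqtl^2 + z_gwas^2)  ~  chi2(1),

and the standard error follows from the first-order delta method (equal to
``|b_smr| / sqrt(T_smr)`` whenever ``b_gwas != 0``). HEIDI asks whether the
Wald ratios at LD-linked instrument SNPs are consistent with the top-SNP
ratio: under a single causal variant they all estimate the same quantity,
under pleiotropy/linkage they disagree. The HEIDI statistic is the sum of
squared standardized ratio differences; its null distribution (a correlated
quadratic form) is approximated by Satterthwaite moment matching on the
eigenvalues of the correlation matrix of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

EQTL_P_THRESHOLD = 5e-8  # instrument significance for the top eQTL
HEIDI_P_THRESHOLD = 1.57e-3  # eQTL significance for HEIDI instruments
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MIN_SNPS = 3  # besides the top SNP
HEIDI_MAX_SNPS = 20
DEFAULT_HEIDI_CUTOFF = 0.01

LOCUS_COLUMNS = ["snp_id", "b_eqtl", "se_eqtl", "b_gwas", "se_gwas"]


def _check_locus(locus: pd.DataFrame) -> None:
    missing = [c for c in LOCUS_COLUMNS if c not in locus.columns]
    if missing:
        raise ValueError(f"locus table missing columns {missing}")
    if (locus["se_eqtl"] <= 0).any() or (locus["se_gwas"] <= 0).any():
        raise ValueError("standard errors must be positive")


def select_top_snp(
    locus: pd.DataFrame, p_threshold: float = EQTL_P_THRESHOLD
) -> str | None:
    """The instrument SNP: maximal eQTL z^2 among SNPs whose eQTL p-value
    passes ``p_threshold``; ``None`` when no SNP qualifies. Ties break by
    snp_id lexicographic."""
    _check_locus(locus)
    z2 = (locus["b_eqtl"] / locus["se_eqtl"]) ** 2
    z2_min = sps.chi2.isf(p_threshold, 1)
    eligible = locus[z2 > z2_min]
    if eligible.empty:
        return None
    key = pd.DataFrame({"z2": z2[eligible.index], "snp_id": eligible["snp_id"]})
    key = key.sort_values(["z2", "snp_id"], ascending=[False, True], kind="mergesort")
    return str(key.iloc[0]["snp_id"])


@dataclass(frozen=True)
class SmrEstimate:
    b_smr: float
    se_smr: float
    t_smr: float
    p_smr: float
    or_smr: float
    ci95: tuple[float, float]


def smr_test(
    b_eqtl: float, se_eqtl: float, b_gwas: float, se_gwas: float
) -> SmrEstimate:
    """Wald-ratio effect of expression on outcome at one SNP with its
    chi2(1) test and 95% CI (odds-ratio scale)."""
    if b_eqtl == 0:
        raise ValueError("b_eqtl must be non-zero for the Wald ratio")
    if se_eqtl <= 0 or se_gwas <= 0:
        raise ValueError("standard errors must be positive")
    zx2 = (b_eqtl / se_eqtl) ** 2
    zy2 = (b_gwas / se_gwas) ** 2
    b = b_gwas / b_eqtl
    denom = zx2 + zy2
    t = zx2 * zy2 / denom if denom > 0 else 0.0
    # delta-method standard error; equals |b|/sqrt(T) for b_gwas != 0
    # (hypot form keeps extreme effect sizes from under/overflowing)
    se = float(np.hypot(se_gwas / b_eqtl, b * se_eqtl / b_eqtl))
    p = float(sps.chi2.sf(t, 1))
    lo, hi = b - 1.959963984540054 * se, b + 1.959963984540054 * se
    with np.errstate(over="ignore"):
        return SmrEstimate(
            b_smr=float(b),
            se_smr=se,
            t_smr=float(t),
            p_smr=p,
            or_smr=float(np.exp(b)),
            ci95=(float(np.exp(lo)), float(np.exp(hi))),
        )


def heidi_test(
    locus: pd.DataFrame,
    ld: np.ndarray,
    top_snp: str,
    p_instrument: float = HEIDI_P_THRESHOLD,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    min_snps: int = HEIDI_MIN_SNPS,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[float, int] | None:
    """HEIDI heterogeneity p-value for one locus, or ``None`` when fewer
    than ``min_snps`` instruments (besides the top SNP) are eligible.

    Instruments are SNPs with eQTL p below ``p_instrument`` and LD r^2 with
    the top SNP inside [``r2_min``, ``r2_max``], capped at the ``max_snps``
    strongest eQTLs. A gene without a HEIDI p-value is never discarded.
    """
    _check_locus(locus)
    m = len(locus)
    ld = np.asarray(ld, float)
    if ld.shape != (m, m):
        raise ValueError(f"LD matrix shape {ld.shape} does not match locus size {m}")

    snp_ids = locus["snp_id"].to_numpy()
    top_pos = int(np.flatnonzero(snp_ids == top_snp)[0])
    bx = locus["b_eqtl"].to_numpy(float)
    sx = locus["se_eqtl"].to_numpy(float)
    bg = locus["b_gwas"].to_numpy(float)
    sg = locus["se_gwas"].to_numpy(float)
    z2 = (bx / sx) ** 2

    z2_min = sps.chi2.isf(p_instrument, 1)
    r2 = ld[:, top_pos] ** 2
    mask = (z2 > z2_min) & (r2 >= r2_min) & (r2 <= r2_max)
    mask[top_pos] = False
    idx = np.flatnonzero(mask)
    if idx.size > max_snps:
        idx = idx[np.argsort(-z2[idx], kind="mergesort")[:max_snps]]
        idx = np.sort(idx)
    if idx.size < min_snps:
        return None

    sel = np.append(idx, top_pos)  # instruments first, top last
    b = bg[sel] / bx[sel]
    r = ld[np.ix_(sel, sel)]
    # delta-method covariance of the Wald ratios across LD-linked SNPs
    cov_b = (
        r * np.outer(sg[sel], sg[sel]) / np.outer(bx[sel], bx[sel])
        + np.outer(b, b) * r * np.outer(sx[sel], sx[sel]) / np.outer(bx[sel], bx[sel])
    )
    k = idx.size
    d = b[:k] - b[k]
    cov_d = (
        cov_b[:k, :k]
        - cov_b[:k, k][:, None]
        - cov_b[k, :k][None, :]
        + cov_b[k, k]
    )
    sd = np.sqrt(np.diag(cov_d))
    t_heidi = float(np.sum((d / sd) ** 2))

    corr = cov_d / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr)
    lam = lam[lam > 1e-12]
    scale = float(np.sum(lam**2) / np.sum(lam))
    dof = float(np.sum(lam) ** 2 / np.sum(lam**2))
    p = float(sps.chi2.sf(t_heidi / scale, dof))
    return p, int(k)


def run_smr_screen(
    loci: list[tuple[str, pd.DataFrame, np.ndarray]],
    fdr_alpha: float = 0.05,
    heidi_cutoff: float = DEFAULT_HEIDI_CUTOFF,
    eqtl_p_threshold: float = EQTL_P_THRESHOLD,
) -> pd.DataFrame:
    """SMR + HEIDI over a set of gene loci with BH FDR across genes.

    Parameters
    ----------
    loci
        (gene_id, summary-statistic table, LD matrix) per gene.
    fdr_alpha
        Unused for the verdict itself (reported q-values carry the FDR
        interpretation) but kept as the conventional reporting threshold.
    heidi_cutoff
        Genes with p_heidi below this are labelled ``pleiotropy_discarded``
        (applied after the FDR adjustment).

    Returns
    -------
    DataFrame with one row per gene: ``gene_id, top_snp, b_smr, se_smr,
    p_smr, or_smr, ci_low, ci_high, p_heidi, n_heidi_snps, q_smr, verdict``.
    """
    if not loci:
        raise ValueError("run_smr_screen needs at least one gene")
    from .stats import bh_adjust

    rows = []
    for gene_id, locus, ld in loci:
        top = select_top_snp(locus, eqtl_p_threshold)
        if top is None:
            rows.append(
                dict(
                    gene_id=gene_id, top_snp=None, b_smr=np.nan, se_smr=np.nan,
                    p_smr=np.nan, or_smr=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_heidi=np.nan, n_heidi_snps=0, verdict="no_instrument",
                )
            )
            continue
        snp = locus[locus["snp_id"] == top].iloc[0]
        est = smr_test(
            float(snp["b_eqtl"]), float(snp["se_eqtl"]),
            float(snp["b_gwas"]), float(snp["se_gwas"]),
        )
        heidi = heidi_test(locus, ld, top)
        p_heidi, n_heidi = (np.nan, 0) if heidi is None else heidi
        rows.append(
            dict(
                gene_id=gene_id, top_snp=top, b_smr=est.b_smr, se_smr=est.se_smr,
                p_smr=est.p_smr, or_smr=est.or_smr,
                ci_low=est.ci95[0], ci_high=est.ci95[1],
                p_heidi=p_heidi, n_heidi_snps=n_heidi, verdict="pass",
            )
        )
    out = pd.DataFrame(rows)

    tested = out["verdict"] != "no_instrument"
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_smr"].to_numpy())
    out["q_smr"] = q
    discard = tested & (out["p_heidi"] < heidi_cutoff)
    out.loc[discard, "verdict"] = "pleiotropy_discarded"
    return out[
        [
            "gene_id", "top_snp", "b_smr", "se_smr", "p_smr", "or_smr",
            "ci_low", "ci_high", "p_heidi", "n_heidi_snps", "q_smr", "verdict",
        ]
    ]


# -- TSV io -------------------------------------------------------------


def read_locus_tsv(path: str | Path) -> pd.DataFrame:
    locus = pd.read_csv(path, sep="\t")
    _check_locus(locus)
    return locus


def read_ld_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Square LD matrix TSV with a header row and a leading snp_id column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"LD matrix in {path} is not square/consistent")
    return df.to_numpy(float), list(df.columns)


def write_ld_tsv(path: str | Path, ld: np.ndarray, snp_ids: list[str]) -> None:
    pd.DataFrame(ld, index=snp_ids, columns=snp_ids).to_csv(path, sep="\t")
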