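"""Cohort QC, fixed-effects IVW meta-analysis and heterogeneity-aware filters.

The meta-analysis pools per-cohort regression betas and standard errors with
inverse-variance weights (METAL-style).  A variant enters the pooled analysis
only if present in at least ``min_studies`` cohorts contributing at least
``min_n`` participants.  A pooled association is declared significant at the
study-wide threshold (5e-10, a Bonferroni correction of the conventional
genome-wide 5e-8 for ~100 proteins); when between-cohort heterogeneity is
material (I2 > 30%) the call additionally requires at least three cohorts to
be individually nominal (p < 0.05) with effect direction matching the pooled
estimate — the guard against a single cohort driving a spurious signal.

All p-value comparisons are done in -log10 space.  Thresholds on p use <=,
on I2 strict >, matching the conventions the defaults were taken from.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pqtlkit.sumstats import VariantKey, mlog10p_from_z, p_from_z

GENOME_WIDE_P = 5e-8
STUDY_WIDE_P = 5e-10


class Verdict(str, Enum):
    EXCLUDED = "excluded"
    NOT_SIGNIFICANT = "not_significant"
    SIGNIFICANT = "significant"
    FILTERED_HETEROGENEOUS = "filtered_heterogeneous"


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity statistics for one variant."""

    key: VariantKey
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    mlog10p: float
    k_studies: int
    n_total: float
    Q: float
    I2: float
    directions: str
    verdict: Verdict | None = None


def study_significance_threshold(genome_wide_p: float = GENOME_WIDE_P,
                                 n_traits: int = 100) -> float:
    """Study-wide threshold: Bonferroni of the genome-wide level over traits."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return genome_wide_p / n_traits


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test level controlling family-wise error at ``alpha``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def cohort_qc(df: pd.DataFrame, maf_min: float = 0.001, hwe_min: float = 1e-6,
              info_min: float = 0.3) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cohort-level variant filters: MAF, Hardy-Weinberg, imputation quality.

    A record is kept iff MAF >= maf_min, HWE p > hwe_min (when present) and
    info >= info_min (when present; boundary inclusive).  Returns the filtered
    frame and per-filter drop counts.
    """
    keep = pd.Series(True, index=df.index)
    counts: dict[str, int] = {}
    if "EAF" in df.columns:
        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
        bad = maf < maf_min
        counts["maf"] = int(bad.sum())
        keep &= ~bad
    if "HWE_P" in df.columns:
        bad = df["HWE_P"].notna() & (df["HWE_P"] <= hwe_min)
        counts["hwe"] = int(bad.sum())
        keep &= ~bad
    if "INFO" in df.columns:
        bad = df["INFO"].notna() & (df["INFO"] < info_min)
        counts["info"] = int(bad.sum())
        keep &= ~bad
    return df[keep].copy(), counts


# ---------------------------------------------------------------------------
# fixed-effects IVW
# ---------------------------------------------------------------------------


def meta_fixed(betas: Sequence[float], ses: Sequence[float],
               ns: Sequence[float] | None = None,
               key: VariantKey | None = None) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pool of one variant.

    w_c = 1/se_c^2; beta = sum(w b)/sum(w); se = 1/sqrt(sum(w));
    Q = sum w (b - beta)^2; I2 = max(0, (Q - (k-1))/Q) * 100 (0 when Q = 0
    or k = 1).  Directions string is '+'/'-' in cohort input order.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    if b.size == 0:
        raise ValueError("need at least one cohort record")
    w = 1.0 / s ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    k = int(b.size)
    Q = float(np.sum(w * (b - beta) ** 2)) if k > 1 else 0.0
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0
    n_total = float(np.sum(ns)) if ns is not None else float("nan")
    return MetaResult(
        key=key, beta_meta=beta, se_meta=se, z_meta=z,
        p_meta=p_from_z(z), mlog10p=mlog10p_from_z(z),
        k_studies=k, n_total=n_total, Q=Q, I2=I2,
        directions="".join("+" if x > 0 else "-" for x in b),
    )


def _stack_cohorts(cohort_dfs: Mapping[str, pd.DataFrame]):
    """Align cohorts on (CHR, POS, EA, OA); returns per-cohort matrices."""
    keys = None
    frames = {}
    for name, df in cohort_dfs.items():
        d = df.set_index(["CHR", "POS", "EA", "OA"])
        frames[name] = d
        keys = d.index if keys is None else keys.union(d.index)
    keys = keys.sort_values()
    k = len(cohort_dfs)
    m = len(keys)
    beta = np.full((m, k), np.nan)
    se = np.full((m, k), np.nan)
    n = np.full((m, k), np.nan)
    mlog = np.full((m, k), np.nan)
    eaf = np.full((m, k), np.nan)
    for j, (name, d) in enumerate(frames.items()):
        d = d.reindex(keys)
        beta[:, j] = d["BETA"].to_numpy()
        se[:, j] = d["SE"].to_numpy()
        n[:, j] = d["N"].to_numpy()
        if "MLOG10P" in d.columns:
            mlog[:, j] = d["MLOG10P"].to_numpy()
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                mlog[:, j] = mlog10p_from_z(d["BETA"].to_numpy() / d["SE"].to_numpy())
        if "EAF" in d.columns:
            eaf[:, j] = d["EAF"].to_numpy()
    return keys, beta, se, n, mlog, eaf, list(frames.keys())


NOMINAL_MLOG10P = -np.log10(0.05)


def meta_analyze(cohort_dfs: Mapping[str, pd.DataFrame],
                 p_sig: float = STUDY_WIDE_P, i2_max: float = 30.0,
                 min_studies: int = 3, min_n: float = 3500.0,
                 min_consistent: int = 3,
                 qc: bool = True, maf_min: float = 0.001,
                 hwe_min: float = 1e-6, info_min: float = 0.3) -> pd.DataFrame:
    """Vectorized meta-analysis of aligned cohort tables for one trait.

    Applies cohort QC, pools with IVW, computes heterogeneity and assigns a
    verdict per variant (see :func:`apply_meta_filters_frame`).  Input frames
    must already be harmonized to a common effect allele per variant.
    """
    if qc:
        cohort_dfs = {name: cohort_qc(df, maf_min, hwe_min, info_min)[0]
                      for name, df in cohort_dfs.items()}
    keys, beta, se, n, mlog, eaf, names = _stack_cohorts(cohort_dfs)
    present = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    w = np.where(present, 1.0 / se ** 2, 0.0)
    sw = w.sum(axis=1)
    beta0 = np.where(present, beta, 0.0)
    beta_meta = (w * beta0).sum(axis=1) / sw
    se_meta = 1.0 / np.sqrt(sw)
    z = beta_meta / se_meta
    k = present.sum(axis=1)
    Q = (w * (beta0 - beta_meta[:, None]) ** 2 * present).sum(axis=1)
    Q = np.where(k > 1, Q, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q) * 100.0, 0.0)
    n_total = np.where(present, n, 0.0).sum(axis=1)
    sign_match = present & (np.sign(beta) == np.sign(beta_meta)[:, None])
    supporting = (sign_match & (mlog > NOMINAL_MLOG10P)).sum(axis=1)
    directions = np.where(present, np.where(beta > 0, "+", "-"), "?")
    out = pd.DataFrame(
        {
            "CHR": keys.get_level_values(0),
            "POS": keys.get_level_values(1),
            "EA": keys.get_level_values(2),
            "OA": keys.get_level_values(3),
            "EAF": np.nanmean(np.where(present, eaf, np.nan), axis=1),
            "BETA": beta_meta,
            "SE": se_meta,
            "Z": z,
            "P": p_from_z(z),
            "MLOG10P": mlog10p_from_z(z),
            "N": n_total,
            "K_STUDIES": k,
            "Q": Q,
            "I2": I2,
            "DIRECTIONS": ["".join(row) for row in directions],
            "N_SUPPORTING": supporting,
        }
    )
    out["VERDICT"] = apply_meta_filters_frame(
        out, p_sig=p_sig, i2_max=i2_max, min_studies=min_studies,
        min_n=min_n, min_consistent=min_consistent)
    return out


def apply_meta_filters_frame(meta: pd.DataFrame, p_sig: float = STUDY_WIDE_P,
                             i2_max: float = 30.0, min_studies: int = 3,
                             min_n: float = 3500.0,
                             min_consistent: int = 3) -> pd.Series:
    """Verdict per variant: presence, significance and heterogeneity filters.

    excluded            — in < min_studies cohorts or < min_n participants
    not_significant     — pooled p above the study-wide threshold
    filtered_heterogeneous — study-wide significant but I2 > i2_max without
                          >= min_consistent cohorts at p < 0.05 in the pooled
                          direction
    significant         — otherwise
    """
    mlog_sig = -np.log10(p_sig)
    verdict = np.full(len(meta), Verdict.SIGNIFICANT.value, dtype=object)
    not_sig = meta["MLOG10P"].to_numpy() < mlog_sig
    verdict[not_sig] = Verdict.NOT_SIGNIFICANT.value
    het = (~not_sig) & (meta["I2"].to_numpy() > i2_max) & (
        meta["N_SUPPORTING"].to_numpy() < min_consistent)
    verdict[het] = Verdict.FILTERED_HETEROGENEOUS.value
    excl = (meta["K_STUDIES"].to_numpy() < min_studies) | (
        meta["N"].to_numpy() < min_n)
    verdict[excl] = Verdict.EXCLUDED.value
    return pd.Series(verdict, index=meta.index, name="VERDICT")


def apply_meta_filters(result: MetaResult, cohort_mlog10p: Sequence[float],
                       cohort_signs: Sequence[float],
                       p_sig: float = STUDY_WIDE_P, i2_max: float = 30.0,
                       min_studies: int = 3, min_n: float = 3500.0,
                       min_consistent: int = 3) -> Verdict:
    """Scalar version of the verdict logic for one :class:`MetaResult`."""
    if result.k_studies < min_studies or result.n_total < min_n:
        return Verdict.EXCLUDED
    if result.mlog10p < -np.log10(p_sig):
        return Verdict.NOT_SIGNIFICANT
    if result.I2 > i2_max:
        ml = np.asarray(cohort_mlog10p, dtype=float)
        sg = np.asarray(cohort_signs, dtype=float)
        n_support = int(np.sum((ml > NOMINAL_MLOG10P)
                               & (sg == np.sign(result.beta_meta))))
        if n_support < min_consistent:
            return Verdict.FILTERED_HETEROGENEOUS
    return Verdict.SIGNIFICANT


def genomic_lambda(z: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2 over its null median.

    Reported per protein for diagnostics; never used to rescale results.
    """
    chi2 = np.asarray(z, dtype=float) ** 2
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# replication comparison
# ---------------------------------------------------------------------------


@dataclass
class ReplicationReport:
    n_testable: int
    n_concordant: int
    pearson_r: float
    n_replicated_study_wide: int
    n_replicated_bonferroni: int
    bonferroni_p: float


def compare_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                        p_study_wide: float = STUDY_WIDE_P,
                        alpha: float = 0.05) -> ReplicationReport:
    """Compare discovery signals against an independent replication cohort.

    Inputs must be harmonized to common effect alleles.  Reports directional
    concordance, the Pearson correlation of effect sizes, and replication
    counts at the study-wide threshold and at a Bonferroni level
    alpha / n_testable.
    """
    m = discovery.merge(replication, on=["CHR", "POS", "EA", "OA"],
                        suffixes=("_disc", "_repl"))
    if len(m) == 0:
        return ReplicationReport(0, 0, float("nan"), 0, 0, float("nan"))
    n_testable = len(m)
    concordant = int((np.sign(m["BETA_disc"]) == np.sign(m["BETA_repl"])).sum())
    if n_testable > 1:
        r = float(np.corrcoef(m["BETA_disc"], m["BETA_repl"])[0, 1])
    else:
        r = float("nan")
    bonf = bonferroni_threshold(alpha, n_testable)
    ml_repl = m["MLOG10P_repl"] if "MLOG10P_repl" in m.columns else -np.log10(m["P_repl"])
    n_sw = int((ml_repl >= -np.log10(p_study_wide)).sum())
    n_bf = int((ml_repl >= -np.log10(bonf)).sum())
    return ReplicationReport(n_testable, concordant, r, n_sw, n_bf, bonf)
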