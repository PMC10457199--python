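"""Pairwise Bayesian colocalization under the single-causal-variant model.

Given two traits' summary statistics over a shared region, each variant's
evidence of association with each trait is summarized by a Wakefield
approximate Bayes factor; the five hypotheses (H0 no association, H1/H2
association with one trait only, H3 both traits but distinct causal
variants, H4 a shared causal variant) are weighted by per-variant priors
(p1, p2, p12) and their posterior probabilities PP0..PP4 computed by
log-sum-exp over variants.  PP4 >= 0.8 is treated as robust evidence of a
shared causal variant.

For loci with multiple conditionally independent signals, ``pwcoco`` first
runs approximate conditional analysis per trait, generates summary
statistics conditioned on each trait's other signals, and colocalizes every
pair of single signals (plus the unconditioned pair), reporting the matrix
and its maximum PP4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pqtlkit.signals import _joint_fit, conditional_stepwise
from pqtlkit.sumstats import LDReference, VariantKey

#: default per-variant prior effect SD, quantitative traits (trait-SD scale)
PRIOR_SD_QUANT = 0.15
#: default per-variant prior effect SD, case-control traits (log-odds scale)
PRIOR_SD_CC = 0.2

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PP4_ROBUST = 0.8


@dataclass
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    pp: np.ndarray                      # PP0..PP4
    n_variants: int
    priors: tuple[float, float, float]
    labf1: np.ndarray = field(repr=False, default=None)
    labf2: np.ndarray = field(repr=False, default=None)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def colocalized(self) -> bool:
        return self.pp4 >= PP4_ROBUST

    def as_dict(self) -> dict[str, float]:
        return {f"PP{i}": float(self.pp[i]) for i in range(5)}


def log_abf(beta, se, prior_sd: float = PRIOR_SD_QUANT):
    """Wakefield log approximate Bayes factor for one association estimate.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:
    log ABF = 0.5 * (log(1 - r) + r z^2).  Positive values favour
    association; the null (z = 0) gives a negative value.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    V = se ** 2
    W = prior_sd ** 2
    r = W / (V + W)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return out if out.ndim else float(out)


def _coloc_from_labf(l1: np.ndarray, l2: np.ndarray,
                     priors=DEFAULT_PRIORS) -> ColocResult:
    p1, p2, p12 = priors
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs i != j: exp(s1 + s2) - exp(s12), in log space
    both = s1 + s2
    with np.errstate(divide="ignore"):
        s3 = both + np.log(max(-np.expm1(min(s12 - both, 0.0)), 0.0))
    h = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + s3,
        np.log(p12) + s12,
    ])
    pp = np.exp(h - logsumexp(h))
    return ColocResult(pp=pp, n_variants=len(l1), priors=tuple(priors),
                       labf1=l1, labf2=l2)


def coloc_pair(trait1: pd.DataFrame, trait2: pd.DataFrame,
               priors=DEFAULT_PRIORS,
               prior_sd1: float = PRIOR_SD_QUANT,
               prior_sd2: float = PRIOR_SD_QUANT) -> ColocResult:
    """Colocalize two traits over their shared, harmonized variants.

    Traits are intersected on (CHR, POS); variants missing from either trait
    are dropped with a log message.  ``prior_sd2`` should be set to
    :data:`PRIOR_SD_CC` when trait 2 is case-control.
    """
    m = trait1.merge(trait2, on=["CHR", "POS"], suffixes=("_1", "_2"))
    if len(m) == 0:
        raise ValueError(
            "no shared variants between traits; harmonize both datasets onto "
            "a common panel before colocalization")
    dropped = max(len(trait1), len(trait2)) - len(m)
    if dropped:
        warnings.warn(f"coloc_pair: {dropped} variants missing from one trait dropped")
    l1 = log_abf(m["BETA_1"].to_numpy(), m["SE_1"].to_numpy(), prior_sd1)
    l2 = log_abf(m["BETA_2"].to_numpy(), m["SE_2"].to_numpy(), prior_sd2)
    return _coloc_from_labf(l1, l2, priors)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------


def conditioned_sumstats(df: pd.DataFrame, ld: LDReference,
                         condition_on: list[VariantKey]) -> pd.DataFrame:
    """Summary statistics adjusted for a set of conditioning variants.

    The conditioning variants' joint effects are estimated from the marginal
    stats and LD, then each remaining variant j is adjusted by
    b_cond_j = b_j - sum_k r[j,k] (s_j/s_k) b_joint_k with per-variant scale
    s = sqrt(1/(2 f (1-f) N)); its SE is inflated by the conditional-variance
    factor 1/sqrt(1 - h_j), h_j = r_jK R_KK^-1 r_Kj.  Conditioned variants
    themselves get b_cond = 0.  Conditioning on the empty set is the identity.
    """
    if not condition_on:
        return df.copy()
    df = df.reset_index(drop=True)
    idx_ld = np.array([ld.index_of(VariantKey(str(c), int(p), str(a), str(o)))
                       for c, p, a, o in zip(df["CHR"], df["POS"], df["EA"], df["OA"])])
    cond_idx_ld = np.array([ld.index_of(v) for v in condition_on])
    pos_in_df = {g: i for i, g in enumerate(idx_ld)}
    cond_rows = [pos_in_df[g] for g in cond_idx_ld if g in pos_in_df]
    if len(cond_rows) != len(cond_idx_ld):
        raise ValueError("conditioning variant absent from the region frame")
    b = df["BETA"].to_numpy(dtype=float)
    se = df["SE"].to_numpy(dtype=float)
    f = df["EAF"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    D = 2.0 * f * (1.0 - f) * n
    s = np.sqrt(1.0 / D)
    R_KK = ld.r[np.ix_(cond_idx_ld, cond_idx_ld)]
    b_joint, _ = _joint_fit(b[cond_rows], D[cond_rows], R_KK)
    r_jK = ld.r[np.ix_(idx_ld, cond_idx_ld)]       # all x cond
    adj = (r_jK * (s[:, None] / s[cond_rows][None, :])) @ b_joint
    b_cond = b - adj
    h = np.einsum("jk,kl,jl->j", r_jK, np.linalg.inv(R_KK + 1e-10 * np.eye(len(cond_rows))), r_jK)
    h = np.clip(h, 0.0, 1.0 - 1e-6)
    se_cond = se / np.sqrt(1.0 - h)
    out = df.copy()
    out["BETA"] = b_cond
    out["SE"] = se_cond
    out.loc[cond_rows, "BETA"] = 0.0
    z = out["BETA"].to_numpy() / out["SE"].to_numpy()
    from pqtlkit.sumstats import mlog10p_from_z, p_from_z
    out["P"] = p_from_z(z)
    out["MLOG10P"] = mlog10p_from_z(z)
    return out


@dataclass
class PwcocoResult:
    """All-pairs conditional colocalization over two traits' signals."""

    matrix: dict[tuple[str, str], ColocResult]
    max_pp4: float
    best_pair: tuple[str, str]
    n_signals1: int
    n_signals2: int

    @property
    def colocalized(self) -> bool:
        return self.max_pp4 >= PP4_ROBUST


def pwcoco(trait1: pd.DataFrame, trait2: pd.DataFrame, ld: LDReference,
           p_cutoff: float = 5e-8, collinearity: float = 0.9,
           priors=DEFAULT_PRIORS,
           prior_sd1: float = PRIOR_SD_QUANT,
           prior_sd2: float = PRIOR_SD_QUANT,
           maf_floor: float = 0.0) -> PwcocoResult:
    """Conditional-then-pairwise colocalization over a region.

    Runs stepwise conditional selection per trait (entry threshold
    ``p_cutoff``), produces for each independent signal the summary
    statistics conditioned on the trait's *other* signals, and colocalizes
    every signal pair plus the unconditioned pair.  Falls back to the plain
    pairwise result with a warning if a conditional solve fails.
    """
    results: dict[tuple[str, str], ColocResult] = {}
    results[("marginal", "marginal")] = coloc_pair(
        trait1, trait2, priors, prior_sd1, prior_sd2)

    def _signal_frames(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        if (df["MLOG10P"].max() if "MLOG10P" in df.columns
                else -np.log10(df["P"].min())) < -np.log10(p_cutoff):
            return {}
        sel = conditional_stepwise(df, ld, p_enter=p_cutoff,
                                   maf_floor=maf_floor, collinearity=collinearity)
        keys = [VariantKey(str(r.CHR), int(r.POS), str(r.EA), str(r.OA))
                for r in sel.itertuples()]
        if len(keys) == 1:
            return {f"{keys[0].chrom}:{keys[0].pos}": df}
        out = {}
        for i, k in enumerate(keys):
            others = [keys[j] for j in range(len(keys)) if j != i]
            out[f"{k.chrom}:{k.pos}"] = conditioned_sumstats(df, ld, others)
        return out

    try:
        frames1 = _signal_frames(trait1)
        frames2 = _signal_frames(trait2)
    except Exception as exc:  # pragma: no cover - degenerate LD input
        warnings.warn(f"conditional solve failed ({exc}); falling back to "
                      "unconditioned colocalization")
        frames1, frames2 = {}, {}
    if len(frames1) > 1 or len(frames2) > 1:
        # with a single signal per trait the conditioned frames are the
        # marginal ones, so the matrix reduces to the unconditioned pair
        for n1, f1 in frames1.items():
            for n2, f2 in frames2.items():
                results[(n1, n2)] = coloc_pair(f1, f2, priors, prior_sd1, prior_sd2)
    best = max(results, key=lambda k: results[k].pp4)
    return PwcocoResult(matrix=results, max_pp4=results[best].pp4,
                        best_pair=best, n_signals1=max(len(frames1), 1),
                        n_signals2=max(len(frames2), 1))
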