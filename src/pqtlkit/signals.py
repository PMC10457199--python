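"""Locus-level signal definition from per-variant meta-analysis results.

Significant variants are flanked by +/-1 Mb, overlapping (or touching)
intervals are merged transitively, and the variant with the lowest p in each
merged region becomes its sentinel.  A region is *cis* when its sentinel lies
within 1 Mb of the transcription start site of the gene encoding the target
protein, otherwise *trans*.  Within a region, conditionally independent
signals are found by approximate stepwise conditional selection from marginal
summary statistics and an LD reference (COJO-style), then pruned to pairwise
r2 <= 0.1 with sentinels forced into the pruned set.  The variance a
protein's sentinels explain is summed as chi2 / (chi2 + N - 2) per sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pqtlkit.meta import STUDY_WIDE_P
from pqtlkit.sumstats import LDReference, VariantKey, mlog10p_from_z

CIS_WINDOW = 1_000_000
REGION_FLANK = 1_000_000


@dataclass
class SignalRegion:
    """A merged genomic interval with its sentinel variant."""

    chrom: str
    start: int
    end: int
    protein: str | None = None
    sentinel: VariantKey | None = None
    sentinel_row: dict = field(default_factory=dict)
    label: str | None = None            # cis | trans | unclassified
    conditional_signals: list = field(default_factory=list)
    pve_contribution: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


# ---------------------------------------------------------------------------
# region definition
# ---------------------------------------------------------------------------


def define_regions(sig: pd.DataFrame, flank: int = REGION_FLANK,
                   protein: str | None = None) -> list[SignalRegion]:
    """Merge +/-flank intervals around significant variants into regions.

    Intervals are closed; exactly-touching intervals merge.  Left bounds clip
    at position 1.  Sentinel per region = lowest p, ties broken by largest
    |z| then smallest position (deterministic).
    """
    regions: list[SignalRegion] = []
    if len(sig) == 0:
        return regions
    for chrom, grp in sig.groupby("CHR", sort=True):
        g = grp.sort_values("POS", kind="mergesort")
        starts = np.maximum(g["POS"].to_numpy() - flank, 1)
        ends = g["POS"].to_numpy() + flank
        cur_s, cur_e = int(starts[0]), int(ends[0])
        members = [0]
        rows = list(range(len(g)))

        def _emit(s, e, idxs):
            sub = g.iloc[idxs]
            ml = sub["MLOG10P"].to_numpy() if "MLOG10P" in sub.columns else -np.log10(sub["P"].to_numpy())
            absz = np.abs(sub["Z"].to_numpy()) if "Z" in sub.columns else np.abs(
                sub["BETA"].to_numpy() / sub["SE"].to_numpy())
            pos = sub["POS"].to_numpy()
            order = np.lexsort((pos, -absz, -ml))  # primary: max mlog10p
            best = sub.iloc[order[0]]
            key = VariantKey(str(best["CHR"]), int(best["POS"]),
                             str(best["EA"]), str(best["OA"]))
            regions.append(SignalRegion(chrom=str(chrom), start=int(s), end=int(e),
                                        protein=protein, sentinel=key,
                                        sentinel_row=dict(best)))

        for i in rows[1:]:
            s, e = int(starts[i]), int(ends[i])
            if s <= cur_e:  # overlap or touch (closed intervals)
                cur_e = max(cur_e, e)
                members.append(i)
            else:
                _emit(cur_s, cur_e, members)
                cur_s, cur_e, members = s, e, [i]
        _emit(cur_s, cur_e, members)
    return regions


def classify_cis_trans(region: SignalRegion, gene_chrom: str | None,
                       tss: int | None, window: int = CIS_WINDOW) -> str:
    """cis iff the sentinel is on the gene's chromosome within ``window`` of its TSS."""
    if gene_chrom is None or tss is None:
        warnings.warn(f"gene unknown for protein {region.protein}; label unclassified")
        region.label = "unclassified"
        return region.label
    if region.sentinel.chrom == str(gene_chrom) and abs(region.sentinel.pos - tss) <= window:
        region.label = "cis"
    else:
        region.label = "trans"
    return region.label


# ---------------------------------------------------------------------------
# approximate conditional analysis (summary stats + LD reference)
# ---------------------------------------------------------------------------


def _joint_fit(b: np.ndarray, D: np.ndarray, R: np.ndarray):
    """Approximate multiple-regression solve from marginal stats.

    X'X is approximated by sqrt(D) R sqrt(D), X'y by D b, with D_j =
    2 f_j (1-f_j) N_j; the phenotypic (residual) variance is fixed at 1,
    appropriate for an inverse-rank-normalized trait whose signals explain
    little variance.  Returns joint betas and their SEs; a numerically
    singular LD submatrix is ridge-stabilized with a warning.
    """
    sd = np.sqrt(D)
    xtx = sd[:, None] * R * sd[None, :]
    xty = D * b
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        warnings.warn("singular LD submatrix; ridge-stabilizing")
        xtx_inv = np.linalg.inv(xtx + 1e-6 * np.diag(np.diag(xtx)))
    bj = xtx_inv @ xty
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 1e-30))
    return bj, se


def conditional_stepwise(region_df: pd.DataFrame, ld: LDReference,
                         p_enter: float = STUDY_WIDE_P,
                         maf_floor: float = 0.01, collinearity: float = 0.9,
                         sentinel: VariantKey | None = None,
                         max_signals: int = 20) -> pd.DataFrame:
    """COJO-style stepwise selection of conditionally independent signals.

    Starts from the sentinel (the lowest-p variant when not given), then
    repeatedly fits the joint model for each remaining candidate together
    with the selected set and admits the candidate with the most significant
    conditional p, while conditional p <= p_enter and max r2 with the
    selected set <= collinearity.  Variants with MAF < maf_floor are
    ineligible unless they are the sentinel.  Returns the selected variants
    with joint betas/SEs/z from the final multiple-regression solve.
    """
    df = region_df.reset_index(drop=True)
    idx_ld = np.array([ld.index_of(VariantKey(str(c), int(p), str(a), str(o)))
                       for c, p, a, o in zip(df["CHR"], df["POS"], df["EA"], df["OA"])])
    b = df["BETA"].to_numpy(dtype=float)
    se = df["SE"].to_numpy(dtype=float)
    f = df["EAF"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    D = 2.0 * f * (1.0 - f) * n
    mlog = df["MLOG10P"].to_numpy() if "MLOG10P" in df.columns else mlog10p_from_z(b / se)
    maf = np.minimum(f, 1.0 - f)
    mlog_enter = -np.log10(p_enter)

    if sentinel is not None:
        start = int(np.where((df["POS"].to_numpy() == sentinel.pos)
                             & (df["CHR"].astype(str).to_numpy() == sentinel.chrom))[0][0])
    else:
        start = int(np.argmax(mlog))
    eligible = (maf >= maf_floor) & (mlog >= mlog_enter)
    eligible[start] = True
    selected = [start]

    while len(selected) < max_signals:
        cand = [j for j in range(len(df)) if j not in selected and eligible[j]]
        if not cand:
            break
        sel_ld = idx_ld[selected]
        best_j, best_ml, best_fit = -1, -np.inf, None
        for j in cand:
            r_with_sel = ld.r[idx_ld[j], sel_ld]
            if np.max(r_with_sel ** 2) > collinearity:
                continue
            ids = selected + [j]
            sub = ld.r[np.ix_(idx_ld[ids], idx_ld[ids])]
            bj, sej = _joint_fit(b[ids], D[ids], sub)
            ml_j = mlog10p_from_z(bj[-1] / sej[-1])
            if ml_j > best_ml:
                best_j, best_ml, best_fit = j, ml_j, (bj, sej)
        if best_j < 0 or best_ml < mlog_enter:
            break
        selected.append(best_j)

    sub = ld.r[np.ix_(idx_ld[selected], idx_ld[selected])]
    bj, sej = _joint_fit(b[selected], D[selected], sub)
    out = df.iloc[selected].copy().reset_index(drop=True)
    out["BETA_JOINT"] = bj
    out["SE_JOINT"] = sej
    out["Z_JOINT"] = bj / sej
    out["MLOG10P_JOINT"] = mlog10p_from_z(out["Z_JOINT"].to_numpy())
    out["IS_SENTINEL"] = [i == start for i in selected]
    return out


def prune_signals(df: pd.DataFrame, ld: LDReference, r2_max: float = 0.1,
                  forced: list[VariantKey] | None = None) -> pd.DataFrame:
    """Greedy LD prune by ascending p; forced variants (sentinels) kept first.

    A variant survives iff its r2 with every already-kept variant is
    <= r2_max.  Forced variants are admitted unconditionally, in input order.
    """
    forced = forced or []
    df = df.reset_index(drop=True)
    idx_ld = np.array([ld.index_of(VariantKey(str(c), int(p), str(a), str(o)))
                       for c, p, a, o in zip(df["CHR"], df["POS"], df["EA"], df["OA"])])
    mlog = df["MLOG10P"].to_numpy() if "MLOG10P" in df.columns else -np.log10(df["P"].to_numpy())
    forced_pos = {(v.chrom, v.pos) for v in forced}
    is_forced = np.array([(str(c), int(p)) in forced_pos
                          for c, p in zip(df["CHR"], df["POS"])])
    kept: list[int] = []
    for i in np.where(is_forced)[0]:
        kept.append(int(i))
    for i in np.argsort(-mlog, kind="stable"):
        i = int(i)
        if i in kept:
            continue
        if all(ld.r[idx_ld[i], idx_ld[j]] ** 2 <= r2_max for j in kept):
            kept.append(i)
    kept_sorted = sorted(kept, key=lambda i: (df["CHR"].iloc[i], df["POS"].iloc[i]))
    return df.iloc[kept_sorted].reset_index(drop=True)


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------


@dataclass
class PveReport:
    protein: str | None
    terms: list[float]
    total: float
    capped: bool = False


def compute_pve(betas, ses, ns, protein: str | None = None) -> PveReport:
    """Proportion of trait variance explained by a set of sentinel variants.

    Each sentinel contributes chi2 / (chi2 + N - 2) with chi2 = (beta/se)^2;
    the total is their sum, flagged if it reaches 1 (non-independent or
    mis-specified inputs).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    n = np.asarray(ns, dtype=float)
    if np.any(s <= 0):
        raise ValueError("se must be > 0")
    if np.any(n <= 2):
        raise ValueError("n must be > 2")
    chi2 = (b / s) ** 2
    terms = chi2 / (chi2 + n - 2.0)
    total = float(terms.sum())
    capped = total >= 1.0
    if capped:
        warnings.warn(f"PVE total {total:.3f} >= 1; sentinels likely not independent")
    return PveReport(protein=protein, terms=list(terms), total=total, capped=capped)


def regions_to_frame(regions: list[SignalRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "CHR": r.chrom, "START": r.start, "END": r.end,
            "PROTEIN": r.protein,
            "SENTINEL_POS": r.sentinel.pos if r.sentinel else None,
            "SENTINEL_EA": r.sentinel.ea if r.sentinel else None,
            "SENTINEL_OA": r.sentinel.oa if r.sentinel else None,
            "LABEL": r.label,
            "N_CONDITIONAL": len(r.conditional_signals),
            "PVE": r.pve_contribution,
        })
    columns = ["CHR", "START", "END", "PROTEIN", "SENTINEL_POS", "SENTINEL_EA",
               "SENTINEL_OA", "LABEL", "N_CONDITIONAL", "PVE"]
    return pd.DataFrame(rows, columns=columns)


def regions_to_bed(regions: list[SignalRegion]) -> pd.DataFrame:
    """0-based half-open BED export of merged regions."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start - 1 for r in regions],
        "end": [r.end for r in regions],
    })
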