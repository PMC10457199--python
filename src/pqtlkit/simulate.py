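"""Synthetic multi-cohort pQTL / eQTL / disease-GWAS generator.

Every downstream stage of the pipeline is exercised against data with a known
answer.  The generator emulates the study design the pipeline targets: ~11
European-ancestry cohorts totalling ~15k participants, each contributing
per-protein GWAS summary statistics over a panel of LD blocks, with planted
cis and trans pQTLs, optional between-cohort heterogeneity, eQTL datasets
sharing (or not sharing) the causal variant, and case-control disease GWAS
generated under a protein -> disease liability model.

Fast path
---------
Summary statistics are drawn directly from sampling theory rather than by
regressing simulated genotypes.  On the standardized-genotype scale the
vector of marginal effect estimates within an LD block is

    b_hat ~ MVN(R beta, R / N)

where ``R`` is the block's dosage correlation matrix and ``beta`` the joint
(causal) standardized effects.  Per-allele effects and standard errors follow
by dividing by ``sqrt(2 f (1-f))``, giving se = 1/sqrt(2 f (1-f) N).  A slow
path that simulates individual genotypes and runs per-variant OLS is kept for
cross-validating the fast path at small n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from pqtlkit.sumstats import LDReference, VariantKey, mlog10p_from_z, p_from_z

#: per-cohort sample sizes; 11 cohorts totalling 14,824 participants
DEFAULT_COHORT_NS = (3500, 2200, 1800, 1500, 1200, 1000, 900, 800, 700, 624, 600)

_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Design of the synthetic study.

    rho is the within-block AR(1) correlation of allele dosages; blocks are
    mutually uncorrelated.  Blocks are spaced ``block_spacing`` bp apart so
    locus definition never merges across blocks.
    """

    n_cohorts: int = len(DEFAULT_COHORT_NS)
    cohort_ns: Sequence[int] = DEFAULT_COHORT_NS
    n_blocks: int = 4
    block_size: int = 50
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing: int = 2_000
    block_spacing: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0,1), got {self.rho}")
        if any(n < 2 for n in self.cohort_ns):
            raise ValueError("all cohort sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if len(self.cohort_ns) != self.n_cohorts:
            raise ValueError("cohort_ns length must equal n_cohorts")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    @property
    def n_total(self) -> int:
        return int(sum(self.cohort_ns))


@dataclass
class PlantedSignal:
    """Ground truth for one planted causal variant."""

    trait: str                      # protein / transcript / disease id
    variant_index: int              # index into the panel
    beta_true: float                # standardized (per genotype-SD) effect
    tau: float = 0.0                # between-cohort heterogeneity SD
    shared_with: tuple[str, ...] = ()


@dataclass
class TruthTable:
    """All planted signals plus the panel they live on."""

    signals: list[PlantedSignal] = field(default_factory=list)
    tss: dict[str, tuple[str, int]] = field(default_factory=dict)  # trait -> (chrom, tss)

    def for_trait(self, trait: str) -> list[PlantedSignal]:
        return [s for s in self.signals if s.trait == trait]

    def validate(self, n_variants: int) -> None:
        for s in self.signals:
            if not (0 <= s.variant_index < n_variants):
                raise ValueError(
                    f"planted variant index {s.variant_index} for trait "
                    f"{s.trait} absent from panel of {n_variants}")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "signals": [
                {"trait": s.trait, "variant_index": s.variant_index,
                 "beta_true": s.beta_true, "tau": s.tau,
                 "shared_with": list(s.shared_with)}
                for s in self.signals
            ],
            "tss": {k: list(v) for k, v in self.tss.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        obj = json.loads(Path(path).read_text())
        return cls(
            signals=[PlantedSignal(trait=s["trait"], variant_index=s["variant_index"],
                                   beta_true=s["beta_true"], tau=s["tau"],
                                   shared_with=tuple(s["shared_with"]))
                     for s in obj["signals"]],
            tss={k: (v[0], int(v[1])) for k, v in obj["tss"].items()},
        )


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------


def ar1_matrix(k: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix r[i,j] = rho^|i-j|."""
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_panel(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, LDReference]:
    """Build the variant panel and its block-diagonal AR(1) LD reference.

    Returns (panel, ld).  The panel frame has columns CHR POS EA OA EAF BLOCK.
    Deterministic given ``config.seed`` (or the supplied generator).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k = config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=k)
    allele_idx = rng.integers(0, 4, size=k)
    ea = _ALLELES[allele_idx]
    # pick a non-complementary other allele so harmonization is unambiguous
    oa = np.empty(k, dtype="<U1")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i, a in enumerate(ea):
        choices = [b for b in "ACGT" if b != a and b != comp[a]]
        oa[i] = choices[rng.integers(0, len(choices))]
    pos = np.empty(k, dtype=np.int64)
    block = np.repeat(np.arange(config.n_blocks), config.block_size)
    for b in range(config.n_blocks):
        start = 1_000_000 + b * config.block_spacing
        pos[block == b] = start + np.arange(config.block_size) * config.variant_spacing
    panel = pd.DataFrame(
        {"CHR": "1", "POS": pos, "EA": ea, "OA": oa, "EAF": maf, "BLOCK": block})
    r = np.zeros((k, k))
    for b in range(config.n_blocks):
        sel = np.where(block == b)[0]
        r[np.ix_(sel, sel)] = ar1_matrix(len(sel), config.rho)
    variants = [VariantKey("1", int(p), str(e), str(o), id=f"var{i}")
                for i, (p, e, o) in enumerate(zip(pos, ea, oa))]
    ld = LDReference(variants=variants, r=r, n_ref=config.n_total)
    return panel, ld


def _block_chols(panel: pd.DataFrame, ld: LDReference) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for b in sorted(panel["BLOCK"].unique()):
        sel = np.where(panel["BLOCK"].to_numpy() == b)[0]
        rb = ld.r[np.ix_(sel, sel)]
        out.append((sel, linalg.cholesky(rb + 1e-10 * np.eye(len(sel)), lower=True)))
    return out


def _marginal_std_effects(panel: pd.DataFrame, ld: LDReference,
                          joint_beta: np.ndarray) -> np.ndarray:
    """Expected marginal standardized effects m = R beta (block-wise)."""
    m = np.zeros(len(panel))
    nz = np.nonzero(joint_beta)[0]
    if len(nz):
        m = ld.r[:, nz] @ joint_beta[nz]
    return m


def _draw_sumstats(panel: pd.DataFrame, chols, m_std: np.ndarray, n: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """One GWAS draw: b_hat_std ~ MVN(m_std, R/N), converted to per-allele."""
    k = len(panel)
    b_std = m_std.copy()
    for sel, L in chols:
        b_std[sel] += (L @ rng.standard_normal(len(sel))) / np.sqrt(n)
    f = panel["EAF"].to_numpy()
    scale = np.sqrt(2.0 * f * (1.0 - f))
    beta = b_std / scale
    se = 1.0 / (scale * np.sqrt(n))
    z = beta / se
    df = panel[["CHR", "POS", "EA", "OA", "EAF"]].copy()
    df["BETA"] = beta
    df["SE"] = se
    df["P"] = p_from_z(z)
    df["N"] = float(n)
    df["MLOG10P"] = mlog10p_from_z(z)
    return df


def simulate_protein_gwas(panel: pd.DataFrame, ld: LDReference,
                          truth: TruthTable, config: SimConfig,
                          trait: str = "protein",
                          rng: np.random.Generator | None = None
                          ) -> dict[str, pd.DataFrame]:
    """Per-cohort marginal summary statistics for one protein.

    Cohort c's joint effect at each planted variant is
    ``beta_true + N(0, tau^2)`` (between-cohort heterogeneity); marginal
    estimates then follow the fast-path sampling law.  Cohorts use
    independent sub-streams of ``rng`` so they are mutually independent.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth.validate(len(panel))
    signals = truth.for_trait(trait)
    chols = _block_chols(panel, ld)
    out: dict[str, pd.DataFrame] = {}
    for c, n_c in enumerate(config.cohort_ns):
        joint = np.zeros(len(panel))
        for s in signals:
            joint[s.variant_index] = s.beta_true + (rng.normal(0.0, s.tau) if s.tau > 0 else 0.0)
        m = _marginal_std_effects(panel, ld, joint)
        out[f"cohort{c + 1}"] = _draw_sumstats(panel, chols, m, n_c, rng)
    return out


def simulate_single_gwas(panel: pd.DataFrame, ld: LDReference,
                         causal: dict[int, float], n: float,
                         rng: np.random.Generator) -> pd.DataFrame:
    """One-dataset quantitative-trait GWAS (used for eQTL datasets)."""
    joint = np.zeros(len(panel))
    for idx, b in causal.items():
        joint[idx] = b
    chols = _block_chols(panel, ld)
    m = _marginal_std_effects(panel, ld, joint)
    return _draw_sumstats(panel, chols, m, n, rng)


def simulate_disease_gwas(panel: pd.DataFrame, ld: LDReference,
                          protein_truth: TruthTable, theta: float,
                          confounder_mode: Literal["none", "ld_confounded"] = "none",
                          n_cases: int = 50_000, n_controls: int = 100_000,
                          trait: str = "protein",
                          confounder_offset: int = 2,
                          confounder_beta: float | None = None,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Case-control disease GWAS under a protein -> disease liability model.

    Under ``none`` (vertical pleiotropy) the disease log-odds effect at each
    protein causal variant is ``theta * beta_protein``; the MR estimand is
    exactly ``theta``.  Under ``ld_confounded`` the protein effects do NOT
    propagate; instead a distinct variant ``confounder_offset`` positions away
    from the first causal variant (hence in AR(1) LD with it) carries an
    independent disease effect — the scenario the HEIDI filter and
    conditional colocalization are designed to flag.

    Effects are on the log-odds scale; the per-allele standard error uses the
    standard case-control approximation se = 1/sqrt(2 f (1-f) N phi (1-phi))
    with phi the case fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    joint = np.zeros(len(panel))
    signals = protein_truth.for_trait(trait)
    if confounder_mode == "none":
        for s in signals:
            joint[s.variant_index] = theta * s.beta_true
    elif confounder_mode == "ld_confounded":
        if not signals:
            raise ValueError("ld_confounded mode needs at least one protein signal")
        anchor = signals[0].variant_index
        idx = anchor + confounder_offset
        if idx >= len(panel):
            idx = anchor - confounder_offset
        joint[idx] = confounder_beta if confounder_beta is not None else 0.15
    else:
        raise ValueError(f"unknown confounder_mode {confounder_mode!r}")
    n = n_cases + n_controls
    phi = n_cases / n
    n_eff = n * phi * (1.0 - phi)
    chols = _block_chols(panel, ld)
    m = _marginal_std_effects(panel, ld, joint)
    # liability effects enter on the standardized scale scaled by sqrt(n_eff)
    df = _draw_sumstats(panel, chols, m, n_eff, rng)
    df["N"] = float(n)
    df["N_CASES"] = float(n_cases)
    df["N_CONTROLS"] = float(n_controls)
    return df


# ---------------------------------------------------------------------------
# slow path: individual-level genotypes + OLS, for cross-validation
# ---------------------------------------------------------------------------


def simulate_genotypes(panel: pd.DataFrame, config: SimConfig, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """n x k dosage matrix whose allele correlation is exactly rho^|i-j|.

    Haplotype alleles within a block follow a Markov copying chain: the next
    allele copies the previous one with probability rho, otherwise it is a
    fresh Bernoulli draw.  With a block-constant allele frequency this gives
    corr(i, j) = rho^|i-j| exactly, matching the fast path's analytic LD.
    The slow path therefore holds frequency constant within each block (the
    block mean of the panel EAFs).
    """
    k = len(panel)
    block = panel["BLOCK"].to_numpy()
    dos = np.zeros((n, k))
    for b in np.unique(block):
        sel = np.where(block == b)[0]
        f = float(panel["EAF"].to_numpy()[sel].mean())
        for _hap in range(2):
            hap = np.empty((n, len(sel)))
            hap[:, 0] = rng.random(n) < f
            for j in range(1, len(sel)):
                copy = rng.random(n) < config.rho
                fresh = rng.random(n) < f
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            dos[:, sel] += hap
    return dos


def gwas_from_genotypes(dosages: np.ndarray, y: np.ndarray,
                        panel: pd.DataFrame) -> pd.DataFrame:
    """Marginal per-variant OLS of y on each dosage column."""
    n, k = dosages.shape
    xc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    beta = xc.T @ yc / sxx
    resid_var = ((yc ** 2).sum() - beta ** 2 * sxx) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    z = beta / se
    df = panel[["CHR", "POS", "EA", "OA"]].copy()
    df["EAF"] = dosages.mean(axis=0) / 2.0
    df["BETA"] = beta
    df["SE"] = se
    df["P"] = p_from_z(z)
    df["N"] = float(n)
    df["MLOG10P"] = mlog10p_from_z(z)
    return df
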