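"""Candidate mediating genes at trans-pQTLs.

A trans association says some locus regulates a distant protein; the gene
doing the mediating is usually, but not always, one of the nearest genes.
Candidates are scored by converging evidence classes:

* bottom-up position — the gene is among the 3 nearest to the sentinel
  within the +/-500 kb local window;
* bottom-up cis-eQTL — the sentinel is (or tags at r2 >= 0.8, or shares a
  credible set with) the local gene's cis-eQTL sentinel;
* protein-protein interaction with the trans-affected target;
* top-down functional overlap — the local gene's annotation terms (GO /
  pathway identifiers) overlap the target's more than chance, by a
  two-sided Fisher exact test over the locus background (all terms of all
  local genes), Bonferroni-corrected for the number of local genes.

The evidence tier is the count of satisfied classes; candidates are ranked
by tier, then adjusted Fisher p, then distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pqtlkit.sumstats import LDReference, VariantKey

LOCAL_WINDOW = 500_000
N_NEAREST = 3
EQTL_TAG_R2 = 0.8
TERM_P_MAX = 0.05


@dataclass
class GeneAnnotation:
    """One gene: position plus functional annotation."""

    gene: str
    chrom: str
    tss: int
    strand: str = "+"
    terms: frozenset[str] = frozenset()
    partners: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be >= 1")
        self.terms = frozenset(self.terms)
        self.partners = frozenset(self.partners)


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Gene table TSV: GENE CHR TSS [STRAND] [TERMS] [PARTNERS] (;-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    out = []
    for row in df.itertuples():
        terms = getattr(row, "TERMS", "")
        partners = getattr(row, "PARTNERS", "")
        out.append(GeneAnnotation(
            gene=str(row.GENE), chrom=str(row.CHR), tss=int(row.TSS),
            strand=str(getattr(row, "STRAND", "+")),
            terms=frozenset(str(terms).split(";")) - {"", "nan"} if pd.notna(terms) else frozenset(),
            partners=frozenset(str(partners).split(";")) - {"", "nan"} if pd.notna(partners) else frozenset(),
        ))
    return out


# ---------------------------------------------------------------------------
# bottom-up: position
# ---------------------------------------------------------------------------


def local_genes(sentinel: VariantKey, genes: list[GeneAnnotation],
                window: int = LOCAL_WINDOW) -> list[tuple[GeneAnnotation, int]]:
    """Genes with |tss - sentinel.pos| <= window on the sentinel chromosome.

    Returned ordered by distance (ties by gene id for determinism); the first
    three are the "3 nearest".  Boundary inclusive.  Invariant to input gene
    ordering.
    """
    hits = [(g, abs(g.tss - sentinel.pos)) for g in genes
            if g.chrom == sentinel.chrom and abs(g.tss - sentinel.pos) <= window]
    hits.sort(key=lambda t: (t[1], t[0].gene))
    return hits


# ---------------------------------------------------------------------------
# top-down: annotation-term overlap
# ---------------------------------------------------------------------------


def term_overlap_test(gene_terms: frozenset[str], target_terms: frozenset[str],
                      background: frozenset[str], n_local_genes: int = 1
                      ) -> tuple[int, float, float]:
    """Two-sided Fisher exact test of term overlap over the locus background.

    The 2x2 table counts background terms by membership in the local gene's
    set x membership in the target's set.  Returns (shared count, raw p,
    Bonferroni-adjusted p = min(1, p * n_local_genes)).
    """
    if not background:
        raise ValueError("empty background term universe; test skipped upstream")
    g = gene_terms & background
    t = target_terms & background
    a = len(g & t)
    b = len(g - t)
    c = len(t - g)
    d = len(background) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return a, float(p), float(min(1.0, p * n_local_genes))


# ---------------------------------------------------------------------------
# combined evidence
# ---------------------------------------------------------------------------


@dataclass
class CandidateGene:
    gene: str
    distance: int
    distance_rank: int
    nearest3: bool
    cis_eqtl_overlap: bool
    ppi_with_target: bool
    shared_terms: int
    term_p: float
    term_p_adjusted: float
    tier: int = 0
    rank: int | None = None


@dataclass
class MediatorReport:
    sentinel: VariantKey
    target: str
    candidates: list[CandidateGene] = field(default_factory=list)
    no_local_candidates: bool = False
    background_size: int = 0


def combine_evidence(nearest3: bool, cis_eqtl_overlap: bool,
                     ppi_with_target: bool, term_p_adjusted: float,
                     term_p_max: float = TERM_P_MAX) -> int:
    """Evidence tier: count of satisfied evidence classes (0-4)."""
    return int(nearest3) + int(cis_eqtl_overlap) + int(ppi_with_target) + \
        int(term_p_adjusted < term_p_max)


def sentinel_tags_eqtl(sentinel: VariantKey, eqtl_sentinel: VariantKey | None,
                       ld: LDReference | None, credible_set: set | None = None,
                       r2_min: float = EQTL_TAG_R2) -> bool:
    """Bottom-up cis-eQTL evidence for one local gene.

    True when the trans sentinel is the gene's eQTL sentinel, is in LD
    r2 >= r2_min with it, or belongs to a supplied credible set.
    """
    if credible_set and (sentinel.chrom, sentinel.pos) in {
            (v.chrom, v.pos) for v in credible_set}:
        return True
    if eqtl_sentinel is None:
        return False
    if (sentinel.chrom, sentinel.pos) == (eqtl_sentinel.chrom, eqtl_sentinel.pos):
        return True
    if ld is not None:
        try:
            i = ld.index_of(sentinel)
            j = ld.index_of(eqtl_sentinel)
        except KeyError:
            return False
        return bool(ld.r[i, j] ** 2 >= r2_min)
    return False


def prioritize_mediators(sentinel: VariantKey, target: GeneAnnotation,
                         genes: list[GeneAnnotation],
                         eqtl_sentinels: dict[str, VariantKey] | None = None,
                         ld: LDReference | None = None,
                         credible_sets: dict[str, set] | None = None,
                         window: int = LOCAL_WINDOW) -> MediatorReport:
    """Rank local genes at a trans-pQTL by converging evidence.

    ``eqtl_sentinels`` maps local gene id -> its cis-eQTL sentinel variant;
    ``credible_sets`` maps gene id -> set of credible-set VariantKeys.  The
    target gene itself is not a local candidate (a trans locus by definition
    excludes it, but synthetic panels may violate this; it is filtered).
    """
    eqtl_sentinels = eqtl_sentinels or {}
    credible_sets = credible_sets or {}
    loc = [(g, d) for g, d in local_genes(sentinel, genes, window)
           if g.gene != target.gene]
    report = MediatorReport(sentinel=sentinel, target=target.gene)
    if not loc:
        report.no_local_candidates = True
        return report
    background = frozenset().union(*(g.terms for g, _ in loc))
    report.background_size = len(background)
    n_local = len(loc)
    for rank0, (g, dist) in enumerate(loc):
        if background:
            shared, p_raw, p_adj = term_overlap_test(
                g.terms, target.terms, background, n_local)
        else:
            shared, p_raw, p_adj = 0, 1.0, 1.0
        cand = CandidateGene(
            gene=g.gene, distance=dist, distance_rank=rank0 + 1,
            nearest3=rank0 < N_NEAREST,
            cis_eqtl_overlap=sentinel_tags_eqtl(
                sentinel, eqtl_sentinels.get(g.gene), ld,
                credible_sets.get(g.gene)),
            ppi_with_target=(target.gene in g.partners) or (g.gene in target.partners),
            shared_terms=shared, term_p=p_raw, term_p_adjusted=p_adj,
        )
        cand.tier = combine_evidence(cand.nearest3, cand.cis_eqtl_overlap,
                                     cand.ppi_with_target, cand.term_p_adjusted)
        report.candidates.append(cand)
    report.candidates.sort(key=lambda c: (-c.tier, c.term_p_adjusted, c.distance))
    for i, c in enumerate(report.candidates):
        c.rank = i + 1
    return report


def report_to_frame(report: MediatorReport) -> pd.DataFrame:
    rows = [{
        "SENTINEL": f"{report.sentinel.chrom}:{report.sentinel.pos}",
        "TARGET": report.target, "GENE": c.gene, "DISTANCE": c.distance,
        "DISTANCE_RANK": c.distance_rank, "NEAREST3": c.nearest3,
        "CIS_EQTL": c.cis_eqtl_overlap, "PPI": c.ppi_with_target,
        "SHARED_TERMS": c.shared_terms, "TERM_P": c.term_p,
        "TERM_P_ADJ": c.term_p_adjusted, "TIER": c.tier, "RANK": c.rank,
    } for c in report.candidates]
    return pd.DataFrame(rows)
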