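"""Shared data model, file I/O, allele harmonization and z/beta conversions.

Summary statistics travel through the pipeline as pandas DataFrames with the
canonical columns ``CHR POS EA OA EAF BETA SE P N`` plus the optional QC
columns ``INFO`` and ``HWE_P``.  Coordinates are 1-based inclusive on a single
build label carried as metadata; there is no liftover.  Association strength
is carried internally in -log10(p) space (column ``MLOG10P``) so that values
far below the float64 underflow limit for p remain comparable; the ``P``
column is kept for display and round-tripping.

All two-sided p-values use the normal approximation (meta-analysis z-tests),
never t.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: canonical column order for summary-statistic TSV files
CANONICAL_COLUMNS = ["CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
OPTIONAL_COLUMNS = ["INFO", "HWE_P", "ID", "MLOG10P"]

_MANDATORY = ["CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

LN10 = np.log(10.0)


class SumStatFormatError(ValueError):
    """A summary-statistic file is missing a mandatory column."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant: position plus effect/other allele.

    ``ea`` is the allele whose dosage the effect size refers to.  The tuple
    (chrom, pos, ea, oa) is unique within any dataset.
    """

    chrom: str
    pos: int
    ea: str
    oa: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ea == self.oa:
            raise ValueError(f"effect and other allele identical: {self.ea}")

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) allele pairs."""
        return _COMPLEMENT.get(self.ea) == self.oa

    def swapped(self) -> "VariantKey":
        return replace(self, ea=self.oa, oa=self.ea)


@dataclass(frozen=True)
class SumStatRecord:
    """One variant's association record: the atom every stage exchanges.

    ``beta`` is the additive per-allele effect (inverse-rank-normalized trait
    SD units for QTL traits, log-odds for case-control), ``se`` its standard
    error, ``eaf`` the effect-allele frequency, ``n`` the sample size.
    """

    key: VariantKey
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    info: float | None = None
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SumStats:
    """A parsed summary-statistic table plus its parse report."""

    df: pd.DataFrame
    n_dropped: int = 0
    n_total: int = 0
    build: str = "synthetic-1"

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LDReference:
    """Pairwise allelic correlation (r) over an ordered variant panel.

    ``r`` is symmetric with unit diagonal; entries are the correlation between
    effect-allele dosages, so the sign convention follows each variant's
    stated effect allele.  ``n_ref`` is the reference sample count.
    """

    variants: list[VariantKey]
    r: np.ndarray
    n_ref: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variants)
        if self.r.shape != (k, k):
            raise ValueError(f"r shape {self.r.shape} != ({k},{k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("r diagonal must be 1")
        self._index = {(v.chrom, v.pos): i for i, v in enumerate(self.variants)}

    def index_of(self, key: VariantKey) -> int:
        try:
            return self._index[(key.chrom, key.pos)]
        except KeyError:
            raise KeyError(f"variant {key.chrom}:{key.pos} not in LD reference") from None

    def submatrix(self, idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        return self.r[np.ix_(idx, idx)]

    def r2(self, i: int, j: int) -> float:
        return float(self.r[i, j] ** 2)

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame, variants: list[VariantKey],
                     ridge: float = 0.0) -> "LDReference":
        """Compute r from a samples x variants dosage table."""
        x = dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        if ridge > 0:
            r = (r + ridge * np.eye(len(r))) / (1.0 + ridge)
        return cls(variants=variants, r=r, n_ref=x.shape[0])

    def write(self, matrix_path: str | Path, index_path: str | Path) -> None:
        np.savetxt(matrix_path, self.r, fmt="%.10g", delimiter="\t")
        idx = pd.DataFrame(
            {
                "CHR": [v.chrom for v in self.variants],
                "POS": [v.pos for v in self.variants],
                "EA": [v.ea for v in self.variants],
                "OA": [v.oa for v in self.variants],
                "ID": [v.id or "" for v in self.variants],
            }
        )
        idx.to_csv(index_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path: str | Path, index_path: str | Path,
             n_ref: int = 0) -> "LDReference":
        r = np.loadtxt(matrix_path, delimiter="\t")
        if r.ndim == 0:
            r = r.reshape(1, 1)
        elif r.ndim == 1:
            r = r.reshape(1, -1) if len(r) == 1 else np.atleast_2d(r)
        idx = pd.read_csv(index_path, sep="\t", dtype={"CHR": str})
        variants = [
            VariantKey(str(row.CHR), int(row.POS), str(row.EA), str(row.OA),
                       str(row.ID) if ("ID" in idx.columns and pd.notna(row.ID) and str(row.ID)) else None)
            for row in idx.itertuples()
        ]
        return cls(variants=variants, r=r, n_ref=n_ref)


# ---------------------------------------------------------------------------
# p/z conversions
# ---------------------------------------------------------------------------


def p_from_z(z):
    """Two-sided normal p-value, survival-function formulation.

    ``2*Phi(-|z|)`` computed via ``norm.sf`` so that p = 1e-300 scale values
    (|z| up to ~37) are representable without underflow to zero.
    """
    z = np.asarray(z, dtype=float)
    out = 2.0 * stats.norm.sf(np.abs(z))
    return out if out.ndim else float(out)


def z_from_p(p, sign=1.0):
    """|z| for a two-sided normal p, with the requested sign attached."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must be in (0, 1]")
    z = stats.norm.isf(p / 2.0)
    out = np.sign(np.where(np.asarray(sign) == 0, 1.0, sign)) * z
    return out if out.ndim else float(out)


def mlog10p_from_z(z):
    """-log10 of the two-sided normal p-value, stable for |z| up to ~1e8."""
    z = np.asarray(z, dtype=float)
    out = -(stats.norm.logsf(np.abs(z)) + np.log(2.0)) / LN10
    return out if out.ndim else float(out)


def z_from_mlog10p(mlog10p, sign=1.0):
    """Inverse of :func:`mlog10p_from_z` (magnitude), sign attached."""
    m = np.atleast_1d(np.asarray(mlog10p, dtype=float))
    logsf = -m * LN10 - np.log(2.0)  # log of the one-tail probability
    z = np.empty_like(m)
    direct = logsf > np.log(1e-280)  # safely representable as a plain p
    z[direct] = stats.norm.isf(np.exp(logsf[direct]))
    if np.any(~direct):
        z[~direct] = _z_from_log_sf(logsf[~direct])
    out = np.sign(np.where(np.asarray(sign) == 0, 1.0, sign)) * z
    if np.ndim(mlog10p) == 0 and np.ndim(sign) == 0:
        return float(out[0] if out.ndim else out)
    return out


def _z_from_log_sf(log_sf: np.ndarray) -> np.ndarray:
    # Newton solve of norm.logsf(z) = log_sf, good far in the tail.
    z = np.sqrt(np.maximum(-2.0 * log_sf, 1.0))
    for _ in range(60):
        f = stats.norm.logsf(z) - log_sf
        # d/dz logsf = -pdf/sf = -exp(logpdf - logsf)
        grad = -np.exp(stats.norm.logpdf(z) - stats.norm.logsf(z))
        step = f / grad
        z = z - np.clip(step, -5.0, 5.0)
        if np.all(np.abs(step) < 1e-12):
            break
    return z


def z_to_beta_se(z, f, n):
    """Reconstruct (beta, se) from a z-score, allele frequency and N.

    Uses ``d = sqrt(2 f (1-f) (z^2 + N))``, ``beta = z/d``, ``se = 1/d`` —
    the standard reconstruction for datasets that publish only z and f.
    The identity ``beta/se == z`` holds to floating round-off.
    """
    z = np.asarray(z, dtype=float)
    f = np.asarray(f, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequency must be in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("n must be > 0")
    d = np.sqrt(2.0 * f * (1.0 - f) * (z ** 2 + n))
    beta = z / d
    se = 1.0 / d
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

UNMATCHABLE = "unmatchable"


def harmonize_record(record: SumStatRecord, target: VariantKey,
                     eaf_target: float | None = None,
                     ambiguous_eaf_margin: float = 0.1):
    """Orient one record onto a target variant's allele frame.

    Returns the (possibly flipped) record, or the string ``"unmatchable"``.
    Swapped alleles flip ``beta -> -beta`` and ``eaf -> 1-eaf``.  For
    strand-ambiguous (A/T, C/G) pairs the orientation is resolved by effect
    allele frequency when the two candidate orientations differ by more than
    ``ambiguous_eaf_margin``; otherwise the record is unmatchable
    (conservative: avoids silent sign errors).
    """
    key = record.key
    if (key.chrom, key.pos) != (target.chrom, target.pos):
        raise ValueError("record and target refer to different positions")
    same = (key.ea, key.oa) == (target.ea, target.oa)
    swapped = (key.ea, key.oa) == (target.oa, target.ea)
    if key.is_ambiguous and (same or swapped):
        if eaf_target is None:
            # no frequency to anchor on: keep the literal allele match
            pass
        else:
            d_same = abs(record.eaf - eaf_target)
            d_swap = abs(record.eaf - (1.0 - eaf_target))
            if abs(d_same - d_swap) <= ambiguous_eaf_margin:
                return UNMATCHABLE
            same, swapped = (d_same < d_swap), (d_same >= d_swap)
    if same:
        return record
    if swapped:
        return SumStatRecord(
            key=VariantKey(key.chrom, key.pos, target.ea, target.oa, key.id),
            eaf=1.0 - record.eaf,
            beta=-record.beta,
            se=record.se,
            p=record.p,
            n=record.n,
            info=record.info,
            hwe_p=record.hwe_p,
        )
    return UNMATCHABLE


def harmonize_frame(df: pd.DataFrame, target: pd.DataFrame,
                    ambiguous_eaf_margin: float = 0.1) -> pd.DataFrame:
    """Orient a summary-statistic frame onto a target frame's allele frame.

    Joins on (CHR, POS); rows absent from the target or unmatchable by allele
    are dropped.  Vectorized equivalent of :func:`harmonize_record` without
    frequency resolution of ambiguous pairs (those with swapped alleles and
    A/T-C/G ambiguity are flipped literally, matching the record-level path
    when no target frequency is supplied).
    """
    t = target[["CHR", "POS", "EA", "OA"]].rename(
        columns={"EA": "EA_t", "OA": "OA_t"})
    m = df.merge(t, on=["CHR", "POS"], how="inner")
    same = (m["EA"] == m["EA_t"]) & (m["OA"] == m["OA_t"])
    swapped = (m["EA"] == m["OA_t"]) & (m["OA"] == m["EA_t"])
    m = m[same | swapped].copy()
    flip = (m["EA"] == m["OA_t"]).to_numpy()
    m.loc[flip, "BETA"] = -m.loc[flip, "BETA"]
    if "EAF" in m.columns:
        m.loc[flip, "EAF"] = 1.0 - m.loc[flip, "EAF"]
    m["EA"] = m.pop("EA_t")
    m["OA"] = m.pop("OA_t")
    return m.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None,
                  build: str = "synthetic-1") -> SumStats:
    """Read a tab-separated summary-statistic file.

    ``dialect`` maps file column names to canonical names (e.g.
    ``{"chromosome": "CHR"}``).  Rows whose mandatory numeric fields fail to
    parse are dropped and counted in the returned report.  Output is sorted
    by (CHR, POS) and carries an ``MLOG10P`` column.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SumStatFormatError(
            f"missing mandatory column(s): {', '.join(missing)} in {path}")
    n_total = len(df)
    numeric = [c for c in ["POS", "EAF", "BETA", "SE", "P", "N", "INFO", "HWE_P", "MLOG10P"]
               if c in df.columns]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    mandatory_numeric = [c for c in ["POS", "BETA", "SE", "P", "N"] if c in df.columns]
    ok = df[mandatory_numeric].notna().all(axis=1)
    ok &= df["SE"] > 0
    df = df[ok].copy()
    df["POS"] = df["POS"].astype(np.int64)
    df["CHR"] = df["CHR"].astype(str)
    if "MLOG10P" not in df.columns:
        z = np.abs(df["BETA"] / df["SE"])
        # prefer the printed p unless it has underflowed
        with np.errstate(divide="ignore"):
            m = -np.log10(df["P"].to_numpy())
        under = ~np.isfinite(m)
        if under.any():
            m[under] = mlog10p_from_z(z.to_numpy()[under])
        df["MLOG10P"] = m
    df = df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return SumStats(df=df, n_dropped=n_total - len(df), n_total=n_total, build=build)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistic frame in canonical TSV column order."""
    cols = [c for c in CANONICAL_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    out = df[cols]
    path = Path(path)
    if path.suffix == ".gz":
        with io.TextIOWrapper(gzip.open(path, "wb")) as fh:
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    else:
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) as 1-based inclusive regions."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["CHR", "START", "END"],
                      dtype={0: str})
    bed["START"] = bed["START"].astype(np.int64) + 1
    bed["END"] = bed["END"].astype(np.int64)
    return bed


def records_to_frame(records: Iterable[SumStatRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "CHR": r.key.chrom, "POS": r.key.pos, "EA": r.key.ea,
                "OA": r.key.oa, "EAF": r.eaf, "BETA": r.beta, "SE": r.se,
                "P": r.p, "N": r.n, "INFO": r.info, "HWE_P": r.hwe_p,
                "ID": r.key.id,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["MLOG10P"] = mlog10p_from_z((df["BETA"] / df["SE"]).to_numpy())
    return df


def frame_to_records(df: pd.DataFrame) -> list[SumStatRecord]:
    out = []
    for row in df.itertuples():
        out.append(
            SumStatRecord(
                key=VariantKey(str(row.CHR), int(row.POS), str(row.EA), str(row.OA),
                               getattr(row, "ID", None) if isinstance(getattr(row, "ID", None), str) else None),
                eaf=float(getattr(row, "EAF", 0.5)),
                beta=float(row.BETA), se=float(row.SE), p=float(row.P),
                n=float(row.N),
                info=float(row.INFO) if hasattr(row, "INFO") and pd.notna(row.INFO) else None,
                hwe_p=float(row.HWE_P) if hasattr(row, "HWE_P") and pd.notna(row.HWE_P) else None,
            )
        )
    return out
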