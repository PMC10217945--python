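"""Per-gene and pooled codon-usage indices.

Implements the classic codonW-style battery of indices:

* codon counts (per gene or pooled over a genome),
* RSCU — relative synonymous codon usage, the observed count of a codon
  divided by its expected count under equal use of the amino acid's
  synonymous codons: ``RSCU_ij = X_ij / ((1/n_i) * sum_j X_ij)``,
* Wright's effective number of codons (ENC/Nc) with the small-sample
  homozygosity estimator, class averaging over the (9, 1, 5, 3)
  degeneracy families, imputation of the 3-fold class and the cap at 61,
* positional GC content (GC1/GC2/GC3, their mean GC, and GC12),
* third-position base composition over synonymous codons (A3/T3/G3/C3)
  and GC3s.

All heavy lifting is vectorised over an ``(n_genes, 64)`` count matrix
whose columns follow :data:`cubkit.genetic_code.CODONS`; the per-gene
functions are thin wrappers over the matrix kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    DEGENERACY,
    DEGENERACY_CLASSES,
    DEGENERATE_AA,
    IS_GC_AT_POS,
    IS_SENSE,
    IS_SYNONYMOUS,
    SYNONYMOUS_CODONS,
    THIRD_BASE_IS,
)
from .sequence_io import CodonSeq

ENC_MIN, ENC_MAX = 20.0, 61.0

#: Fixed column order of the per-gene profile table.
PROFILE_COLUMNS = (
    "gene", "genome", "length_codons", "ENC",
    "GC", "GC1", "GC2", "GC3", "GC12", "GC3s",
    "A3", "T3", "G3", "C3",
)

# Per-amino-acid codon index lists (into the 64-codon axis), degenerate only.
_AA_CODON_IDX: dict[str, np.ndarray] = {
    aa: np.array([CODON_INDEX[c] for c in AA_TO_CODONS[aa]])
    for aa in DEGENERATE_AA
}
_SYN_IDX = np.array([CODON_INDEX[c] for c in SYNONYMOUS_CODONS])


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of the 64 codons for one gene or one pooled genome."""

    scope: str
    counts: np.ndarray  # shape (64,), non-negative ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (arr < 0).any():
            raise ValueError("negative codon counts")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n_sense(self) -> int:
        return int(self.counts[IS_SENSE].sum())

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            scope=f"{self.scope}+{other.scope}", counts=self.counts + other.counts
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CODONS), name=self.scope)


def count_codons(cs: CodonSeq) -> CodonCountTable:
    """Count the 64 codons of one tokenized gene."""
    if not cs.codons:
        raise ValueError(f"empty codon list for {cs.gene_id!r}")
    counts = np.zeros(64, dtype=np.int64)
    idx = np.fromiter((CODON_INDEX[c] for c in cs.codons), dtype=np.int64)
    np.add.at(counts, idx, 1)
    return CodonCountTable(scope=cs.gene_id, counts=counts)


def codon_count_matrix(codon_seqs: Sequence[CodonSeq]) -> pd.DataFrame:
    """Stack per-gene codon counts into a genes x 64 DataFrame."""
    if not codon_seqs:
        raise ValueError("no sequences")
    mat = np.zeros((len(codon_seqs), 64), dtype=np.int64)
    for i, cs in enumerate(codon_seqs):
        for c in cs.codons:
            mat[i, CODON_INDEX[c]] += 1
    return pd.DataFrame(mat, index=[cs.gene_id for cs in codon_seqs], columns=list(CODONS))


def pool_counts(
    tables: Iterable[CodonCountTable] | pd.DataFrame, scope: str = "pooled"
) -> CodonCountTable:
    """Sum counts over genes into one genome-scope table."""
    if isinstance(tables, pd.DataFrame):
        counts = tables.to_numpy().sum(axis=0)
    else:
        counts = np.zeros(64, dtype=np.int64)
        for t in tables:
            counts += t.counts
    return CodonCountTable(scope=scope, counts=counts)


# ---------------------------------------------------------------------------
# matrix kernels


def rscu_matrix(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """RSCU over the 59 synonymous codons, row-wise.

    Amino acids absent from a row are left as NaN (undefined rather than 0).
    """
    C = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    C = np.atleast_2d(C).astype(float)
    out = np.full((C.shape[0], 64), np.nan)
    for aa in DEGENERATE_AA:
        idx = _AA_CODON_IDX[aa]
        n_aa = C[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = C[:, idx] * DEGENERACY[aa] / n_aa[:, None]
        vals[n_aa == 0] = np.nan
        out[:, idx] = vals
    out = out[:, _SYN_IDX]
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=list(SYNONYMOUS_CODONS))
    return out


def rscu(table: CodonCountTable) -> pd.Series:
    """RSCU vector of one count table (59 synonymous codons; NaN = undefined)."""
    if table.n_sense < 1:
        raise ValueError(f"no sense codons in {table.scope!r}")
    vals = rscu_matrix(table.counts[None, :])[0]
    return pd.Series(vals, index=list(SYNONYMOUS_CODONS), name=table.scope)


def enc_matrix(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Wright's ENC per row of a count matrix; NaN where undefined.

    Per degenerate amino acid with occurrence count n >= 2 the codon
    homozygosity is estimated as ``F = (n * sum_j p_j**2 - 1) / (n - 1)``;
    amino acids with F <= 0 or n < 2 are excluded from their class mean.
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` with the 3-fold class imputed
    as ``(F2 + F4)/2`` when Ile is unusable; a missing 2-, 4- or 6-fold
    class mean makes ENC undefined.  Values above 61 are capped.
    """
    C = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    C = np.atleast_2d(C).astype(float)

    f_hat = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for aa in DEGENERATE_AA:
            idx = _AA_CODON_IDX[aa]
            n = C[:, idx].sum(axis=1)
            p2 = (C[:, idx] / n[:, None]) ** 2
            f = (n * p2.sum(axis=1) - 1.0) / (n - 1.0)
            f[(n < 2) | ~np.isfinite(f)] = np.nan
            f[f <= 0] = np.nan
            f_hat[aa] = f

    class_mean = {}
    for k, members in DEGENERACY_CLASSES.items():
        stack = np.stack([f_hat[aa] for aa in members])  # (n_members, n_rows)
        n_ok = (~np.isnan(stack)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            class_mean[k] = np.where(n_ok > 0, np.nansum(stack, axis=0) / n_ok, np.nan)

    f2, f3, f4, f6 = (class_mean[k] for k in (2, 3, 4, 6))
    f3 = np.where(np.isnan(f3), (f2 + f4) / 2.0, f3)
    with np.errstate(invalid="ignore", divide="ignore"):
        enc = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    enc = np.where(np.isnan(f2) | np.isnan(f4) | np.isnan(f6), np.nan, enc)
    enc = np.minimum(enc, ENC_MAX)
    # The theoretical floor of 20 is asserted, never clamped: a violation
    # would mean a bug, not a boundary case.
    assert not (enc < ENC_MIN - 1e-9).any(), "ENC below theoretical floor of 20"
    return enc


def enc_wright(table: CodonCountTable) -> float:
    """Wright's effective number of codons for one gene (NaN if undefined)."""
    return float(enc_matrix(table.counts[None, :])[0])


def _positional_gc_matrix(C: np.ndarray) -> dict[str, np.ndarray]:
    sense = C * IS_SENSE
    n_sense = sense.sum(axis=1).astype(float)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(3):
            out[f"GC{k + 1}"] = (C * (IS_GC_AT_POS[k] & IS_SENSE)).sum(axis=1) / n_sense
    out["GC"] = (out["GC1"] + out["GC2"] + out["GC3"]) / 3.0
    out["GC12"] = (out["GC1"] + out["GC2"]) / 2.0
    return out


def _third_base_matrix(C: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for b in "ATGC":
        out[f"{b}3"] = (C * (THIRD_BASE_IS[b] & IS_SYNONYMOUS)).sum(axis=1)
    total = sum(out[f"{b}3"] for b in "ATGC").astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc3s = (out["G3"] + out["C3"]) / total
    out["GC3s"] = np.where(total == 0, np.nan, gc3s)
    return out


@dataclass(frozen=True)
class PositionalGC:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float


@dataclass(frozen=True)
class ThirdBaseComposition:
    a3: int
    t3: int
    g3: int
    c3: int
    gc3s: float  # NaN when no synonymous codons


def positional_gc(cs: CodonSeq) -> PositionalGC:
    """GC fraction at each codon position over all sense codons of one gene."""
    C = count_codons(cs).counts[None, :]
    d = _positional_gc_matrix(C)
    return PositionalGC(*(float(d[k][0]) for k in ("GC", "GC1", "GC2", "GC3", "GC12")))


def synonymous_third_base(cs: CodonSeq) -> ThirdBaseComposition:
    """Third-position base counts over the 59 synonymous codons of one gene."""
    C = count_codons(cs).counts[None, :]
    d = _third_base_matrix(C)
    return ThirdBaseComposition(
        a3=int(d["A3"][0]), t3=int(d["T3"][0]), g3=int(d["G3"][0]),
        c3=int(d["C3"][0]), gc3s=float(d["GC3s"][0]),
    )


@dataclass(frozen=True)
class UsageProfile:
    """All per-gene indices in one record."""

    gene_id: str
    genome: str
    length_codons: int
    enc: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3: int
    t3: int
    g3: int
    c3: int


def profile_table(
    counts: pd.DataFrame,
    genomes: Mapping[str, str] | str = "",
) -> pd.DataFrame:
    """Compute the full per-gene profile table from a genes x 64 count matrix.

    Returns a DataFrame with :data:`PROFILE_COLUMNS`; ``length_codons`` is
    the total number of codons counted (including start and stop).
    """
    C = counts.to_numpy().astype(float)
    gc = _positional_gc_matrix(C)
    tb = _third_base_matrix(C)
    enc = enc_matrix(C)
    if isinstance(genomes, str):
        genome_col = [genomes] * len(counts)
    else:
        genome_col = [genomes.get(g, "") for g in counts.index]
    df = pd.DataFrame(
        {
            "gene": counts.index.astype(str),
            "genome": genome_col,
            "length_codons": C.sum(axis=1).astype(int),
            "ENC": enc,
            "GC": gc["GC"],
            "GC1": gc["GC1"],
            "GC2": gc["GC2"],
            "GC3": gc["GC3"],
            "GC12": gc["GC12"],
            "GC3s": tb["GC3s"],
            "A3": tb["A3"].astype(int),
            "T3": tb["T3"].astype(int),
            "G3": tb["G3"].astype(int),
            "C3": tb["C3"].astype(int),
        }
    ).reset_index(drop=True)
    return df


def profile_gene(cs: CodonSeq, genome: str = "") -> UsageProfile:
    """Profile one gene (composition of all the per-gene indices)."""
    table = count_codons(cs)
    pg = positional_gc(cs)
    tb = synonymous_third_base(cs)
    return UsageProfile(
        gene_id=cs.gene_id,
        genome=genome or cs.genome,
        length_codons=table.n_total,
        enc=enc_wright(table),
        gc=pg.gc, gc1=pg.gc1, gc2=pg.gc2, gc3=pg.gc3, gc12=pg.gc12,
        gc3s=tb.gc3s, a3=tb.a3, t3=tb.t3, g3=tb.g3, c3=tb.c3,
    )


def profile_genes(codon_seqs: Sequence[CodonSeq], genome: str = "") -> pd.DataFrame:
    """Tokenized genes -> profile table (vectorised path)."""
    counts = codon_count_matrix(codon_seqs)
    genomes = {cs.gene_id: (genome or cs.genome) for cs in codon_seqs}
    return profile_table(counts, genomes)


def rscu_table(table: CodonCountTable) -> pd.DataFrame:
    """Pooled RSCU as a tidy 59-row table (codon, amino acid, count, RSCU)."""
    vec = rscu(table)
    return pd.DataFrame(
        {
            "codon": list(SYNONYMOUS_CODONS),
            "amino_acid": [CODON_TO_AA[c] for c in SYNONYMOUS_CODONS],
            "count": [int(table.counts[CODON_INDEX[c]]) for c in SYNONYMOUS_CODONS],
            "RSCU": vec.to_numpy(),
        }
    )
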