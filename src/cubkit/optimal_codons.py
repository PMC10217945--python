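"""Optimal-codon determination via ENC-extreme groups and ΔRSCU.

Genes are ranked by ENC; the lowest-ENC tail (strongest bias, a proxy for
high expression) and the highest-ENC tail (weakest bias) each receive a
fixed fraction (default 5%) of the genes.  RSCU is computed on the pooled
codon counts of each tail and ``ΔRSCU = RSCU_high_bias - RSCU_low_bias``.
A codon is called *optimal* when ``RSCU > 1`` in the high-bias pool and
``ΔRSCU > 0.08`` (both strict).  Over-/under-representation flags use the
conventional 1.6 / 0.6 thresholds on the whole-dataset pooled RSCU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .codon_metrics import CodonCountTable, pool_counts, rscu
from .genetic_code import CODON_TO_AA, SYNONYMOUS_CODONS

DELTA_RSCU_THRESHOLD = 0.08
RSCU_HIGH_THRESHOLD = 1.0
OVERREPRESENTED_RSCU = 1.6
UNDERREPRESENTED_RSCU = 0.6


@dataclass(frozen=True)
class ExtremeGroups:
    """Gene ids in the low-ENC (high-bias) and high-ENC (low-bias) tails."""

    high_bias_ids: tuple[str, ...]
    low_bias_ids: tuple[str, ...]
    fraction: float
    n_genes: int

    @property
    def group_size(self) -> int:
        return len(self.high_bias_ids)


def select_extreme_groups(
    profiles: pd.DataFrame, fraction: float = 0.05
) -> ExtremeGroups:
    """Pick the ENC tails (size ``ceil(fraction * n)`` each).

    Ties at a cutoff are broken by gene id (lexicographic), so group
    membership is deterministic.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    sub = profiles.loc[profiles["ENC"].notna(), ["gene", "ENC"]]
    n = len(sub)
    if n < 40:
        raise ValueError(f"need at least 40 genes with defined ENC, got {n}")
    m = math.ceil(fraction * n)
    low_enc = sub.sort_values(["ENC", "gene"], ascending=[True, True]).head(m)
    high_enc = sub.sort_values(["ENC", "gene"], ascending=[False, True]).head(m)
    high_ids = tuple(low_enc["gene"])
    low_ids = tuple(high_enc["gene"])
    if set(high_ids) & set(low_ids):
        raise ValueError("ENC tails overlap; dataset too small for this fraction")
    return ExtremeGroups(
        high_bias_ids=high_ids, low_bias_ids=low_ids, fraction=fraction, n_genes=n
    )


def delta_rscu(high: CodonCountTable, low: CodonCountTable) -> pd.DataFrame:
    """Per-codon RSCU in both pools and their difference (high - low).

    Codons of an amino acid absent from either pool get NaN in the
    affected column(s) and a NaN delta (masked, not zero).
    """
    if high.n_sense == 0 or low.n_sense == 0:
        raise ValueError("empty codon pool")
    r_high = rscu(high)
    r_low = rscu(low)
    out = pd.DataFrame(
        {
            "codon": list(SYNONYMOUS_CODONS),
            "amino_acid": [CODON_TO_AA[c] for c in SYNONYMOUS_CODONS],
            "rscu_high": r_high.to_numpy(),
            "rscu_low": r_low.to_numpy(),
        }
    )
    out["delta_rscu"] = out["rscu_high"] - out["rscu_low"]
    return out


def call_optimal(
    dr: pd.DataFrame, pooled_rscu: pd.Series | None = None
) -> pd.DataFrame:
    """Apply the optimal-codon rule to a :func:`delta_rscu` table.

    ``is_optimal = (rscu_high > 1) & (delta_rscu > 0.08)`` with strict
    inequalities; the RSCU condition is evaluated on the high-bias pool.
    If ``pooled_rscu`` (whole-dataset RSCU) is given, each codon also gets
    a representation flag: over (> 1.6), under (< 0.6) or normal.
    """
    if dr["delta_rscu"].notna().sum() == 0:
        raise ValueError("delta RSCU undefined for every codon")
    out = dr.copy()
    out["is_high_frequency"] = out["rscu_high"] > RSCU_HIGH_THRESHOLD
    out["is_optimal"] = out["is_high_frequency"] & (
        out["delta_rscu"] > DELTA_RSCU_THRESHOLD
    )
    out["third_base"] = [c[2] for c in out["codon"]]
    if pooled_rscu is not None:
        vals = pooled_rscu.reindex(out["codon"]).to_numpy()
        rep = pd.Series(["normal"] * len(out))
        rep[vals > OVERREPRESENTED_RSCU] = "over"
        rep[vals < UNDERREPRESENTED_RSCU] = "under"
        rep[pd.isna(vals)] = "undefined"
        out["representation"] = rep.to_numpy()
        out["rscu_pooled"] = vals
    return out


def ending_base_summary(calls: pd.DataFrame) -> str:
    """One-line summary of optimal codons by third base (RNA-style U)."""
    opt = calls.loc[calls["is_optimal"]]
    counts = {b: int((opt["third_base"] == b).sum()) for b in "ATGC"}
    return (
        f"n_optimal={len(opt)}; "
        f"A:{counts['A']}, U:{counts['T']}, G:{counts['G']}, C:{counts['C']}"
    )


@dataclass(frozen=True)
class OptimalCodonResult:
    groups: ExtremeGroups
    calls: pd.DataFrame
    summary: str

    @property
    def optimal_codons(self) -> tuple[str, ...]:
        return tuple(self.calls.loc[self.calls["is_optimal"], "codon"])


def find_optimal_codons(
    profiles: pd.DataFrame,
    counts: pd.DataFrame,
    fraction: float = 0.05,
) -> OptimalCodonResult:
    """End-to-end: ENC tails -> pooled ΔRSCU -> optimal-codon calls.

    ``counts`` is the genes x 64 codon count matrix (rows indexed by gene
    id) from which the tail pools and the whole-dataset RSCU are pooled.
    """
    groups = select_extreme_groups(profiles, fraction)
    high = pool_counts(counts.loc[list(groups.high_bias_ids)], scope="high_bias")
    low = pool_counts(counts.loc[list(groups.low_bias_ids)], scope="low_bias")
    dr = delta_rscu(high, low)
    overall = rscu(pool_counts(counts, scope="all"))
    calls = call_optimal(dr, pooled_rscu=overall)
    return OptimalCodonResult(
        groups=groups, calls=calls, summary=ending_base_summary(calls)
    )
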