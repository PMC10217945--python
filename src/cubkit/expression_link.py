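"""Expression–bias association at sequence, codon and amino-acid level.

Genes are tiered by mean RPKM (high > 10, 1 < medium ≤ 10, 0 < low ≤ 1;
RPKM = 0 excluded) and, within each tier, split into strong- and
weak-bias groups by ENC.  Welch two-sample t-tests then ask, at three
levels, whether expression tracks codon bias:

* **sequence level** — RPKM of strong- vs weak-bias genes within a tier;
* **codon level** — RPKM across the four groups defined by each gene's
  dominant synonymous third base (all pairwise tests plus a combined
  G/C vs A/T test);
* **amino-acid level** — for each degenerate amino acid, RPKM of genes
  whose within-gene preferred codon (maximal RSCU) ends in G/C vs A/U.

RPKM is log10(x + 1)-transformed before testing by default to tame the
heavy right tail of expression data; raw-scale testing is available via
``log_transform=False``.  Raw p-values carry the significance flags (at
0.05); Benjamini–Hochberg-adjusted p-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import AA_TO_CODONS, DEGENERACY, DEGENERATE_AA

TIER_HIGH_RPKM = 10.0
TIER_LOW_RPKM = 1.0
#: Tie order for the dominant third base (first listed wins a tie).
THIRD_BASE_TIE_ORDER = ("T", "A", "G", "C")


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test (x vs y; t > 0 means mean(x) > mean(y))."""

    label_x: str
    label_y: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_statistic: float
    p_value: float
    df: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def welch_t(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> TTestResult:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Convention: ``t = (mean(x) - mean(y)) / se``, two-sided p from the
    Student t distribution.  Both samples must have n >= 3.  If both
    sample variances are zero the test degenerates: t = 0, p = 1 for
    equal means, otherwise t = ±inf with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if mx == my:
            t, p, df = 0.0, 1.0, float(len(x) + len(y) - 2)
        else:
            t, p, df = math_inf_sign(mx - my), 0.0, float(len(x) + len(y) - 2)
    else:
        se2 = vx / len(x) + vy / len(y)
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (
            (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
        )
        p = float(2.0 * stats.t.sf(abs(t), df))
        p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return TTestResult(
        label_x=label_x, label_y=label_y,
        n1=len(x), n2=len(y), mean1=float(mx), mean2=float(my),
        t_statistic=float(t), p_value=float(p), df=float(df),
    )


def math_inf_sign(d: float) -> float:
    return float(np.inf if d > 0 else -np.inf)


def summarize_expression(expr: pd.DataFrame) -> pd.Series:
    """Per-gene summary RPKM = mean across tissue columns."""
    s = expr.mean(axis=1)
    s.name = "rpkm"
    return s


def _transform(r: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log10(r + 1.0) if log_transform else r


def assign_tiers(
    expr: pd.DataFrame,
    profiles: pd.DataFrame,
    enc_split: str | float = "median",
) -> pd.DataFrame:
    """Join expression with profiles; tier by RPKM and split by ENC.

    Tiers: high (RPKM > 10), medium (1 < RPKM ≤ 10), low (0 < RPKM ≤ 1),
    excluded (RPKM = 0).  Within each tier genes are labelled
    ``strong_bias`` (ENC ≤ split point) or ``weak_bias`` (ENC > split
    point); the split point is the within-tier median ENC by default, or
    a fixed ENC value if ``enc_split`` is numeric.
    """
    rpkm = summarize_expression(expr)
    prof = profiles.set_index("gene")
    joined = prof.join(rpkm, how="inner")
    if joined.empty:
        raise ValueError("no overlapping gene ids between expression and profiles")
    n_unmatched = len(expr) - len(joined)

    r = joined["rpkm"]
    tier = pd.Series("excluded", index=joined.index)
    tier[r > TIER_HIGH_RPKM] = "high"
    tier[(r > TIER_LOW_RPKM) & (r <= TIER_HIGH_RPKM)] = "medium"
    tier[(r > 0) & (r <= TIER_LOW_RPKM)] = "low"

    out = pd.DataFrame(
        {
            "gene": joined.index,
            "rpkm": r.to_numpy(),
            "tier": tier.to_numpy(),
            "enc": joined["ENC"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["enc_group"] = pd.NA
    for t in ("high", "medium", "low"):
        mask = (out["tier"] == t) & out["enc"].notna()
        if not mask.any():
            continue
        split = (
            float(out.loc[mask, "enc"].median())
            if enc_split == "median"
            else float(enc_split)
        )
        out.loc[mask & (out["enc"] <= split), "enc_group"] = "strong_bias"
        out.loc[mask & (out["enc"] > split), "enc_group"] = "weak_bias"
    out.attrs["n_unmatched"] = n_unmatched
    return out


def sequence_level_test(
    assignments: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Welch test of RPKM between strong- and weak-bias genes per tier.

    ``t > 0`` means the strong-bias group has the higher mean.  Tiers
    where either group has n < 3 are reported as untestable.
    """
    rows = []
    for tier in ("high", "medium", "low"):
        sub = assignments[assignments["tier"] == tier]
        xs = _transform(
            sub.loc[sub["enc_group"] == "strong_bias", "rpkm"].to_numpy(float),
            log_transform,
        )
        ys = _transform(
            sub.loc[sub["enc_group"] == "weak_bias", "rpkm"].to_numpy(float),
            log_transform,
        )
        if len(xs) < 3 or len(ys) < 3:
            rows.append((tier, len(xs), len(ys), np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = welch_t(xs, ys, "strong_bias", "weak_bias")
        rows.append(
            (tier, res.n1, res.n2, res.mean1, res.mean2,
             res.t_statistic, res.p_value, True)
        )
    out = pd.DataFrame(
        rows,
        columns=["tier", "n_strong", "n_weak", "mean_strong", "mean_weak",
                 "t", "p", "testable"],
    )
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < 0.05
    return out


def dominant_third_base(profiles: pd.DataFrame) -> pd.Series:
    """Per-gene dominant synonymous third base (tie order T > A > G > C)."""
    order = [f"{b}3" for b in THIRD_BASE_TIE_ORDER]
    counts = profiles[order].to_numpy()
    winners = np.array(THIRD_BASE_TIE_ORDER)[counts.argmax(axis=1)]
    return pd.Series(winners, index=profiles["gene"].to_numpy(), name="dominant_base")


def codon_level_groups(
    profiles: pd.DataFrame,
    expr: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group genes by dominant third base; compare RPKM across groups.

    Returns the per-gene group table and a test table with the six
    pairwise Welch tests plus the combined G/C vs A/T test.
    """
    rpkm = summarize_expression(expr)
    dom = dominant_third_base(profiles)
    groups = pd.DataFrame({"dominant_base": dom}).join(rpkm, how="inner")
    groups.index.name = "gene"
    if groups.empty:
        raise ValueError("no overlapping gene ids")

    samples = {
        b: _transform(
            groups.loc[groups["dominant_base"] == b, "rpkm"].to_numpy(float),
            log_transform,
        )
        for b in "ATGC"
    }
    rows = []
    bases = ["A", "T", "G", "C"]
    pairs = [(a, b) for i, a in enumerate(bases) for b in bases[i + 1:]]
    for a, b in pairs:
        rows.append(_test_row(f"{a}3", f"{b}3", samples[a], samples[b]))
    gc = np.concatenate([samples["G"], samples["C"]])
    at = np.concatenate([samples["A"], samples["T"]])
    rows.append(_test_row("GC3", "AT3", gc, at))
    tests = pd.DataFrame(
        rows,
        columns=["group1", "group2", "n1", "n2", "mean1", "mean2", "t", "p", "testable"],
    )
    ok = tests["p"].notna()
    tests["p_adj"] = np.nan
    if ok.any():
        tests.loc[ok, "p_adj"] = multipletests(tests.loc[ok, "p"], method="fdr_bh")[1]
    tests["significant"] = tests["p"] < 0.05
    return groups.reset_index(), tests


def _test_row(l1: str, l2: str, x: np.ndarray, y: np.ndarray) -> tuple:
    if len(x) < 3 or len(y) < 3:
        return (l1, l2, len(x), len(y), np.nan, np.nan, np.nan, np.nan, False)
    r = welch_t(x, y, l1, l2)
    return (l1, l2, r.n1, r.n2, r.mean1, r.mean2, r.t_statistic, r.p_value, True)


def amino_acid_level_groups(
    counts: pd.DataFrame,
    expr: pd.DataFrame,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per amino acid: compare RPKM of G/C- vs A/U-ending codon preferrers.

    For each degenerate amino acid, every gene that uses it is assigned
    the synonymous codon with the maximal within-gene RSCU (equivalently,
    the maximal count); ties exclude the gene for that amino acid.  The
    Welch test then compares expression between genes preferring a
    G/C-ending codon and genes preferring an A/U-ending codon.
    """
    rpkm = summarize_expression(expr)
    common = counts.index.intersection(rpkm.index)
    if common.empty:
        raise ValueError("no overlapping gene ids")
    C = counts.loc[common]
    r = rpkm.loc[common].to_numpy(float)

    rows = []
    for aa in DEGENERATE_AA:
        codons = AA_TO_CODONS[aa]
        sub = C[[c for c in codons]].to_numpy()
        total = sub.sum(axis=1)
        present = total > 0
        best = sub.argmax(axis=1)
        # a tie for the maximum excludes the gene for this amino acid
        sorted_counts = np.sort(sub, axis=1)
        tied = sorted_counts[:, -1] == sorted_counts[:, -2]
        usable = present & ~tied
        n_tied = int((present & tied).sum())
        ends_gc = np.array([c[2] in "GC" for c in codons])
        gc_pref = usable & ends_gc[best]
        au_pref = usable & ~ends_gc[best]
        x = _transform(r[gc_pref], log_transform)
        y = _transform(r[au_pref], log_transform)
        family = DEGENERACY[aa]
        if len(x) < 3 or len(y) < 3:
            rows.append((aa, family, len(x), len(y), n_tied,
                         np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = welch_t(x, y, "gc_pref", "au_pref")
        rows.append((aa, family, res.n1, res.n2, n_tied, res.mean1, res.mean2,
                     res.t_statistic, res.p_value, True))
    out = pd.DataFrame(
        rows,
        columns=["amino_acid", "family", "n_gc_pref", "n_au_pref", "n_tied",
                 "mean_gc_pref", "mean_au_pref", "t", "p", "testable"],
    )
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < 0.05
    return out
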