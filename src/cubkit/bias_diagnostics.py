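"""Bias-source diagnostics: ENC-plot, PR2 plot and neutrality regression.

Three classic graphical tests of whether codon usage is driven by
mutational (compositional) pressure or by selection:

* **ENC-plot** — observed ENC against GC3s, compared with the expected
  curve under pure compositional drive,
  ``ENC_exp(s) = 2 + s + 29 / (s**2 + (1 - s)**2)``.  Genes far below the
  curve use fewer codons than composition alone explains (selection).
* **PR2 plot** — per-gene ``x = G3/(G3+C3)`` vs ``y = A3/(A3+T3)`` over
  synonymous third positions; (0.5, 0.5) is the strand-symmetric
  (A = T, G = C) point expected under no bias.
* **Neutrality plot** — OLS regression of GC12 (mean of first- and
  second-position GC) on GC3; a slope near 1 indicates mutation-dominated
  usage, near 0 selection-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def enc_expected(gc3s):
    """Expected ENC under pure compositional drive at synonymous GC3 = s.

    ``ENC_exp = 2 + s + 29 / (s^2 + (1-s)^2)``; accepts scalars or arrays
    in [0, 1].
    """
    s = np.asarray(gc3s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("GC3s must lie in [0, 1]")
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if np.isscalar(gc3s) else out


def enc_plot_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """ENC-plot coordinates per gene, with the deviation from the curve.

    Deviation is ``ENC_exp - ENC_obs``: positive means the gene lies
    below the expected curve (selection-consistent).  Genes with missing
    ENC or GC3s are skipped; their count is stored in
    ``result.attrs["n_skipped"]``.
    """
    if profiles.empty:
        raise ValueError("no profiles")
    ok = profiles["ENC"].notna() & profiles["GC3s"].notna()
    if not ok.any():
        raise ValueError("no genes with defined ENC and GC3s")
    sub = profiles.loc[ok]
    out = pd.DataFrame(
        {
            "gene": sub["gene"].to_numpy(),
            "GC3s": sub["GC3s"].to_numpy(),
            "ENC_obs": sub["ENC"].to_numpy(),
            "ENC_exp": enc_expected(sub["GC3s"].to_numpy()),
        }
    )
    out["deviation"] = out["ENC_exp"] - out["ENC_obs"]
    out.attrs["n_skipped"] = int((~ok).sum())
    return out


def pr2_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """PR2 coordinates per gene; NaN where a denominator is zero."""
    if profiles.empty:
        raise ValueError("no profiles")
    g3 = profiles["G3"].to_numpy(float)
    c3 = profiles["C3"].to_numpy(float)
    a3 = profiles["A3"].to_numpy(float)
    t3 = profiles["T3"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(g3 + c3 > 0, g3 / (g3 + c3), np.nan)
        y = np.where(a3 + t3 > 0, a3 / (a3 + t3), np.nan)
    out = pd.DataFrame({"gene": profiles["gene"].to_numpy(), "x": x, "y": y})
    out.attrs["n_undefined"] = int(np.isnan(x).sum() + np.isnan(y).sum())
    return out


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the Pearson correlation."""

    n_genes: int
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    gc3_range: tuple[float, float]
    gc12_range: tuple[float, float]

    def summary(self) -> str:
        return (
            f"Neutrality plot: GC12 = {self.intercept:.4f} + {self.slope:.4f} * GC3 "
            f"(n = {self.n_genes}, r = {self.pearson_r:.4f}, p = {self.p_value:.3g}); "
            f"GC3 in [{self.gc3_range[0]:.3f}, {self.gc3_range[1]:.3f}], "
            f"GC12 in [{self.gc12_range[0]:.3f}, {self.gc12_range[1]:.3f}]"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genes": [self.n_genes],
                "slope": [self.slope],
                "intercept": [self.intercept],
                "pearson_r": [self.pearson_r],
                "p_value": [self.p_value],
                "gc3_min": [self.gc3_range[0]],
                "gc3_max": [self.gc3_range[1]],
                "gc12_min": [self.gc12_range[0]],
                "gc12_max": [self.gc12_range[1]],
            }
        )


def neutrality_fit(profiles: pd.DataFrame) -> NeutralityFit:
    """Regress GC12 on GC3 across genes (ordinary least squares).

    The p-value is the two-sided test of zero Pearson correlation
    (Student t with n - 2 degrees of freedom).
    """
    ok = profiles["GC12"].notna() & profiles["GC3"].notna()
    gc3 = profiles.loc[ok, "GC3"].to_numpy(float)
    gc12 = profiles.loc[ok, "GC12"].to_numpy(float)
    if len(gc3) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if np.ptp(gc3) == 0:
        raise ValueError("degenerate regressor: GC3 is constant")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        n_genes=len(gc3),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        gc3_range=(float(gc3.min()), float(gc3.max())),
        gc12_range=(float(gc12.min()), float(gc12.max())),
    )


# ---------------------------------------------------------------------------
# plotting (optional, SVG-oriented)


def plot_enc(table: pd.DataFrame, path) -> None:
    """Scatter of ENC vs GC3s with the expected curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["GC3s"], table["ENC_obs"], s=8, alpha=0.5, label="genes")
    s = np.linspace(0.0, 1.0, 200)
    ax.plot(s, enc_expected(s), color="red", label="expected")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 63)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pr2(table: pd.DataFrame, path) -> None:
    """PR2 scatter with the neutral center lines at 0.5."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(table["x"], table["y"], s=8, alpha=0.5)
    ax.axhline(0.5, color="red", lw=0.8)
    ax.axvline(0.5, color="red", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_neutrality(profiles: pd.DataFrame, fit: NeutralityFit, path) -> None:
    """Neutrality scatter with the fitted line and the GC12 = GC3 diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(profiles["GC3"], profiles["GC12"], s=8, alpha=0.5)
    x = np.linspace(*fit.gc3_range, 50)
    ax.plot(x, fit.intercept + fit.slope * x, color="black",
            label=f"slope = {fit.slope:.3f}")
    ax.plot(x, x, color="red", lw=0.8, label="GC12 = GC3")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
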