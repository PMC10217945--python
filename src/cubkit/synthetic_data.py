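"""Synthetic CDS panels and expression matrices with known bias structure.

The generator gives every pipeline stage a ground truth to recover.  Each
gene is built codon by codon:

* the amino-acid sequence is drawn i.i.d. from a 20-letter frequency
  vector, exponentially tilted per gene so that the *expected* GC content
  at codon positions 1+2 equals the gene's GC12 target;
* given the amino acid, the codon is drawn from a mixture: with
  probability β (the gene's bias strength) the amino acid's designated
  preferred codon, otherwise a third-base draw — G/C-ending with
  probability equal to the gene's GC3 target, then uniform within the
  chosen third-base group.  At a GC3 target of 0.5 this base
  distribution reduces to the plain uniform-plus-point-mass mixture.

GC3 targets are sampled per gene from ``gc3_range``; GC12 targets are
``λ · gc3 + (1 − λ) · gc12_base + ε`` with ``ε ~ N(0, gc12_noise)``, so
the coupling parameter λ (``gc3_coupling``) *is* the true neutrality-plot
slope.  Expression is log-normal around tier-specific means with an
additive term ``γ · β`` (``expression_coupling``) linking bias strength
to expression; a configurable fraction of genes is silent (RPKM 0).

Every generated CDS starts with ATG, ends with a stop codon, contains no
internal stop and is at least 300 bp, so the whole panel passes QC
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_metrics import pool_counts, rscu
from .genetic_code import (
    AA_INDEX,
    AA_ORDER,
    AA_TO_CODONS,
    CODON_INDEX,
    CODONS,
    DEGENERATE_AA,
    STOP_CODONS,
)
from .sequence_io import CodingSequence

#: Default preferred codon per degenerate amino acid: A/U-ending choices,
#: matching the A/U-ending preference typical of plant genomes.
DEFAULT_PREFERRED_CODONS: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "N": "AAT", "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT",
    "T": "ACT", "V": "GTT", "Y": "TAT",
}

#: Default amino-acid frequencies (typical globular-protein composition).
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 0.079, "R": 0.049, "N": 0.043, "D": 0.054, "C": 0.018,
    "Q": 0.038, "E": 0.063, "G": 0.071, "H": 0.022, "I": 0.053,
    "L": 0.091, "K": 0.058, "M": 0.022, "F": 0.040, "P": 0.048,
    "S": 0.068, "T": 0.054, "W": 0.013, "Y": 0.030, "V": 0.066,
}

_STOPS = sorted(STOP_CODONS)
_CODON_ARR = np.array(CODONS)

# --- per-amino-acid third-base group tables (built once) -------------------
_N_AA = len(AA_ORDER)
_MAX_GROUP = 3  # largest third-base group (6-fold families: 3 + 3)
_AT_LIST = np.zeros((_N_AA, _MAX_GROUP), dtype=np.int64)
_GC_LIST = np.zeros((_N_AA, _MAX_GROUP), dtype=np.int64)
_AT_SIZE = np.zeros(_N_AA, dtype=np.int64)
_GC_SIZE = np.zeros(_N_AA, dtype=np.int64)
#: GC fraction at codon positions 1+2, per codon (0, 0.5 or 1).
_C12 = np.array([(c[0] in "GC") + (c[1] in "GC") for c in CODONS]) / 2.0
#: Third base is G or C, per codon.
IS_GC_THIRD = np.array([c[2] in "GC" for c in CODONS], dtype=float)

for _aa, _codons in AA_TO_CODONS.items():
    _ai = AA_INDEX[_aa]
    at = [CODON_INDEX[c] for c in _codons if c[2] in "AT"]
    gc = [CODON_INDEX[c] for c in _codons if c[2] in "GC"]
    _AT_SIZE[_ai], _GC_SIZE[_ai] = len(at), len(gc)
    _AT_LIST[_ai, : len(at)] = at
    _GC_LIST[_ai, : len(gc)] = gc

# mean positions-1+2 GC of each third-base group; empty groups (Met, Trp)
# inherit the other group's value so the tilt math stays well defined
_C12_AT = np.zeros(_N_AA)
_C12_GC = np.zeros(_N_AA)
for _ai in range(_N_AA):
    at_mean = _C12[_AT_LIST[_ai, : _AT_SIZE[_ai]]].mean() if _AT_SIZE[_ai] else np.nan
    gc_mean = _C12[_GC_LIST[_ai, : _GC_SIZE[_ai]]].mean() if _GC_SIZE[_ai] else np.nan
    _C12_AT[_ai] = at_mean if _AT_SIZE[_ai] else gc_mean
    _C12_GC[_ai] = gc_mean if _GC_SIZE[_ai] else at_mean


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the package's study conditions.

    Parameters
    ----------
    n_genes
        Number of CDS to generate.
    length_range
        Inclusive range of total codons per gene (start + body + stop);
        the minimum must be >= 100 so every CDS is >= 300 bp.
    amino_acid_freqs
        20-letter amino-acid frequency map (normalised internally).
    bias_strength
        β ∈ [0, 1): probability that an amino acid with a preferred codon
        uses it outright.  A scalar applies globally, a (lo, hi) pair is
        sampled per gene, an array gives per-gene values.
    preferred_codons
        Amino acid -> preferred codon.  Amino acids missing from the map
        are never biased.  Default: A/U-ending codons for all 18
        degenerate amino acids.
    gc3_coupling
        λ ∈ [0, 1]: the true neutrality-plot slope (degree to which GC12
        targets track GC3 targets).
    gc3_range
        Per-gene GC3 targets are Uniform over this interval.
    gc12_base, gc12_noise
        Baseline GC12 (weight 1 − λ) and the s.d. of the Gaussian noise
        on the per-gene GC12 target.
    expression_coupling
        γ: additive effect of β on mean log10 RPKM.
    tier_probs
        Probabilities of the latent (high, medium, low, silent) tiers.
    tier_means
        Mean log10 RPKM of the three expressed tiers.
    gene_sd, tissue_sd
        Between-gene and between-tissue s.d. of log10 RPKM.
    """

    n_genes: int = 500
    length_range: tuple[int, int] = (100, 300)
    amino_acid_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQS)
    )
    bias_strength: float | tuple[float, float] | Sequence[float] = (0.0, 0.6)
    preferred_codons: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PREFERRED_CODONS)
    )
    gc3_coupling: float = 0.5
    gc3_range: tuple[float, float] = (0.25, 0.65)
    gc12_base: float = 0.42
    gc12_noise: float = 0.02
    expression_coupling: float = 0.5
    tier_probs: tuple[float, float, float, float] = (0.30, 0.35, 0.25, 0.10)
    tier_means: tuple[float, float, float] = (1.8, 0.5, -0.7)
    gene_sd: float = 0.25
    tissue_sd: float = 0.1
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "seed")
    genome_label: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_range[0] < 100 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range minimum must be >= 100 codons (300 bp)")
        freqs = np.array([self.amino_acid_freqs.get(aa, 0.0) for aa in AA_ORDER])
        if (freqs < 0).any() or freqs.sum() <= 0:
            raise ValueError("invalid amino acid frequencies")
        if not 0.0 <= self.gc3_coupling <= 1.0:
            raise ValueError("gc3_coupling must be in [0, 1]")
        if not 0.0 <= self.gc3_range[0] <= self.gc3_range[1] <= 1.0:
            raise ValueError("gc3_range must be within [0, 1]")
        for aa, codon in self.preferred_codons.items():
            if aa not in DEGENERATE_AA:
                raise ValueError(f"preferred codon given for non-degenerate {aa!r}")
            if codon not in AA_TO_CODONS[aa]:
                raise ValueError(f"{codon!r} does not encode {aa!r}")
        beta = self.resolve_beta(np.random.default_rng(0))
        if (beta < 0).any() or (beta >= 1).any():
            raise ValueError("bias_strength must lie in [0, 1)")

    def resolve_beta(self, rng: np.random.Generator) -> np.ndarray:
        b = self.bias_strength
        if np.isscalar(b):
            return np.full(self.n_genes, float(b))
        b = np.asarray(b, dtype=float)
        if b.shape == (2,) and not isinstance(self.bias_strength, np.ndarray):
            return rng.uniform(b[0], b[1], self.n_genes)
        if b.shape != (self.n_genes,):
            raise ValueError("per-gene bias_strength must have length n_genes")
        return b


@dataclass
class SyntheticDataset:
    """Generated CDS panel plus ground truth (and, optionally, expression)."""

    config: SimulationConfig
    sequences: list[CodingSequence]
    counts: pd.DataFrame  # genes x 64 codon counts
    truth: pd.DataFrame  # gene, beta, gc3_target, gc12_target, length_codons
    expression: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sequences:
                fh.write(f">{s.id}\n{s.seq}\n")

    def pooled_rscu(self) -> pd.Series:
        return rscu(pool_counts(self.counts, scope=self.config.genome_label))


def _tilt_aa_distributions(
    p0: np.ndarray, c_bar: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Exponentially tilt p0 so each row's expected c equals its target.

    Solves ``E_p[c] = target`` with ``p ∝ p0 * exp(θ c)`` by vectorised
    Newton iteration (the map θ -> E[c] is strictly increasing).
    """
    lo = c_bar.min(axis=1)
    hi = c_bar.max(axis=1)
    t = np.clip(targets, lo + 0.02, hi - 0.02)
    theta = np.zeros(len(t))
    for _ in range(60):
        w = p0 * np.exp(np.clip(theta[:, None] * c_bar, -700, 700))
        z = w.sum(axis=1)
        m = (w * c_bar).sum(axis=1) / z
        v = (w * c_bar**2).sum(axis=1) / z - m**2
        theta = np.clip(theta + (t - m) / np.maximum(v, 1e-8), -80.0, 80.0)
    w = p0 * np.exp(np.clip(theta[:, None] * c_bar, -700, 700))
    return w / w.sum(axis=1, keepdims=True)


def simulate_cds(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a CDS panel under the configured bias model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    p0 = np.array([cfg.amino_acid_freqs.get(aa, 0.0) for aa in AA_ORDER])
    p0 = p0 / p0.sum()

    pref_idx = np.full(_N_AA, -1, dtype=np.int64)
    for aa, codon in cfg.preferred_codons.items():
        pref_idx[AA_INDEX[aa]] = CODON_INDEX[codon]
    has_pref = pref_idx >= 0

    beta = cfg.resolve_beta(rng)
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, n)
    gc3_t = rng.uniform(cfg.gc3_range[0], cfg.gc3_range[1], n)

    # Probability that each amino acid's codon draw is G/C-ending, given
    # the gene's GC3 target: codon weights are gc3 for G/C-ending and
    # 1 - gc3 for A/T-ending codons, so the group probability scales with
    # group size and the base distribution is exactly uniform at gc3 = 0.5.
    w_gc = _GC_SIZE[None, :] * gc3_t[:, None]
    w_at = _AT_SIZE[None, :] * (1.0 - gc3_t[:, None])
    with np.errstate(invalid="ignore"):
        q_gc = np.where(w_gc + w_at > 0, w_gc / (w_gc + w_at), 0.0)
    q_gc = np.where(_AT_SIZE[None, :] == 0, 1.0, q_gc)
    q_gc = np.where(_GC_SIZE[None, :] == 0, 0.0, q_gc)

    # expected positions-1+2 GC per amino acid, given each gene's codon rule
    base_c12 = q_gc * _C12_GC[None, :] + (1.0 - q_gc) * _C12_AT[None, :]
    pref_c12 = np.where(has_pref, _C12[np.maximum(pref_idx, 0)], 0.0)
    b_eff = beta[:, None] * has_pref[None, :]
    c_bar = b_eff * pref_c12[None, :] + (1.0 - b_eff) * base_c12

    # GC12 targets couple to each gene's *expected realized* GC3 (third
    # base G/C over sense codons, including the invariant G contributed
    # by Met, Trp and the start codon), so the coupling parameter is the
    # neutrality slope on the scale the diagnostics measure.  The
    # expectation depends (weakly) on the tilted amino-acid
    # distribution, so tilt twice.
    eps = rng.normal(0.0, cfg.gc12_noise, n)
    third_gc = b_eff * IS_GC_THIRD[np.maximum(pref_idx, 0)][None, :] + (1.0 - b_eff) * q_gc
    body = (lengths - 2).astype(float)
    gc12_t = cfg.gc3_coupling * gc3_t + (1.0 - cfg.gc3_coupling) * cfg.gc12_base + eps
    p_aa = np.broadcast_to(p0, c_bar.shape)
    for _ in range(2):
        p_aa = _tilt_aa_distributions(np.broadcast_to(p0, c_bar.shape), c_bar, gc12_t)
        exp_gc3 = (body * (p_aa * third_gc).sum(axis=1) + 1.0) / (body + 1.0)
        gc12_t = (
            cfg.gc3_coupling * exp_gc3
            + (1.0 - cfg.gc3_coupling) * cfg.gc12_base
            + eps
        )
    cum = np.cumsum(p_aa, axis=1)

    start_idx = CODON_INDEX["ATG"]
    stop_idx = np.array([CODON_INDEX[s] for s in _STOPS])

    gene_ids = [f"{cfg.genome_label}_{i:05d}" for i in range(n)]
    sequences: list[CodingSequence] = []
    counts = np.zeros((n, 64), dtype=np.int64)
    for g in range(n):
        blen = int(lengths[g]) - 2
        aa = np.searchsorted(cum[g], rng.random(blen))
        use_pref = (rng.random(blen) < beta[g]) & has_pref[aa]
        use_gc = rng.random(blen) < q_gc[g, aa]
        size = np.where(use_gc, _GC_SIZE[aa], _AT_SIZE[aa])
        k = (rng.random(blen) * size).astype(np.int64)
        codon = np.where(use_gc, _GC_LIST[aa, k], _AT_LIST[aa, k])
        codon[use_pref] = pref_idx[aa[use_pref]]
        full = np.concatenate(
            ([start_idx], codon, [stop_idx[rng.integers(0, len(stop_idx))]])
        )
        counts[g] = np.bincount(full, minlength=64)
        sequences.append(
            CodingSequence(
                id=gene_ids[g],
                seq="".join(_CODON_ARR[full]),
                genome=cfg.genome_label,
            )
        )

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=list(CODONS))
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "beta": beta,
            "gc3_target": gc3_t,
            "gc12_target": gc12_t,
            "length_codons": lengths,
        }
    )
    return SyntheticDataset(
        config=cfg, sequences=sequences, counts=counts_df, truth=truth
    )


def simulate_expression(
    cfg: SimulationConfig, dataset: SyntheticDataset
) -> pd.DataFrame:
    """Attach a tissue RPKM matrix coupled to each gene's bias strength.

    Per gene: a latent tier (high/medium/low/silent) is drawn from
    ``tier_probs``; expressed genes get
    ``log10 RPKM ~ N(tier_mean + γ · β, gene_sd)`` with tissues as noisy
    replicates (``tissue_sd``); silent genes are 0 in every tissue.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(dataset.counts)
    beta = dataset.truth["beta"].to_numpy()
    tier = rng.choice(4, size=n, p=np.asarray(cfg.tier_probs) / sum(cfg.tier_probs))
    mu_tier = np.append(np.asarray(cfg.tier_means), 0.0)[tier]
    log_mu = mu_tier + cfg.expression_coupling * beta + rng.normal(0, cfg.gene_sd, n)
    vals = 10.0 ** (log_mu[:, None] + rng.normal(0, cfg.tissue_sd, (n, len(cfg.tissues))))
    vals[tier == 3] = 0.0
    expr = pd.DataFrame(vals, index=dataset.gene_ids, columns=list(cfg.tissues))
    expr.index.name = "gene_id"
    dataset.expression = expr
    dataset.truth["latent_tier"] = np.array(["high", "medium", "low", "silent"])[tier]
    return expr


@dataclass
class GenomePanel:
    """Panel of genomes with planted group structure (for clustering tests)."""

    datasets: list[SyntheticDataset]
    truth: pd.DataFrame  # genome, group

    def feature_matrix(self) -> pd.DataFrame:
        rows = {
            ds.config.genome_label: ds.pooled_rscu() for ds in self.datasets
        }
        return pd.DataFrame(rows).T


def simulate_genome_panel(
    n_genomes: int,
    divergence: float,
    cfg: SimulationConfig | None = None,
    n_groups: int = 1,
    within_divergence: float = 0.0,
) -> GenomePanel:
    """Generate genomes whose preferred-codon maps diverge between groups.

    Each of ``n_groups`` groups perturbs the default preferred-codon map:
    every amino acid's preferred codon is switched to a different
    synonymous codon with probability ``divergence`` (group level) and
    again with ``within_divergence`` (genome level).  Group labels are
    recorded as ground truth.
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if cfg is None:
        cfg = SimulationConfig(n_genes=80, bias_strength=0.5)
    rng = np.random.default_rng(cfg.seed)

    def perturb(base: dict[str, str], prob: float) -> dict[str, str]:
        out = dict(base)
        for aa in DEGENERATE_AA:
            if rng.random() < prob:
                options = [c for c in AA_TO_CODONS[aa] if c != base.get(aa)]
                out[aa] = options[rng.integers(0, len(options))]
        return out

    group_maps = [
        perturb(dict(DEFAULT_PREFERRED_CODONS), divergence) for _ in range(n_groups)
    ]
    datasets = []
    rows = []
    for i in range(n_genomes):
        group = i * n_groups // n_genomes
        genome_map = perturb(group_maps[group], within_divergence)
        sub = replace(
            cfg,
            preferred_codons=genome_map,
            genome_label=f"genome{i:02d}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        datasets.append(simulate_cds(sub))
        rows.append((sub.genome_label, group))
    truth = pd.DataFrame(rows, columns=["genome", "group"])
    return GenomePanel(datasets=datasets, truth=truth)


def preset_config(kind: str, n_genes: int = 500, seed: int = 0) -> SimulationConfig:
    """Qualitative presets emulating nuclear-like and plastid-like usage.

    ``nuclear`` targets mildly biased, mid-GC usage (mean ENC in the low
    50s, GC around 0.45); ``chloroplast`` targets slightly stronger bias
    and lower GC (mean ENC around 50, GC around 0.39).
    """
    if kind == "nuclear":
        return SimulationConfig(
            n_genes=n_genes, seed=seed, bias_strength=(0.0, 0.45),
            gc3_range=(0.3, 0.6), gc12_base=0.47, gc3_coupling=0.3,
            genome_label="nuclear",
        )
    if kind == "chloroplast":
        return SimulationConfig(
            n_genes=n_genes, seed=seed, bias_strength=(0.1, 0.55),
            gc3_range=(0.2, 0.45), gc12_base=0.41, gc3_coupling=0.3,
            genome_label="chloroplast",
        )
    raise ValueError("preset kind must be 'nuclear' or 'chloroplast'")
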