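"""Standard genetic code bookkeeping for codon-usage statistics.

Codon usage indices are all defined over the *synonymous* part of the
standard genetic code: the 61 sense codons minus the two single-codon
amino acids (Met/ATG, Trp/TGG), i.e. 59 codons spread over 18 degenerate
amino acids.  Wright's effective-number-of-codons statistic additionally
needs the amino acids grouped by synonymous-family size (degeneracy):
nine 2-fold, one 3-fold (Ile), five 4-fold and three 6-fold families.

Everything here is derived at import time from Biopython's standard DNA
codon table and frozen into plain tuples/dicts plus a few numpy indicator
arrays used by the vectorised metric routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

_BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: All 64 codons in alphabetical order; this ordering is the canonical
#: column order for every count vector / matrix in the package.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)  # 61 sense codons

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Amino acids encoded by a single codon; excluded from all synonymous-usage
#: statistics (their "usage" carries no choice).
SINGLE_CODON_AA: frozenset[str] = frozenset({"M", "W"})

SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AA
)

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AA_TO_CODONS
}

DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: The 18 amino acids with ≥2 synonymous codons, alphabetical.
DEGENERATE_AA: tuple[str, ...] = tuple(
    sorted(aa for aa, d in DEGENERACY.items() if d >= 2)
)

#: Degeneracy classes used in Wright's ENC class averaging.  Six-fold
#: families (Leu, Ser, Arg) are kept whole, not split 2+4.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa in DEGENERATE_AA if DEGENERACY[aa] == k))
    for k in (2, 3, 4, 6)
}

# Sanity: the standard code gives exactly (9, 1, 5, 3) families.
assert tuple(len(v) for v in DEGENERACY_CLASSES.values()) == (9, 1, 5, 3)
assert len(SYNONYMOUS_CODONS) == 59

#: All 20 amino acids, alphabetical; row/one-hot order for generator code.
AA_ORDER: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}


def _indicator(pred) -> np.ndarray:
    return np.array([bool(pred(c)) for c in CODONS])


#: Boolean masks over the canonical 64-codon axis.
IS_SENSE: np.ndarray = _indicator(lambda c: c not in STOP_CODONS)
IS_SYNONYMOUS: np.ndarray = _indicator(lambda c: c in SYNONYMOUS_CODONS)
#: IS_GC_AT_POS[k, i]: codon i has G or C at position k (0-based).
IS_GC_AT_POS: np.ndarray = np.stack(
    [_indicator(lambda c, k=k: c[k] in "GC") for k in range(3)]
)
#: THIRD_BASE_IS[b][i]: codon i's third base equals b.
THIRD_BASE_IS: dict[str, np.ndarray] = {
    b: _indicator(lambda c, b=b: c[2] == b) for b in _BASES
}
#: Codon index -> amino acid index in AA_ORDER, -1 for stop codons.
CODON_AA_INDEX: np.ndarray = np.array(
    [AA_INDEX[CODON_TO_AA[c]] if c not in STOP_CODONS else -1 for c in CODONS]
)


@dataclass(frozen=True)
class GeneticCodeTable:
    """Frozen view of the standard genetic code as used by this package."""

    codon_to_aa: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))
    stop_codons: frozenset[str] = STOP_CODONS
    single_codon_aa: frozenset[str] = SINGLE_CODON_AA
    synonymous_codons: tuple[str, ...] = SYNONYMOUS_CODONS
    degeneracy_classes: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEGENERACY_CLASSES)
    )

    @property
    def n_synonymous(self) -> int:
        return len(self.synonymous_codons)

    def codons_for(self, aa: str) -> tuple[str, ...]:
        return AA_TO_CODONS[aa]


#: Shared default instance.
STANDARD_CODE = GeneticCodeTable()
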