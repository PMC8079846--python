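"""tRNA adaptation index (tAI) from tRNA gene copy numbers.

The tAI of a codon measures how well the cellular tRNA pool serves it during
translation elongation.  Each codon receives a weighted sum of the gene copy
numbers (tGCN) of every anticodon that can decode it, with non-Watson–Crick
("wobble") codon:anticodon pairings at the third codon position discounted by
a penalty ``s`` in [0, 1]:

    W(codon) = sum over pairing anticodons of (1 - s) * tGCN(anticodon)

The weights are normalised by the best codon, ``w = W / max(W)``, so the most
tRNA-adapted codon has ``w = 1``.  Codons with ``W = 0`` are assigned the
geometric mean of the non-zero weights so that gene-level geometric means stay
defined.  The tAI of a gene is the geometric mean of ``w`` over its codons
(initiator and stop codon excluded here).

The default wobble penalties are the canonical eukaryotic constants:
``s(G:U) = 0.41``, ``s(I:C) = 0.28``, ``s(I:A) = 0.9999``, ``s(U:G) = 0.68``,
Watson–Crick pairs ``s = 0``, with anticodons whose position-34 base is A
treated as inosine-modified (I34), which lets them decode third-position
U, C and A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# Genetic-code constants (shared by the classification layer)
# ---------------------------------------------------------------------------

DNA_BASES = "ACGT"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with "*" for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Wobble rules
# ---------------------------------------------------------------------------

#: (anticodon position-34 base, codon third base) -> penalty s
DEFAULT_WOBBLE_S: dict[tuple[str, str], float] = {
    ("G", "T"): 0.41,  # G:U
    ("A", "C"): 0.28,  # I:C (A34 read as inosine)
    ("A", "A"): 0.9999,  # I:A
    ("T", "G"): 0.68,  # U:G
}

_WATSON_CRICK: tuple[tuple[str, str], ...] = (
    ("A", "T"),
    ("C", "G"),
    ("G", "C"),
    ("T", "A"),
)


@dataclass(frozen=True)
class WobbleRules:
    """Allowed codon(third base):anticodon(position 34) pairings.

    ``pairs`` maps ``(anticodon_34_base, codon_third_base)`` to the penalty
    ``s`` in [0, 1]; Watson–Crick pairs carry ``s = 0``.
    """

    pairs: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, c), s in self.pairs.items():
            if a not in DNA_BASES or c not in DNA_BASES:
                raise ValueError(f"invalid pairing alphabet: {(a, c)!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"penalty s={s} for {(a, c)} outside [0, 1]")

    @classmethod
    def default(cls, inosine: bool = True, s_values: Mapping[tuple[str, str], float] | None = None) -> "WobbleRules":
        """Canonical eukaryotic rules; ``inosine=False`` drops the I34 pairings.

        ``s_values`` overrides individual penalties, keyed like ``("G", "T")``.
        """
        pairs: dict[tuple[str, str], float] = {p: 0.0 for p in _WATSON_CRICK}
        overrides = dict(s_values or {})
        for key, s in DEFAULT_WOBBLE_S.items():
            if not inosine and key[0] == "A" and key != ("A", "T"):
                continue
            pairs[key] = overrides.pop(key, s)
        for key, s in overrides.items():
            pairs[key] = s
        return cls(pairs=pairs)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


@dataclass
class TAIWeights:
    """Normalised per-codon tAI weights.

    ``w`` maps every sense codon to a weight in (0, 1] (after zero-replacement);
    ``raw`` keeps the unnormalised weighted sums W, with 0.0 where no anticodon
    decodes the codon.
    """

    w: dict[str, float]
    raw: dict[str, float]

    def __post_init__(self) -> None:
        if self.w:
            m = max(self.w.values())
            if abs(m - 1.0) > 1e-9:
                raise ValueError(f"weights not normalised: max w = {m}")


def _normalize_anticodon(anticodon: str) -> str:
    ac = anticodon.strip().upper().replace("U", "T")
    if len(ac) != 3 or any(b not in DNA_BASES for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return ac


def anticodon_contributions(
    trnas: Mapping[str, int], rules: WobbleRules
) -> dict[str, dict[str, float]]:
    """Per-codon map anticodon -> (1 - s) * tGCN for every pairing anticodon.

    Codon positions 1–2 pair Watson–Crick with anticodon positions 36–35;
    only the codon third base : anticodon position-34 pairing is rule-driven.
    """
    contrib: dict[str, dict[str, float]] = {c: {} for c in SENSE_CODONS}
    for anticodon, copies in trnas.items():
        ac = _normalize_anticodon(anticodon)
        if copies < 0:
            raise ValueError(f"negative copy number for anticodon {anticodon!r}")
        if copies == 0:
            continue
        wobble34 = ac[0]
        codon_prefix = revcomp(ac[1:])  # codon bases 1-2
        for (a34, codon3), s in rules.pairs.items():
            if a34 != wobble34:
                continue
            codon = codon_prefix + codon3
            if codon in STOP_CODONS:
                continue
            value = (1.0 - s) * copies
            if value > 0.0:
                contrib[codon][ac] = contrib[codon].get(ac, 0.0) + value
    return contrib


def compute_weights(trnas: Mapping[str, int], rules: WobbleRules | None = None) -> TAIWeights:
    """Compute normalised tAI weights for all 61 sense codons.

    Raises ``ValueError`` when no codon receives any tRNA contribution.
    """
    rules = rules or WobbleRules.default()
    contrib = anticodon_contributions(trnas, rules)
    raw = {codon: sum(per.values()) for codon, per in contrib.items()}
    w_max = max(raw.values())
    if w_max <= 0.0:
        raise ValueError("no anticodon in the table decodes any sense codon")
    w = {codon: W / w_max for codon, W in raw.items()}
    nonzero = [x for x in w.values() if x > 0.0]
    fill = math.exp(sum(math.log(x) for x in nonzero) / len(nonzero))
    for codon, x in w.items():
        if x == 0.0:
            w[codon] = fill
    return TAIWeights(w=w, raw=raw)


def gene_tai(cds, weights: TAIWeights, skip_initiator: bool = True) -> float:
    """Geometric mean of codon weights over a coding sequence.

    ``cds`` is a list of codon strings or an object with a ``codons``
    attribute.  The initiator codon (index 0) and stop codons are excluded,
    as are codons containing ambiguity bases.
    """
    codons = getattr(cds, "codons", cds)
    log_sum = 0.0
    n = 0
    for i, codon in enumerate(codons):
        if skip_initiator and i == 0:
            continue
        if codon in STOP_CODONS or codon not in GENETIC_CODE:
            continue
        log_sum += math.log(weights.w[codon])
        n += 1
    if n == 0:
        raise ValueError("no usable codons for gene tAI")
    return math.exp(log_sum / n)


def delta_tai(ref_codon: str, alt_codon: str, weights: TAIWeights) -> float:
    """Signed weight change ``w(alt) - w(ref)`` of a substitution."""
    for codon in (ref_codon, alt_codon):
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} has no tAI weight")
        if codon not in weights.w:
            raise ValueError(f"not a sense codon: {codon!r}")
    return weights.w[alt_codon] - weights.w[ref_codon]


def tai_direction(delta: float) -> str:
    """Classify a delta-tAI value as ``tai_up`` / ``tai_down`` / ``tai_neutral``."""
    if delta > 0.0:
        return "tai_up"
    if delta < 0.0:
        return "tai_down"
    return "tai_neutral"
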