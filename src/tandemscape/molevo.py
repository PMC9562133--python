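"""Codon-level divergence between duplicated genes.

Pairwise protein alignment guides a back-translation to a codon alignment,
on which synonymous (Ks) and nonsynonymous (Ka) substitution rates are
estimated with the Nei–Gojobori (1986) counting method: fractional site
counting, pathway-averaged difference counting and the Jukes–Cantor
multiple-hit correction d = -(3/4)·ln(1 - (4/3)p).

Ks is approximately clock-like, so a duplication event is dated as

    T = Ks / (2 λ)

with λ the synonymous substitution rate per site per year (default
1.5×10⁻⁸, typical of grasses).  The Ka/Ks ratio classifies the selective
regime of a pair: <1 purifying (negative), ≈1 neutral, >1 positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import (
    GENETIC_CODE,
    STOP,
    is_valid_codon,
    pathway_differences,
    synonymous_site_count,
    translate,
)

GAP_CODON = "---"

#: Fraction-of-differences ceiling beyond which the Jukes–Cantor correction
#: is undefined; reaching it flags the estimate as saturated.
JC_SATURATION = 0.75


@dataclass(frozen=True)
class ClockParams:
    """Molecular-clock parameter: synonymous substitutions per site per year."""

    lam: float = 1.5e-8

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError(f"clock rate must be positive, got {self.lam}")


@dataclass
class CodonAlignment:
    """Two CDS aligned codon-wise under a guiding protein alignment.

    ``included`` masks the columns used for Ka/Ks: columns containing a
    gap, a stop codon or an ambiguous base are excluded.
    """

    id1: str
    id2: str
    codons1: list[str]
    codons2: list[str]
    included: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not (len(self.codons1) == len(self.codons2) == len(self.included)):
            raise ValueError("codon rows and mask must have equal length")

    def __len__(self) -> int:
        return len(self.codons1)

    @property
    def included_pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b, ok in zip(self.codons1, self.codons2, self.included)
            if ok
        ]


@dataclass
class KaKsResult:
    """NG86 estimates for one gene pair.

    S, N are synonymous/nonsynonymous site counts (S + N = 3 × included
    codons); Sd, Nd the pathway-averaged difference counts.  ``ratio`` is
    ``nan`` when Ks = 0 or the estimate is saturated, and ``selection`` is
    then "undefined".
    """

    id1: str = ""
    id2: str = ""
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    Ka: float = float("nan")
    Ks: float = float("nan")
    ratio: float = float("nan")
    selection: str = "undefined"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, as used in report tables (0.145 -> 0.15)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def align_proteins(
    p1: str,
    p2: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[str, str, float]:
    """Global (Needleman–Wunsch) protein alignment with affine gaps.

    Returns the two gapped rows and the optimal score.  The aligner's
    enumeration order makes the returned alignment deterministic among
    co-optimal ones.
    """
    if not p1 or not p2:
        raise ValueError("cannot align an empty protein sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = next(iter(aligner.align(p1, p2)))
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def backtranslate(
    aln1: str,
    aln2: str,
    cds1: str,
    cds2: str,
    id1: str = "seq1",
    id2: str = "seq2",
) -> CodonAlignment:
    """Thread CDS codons through a protein alignment (PAL2NAL-style).

    Each amino-acid column becomes its source codon; protein gaps become
    ``---`` codon gaps.  The CDS must be exactly 3× the ungapped protein
    length and translate to it.
    """
    rows = []
    for aln, cds, pid in ((aln1, cds1, id1), (aln2, cds2, id2)):
        protein = aln.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{pid}: CDS length {len(cds)} != 3 x protein length {len(protein)}"
            )
        if translate(cds, pid) != protein:
            raise ValueError(f"{pid}: CDS does not translate to the aligned protein")
        codons = []
        k = 0
        for aa in aln:
            if aa == "-":
                codons.append(GAP_CODON)
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append(codons)
    codons1, codons2 = rows
    included = np.array(
        [_usable_column(a, b) for a, b in zip(codons1, codons2)], dtype=bool
    )
    return CodonAlignment(id1, id2, codons1, codons2, included)


def _usable_column(a: str, b: str) -> bool:
    if a == GAP_CODON or b == GAP_CODON:
        return False
    if not (is_valid_codon(a) and is_valid_codon(b)):
        return False
    return GENETIC_CODE[a] != STOP and GENETIC_CODE[b] != STOP


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4)·ln(1 - (4/3)p); nan at/after saturation."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= JC_SATURATION:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(ca: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks on a codon alignment.

    Site counts average the two sequences' fractional synonymous sites.
    Differences average all k! mutational pathways per codon pair, each
    step classified by the universal code; pathways through stop codons
    are dropped and a pair with no viable pathway is excluded entirely
    (from sites and differences both).
    """
    pairs = ca.included_pairs
    if not pairs:
        raise ValueError("codon alignment has no included columns")
    S = N = Sd = Nd = 0.0
    used = 0
    for a, b in pairs:
        sd, nd, viable = pathway_differences(a, b)
        if not viable:
            continue
        s = 0.5 * (synonymous_site_count(a) + synonymous_site_count(b))
        S += s
        N += 3.0 - s
        Sd += sd
        Nd += nd
        used += 1
    result = KaKsResult(id1=ca.id1, id2=ca.id2, S=S, N=N, Sd=Sd, Nd=Nd)
    if used == 0:
        return result
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    result.Ks = jukes_cantor(pS)
    result.Ka = jukes_cantor(pN)
    if math.isnan(result.Ka) or math.isnan(result.Ks):
        return result  # saturated: left flagged undefined
    result.ratio = kaks_ratio_raw(result.Ka, result.Ks)
    result.selection = classify_selection(result.ratio)
    return result


def kaks_pair(
    cds1: str, cds2: str, id1: str = "seq1", id2: str = "seq2", **align_kw
) -> KaKsResult:
    """Convenience: align translations, back-translate, run NG86."""
    p1 = translate(cds1, id1)
    p2 = translate(cds2, id2)
    a1, a2, _score = align_proteins(p1, p2, **align_kw)
    return ng86(backtranslate(a1, a2, cds1, cds2, id1, id2))


def kaks_ratio_raw(ka: float, ks: float) -> float:
    return ka / ks if ks > 0 else float("nan")


def kaks_ratio(ka: float, ks: float) -> float:
    """Report-table Ka/Ks: ka/ks rounded half-up to two decimals.

    Undefined (nan) when ks = 0 — a zero synonymous distance carries no
    information about relative rates.
    """
    if not ks > 0:
        return float("nan")
    return round_half_up(ka / ks, 2)


def classify_selection(ratio: float, tol: float = 1e-9) -> str:
    """<1 negative (purifying), =1 neutral, >1 positive; nan -> undefined."""
    if ratio is None or math.isnan(ratio):
        return "undefined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "negative" if ratio < 1.0 else "positive"


def divergence_time(ks: float, clock: ClockParams = ClockParams()) -> float:
    """Duplication age in millions of years: T = Ks / (2 λ) / 10⁶."""
    if ks < 0:
        raise ValueError(f"Ks must be non-negative, got {ks}")
    return ks / (2.0 * clock.lam) / 1e6


def divergence_time_ma(ks: float, clock: ClockParams = ClockParams()) -> float:
    """`divergence_time` rounded half-up to one decimal, as reported."""
    return round_half_up(divergence_time(ks, clock), 1)
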