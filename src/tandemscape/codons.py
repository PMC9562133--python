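"""Genetic-code utilities shared by the Ka/Ks estimator and the sequence simulator.

The universal (standard) nuclear code is the default everywhere; every
public function accepts an alternative ``code`` mapping so non-standard
tables can be injected.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

STOP = "*"


def standard_code() -> dict[str, str]:
    """Codon -> amino acid (one letter), stops mapped to ``"*"``."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = STOP
    return code


GENETIC_CODE = standard_code()

SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP))


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def translate(cds: str, name: str = "sequence") -> str:
    """Translate an in-frame, stop-free CDS; raises on length or alphabet problems."""
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if not is_valid_codon(codon):
            raise ValueError(f"{name}: ambiguous or invalid codon {codon!r} at codon {i // 3}")
        aas.append(GENETIC_CODE[codon])
    return "".join(aas)


def single_neighbours(codon: str):
    """All nine codons one nucleotide change away, with (position, new base)."""
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """Number of synonymous sites in a codon, NG86 style.

    Each position contributes (number of synonymous single-nucleotide
    changes at that position) / 3; changes that create a stop codon are
    counted as nonsynonymous.  The nonsynonymous site count is 3 minus
    this value by construction.
    """
    aa = GENETIC_CODE[codon]
    syn = 0
    for _pos, _base, mutant in single_neighbours(codon):
        if GENETIC_CODE[mutant] == aa and GENETIC_CODE[mutant] != STOP:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Averages over all k! orderings of the k differing positions; each step
    is classified by the genetic code.  A pathway passing through a stop
    codon is dropped; if every pathway drops, the pair is unusable and the
    third element of the result is False (the codon column is excluded).
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0, True
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        current = codon_a
        syn = 0
        nonsyn = 0
        viable = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == STOP:
                viable = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if viable:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return syn_total / n_paths, nonsyn_total / n_paths, True


def random_cds(rng, n_codons: int) -> str:
    """Uniform random stop-free CDS of ``n_codons`` codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)
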