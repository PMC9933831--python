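"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with pepscout.digestion: cleavage positions
are found by a direct scan and digestion by enumerating every substring and
testing its boundaries, so the two routes can disagree if either is wrong.
"""

from __future__ import annotations

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def oracle_trypsin_sites(sequence: str) -> set[int]:
    """1-based positions after which trypsin cuts (K/R not before P)."""
    return {
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    }


def oracle_digest(
    sequence: str,
    max_missed: int = 1,
    min_length: int = 7,
    max_length: int = 25,
    exclude_nonstandard: bool = True,
) -> list[tuple[str, int, int, int]]:
    """Every substring whose boundaries are cleavage boundaries or termini,
    with internal cut count within the missed-cleavage budget and length in
    the window. Returns (sequence, start, end, missed) sorted by start then
    length — the same order digest() promises."""
    sites = oracle_trypsin_sites(sequence)
    boundaries = sites | {0, len(sequence)}
    out = []
    for start in range(1, len(sequence) + 1):
        if start - 1 not in boundaries:
            continue
        for end in range(start, len(sequence) + 1):
            if end not in boundaries:
                continue
            internal = sum(1 for s in sites if start - 1 < s < end)
            if internal > max_missed:
                continue
            length = end - start + 1
            if not (min_length <= length <= max_length):
                continue
            sub = sequence[start - 1 : end]
            if exclude_nonstandard and not set(sub) <= CANONICAL:
                continue
            out.append((sub, start, end, internal))
    out.sort(key=lambda t: (t[1], t[2] - t[1]))
    return out


def oracle_unique_peptides(sequences: dict[str, str], target: str, **digest_kw) -> set[str]:
    """Full-library cross-digest: a target peptide is unique iff it appears
    in no other record's digest."""
    digests = {
        acc: {t[0] for t in oracle_digest(seq, **digest_kw)}
        for acc, seq in sequences.items()
    }
    others = set()
    for acc, peps in digests.items():
        if acc != target:
            others |= peps
    return digests[target] - others
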