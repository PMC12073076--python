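"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, written against the rule/statistic
definitions directly and sharing no code with the package internals.
"""

from __future__ import annotations


def oracle_cut_flags(sequence: str, enzymes) -> list:
    """For each bond i (between residues i and i+1, 0-based), is it cut?"""
    flags = []
    for i in range(len(sequence) - 1):
        cut = False
        for enzyme in enzymes:
            for rule in enzyme.rules:
                if sequence[i] in rule.p1_residues and sequence[i + 1] not in rule.p1prime_blocked:
                    cut = True
        flags.append(cut)
    return flags


def oracle_digest(sequence: str, enzymes) -> list:
    """Fragment sequences by a per-bond scan."""
    flags = oracle_cut_flags(sequence, enzymes)
    fragments, current = [], sequence[0]
    for i in range(1, len(sequence)):
        if flags[i - 1]:
            fragments.append(current)
            current = ""
        current += sequence[i]
    fragments.append(current)
    return fragments


def oracle_release_stats(sequence: str, enzymes, table, activity) -> dict:
    """a, d, A, A_E, B, B_E by exhaustive substring and fragment enumeration."""
    records = {}
    for record in table:
        if record.activity == activity:
            records.setdefault(record.sequence, record)

    n = len(sequence)
    a = 0
    b_sum = 0.0
    for i in range(n):
        for j in range(i + 2, n + 1):  # peptides only: length >= 2
            record = records.get(sequence[i:j])
            if record is not None:
                a += 1
                if record.ic50_uM is not None:
                    b_sum += 1.0 / record.ic50_uM

    d = 0
    be_sum = 0.0
    for fragment in oracle_digest(sequence, enzymes):
        record = records.get(fragment) if len(fragment) >= 2 else None
        if record is not None:
            d += 1
            if record.ic50_uM is not None:
                be_sum += 1.0 / record.ic50_uM

    return {
        "a": a, "d": d,
        "A": a / n, "A_E": d / n,
        "B": b_sum / n, "B_E": be_sum / n,
    }
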