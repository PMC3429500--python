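"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: structures are
enumerated exhaustively, genomes are scanned offset by offset, and windows
are scored with a separate rule transcription, so agreement is evidence
rather than tautology.
"""

from __future__ import annotations

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}
PAIR_E = {("A", "T"): -2.0, ("T", "A"): -2.0, ("G", "C"): -3.0, ("C", "G"): -3.0,
          ("G", "T"): -1.0, ("T", "G"): -1.0}
COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def can_pair(a: str, b: str) -> bool:
    return (dna(a), dna(b)) in WC or (dna(a), dna(b)) in WOBBLE


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(dna(seq)))


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested pair set of ``seq`` (hairpin loops >= min_loop)."""
    seq = dna(seq)

    def gen(i: int, j: int):
        if j - i <= min_loop:
            yield frozenset()
            return
        yield from gen(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                for left in gen(i, k - 1):
                    for inner in gen(k + 1, j - 1):
                        yield left | inner | {(k, j)}

    yield from gen(0, len(seq) - 1)


def pairset_energy(seq: str, pairs, hairpin_cost: float = 3.0) -> float:
    """Direct energy of an explicit structure: stacked pairs contribute
    their own pair energy, each hairpin loop costs +3."""
    seq = dna(seq)
    ps = set(pairs)
    e = 0.0
    for i, j in ps:
        if (i - 1, j + 1) in ps:
            e += PAIR_E[(seq[i], seq[j])]
        if not any(i < a and b < j for a, b in ps):
            e += hairpin_cost
    return e


def brute_mfe(seq: str) -> float:
    return min(
        (pairset_energy(seq, s) for s in enumerate_structures(seq)), default=0.0
    )


def brute_map(tag: str, scaffolds: dict[str, str], max_mismatch: int):
    """All-offsets, both-strand scan for <=max_mismatch occurrences."""
    hits = []
    for query, strand in ((dna(tag), "+"), (revcomp(tag), "-")):
        L = len(query)
        for name, seq in scaffolds.items():
            seq = dna(seq)
            for s in range(len(seq) - L + 1):
                mism = sum(a != b for a, b in zip(query, seq[s : s + L]))
                if mism <= max_mismatch:
                    hits.append((name, s, strand, mism))
    return sorted(hits)


def brute_site_scan(mirna: str, transcript: str, penalty_max: float = 2.0):
    """Exhaustive window oracle for target scanning: returns accepted
    (start, penalty) windows under a from-scratch transcription of the
    penalty and positional rules."""
    mirna, transcript = dna(mirna), dna(transcript)
    L = len(mirna)
    out = []
    for s in range(len(transcript) - L + 1):
        site = transcript[s : s + L]
        penalty = 0.0
        xs = []
        for i in range(L):  # miRNA position i+1 faces site position L-1-i
            pair = (mirna[i], site[L - 1 - i])
            if pair in WC:
                continue
            if pair in WOBBLE:
                penalty += 0.5
            else:
                penalty += 1.0
                xs.append(i + 1)
        if penalty > penalty_max or len(xs) > 4:
            continue
        if any(p in (10, 11) for p in xs):
            continue
        if sum(1 for p in xs if 2 <= p <= 11) > 1:
            continue
        tail = [p for p in xs if 12 <= p <= min(21, L)]
        if len(tail) > 3:
            continue
        if any(
            all(q in xs for q in (p, p + 1, p + 2))
            for p in range(12, min(21, L) - 1)
        ):
            continue
        out.append((s, penalty))
    return out
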