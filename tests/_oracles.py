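"""Brute-force oracles for motif matching and subsumption, independent of
the package implementation: every wildcard length and start position is
enumerated directly."""

import itertools

from goxprofile.motifs import MotifPattern, MotifToken


def oracle_token_sets(pattern, lengths):
    """Expand tokens to position sets (None = wildcard, any character)."""
    sets = []
    for tok, L in zip(pattern.tokens, lengths):
        if tok.is_wild:
            sets.extend([None] * L)
        else:
            sets.append(set(tok.residues))
    return sets


def oracle_assignments(pattern):
    ranges = [
        range(t.min_len, t.max_len + 1) if t.is_wild else range(1, 2)
        for t in pattern.tokens
    ]
    for lengths in itertools.product(*ranges):
        yield oracle_token_sets(pattern, lengths)


def oracle_match(pattern, seq):
    """Every-start, every-wildcard-assignment brute-force matcher."""
    hits = set()
    for sets in oracle_assignments(pattern):
        L = len(sets)
        for s in range(len(seq) - L + 1):
            if all(sets[k] is None or seq[s + k] in sets[k] for k in range(L)):
                hits.add((s + 1, s + L))
    return hits


def oracle_full_match(pattern, s):
    return any(
        len(sets) == len(s)
        and all(sets[k] is None or ch in sets[k] for k, ch in enumerate(s))
        for sets in oracle_assignments(pattern)
    )


def oracle_subsumes(general, specific, alphabet):
    """Enumerate every string matching `specific` over a small alphabet."""
    lo, hi = specific.length_range()
    for L in range(lo, hi + 1):
        for s in itertools.product(alphabet, repeat=L):
            word = "".join(s)
            if oracle_full_match(specific, word) and not oracle_full_match(general, word):
                return False
    return True


def random_pattern(rng, alphabet="ABC", max_tokens=5):
    n = int(rng.integers(1, max_tokens + 1))
    tokens = []
    for i in range(n):
        anchored = i == 0 or i == n - 1
        kind = "anchor" if anchored else rng.choice(["anchor", "wild"], p=[0.6, 0.4])
        if kind == "wild":
            if rng.random() < 0.5:
                tokens.append(MotifToken("wild"))
            else:
                lo = int(rng.integers(1, 3))
                tokens.append(
                    MotifToken("wild", min_len=lo, max_len=lo + int(rng.integers(0, 2)))
                )
        else:
            if rng.random() < 0.5:
                tokens.append(
                    MotifToken("fixed", alphabet[int(rng.integers(len(alphabet)))])
                )
            else:
                pair = rng.choice(len(alphabet), size=2, replace=False)
                tokens.append(MotifToken("class", alphabet[pair[0]] + alphabet[pair[1]]))
    return MotifPattern(tokens=tokens)
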