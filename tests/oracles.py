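"""Independent brute-force oracles used by the structure tests.

These deliberately avoid the package's dynamic program: structures are
enumerated recursively and scored by direct scanning of the pair set,
so agreement with ``mirforge.folding.fold`` is a genuine cross-check.
The energy parameter table is shared (it is the model, not the
algorithm).
"""

from mirforge.folding import MIN_LOOP, PAIR_OK, STACK_CENTI
from mirforge._seq import encode


def enumerate_structures(seq):
    """All pseudoknot-free pair sets with hairpin loops >= MIN_LOOP."""
    s = encode(seq)
    memo = {}

    def rec(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if i >= j:
            return [()]
        out = [tuple(p) for p in rec(i + 1, j)]
        for k in range(i + MIN_LOOP + 1, j + 1):
            if PAIR_OK[s[i], s[k]]:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        memo[(i, j)] = out
        return out

    return rec(0, len(seq) - 1)


def structure_energy_centi(pairs, seq):
    """Sum of stacking terms over adjacent pairs, centi-kcal/mol."""
    s = encode(seq)
    pset = set(pairs)
    e = 0
    for i, j in pairs:
        if (i + 1, j - 1) in pset:
            e += int(STACK_CENTI[s[i], s[j], s[i + 1], s[j - 1]])
    return e


def brute_force_optimum(seq):
    """(energy_centi, n_pairs) minimising energy, then pair count."""
    return min((structure_energy_centi(p, seq), len(p))
               for p in enumerate_structures(seq))
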