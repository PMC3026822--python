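"""Secondary-structure prediction for candidate miRNA precursors.

The built-in backend minimises a nearest-neighbour stacking free energy
over all pseudoknot-free structures: every pair of adjacent base pairs
(i,j)/(i+1,j-1) contributes a Turner-style stacking term, hairpin loops
must span at least ``MIN_LOOP`` unpaired bases, and Watson-Crick plus
G:U wobble pairs are allowed.  There are no loop or multiloop penalties,
so the model is a stacking-only approximation of the full thermodynamic
treatment; an external folding engine can be swapped in through the same
``(structure, delta_g)`` contract.

Energies are handled internally in integer centi-kcal/mol so that ties
are exact.  Optimality is defined lexicographically: minimum energy
first, then the fewest base pairs (a lone pair contributes no stacking
energy, so zero-energy decorations are dropped).

Significance of a fold is assessed against dinucleotide-preserving
shuffles (Altschul-Erikson procedure): shuffled sequences have exactly
the input's dinucleotide count vector, and the empirical p-value is
(1 + #{shuffles with dG <= dG(seq)}) / (n_shuffles + 1).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

from ._seq import encode

MIN_LOOP = 3  # minimum unpaired bases closed by a hairpin pair

# Base codes: A=0, C=1, G=2, U=3.
PAIR_OK = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    PAIR_OK[_a, _b] = True

# Turner-style 37C stacking free energies, centi-kcal/mol.  Entry
# [a,b,c,d] is the increment for outer pair a:b stacked on inner pair
# c:d (c = a+1, d = b-1 in sequence coordinates).
_STACK_BY_PAIR = {
    # outer: {inner: dG}
    ("A", "U"): {("A", "U"): -93, ("C", "G"): -224, ("G", "C"): -208,
                 ("G", "U"): -55, ("U", "A"): -110, ("U", "G"): -136},
    ("C", "G"): {("A", "U"): -211, ("C", "G"): -326, ("G", "C"): -236,
                 ("G", "U"): -141, ("U", "A"): -208, ("U", "G"): -211},
    ("G", "C"): {("A", "U"): -235, ("C", "G"): -342, ("G", "C"): -326,
                 ("G", "U"): -153, ("U", "A"): -224, ("U", "G"): -251},
    ("G", "U"): {("A", "U"): -127, ("C", "G"): -251, ("G", "C"): -211,
                 ("G", "U"): -50, ("U", "A"): -136, ("U", "G"): 129},
    ("U", "A"): {("A", "U"): -133, ("C", "G"): -235, ("G", "C"): -211,
                 ("G", "U"): -100, ("U", "A"): -93, ("U", "G"): -127},
    ("U", "G"): {("A", "U"): -100, ("C", "G"): -153, ("G", "C"): -141,
                 ("G", "U"): 30, ("U", "A"): -55, ("U", "G"): -50},
}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
STACK_CENTI = np.zeros((4, 4, 4, 4), dtype=np.int64)
for (_oa, _ob), _inner in _STACK_BY_PAIR.items():
    for (_ia, _ib), _e in _inner.items():
        STACK_CENTI[_CODE[_oa], _CODE[_ob], _CODE[_ia], _CODE[_ib]] = _e

_INF = np.int64(1 << 40)


@njit(cache=True)
def _fill(s, stack, pair_ok):  # pragma: no cover - exercised via fold()
    L = s.shape[0]
    V = np.full((L, L), _INF, dtype=np.int64)
    VP = np.zeros((L, L), dtype=np.int64)
    Wns = np.zeros((L, L), dtype=np.int64)
    WnsP = np.zeros((L, L), dtype=np.int64)
    W = np.zeros((L, L), dtype=np.int64)
    WP = np.zeros((L, L), dtype=np.int64)
    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            # Wns: best structure on [i, j] with i and j not paired to
            # each other.  Option 1: j unpaired.
            be = W[i, j - 1]
            bp = WP[i, j - 1]
            # Option 2: j paired with k in (i, j).
            for k in range(i + 1, j - MIN_LOOP):
                if pair_ok[s[k], s[j]] and V[k, j] < _INF:
                    e = W[i, k - 1] + V[k, j]
                    p = WP[i, k - 1] + VP[k, j]
                    if e < be or (e == be and p < bp):
                        be = e
                        bp = p
            Wns[i, j] = be
            WnsP[i, j] = bp
            # V: best structure given (i, j) paired.
            if pair_ok[s[i], s[j]] and span > MIN_LOOP:
                ie = Wns[i + 1, j - 1]
                ip = WnsP[i + 1, j - 1]
                if span - 2 > MIN_LOOP and pair_ok[s[i + 1], s[j - 1]] \
                        and V[i + 1, j - 1] < _INF:
                    e = stack[s[i], s[j], s[i + 1], s[j - 1]] + V[i + 1, j - 1]
                    p = VP[i + 1, j - 1]
                    if e < ie or (e == ie and p < ip):
                        ie = e
                        ip = p
                V[i, j] = ie
                VP[i, j] = ip + 1
            # W: unconstrained optimum.
            be = Wns[i, j]
            bp = WnsP[i, j]
            if V[i, j] < be or (V[i, j] == be and VP[i, j] < bp):
                be = V[i, j]
                bp = VP[i, j]
            W[i, j] = be
            WP[i, j] = bp
    return V, VP, Wns, WnsP, W, WP


def _traceback(s, tabs):
    V, VP, Wns, WnsP, W, WP = tabs
    L = s.shape[0]
    pairs = []
    stack = [(0, L - 1, 0)]  # state: 0=W, 1=Wns, 2=V
    while stack:
        i, j, state = stack.pop()
        if j <= i:
            continue
        if state == 0:
            if (V[i, j] < Wns[i, j]
                    or (V[i, j] == Wns[i, j] and VP[i, j] < WnsP[i, j])):
                stack.append((i, j, 2))
            else:
                stack.append((i, j, 1))
        elif state == 1:
            be, bp, bk = W[i, j - 1], WP[i, j - 1], -1
            for k in range(i + 1, j - MIN_LOOP):
                if PAIR_OK[s[k], s[j]] and V[k, j] < _INF:
                    e = W[i, k - 1] + V[k, j]
                    p = WP[i, k - 1] + VP[k, j]
                    if e < be or (e == be and p < bp):
                        be, bp, bk = e, p, k
            if bk < 0:
                stack.append((i, j - 1, 0))
            else:
                stack.append((i, bk - 1, 0))
                stack.append((bk, j, 2))
        else:
            pairs.append((i, j))
            span = j - i
            ie, ip = Wns[i + 1, j - 1], WnsP[i + 1, j - 1]
            use_stack = False
            if span - 2 > MIN_LOOP and PAIR_OK[s[i + 1], s[j - 1]] \
                    and V[i + 1, j - 1] < _INF:
                e = STACK_CENTI[s[i], s[j], s[i + 1], s[j - 1]] + V[i + 1, j - 1]
                p = VP[i + 1, j - 1]
                if e < ie or (e == ie and p < ip):
                    use_stack = True
            if use_stack:
                stack.append((i + 1, j - 1, 2))
            else:
                stack.append((i + 1, j - 1, 1))
    return pairs


@lru_cache(maxsize=4096)
def fold(seq: str) -> tuple[str, float]:
    """Predict a minimum-energy structure for ``seq``.

    Returns a dot-bracket string of the same length and the folding free
    energy dG in kcal/mol (0.0 when no pair is formed).  Characters
    outside AUCG/T raise ``ValueError``.
    """
    if len(seq) == 0:
        return "", 0.0
    s = encode(seq)
    if len(seq) < MIN_LOOP + 2:
        return "." * len(seq), 0.0
    tabs = _fill(s, STACK_CENTI, PAIR_OK)
    energy = int(tabs[4][0, len(seq) - 1])
    pairs = _traceback(s, tabs)
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db), energy / 100.0


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        out[d] = out.get(d, 0) + 1
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts.

    First and last characters are fixed; the returned permutation uses
    every original dinucleotide edge exactly once (an Eulerian walk on
    the dinucleotide multigraph).
    """
    if len(seq) < 4:
        raise ValueError("sequence too short to shuffle (<4 nt)")
    chars = list(seq)
    last = chars[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    verts = [v for v in edges if v != last]
    if not verts:  # homopolymer (or e.g. "ABBB..B"): walk is forced
        pools = {v: list(es) for v, es in edges.items()}
    else:
        # Choose a terminal edge per non-final vertex forming a tree
        # into `last`; rejection-sample (the original ordering is a
        # witness, so success probability is bounded away from zero).
        while True:
            term = {v: es[rng.integers(len(es))] for v, es in edges.items()
                    if v != last}
            ok = True
            for v in verts:
                seen = {v}
                cur = v
                while cur != last:
                    cur = term.get(cur)
                    if cur is None or cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                if not ok:
                    break
            if ok:
                break
        pools = {}
        for v, es in edges.items():
            rest = list(es)
            if v != last:
                rest.remove(term[v])
            order = rng.permutation(len(rest))
            shuffled = [rest[k] for k in order]
            if v != last:
                shuffled.append(term[v])
            pools[v] = shuffled
    idx = {v: 0 for v in pools}
    out = [chars[0]]
    cur = chars[0]
    for _ in range(len(chars) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_significance(seq: str, n_shuffles: int = 99,
                         seed: int | None = None) -> float:
    """Empirical p-value of dG(seq) against dinucleotide shuffles."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(seq) < 4:
        raise ValueError("sequence too short to shuffle (<4 nt)")
    rng = np.random.default_rng(seed)
    _, dg0 = fold(seq)
    hits = 0
    for _ in range(n_shuffles):
        _, dg = fold(dinucleotide_shuffle(seq, rng))
        if dg <= dg0:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)
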