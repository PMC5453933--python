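"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity from first principles (enumeration,
closed form, or naive recursion) without importing the implementation it
checks.
"""

from itertools import combinations, permutations
from math import comb, exp, log

# --- genetic code, built independently (table literal, not the package's) ---

_CODON_TABLE = """
TTT F  TTC F  TTA L  TTG L  CTT L  CTC L  CTA L  CTG L
ATT I  ATC I  ATA I  ATG M  GTT V  GTC V  GTA V  GTG V
TCT S  TCC S  TCA S  TCG S  CCT P  CCC P  CCA P  CCG P
ACT T  ACC T  ACA T  ACG T  GCT A  GCC A  GCA A  GCG A
TAT Y  TAC Y  TAA *  TAG *  CAT H  CAC H  CAA Q  CAG Q
AAT N  AAC N  AAA K  AAG K  GAT D  GAC D  GAA E  GAG E
TGT C  TGC C  TGA *  TGG W  CGT R  CGC R  CGA R  CGG R
AGT S  AGC S  AGA R  AGG R  GGT G  GGC G  GGA G  GGG G
"""
CODE = dict(zip(_CODON_TABLE.split()[0::2], _CODON_TABLE.split()[1::2]))


def ng86_brute(codons_a, codons_b):
    """Nei-Gojobori counts by direct enumeration.

    Returns (S, N, Sd, Nd).  Site fractions: per position, share of the
    three single-base changes that preserve the amino acid (stop-creating
    changes count as nonsynonymous), averaged over the two sequences.
    Differences: average over all orderings of the differing positions,
    dropping orderings that pass through a stop (all orderings if none
    survive).
    """
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb:
            continue
        for codon in (ca, cb):
            syn = 0.0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mutated = codon[:pos] + base + codon[pos + 1:]
                    if CODE[mutated] == CODE[codon]:
                        syn += 1.0
            S += syn / 3.0 / 2.0
            N += (9.0 - syn) / 3.0 / 2.0
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        if not diffs:
            continue
        results = []
        for order in permutations(diffs):
            current, s_cnt, n_cnt, hits_stop = ca, 0, 0, False
            for pos in order:
                nxt = current[:pos] + cb[pos] + current[pos + 1:]
                if CODE[nxt] == "*":
                    hits_stop = True
                if CODE[nxt] == CODE[current]:
                    s_cnt += 1
                else:
                    n_cnt += 1
                current = nxt
            results.append((s_cnt, n_cnt, hits_stop))
        clean = [r for r in results if not r[2]] or results
        Sd += sum(r[0] for r in clean) / len(clean)
        Nd += sum(r[1] for r in clean) / len(clean)
    return S, N, Sd, Nd


def jukes_cantor_brute(p):
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


# --------------------------------------------------------------- chaining

def _chain_valid(anchors, max_gap):
    """anchors: list of (r1, r2) in candidate order."""
    for direction in (1, -1):
        ok = True
        for (a1, a2), (b1, b2) in zip(anchors, anchors[1:]):
            if not (0 < b1 - a1 <= max_gap):
                ok = False
                break
            if not (0 < (b2 - a2) * direction <= max_gap):
                ok = False
                break
        if ok:
            return True
    return False


def longest_chain_brute(anchors, max_gap):
    """Maximum-size valid chain by subset enumeration (anchors <= ~14).

    Anchors are (r1, r2) tuples.  Returns the best size (0 if none).
    """
    pts = sorted(anchors)
    best = 0
    n = len(pts)
    for size in range(n, 0, -1):
        if size <= best:
            break
        for subset in combinations(range(n), size):
            chain = [pts[i] for i in subset]
            if _chain_valid(chain, max_gap):
                best = size
                break
        if best:
            break
    return best


# --------------------------------------------------------------- alignment

def align_score_brute(a, b, score, open_gap=-10.0, extend=-0.5):
    """Best global alignment score by exhaustive enumeration.

    ``score(x, y)`` gives the substitution score.  Affine gaps: the first
    gap column of a run costs ``open_gap``, later columns ``extend``.
    Suitable only for very short sequences.
    """
    best = [float("-inf")]

    def rec(i, j, acc, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]), "m")
        if i < len(a):
            cost = extend if state == "d" else open_gap
            rec(i + 1, j, acc + cost, "d")
        if j < len(b):
            cost = extend if state == "i" else open_gap
            rec(i, j + 1, acc + cost, "i")

    rec(0, 0, 0.0, "m")
    return best[0]


# --------------------------------------------------------------- exact tests

def binom_pmf(k, n, p):
    return comb(n, k) * p ** k * (1.0 - p) ** (n - k)


def binom_upper_tail(k, n, p):
    """P(X >= k) by summation."""
    return sum(binom_pmf(i, n, p) for i in range(k, n + 1))


def binom_lower_tail(k, n, p):
    """P(X <= k) by summation."""
    return sum(binom_pmf(i, n, p) for i in range(0, k + 1))


def fisher_2x2_brute(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration (small margins).

    Table [[a, b], [c, d]]; sums probabilities of all tables with the same
    margins whose probability does not exceed the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x) * comb(n - col1, row1 - x)) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))
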