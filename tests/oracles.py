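"""Independent reference implementations used only to cross-check the library.

These deliberately use different algorithms from the package: the LCS
oracle is a top-down memoized recursion over suffixes (the library uses an
iterative two-row DP), and the n-gram overlap oracle counts per-gram
minima explicitly instead of Counter intersection.
"""

from functools import lru_cache


def oracle_lcs(a: tuple, b: tuple) -> int:
    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + go(i + 1, j + 1)
        return max(go(i + 1, j), go(i, j + 1))

    return go(0, 0)


def oracle_ngram_overlap(answer: list, reference: list, n: int) -> tuple[int, int, int]:
    """(clipped overlap, answer n-gram count, reference n-gram count)."""
    ans = [tuple(answer[i:i + n]) for i in range(len(answer) - n + 1)]
    ref = [tuple(reference[i:i + n]) for i in range(len(reference) - n + 1)]
    overlap = 0
    for gram in set(ans):
        overlap += min(ans.count(gram), ref.count(gram))
    return overlap, len(ans), len(ref)


def oracle_rouge(answer: list, reference: list, n: int | None) -> tuple[float, float, float]:
    """(precision, recall, F) for ROUGE-n (n in {1,2}) or ROUGE-L (n=None)."""
    if n is None:
        lcs = oracle_lcs(tuple(answer), tuple(reference))
        overlap, n_ans, n_ref = lcs, len(answer), len(reference)
    else:
        overlap, n_ans, n_ref = oracle_ngram_overlap(answer, reference, n)
    p = overlap / n_ans if n_ans else 0.0
    r = overlap / n_ref if n_ref else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f
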