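"""Independent brute-force Smith-Waterman oracle.

A deliberately naive, pure-Python full-matrix DP used only to verify the
production aligner.  It shares no code with palsplit.align.
"""


def naive_sw_score(query: str, target: str, match: int = 3,
                   mismatch: int = -4, gap: int = -3) -> int:
    """Optimal local alignment score by full-matrix DP (linear gaps).

    N never matches anything, including another N.
    """
    q = query.upper()
    t = target.upper()
    n, m = len(q), len(t)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qi == t[j - 1] and qi != "N") else mismatch
            cell = max(0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = cell
            if cell > best:
                best = cell
        prev = cur
    return best
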