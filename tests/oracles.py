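"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: full DP matrices, all-window scans,
all-substring enumerations. The oracles share only the *declared* semantics
with the package, never its code paths.
"""

from __future__ import annotations

from igconvert.germline import GAP_CHAR, GAP_EXTEND, GAP_OPEN, MATCH_SCORE, MISMATCH_SCORE


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix edit distance."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1, D[i - 1][j - 1] + cost)
    return D[n][m]


def gotoh_value_full_matrix(a: str, b: str) -> tuple[float, int, int]:
    """Optimal (score, matches, -columns) via full three-matrix DP on the
    reversed sequences (alignment reversal preserves all three components)."""
    a, b = a[::-1], b[::-1]
    n, m = len(a), len(b)
    NEG = (float("-inf"), 0, 0)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = (0.0, 0, 0)
    for j in range(1, m + 1):
        E[0][j] = H[0][j] = (GAP_OPEN + (j - 1) * GAP_EXTEND, 0, -j)
    for i in range(1, n + 1):
        F[i][0] = H[i][0] = (GAP_OPEN + (i - 1) * GAP_EXTEND, 0, -i)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            sub = MATCH_SCORE if match else MISMATCH_SCORE
            hd = H[i - 1][j - 1]
            diag = (hd[0] + sub, hd[1] + (1 if match else 0), hd[2] - 1)
            hl, el = H[i][j - 1], E[i][j - 1]
            E[i][j] = max(
                (hl[0] + GAP_OPEN, hl[1], hl[2] - 1),
                (el[0] + GAP_EXTEND, el[1], el[2] - 1),
            )
            hu, fu = H[i - 1][j], F[i - 1][j]
            F[i][j] = max(
                (hu[0] + GAP_OPEN, hu[1], hu[2] - 1),
                (fu[0] + GAP_EXTEND, fu[1], fu[2] - 1),
            )
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[n][m]


def identity_oracle(a: str, b: str) -> float:
    score, matches, neg_cols = gotoh_value_full_matrix(a, b)
    return 100.0 * matches / -neg_cols


def naive_aid_scan(seq: str) -> list[tuple[str, int, int]]:
    """All-window IUPAC scan for the four AID hotspot motif classes.

    Returns (class, gapped start, gapped end) triples; gap columns skipped,
    coordinates gapped; 'N' never matches.
    """
    W = set("AT")
    R = set("AG")
    Y = set("CT")
    text = []
    pos = []
    for i, c in enumerate(seq.upper()):
        if c != GAP_CHAR:
            text.append(c)
            pos.append(i)
    out = []
    n = len(text)
    for i in range(n):
        if i + 4 <= n:
            w = text[i : i + 4]
            if w[0] in W and w[1] in R and w[2] == "C" and w[3] in Y:
                out.append(("WRCY", pos[i], pos[i + 3] + 1))
            if w[0] in R and w[1] == "G" and w[2] in Y and w[3] in W:
                out.append(("RGYW", pos[i], pos[i + 3] + 1))
        if i + 2 <= n:
            w = text[i : i + 2]
            if w[0] == "T" and w[1] in W:
                out.append(("TW", pos[i], pos[i + 1] + 1))
            if w[0] in W and w[1] == "A":
                out.append(("WA", pos[i], pos[i + 1] + 1))
    out.sort(key=lambda t: (t[1], t[2], t[0]))
    return out


def brute_force_direct_repeats(seq: str, arm_min: int, spacer_max: int) -> set[tuple[int, int]]:
    """Quadratic exhaustive direct-repeat scan under the declared semantics:
    one occurrence per (equality-run, arm shift), arms as long as the run
    allows capped at the shift, anchored at the run start."""
    n = len(seq)
    out = set()
    for d in range(arm_min, n - arm_min + 1):
        for i in range(n - d):
            if seq[i] != seq[i + d]:
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + d]:
                continue  # not a run start
            run = 0
            while i + run < n - d and seq[i + run] == seq[i + run + d]:
                run += 1
            arm = min(run, d)
            spacer = d - arm
            if arm >= arm_min and spacer <= spacer_max:
                out.add((i, i + d + arm))
    return out


def brute_force_donor_hits(
    query: str, donor_seq: str, max_lev: int
) -> list[tuple[int, int, int]]:
    """All (offset, length, dist) with minimal dist <= max_lev, by scoring
    every substring whose length could reach the cap."""
    m = len(query)
    best = max_lev + 1
    hits: list[tuple[int, int, int]] = []
    for length in range(max(1, m - max_lev), m + max_lev + 1):
        for o in range(0, len(donor_seq) - length + 1):
            d = dp_levenshtein(query, donor_seq[o : o + length])
            if d < best:
                best = d
                hits = [(o, length, d)]
            elif d == best:
                hits.append((o, length, d))
    return hits if best <= max_lev else []


def outward_flank_walk(
    acc: str, don: str, a5: int, d5: int, a3: int, d3: int
) -> tuple[int, int]:
    """Position-by-position outward identity walk (flank oracle)."""
    five = 0
    i, j = a5 - 1, d5 - 1
    while i >= 0 and j >= 0 and acc[i] == don[j]:
        five += 1
        i -= 1
        j -= 1
    three = 0
    i, j = a3, d3
    while i < len(acc) and j < len(don) and acc[i] == don[j]:
        three += 1
        i += 1
        j += 1
    return five, three
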