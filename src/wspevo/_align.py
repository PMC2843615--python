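"""Deterministic global pairwise alignment (Needleman–Wunsch).

Scoring is fixed at match +1 / mismatch -1 / gap -1 with no end-gap bonus.
Ties in the traceback prefer substitutions over gaps (diagonal first, then a
gap in the second sequence, then a gap in the first), which makes change
counts reproducible for the near-identical peptides this package aligns.
This is hand-written because the library aligners do not expose the
tie-break, and the sequences involved are short (peptides and their coding
sections), so performance is not a concern.
"""

from __future__ import annotations

MATCH = 1
MISMATCH = -1
GAP = -1


def global_align(a: str, b: str) -> tuple[str, str]:
    """Return one optimal global alignment of ``a`` and ``b`` as gapped strings."""
    n, m = len(a), len(b)
    # score[i][j]: best score aligning a[:i] with b[:j]
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * GAP
    for j in range(1, m + 1):
        score[0][j] = j * GAP
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            up = prev[j] + GAP
            left = row[j - 1] + GAP
            row[j] = diag if diag >= up and diag >= left else max(up, left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1][j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            if score[i][j] == diag:  # substitutions preferred on ties
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + GAP:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def diff_columns(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """(mismatch columns, gap columns) of an alignment."""
    subs = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x != y and "-" not in (x, y)
    )
    indels = sum(1 for x, y in zip(aligned_a, aligned_b) if "-" in (x, y))
    return subs, indels


def count_changes(a: str, b: str) -> tuple[int, int]:
    """(substitution columns, indel columns) from a fresh global alignment."""
    return diff_columns(*global_align(a, b))
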