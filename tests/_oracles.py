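"""Independent reference implementations used only to check the package."""

from __future__ import annotations


def levenshtein(a: str, b: str) -> int:
    """Plain full-matrix edit distance."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def start_distance(read: str, ref: str, s: int, slack: int = 8) -> int:
    """min over window ends of levenshtein(read, ref[s:end]).

    Windows longer than len(read) + slack need > slack edits, so capping the
    end range is exact whenever the true distance is <= slack.
    """
    hi = min(len(ref), s + len(read) + slack)
    return min(levenshtein(read, ref[s:e]) for e in range(s, hi + 1))


def all_placements(read: str, ref: str, max_edit: int) -> dict[int, int]:
    """Every start with placement distance <= max_edit (brute force)."""
    out = {}
    hi = len(ref) - max(len(read) - max_edit, 1)
    for s in range(0, hi + 1):
        d = start_distance(read, ref, s)
        if d <= max_edit:
            out[s] = d
    return out


def edlib_placements(read: str, ref: str, max_edit: int) -> dict[int, int]:
    """Same scan, but each start scored by edlib prefix-mode alignment."""
    import edlib

    out = {}
    hi = len(ref) - max(len(read) - max_edit, 1)
    for s in range(0, hi + 1):
        window = ref[s : s + len(read) + max_edit]
        d = edlib.align(read, window, mode="SHW", task="distance",
                        k=max_edit)["editDistance"]
        if d != -1 and d <= max_edit:
            out[s] = d
    return out
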