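"""Naive reference implementation of the series-shrinking procedure.

Deliberately independent of the package implementation: works on plain
(day, game) tuples and recomputes everything from first principles at every
iteration. Used only as a test oracle.
"""

from __future__ import annotations


def reference_shrink(
    items: list[tuple[int, int]], target: int, small_gap_first: bool = True
) -> list[tuple[int, int]]:
    """items: chronological (day, game) pairs; returns the surviving pairs."""
    current = list(items)
    while len(current) > target:
        days = sorted({d for d, _ in current})
        # rank date groups: more unique games first; tie -> adjacent-gap rule;
        # tie -> earlier day
        def group_key(d):
            members = [g for dd, g in current if dd == d]
            uniq = len(set(members))
            idx = days.index(d)
            gaps = []
            if idx > 0:
                gaps.append(d - days[idx - 1])
            if idx < len(days) - 1:
                gaps.append(days[idx + 1] - d)
            gap = min(gaps) if gaps else float("inf")
            return (-uniq, gap if small_gap_first else -gap, d)

        top_day = min(days, key=group_key)
        freq: dict[int, int] = {}
        for _, g in current:
            freq[g] = freq.get(g, 0) + 1
        group_games = {g for d, g in current if d == top_day}
        victim = min(group_games, key=lambda g: (-freq[g], g))
        # remove the first (only) session of that game in the top group
        for i, (d, g) in enumerate(current):
            if d == top_day and g == victim:
                del current[i]
                break
    return current
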