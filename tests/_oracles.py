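"""Independent oracles shared by test modules."""


def brute_force_digest(seq, max_missed=2, lo=7, hi=30, proline_rule=True):
    """Independent enumerator: every substring bounded by cut sites/termini."""
    import bisect

    cuts = sorted(
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P")
    )
    bounds = set(cuts) | {0, len(seq)}
    peptides = []
    for i in sorted(bounds):
        for j in sorted(bounds):
            if j <= i:
                continue
            length = j - i
            if not (lo <= length <= (hi if hi is not None else 10**9)):
                continue
            internal = bisect.bisect_left(cuts, j) - bisect.bisect_right(cuts, i)
            if internal <= max_missed:
                peptides.append(seq[i:j])
    return sorted(peptides)
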