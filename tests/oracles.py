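"""Independent reference implementations used as test oracles.

These deliberately re-derive expected results through different code paths
(list/groupby scans, explicit path enumeration) than the package modules
they check.
"""

from __future__ import annotations

from itertools import groupby


def oracle_segments(calls, positions, chromosome_length):
    """Brute-force donor-segment caller: run detection via groupby.

    Returns (start_bp, end_bp, zygosity, n_markers) tuples.
    """
    informative = [(c, p) for c, p in zip(calls, positions) if c != "U"]
    if not informative:
        return []
    out = []
    idx = 0
    for is_donor, grp in groupby(informative, key=lambda cp: cp[0] in ("B", "H")):
        grp = list(grp)
        if is_donor:
            first_i, last_i = idx, idx + len(grp) - 1
            if first_i == 0:
                start = 1
            else:
                prev_pos = informative[first_i - 1][1]
                start = (prev_pos + grp[0][1]) // 2 + 1
            if last_i == len(informative) - 1:
                end = chromosome_length
            else:
                next_pos = informative[last_i + 1][1]
                end = (grp[-1][1] + next_pos) // 2
            codes = {c for c, _ in grp}
            if codes == {"B"}:
                zyg = "homozygous"
            elif codes == {"H"}:
                zyg = "heterozygous"
            else:
                zyg = "mixed"
            out.append((start, end, zyg, len(grp)))
        idx += len(grp)
    return out


def oracle_bins(columns):
    """Set-based bin oracle: a run of adjacent markers is a valid bin iff for
    every line the non-missing calls within the run are all equal. Maximal
    runs are taken left to right. ``columns`` is a list of per-marker call
    lists; returns the list of bin sizes.
    """
    n_lines = len(columns[0])

    def is_bin(run):
        for i in range(n_lines):
            seen = {col[i] for col in run} - {"U"}
            if len(seen) > 1:
                return False
        return True

    sizes = []
    start = 0
    while start < len(columns):
        end = start + 1
        while end < len(columns) and is_bin(columns[start : end + 1]):
            end += 1
        sizes.append(end - start)
        start = end
    return sizes


def oracle_hk_dosage(left, right, r1, r2):
    """Expected donor state at the middle locus by explicit enumeration of
    the four donor/recurrent paths through a three-locus haploid chain,
    conditioned on the observed flanks.
    """

    def step(a, b, r):
        return r if a != b else 1.0 - r

    weights = {}
    for q in (0, 1):
        w = 1.0
        if left is not None:
            w *= step(left, q, r1)
        if right is not None:
            w *= step(q, right, r2)
        weights[q] = w
    total = weights[0] + weights[1]
    return weights[1] / total
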