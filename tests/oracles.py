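"""Independent brute-force oracles for the interval algebra.

Deliberately naive O(n*m) implementations used only to cross-check the
package's searchsorted/merge-based routines; they share no code with
the implementation under test.
"""

from __future__ import annotations


def overlaps(iv1: tuple[str, int, int], iv2: tuple[str, int, int], min_bp: int = 1) -> bool:
    c1, s1, e1 = iv1
    c2, s2, e2 = iv2
    if c1 != c2:
        return False
    return min(e1, e2) - max(s1, s2) >= min_bp


def brute_count_once(query, reference, min_bp: int = 1) -> int:
    """Number of query intervals sharing >= min_bp with at least one
    single reference interval."""
    return sum(
        1 for q in query if any(overlaps(q, r, min_bp) for r in reference)
    )


def brute_count_pairwise(query, reference, min_bp: int = 1) -> int:
    return sum(
        1 for q in query for r in reference if overlaps(q, r, min_bp)
    )


def brute_filter(query, reference, keep: str):
    flagged = [any(overlaps(q, r) for r in reference) for q in query]
    want = keep == "overlapping"
    return [q for q, f in zip(query, flagged) if f == want]


def brute_merge(intervals):
    """Merge (chrom, start, end) triples; adjacent intervals merge."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def brute_coverage(intervals) -> int:
    return sum(e - s for _, s, e in brute_merge(intervals))
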