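"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: common elements by full
substring enumeration, conserved runs by a column-by-column scan, clustering
by single-linkage over all pairwise gaps.
"""

from __future__ import annotations


def all_substrings(seqs, min_len=6):
    subs = set()
    for s in seqs:
        s = s.upper()
        for i in range(len(s)):
            for j in range(i + min_len, len(s) + 1):
                subs.add(s[i:j])
    return subs


def brute_force_common(a, b, min_len=6):
    """Maximal shared substrings >= min_len by full enumeration."""
    common = all_substrings(a, min_len) & all_substrings(b, min_len)
    return {s for s in common if not any(s != t and s in t for t in common)}


def scan_conserved_runs(columns, ref_positions, ref_chars, strand, min_len=6):
    """Column-by-column conserved-run scan.

    ``columns`` are per-position species character tuples (None = missing);
    a run requires every species present, ungapped, unambiguous and equal,
    and consecutive reference positions (strand-aware step).
    """
    step = 1 if strand == "+" else -1

    def ok(col):
        if any(c is None for c in col):
            return False
        ups = [c.upper() for c in col]
        if any(u not in "ACGT" for u in ups):
            return False
        return len(set(ups)) == 1

    runs = []
    current = []  # list of column indices
    for i, col in enumerate(columns):
        contiguous = bool(current) and ref_positions[i] == ref_positions[current[-1]] + step
        if ok(col) and current and contiguous:
            current.append(i)
        elif ok(col):
            if len(current) >= min_len:
                runs.append(list(current))
            current = [i]
        else:
            if len(current) >= min_len:
                runs.append(list(current))
            current = []
    if len(current) >= min_len:
        runs.append(list(current))
    out = []
    for run in runs:
        seq = "".join(ref_chars[i] for i in run).upper()
        positions = [ref_positions[i] for i in run]
        out.append((seq, min(positions), max(positions) + 1))
    return out


def brute_force_clusters(loci, max_gap):
    """Single-linkage clustering over all pairwise closest-end gaps.

    ``loci`` is a list of (start, end); two loci link when
    max(start_i, start_j) - min(end_i, end_j) <= max_gap.
    """
    n = len(loci)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(loci[i][0], loci[j][0]) - min(loci[i][1], loci[j][1])
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())
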