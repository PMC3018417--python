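"""Independent brute-force oracles for the test suite.

Everything here is deliberately naive: exhaustive enumeration, direct
column walks and triangle counts.  Nothing imports the implementation
paths it is used to check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

GAP = "-"

# Column operations: D = residue pair, X = query char over gap (gap in the
# subject string), Y = gap in the query string under a subject char.


@lru_cache(maxsize=None)
def _paths(m: int, n: int) -> tuple[str, ...]:
    """All monotone alignment paths of an m-residue query vs n-residue subject."""
    if m == 0 and n == 0:
        return ("",)
    out = []
    if m > 0 and n > 0:
        out.extend(p + "D" for p in _paths(m - 1, n - 1))
    if m > 0:
        out.extend(p + "X" for p in _paths(m - 1, n))
    if n > 0:
        out.extend(p + "Y" for p in _paths(m, n - 1))
    return tuple(out)


def _gap_cost(path: str, gap_open: float, gap_extend: float) -> float:
    """Affine cost of the gap runs in a path; first and last run free if gaps."""
    runs: list[tuple[str, int]] = []
    for op in path:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    cost = 0.0
    for idx, (op, length) in enumerate(runs):
        if op == "D":
            continue
        if idx == 0 or idx == len(runs) - 1:
            continue  # end run: free under the ends-free convention
        cost += gap_open + gap_extend * (length - 1)
    return cost


@lru_cache(maxsize=None)
def _path_info(
    m: int, n: int, gap_open: float, gap_extend: float
) -> tuple[tuple[tuple[tuple[int, int], ...], float], ...]:
    """Per path: the (i, j) residue pairs it aligns and its fixed gap cost."""
    out = []
    for path in _paths(m, n):
        i = j = 0
        pairs = []
        for op in path:
            if op == "D":
                pairs.append((i, j))
                i += 1
                j += 1
            elif op == "X":
                i += 1
            else:
                j += 1
        out.append((tuple(pairs), _gap_cost(path, gap_open, gap_extend)))
    return tuple(out)


def brute_force_ends_free_score(
    q: str,
    s: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Maximum ends-free score over every possible gapped alignment of q vs s."""
    best = float("-inf")
    for pairs, gap_cost in _path_info(len(q), len(s), gap_open, gap_extend):
        score = gap_cost
        for i, j in pairs:
            score += match if q[i] == s[j] else mismatch
        best = max(best, score)
    return best


def score_alignment(
    query_aligned: str,
    subject_aligned: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Score one explicit gapped alignment under the same ends-free convention."""
    path = []
    pairs = 0.0
    for qc, sc in zip(query_aligned, subject_aligned):
        if qc == GAP:
            path.append("Y")
        elif sc == GAP:
            path.append("X")
        else:
            path.append("D")
            pairs += match if qc == sc else mismatch
    return pairs + _gap_cost("".join(path), gap_open, gap_extend)


def column_walk_map(
    query_aligned: str,
    subject_aligned: str,
    query_start: int,
    subject_start: int,
    position: int,
    subject_len_hint: int | None = None,
) -> tuple[str, int | None]:
    """Map a 1-based subject position onto the query by direct column scan."""
    spos = subject_start - 1
    qpos = query_start - 1
    for qc, sc in zip(query_aligned, subject_aligned):
        qp = None
        if qc != GAP:
            qpos += 1
            qp = qpos
        if sc != GAP:
            spos += 1
            if spos == position:
                return ("mapped", qp) if qp is not None else ("gapped", None)
    return "outside", None


def triangle_clustering(adj: dict[str, set[str]], node: str) -> float:
    """Watts–Strogatz clustering by explicit neighbor-pair counting."""
    nbrs = adj[node]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
    return 2.0 * links / (k * (k - 1))


def bfs_within(adj: dict[str, set[str]], source: str, depth: int) -> set[str]:
    """Nodes at graph distance <= depth from source, by plain BFS."""
    frontier = {source}
    seen = {source}
    for _ in range(depth):
        frontier = {v for u in frontier for v in adj[u]} - seen
        seen |= frontier
    return seen
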