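"""Robinson-Foulds symmetric-difference distance between dendrograms.

Every internal edge of the unrooted version of a tree splits the leaves into
two blocks (a bipartition).  The Robinson-Foulds distance between two trees
over the same leaf set is the number of bipartitions present in exactly one
of them.  Branch lengths are ignored; trees differing only in root placement
have distance 0, because rooting does not change the split set.
"""

from __future__ import annotations

__all__ = ["bipartitions", "robinson_foulds"]


def _leafset(node) -> frozenset[str]:
    if not node.children:
        return frozenset([node.label])
    out: set[str] = set()
    for c in node.children:
        out |= _leafset(c)
    return frozenset(out)


def bipartitions(d) -> frozenset[frozenset[str]]:
    """Non-trivial splits of the unrooted version of a rooted merge tree.

    Accepts any rooted tree object exposing ``root`` with ``children`` and
    leaf ``label`` attributes.  Each internal node below the root contributes
    the set of leaves beneath it; the root's children describe the same edge
    of the unrooted tree, so their splits coincide after canonicalization.
    Splits are canonicalized to the side NOT containing the lexicographically
    smallest leaf; trivial splits (singletons or the full set) are dropped.
    """
    universe = _leafset(d.root)
    n = len(universe)
    anchor = min(universe)
    splits: set[frozenset[str]] = set()

    def visit(node) -> frozenset[str]:
        if not node.children:
            return frozenset([node.label])
        below: set[str] = set()
        for c in node.children:
            below |= visit(c)
        below = frozenset(below)
        if 2 <= len(below) <= n - 2:
            side = below if anchor not in below else universe - below
            splits.add(side)
        return below

    for c in d.root.children:
        visit(c)
    return frozenset(splits)


def robinson_foulds(d1, d2) -> int:
    """|B1 symmetric-difference B2| over the two trees' bipartition sets."""
    l1, l2 = _leafset(d1.root), _leafset(d2.root)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    b1, b2 = bipartitions(d1), bipartitions(d2)
    return len(b1 ^ b2)
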