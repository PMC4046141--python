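"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own graph/tree code: the codon-graph
oracle is a plain breadth-first search written from the definition, and the
tree oracle computes clades directly from a nested-tuple topology rather
than from any Newick parser.
"""

from __future__ import annotations

import itertools
import random
from collections import deque

NUCS = "ACGT"
ALL_CODONS = ["".join(p) for p in itertools.product(NUCS, repeat=3)]

# standard genetic code, typed out independently of Biopython
_CODE_BLOCKS = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "*": ["TAA", "TAG", "TGA"],
}
ORACLE_CODE = {codon: aa for aa, codons in _CODE_BLOCKS.items() for codon in codons}
assert len(ORACLE_CODE) == 64
ORACLE_AAS = sorted(_CODE_BLOCKS)  # 20 amino acids + '*'


def hamming1(a: str, b: str) -> bool:
    return sum(x != y for x, y in zip(a, b)) == 1


def oracle_min_substitutions(src_aa: str, dst_aa: str,
                             exclude_stops: bool = True) -> float:
    """Shortest stop-free codon path length between two amino acids, by BFS."""
    src = {c for c, a in ORACLE_CODE.items() if a == src_aa}
    dst = {c for c, a in ORACLE_CODE.items() if a == dst_aa}
    if src & dst:
        return 0
    allowed = set(ALL_CODONS)
    if exclude_stops:
        allowed = {c for c in allowed if ORACLE_CODE[c] != "*"} | src | dst
    dist = {c: 0 for c in src}
    q = deque(src)
    while q:
        cur = q.popleft()
        for nb in ALL_CODONS:
            if nb in allowed and nb not in dist and hamming1(cur, nb):
                dist[nb] = dist[cur] + 1
                q.append(nb)
    reached = [dist[c] for c in dst if c in dist]
    return min(reached) if reached else float("inf")


def oracle_minimal_interiors(src_aa: str, dst_aa: str) -> set[str]:
    """Amino acids of non-silent interiors of minimal stop-free paths."""
    src = {c for c, a in ORACLE_CODE.items() if a == src_aa}
    dst = {c for c, a in ORACLE_CODE.items() if a == dst_aa}
    k = oracle_min_substitutions(src_aa, dst_aa)
    if k in (0, float("inf")):
        return set()
    out: set[str] = set()

    def walk(path):
        if len(path) - 1 == k:
            if path[-1] in dst:
                for c in path[1:-1]:
                    aa = ORACLE_CODE[c]
                    if aa not in (src_aa, dst_aa, "*"):
                        out.add(aa)
            return
        for nb in ALL_CODONS:
            if nb not in path and hamming1(path[-1], nb) and ORACLE_CODE[nb] != "*":
                walk(path + [nb])

    for start in src:
        walk([start])
    return out


# --- random nested-tuple trees with structure-derived clades -------------

def random_topology(labels: list[str], rng: random.Random):
    """A random binary topology as nested tuples over the given labels."""
    nodes = list(labels)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def topology_to_newick(top) -> str:
    def render(node):
        if isinstance(node, tuple):
            return "(" + ",".join(render(ch) for ch in node) + ")"
        return node
    return render(top) + ";"


def topology_sides(top) -> set[frozenset]:
    """All tip sets on either side of every branch, from the structure."""
    leaves = frozenset(_tips(top))
    sides = {leaves}

    def visit(node):
        if isinstance(node, tuple):
            s = frozenset(_tips(node))
            sides.add(s)
            sides.add(leaves - s)
            for ch in node:
                visit(ch)
        else:
            sides.add(frozenset([node]))
            sides.add(leaves - frozenset([node]))

    visit(top)
    return sides


def _tips(node):
    if isinstance(node, tuple):
        for ch in node:
            yield from _tips(ch)
    else:
        yield node


def topology_clades(top) -> set[frozenset]:
    """Rooted clades (subtree tip sets) of the structure, root included."""
    clades = {frozenset(_tips(top))}

    def visit(node):
        if isinstance(node, tuple):
            clades.add(frozenset(_tips(node)))
            for ch in node:
                visit(ch)
        else:
            clades.add(frozenset([node]))

    visit(top)
    return clades


def oracle_monophyly(top, subset: set[str]) -> tuple[bool, int]:
    """Flag from unrooted bipartition sides; size from the rooted MRCA clade."""
    subset = frozenset(subset)
    mono = subset in topology_sides(top)
    mrca = min((c for c in topology_clades(top) if subset <= c), key=len)
    return mono, len(mrca)
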