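"""Codon tables and parsimonious mutational pathways between amino acids.

Plant ALDH10 isoenzymes gained betaine aldehyde dehydrogenase activity when
an isoleucine at the position equivalent to 441 of the spinach enzyme mutated
to alanine or cysteine.  Because every Ile codon differs from every Ala or Cys
codon at two nucleotide positions, the change must have passed through a
single-substitution intermediate.  This module models the genetic code as a
graph whose nodes are the 64 codons and whose edges connect codons differing
at exactly one position, and enumerates the minimal mutational pathways and
the amino acids of their intermediates.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

__all__ = [
    "GeneticCode",
    "CodonPath",
    "CodonPathwaySet",
    "normalize_codon",
    "codons_for",
    "snv_neighbors",
    "min_substitutions",
    "enumerate_pathways",
    "stop_reachable_single_snv",
    "codon_usage_table",
    "UNREACHABLE",
]

#: Sentinel distance returned when no stop-free path exists.
UNREACHABLE = float("inf")


def normalize_codon(codon: str) -> str:
    """Upper-case a triplet and map RNA U to DNA T; reject malformed input."""
    if not isinstance(codon, str):
        raise ValueError(f"codon must be a string, got {type(codon).__name__}")
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or any(b not in NUCLEOTIDES for b in c):
        raise ValueError(f"malformed codon {codon!r}: expected a triplet over {{A,C,G,T}}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid table over the DNA alphabet, '*' marking stops."""

    name: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.name!r} has {len(self.codon_to_aa)} codons, expected 64"
            )
        for codon in self.codon_to_aa:
            if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
                raise ValueError(f"invalid codon {codon!r} in code {self.name!r}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear code (NCBI translation table 1)."""
        table = _BioCodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(name="standard", codon_to_aa=mapping)

    @classmethod
    def from_table(cls, path, name: str | None = None) -> "GeneticCode":
        """Load a code from a two-column (codon, amino acid) text table."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         names=["codon", "aa"], header=None, dtype=str)
        mapping = {normalize_codon(c): a.strip().upper() for c, a in
                   zip(df["codon"], df["aa"])}
        return cls(name=name or str(path), codon_to_aa=mapping)

    @property
    def amino_acids(self) -> set[str]:
        return set(self.codon_to_aa.values())

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, a in self.codon_to_aa.items() if a == STOP}


STANDARD_CODE = GeneticCode.standard()


def codons_for(aa: str, code: GeneticCode = STANDARD_CODE) -> set[str]:
    """All codons translating to amino acid ``aa`` ('*' for stop)."""
    aa = aa.strip().upper()
    hits = {c for c, a in code.codon_to_aa.items() if a == aa}
    if not hits:
        raise ValueError(f"unknown amino acid symbol {aa!r} for code {code.name!r}")
    return hits


def snv_neighbors(codon: str) -> set[str]:
    """The 9 codons at Hamming distance one from ``codon``."""
    c = normalize_codon(codon)
    out = set()
    for i, base in enumerate(c):
        for alt in NUCLEOTIDES:
            if alt != base:
                out.add(c[:i] + alt + c[i + 1:])
    return out


def _allowed_nodes(code: GeneticCode, exclude_stops: bool,
                   endpoints: Iterable[str]) -> set[str]:
    nodes = set(code.codon_to_aa)
    if exclude_stops:
        nodes -= code.stop_codons
        nodes |= set(endpoints)  # endpoints stay even if they are stops
    return nodes


def min_substitutions(src_aa: str, dst_aa: str,
                      code: GeneticCode = STANDARD_CODE,
                      exclude_stops: bool = True) -> float:
    """Minimum number of single-nucleotide substitutions converting any codon
    of ``src_aa`` into any codon of ``dst_aa``.

    With ``exclude_stops`` (default) path interiors may not pass through stop
    codons — a nonsense intermediate truncates the protein.  Returns
    :data:`UNREACHABLE` if no such path exists.
    """
    src = codons_for(src_aa, code)
    dst = codons_for(dst_aa, code)
    if src & dst:
        return 0
    allowed = _allowed_nodes(code, exclude_stops, src | dst)
    # multi-source BFS over the 64-codon graph
    dist = {c: 0 for c in src}
    queue = deque(src)
    while queue:
        cur = queue.popleft()
        for nb in snv_neighbors(cur):
            if nb in allowed and nb not in dist:
                dist[nb] = dist[cur] + 1
                if nb in dst:
                    return dist[nb]
                queue.append(nb)
    hits = [dist[c] for c in dst if c in dist]
    return min(hits) if hits else UNREACHABLE


@dataclass(frozen=True)
class CodonPath:
    """One ordered codon trajectory from a source to a destination codon.

    ``intermediates`` holds the amino acids of the interior codons;
    ``silent_flags`` marks interior codons whose amino acid equals the source
    or destination amino acid (a synonymous step that Figure-style pathway
    diagrams do not count as a distinct evolutionary intermediate).
    """

    codons: tuple[str, ...]
    intermediates: tuple[str, ...]
    silent_flags: tuple[bool, ...]

    @property
    def length(self) -> int:
        return len(self.codons) - 1

    def __str__(self) -> str:
        return " -> ".join(self.codons)


@dataclass
class CodonPathwaySet:
    """All mutational pathways between two amino acids' codon sets."""

    source_aa: str
    dest_aa: str
    min_length: int
    paths: list[CodonPath] = field(default_factory=list)
    intermediate_aas: set[str] = field(default_factory=set)

    def minimal_paths(self) -> list[CodonPath]:
        return [p for p in self.paths if p.length == self.min_length]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_aa": self.source_aa,
                "dest_aa": self.dest_aa,
                "path": str(p),
                "length": p.length,
                "intermediates": "".join(p.intermediates),
                "silent": "".join("1" if s else "0" for s in p.silent_flags),
            }
            for p in self.paths
        ]
        return pd.DataFrame(rows, columns=["source_aa", "dest_aa", "path",
                                           "length", "intermediates", "silent"])


def enumerate_pathways(src_aa: str, dst_aa: str,
                       code: GeneticCode = STANDARD_CODE,
                       max_extra_steps: int = 0,
                       exclude_stops: bool = True) -> CodonPathwaySet:
    """Enumerate all codon pathways of length up to the minimum plus
    ``max_extra_steps`` between two amino acids.

    Distinct substitution orderings count as distinct paths.  The set of
    evolutionary intermediates (``intermediate_aas``) is taken from the
    non-silent interior codons of the *minimal* paths only.
    """
    if max_extra_steps < 0:
        raise ValueError("max_extra_steps must be >= 0")
    src_aa = src_aa.strip().upper()
    dst_aa = dst_aa.strip().upper()
    src = codons_for(src_aa, code)
    dst = codons_for(dst_aa, code)
    min_len = min_substitutions(src_aa, dst_aa, code, exclude_stops)
    if min_len is UNREACHABLE or min_len == UNREACHABLE:
        raise ValueError(
            f"{src_aa} -> {dst_aa} unreachable without passing through a stop codon"
        )
    min_len = int(min_len)
    max_len = min_len + max_extra_steps
    allowed = _allowed_nodes(code, exclude_stops, src | dst)

    paths: list[list[str]] = []

    def extend(path: list[str]) -> None:
        cur = path[-1]
        if cur in dst and len(path) > 1:
            paths.append(list(path))
            # a destination codon may still be an interior node of a longer
            # path; continue only if extra steps remain
        if len(path) - 1 >= max_len:
            return
        for nb in sorted(snv_neighbors(cur)):
            if nb in allowed and nb not in path:
                path.append(nb)
                extend(path)
                path.pop()

    if min_len == 0:
        # identity: shared codons need no substitution
        result = CodonPathwaySet(src_aa, dst_aa, 0)
        if max_extra_steps == 0:
            return result
    for start in sorted(src):
        extend([start])

    out = CodonPathwaySet(src_aa, dst_aa, min_len)
    for p in paths:
        interior = p[1:-1]
        aas = tuple(code.translate(c) for c in interior)
        silent = tuple(a in (src_aa, dst_aa) for a in aas)
        out.paths.append(CodonPath(tuple(p), aas, silent))
    for cp in out.minimal_paths():
        for aa, is_silent in zip(cp.intermediates, cp.silent_flags):
            if not is_silent and aa != STOP:
                out.intermediate_aas.add(aa)
    return out


def stop_reachable_single_snv(codon: str,
                              code: GeneticCode = STANDARD_CODE
                              ) -> tuple[bool, set[str]]:
    """Whether one point mutation can turn ``codon`` into a stop codon.

    A targeting-signal residue whose codon is one substitution away from a
    stop can be lost by premature termination — the mechanism invoked for the
    loss of the C-terminal peroxisomal signal in some isoenzymes.
    """
    stops = {nb for nb in snv_neighbors(codon) if code.is_stop(nb)}
    return bool(stops), stops


def codon_usage_table(records: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Counts and within-group frequencies of codons.

    ``records`` are (group label, codon) pairs, e.g. ("monocot", "ATT").
    Returns a tidy frame with columns group, codon, count, frequency where
    frequencies sum to one within each group.  Empty input yields an empty
    frame.
    """
    rows = []
    for group, codon in records:
        if not str(group):
            raise ValueError("empty group label")
        rows.append((str(group), normalize_codon(codon)))
    cols = ["group", "codon", "count", "frequency"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["group", "codon"])
    counts = df.value_counts(["group", "codon"]).rename("count").reset_index()
    totals = counts.groupby("group")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts.sort_values(["group", "codon"], ignore_index=True)[cols]
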