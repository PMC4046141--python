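"""Rule-based classification of ALDH10 isoenzymes from aligned sequences.

The residue at the position equivalent to 441 of the spinach betaine aldehyde
dehydrogenase (SoBADH numbering) gates betaine aldehyde (BAL) binding:
Ile-type enzymes are aminoaldehyde dehydrogenases (AMADH) only, while Ala,
Cys, Ser or Thr at this position open the trimethylammonium-binding pocket
and confer BADH activity.  Subcellular location is read from the C-terminal
peroxisomal targeting signal (PTS1) tripeptide.  Together these two features
predict whether a plant can accumulate the osmoprotectant glycine betaine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import GeneticCode, STANDARD_CODE, normalize_codon

GAP = "-"
UNKNOWN = "?"

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Residue types named after the 441-equivalent residue.  Anything else
#: (gap, X, other residues) is labelled "other".
TYPED_RESIDUES = {"I", "A", "C", "V", "T", "S", "F"}

#: Residue types predicted to carry betaine aldehyde dehydrogenase activity
#: in addition to the ancestral aminoaldehyde dehydrogenase activity.
BADH_ACTIVE_TYPES = {"A441", "C441", "S441", "T441"}

#: PTS1 position-wise consensus presets.  Two are in circulation for plant
#: ALDH10s; "results-text" is the default.
PTS1_PRESETS: dict[str, tuple[frozenset, frozenset, frozenset]] = {
    "results-text": (frozenset("SA"), frozenset("KR"), frozenset("LMI")),
    "figure-legend": (frozenset("SAC"), frozenset("KRH"), frozenset("LM")),
}

# Trp/Tyr/cystine molar absorptivities at 280 nm (M^-1 cm^-1), Gill &
# von Hippel coefficients.
EPS_TRP = 5500.0
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0

__all__ = [
    "SequenceEntry",
    "AlignedSequenceSet",
    "IsoenzymeRecord",
    "PhenotypePrediction",
    "ActivityPrediction",
    "ClassificationReport",
    "map_reference_position",
    "classify_residue_type",
    "extract_codon441",
    "detect_pts1",
    "predict_activity",
    "predict_location",
    "predict_gb_phenotype",
    "extinction_coefficient_280",
    "monophyly_check",
    "classification_report",
    "PTS1_PRESETS",
]


@dataclass
class SequenceEntry:
    """One aligned protein with optional in-frame CDS and group label."""

    id: str
    protein: str  # aligned, '-' for gaps
    cds: str | None = None  # unaligned, in frame with the ungapped protein
    group: str | None = None  # e.g. taxon group: monocot / eudicot
    species: str | None = None

    @property
    def ungapped(self) -> str:
        return self.protein.replace(GAP, "")


@dataclass
class AlignedSequenceSet:
    """A protein multiple sequence alignment with a designated reference."""

    entries: list[SequenceEntry]
    reference_id: str

    def __post_init__(self) -> None:
        lengths = {len(e.protein) for e in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if self.reference_id not in {e.id for e in self.entries}:
            raise ValueError(f"reference {self.reference_id!r} absent from alignment")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, identifier: str) -> SequenceEntry:
        for e in self.entries:
            if e.id == identifier:
                return e
        raise KeyError(identifier)

    @property
    def reference(self) -> SequenceEntry:
        return self[self.reference_id]

    @property
    def n_columns(self) -> int:
        return len(self.entries[0].protein) if self.entries else 0

    @classmethod
    def from_fasta(cls, protein_path, reference_id: str,
                   cds_path=None,
                   groups: Mapping[str, str] | None = None,
                   species: Mapping[str, str] | None = None
                   ) -> "AlignedSequenceSet":
        """Read an aligned protein FASTA (and optional unaligned CDS FASTA)."""
        entries = []
        for rec in SeqIO.parse(str(protein_path), "fasta"):
            entries.append(SequenceEntry(
                id=rec.id,
                protein=str(rec.seq).upper(),
                group=(groups or {}).get(rec.id),
                species=(species or {}).get(rec.id),
            ))
        if cds_path is not None:
            cds = {rec.id: str(rec.seq).upper() for rec in
                   SeqIO.parse(str(cds_path), "fasta")}
            for e in entries:
                e.cds = cds.get(e.id)
        return cls(entries=entries, reference_id=reference_id)


class ActivityPrediction(NamedTuple):
    activity: str  # "AMADH-only" | "AMADH+BADH"
    low_confidence: bool


@dataclass
class IsoenzymeRecord:
    """Classification of one isoenzyme sequence."""

    identifier: str
    residue441: str  # one-letter amino acid, or '?' when unknown
    codon441: str  # triplet or '?'
    type_label: str  # I441/A441/C441/V441/T441/S441/F441/other
    pts1: str  # match / no-match / truncated-unknown
    pts1_tripeptide: str | None
    predicted_activity: str  # AMADH-only / AMADH+BADH
    predicted_location: str  # peroxisomal / non-peroxisomal
    low_confidence: bool = False
    group: str | None = None
    species: str | None = None


@dataclass
class PhenotypePrediction:
    """Glycine-betaine accumulation class predicted for one species."""

    species: str
    records: list[IsoenzymeRecord]
    gb_class: str  # non-accumulator / low/moderate-accumulator / high-accumulator


def map_reference_position(alignment: AlignedSequenceSet, ref_position: int) -> int:
    """Alignment column (1-based) holding the ``ref_position``-th ungapped
    residue of the reference sequence."""
    if ref_position < 1:
        raise ValueError(f"ref_position must be >= 1, got {ref_position}")
    seen = 0
    for col, ch in enumerate(alignment.reference.protein, start=1):
        if ch != GAP:
            seen += 1
            if seen == ref_position:
                return col
    raise ValueError(
        f"ref_position {ref_position} beyond reference length "
        f"({seen} ungapped residues)"
    )


def classify_residue_type(residue: str) -> str:
    """Name the isoenzyme type after the 441-equivalent residue.

    Total function: gaps, X and any untyped residue map to "other".
    """
    r = str(residue).strip().upper()
    return f"{r}441" if r in TYPED_RESIDUES else "other"


def extract_codon441(entry: SequenceEntry, column: int,
                     code: GeneticCode = STANDARD_CODE) -> str:
    """The in-frame CDS triplet coding the residue at an alignment column.

    The CDS must be a multiple of 3, cover the ungapped protein, and the
    mapped codon must translate to the aligned residue.
    """
    if entry.cds is None:
        raise ValueError(f"{entry.id}: no CDS available")
    cds = entry.cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{entry.id}: CDS length {len(cds)} not a multiple of 3")
    residue = entry.protein[column - 1]
    if residue == GAP:
        raise ValueError(f"{entry.id}: gap at alignment column {column}")
    # index of the residue within the ungapped protein
    idx = sum(1 for ch in entry.protein[: column - 1] if ch != GAP)
    if len(cds) < 3 * (idx + 1):
        raise ValueError(f"{entry.id}: CDS too short for residue index {idx + 1}")
    codon = normalize_codon(cds[3 * idx: 3 * idx + 3])
    translated = code.translate(codon)
    if translated != residue:
        raise ValueError(
            f"{entry.id}: codon {codon} translates to {translated}, "
            f"but aligned protein has {residue} at column {column}"
        )
    return codon


def detect_pts1(protein: str, preset: str = "results-text"
                ) -> tuple[str, str | None]:
    """Check the C-terminal tripeptide against a PTS1 consensus.

    Returns (status, tripeptide) with status one of "match", "no-match",
    "truncated-unknown".  Only the final three residues matter.
    """
    try:
        consensus = PTS1_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown PTS1 preset {preset!r}; available: {sorted(PTS1_PRESETS)}"
        ) from None
    seq = protein.replace(GAP, "").upper()
    if len(seq) < 3:
        return "truncated-unknown", None
    tri = seq[-3:]
    ok = all(ch in allowed for ch, allowed in zip(tri, consensus))
    return ("match" if ok else "no-match"), tri


def predict_activity(type_label: str) -> ActivityPrediction:
    """Predict substrate scope from the 441-type.

    Ala/Cys/Ser/Thr-types additionally oxidize betaine aldehyde
    (AMADH+BADH); Ile/Val/Phe-types are AMADH-only.  The Ser and Phe calls
    are inferred from engineered variants (no natural S441/F441 isoenzyme is
    known); an untyped residue yields AMADH-only with a low-confidence flag.
    """
    if type_label in BADH_ACTIVE_TYPES:
        return ActivityPrediction("AMADH+BADH", False)
    if type_label in {"I441", "V441", "F441"}:
        return ActivityPrediction("AMADH-only", False)
    if type_label == "other":
        return ActivityPrediction("AMADH-only", True)
    raise ValueError(f"unknown type label {type_label!r}")


def predict_location(pts1_status: str) -> str:
    """Peroxisomal iff the PTS1 tripeptide matches; a truncated or mutated
    C-terminus means the protein is not imported into the peroxisome."""
    return "peroxisomal" if pts1_status == "match" else "non-peroxisomal"


def predict_gb_phenotype(records: Sequence[IsoenzymeRecord],
                         species: str = "") -> PhenotypePrediction:
    """Predict a species' glycine-betaine accumulation class.

    A non-peroxisomal BADH-active isoenzyme supports high accumulation; a
    peroxisomal BADH-active one only low/moderate accumulation (peroxisomal
    synthesis is substrate-transport limited); with no BADH-active
    isoenzyme the plant cannot make glycine betaine.
    """
    if not records:
        raise ValueError("at least one isoenzyme record required")
    badh = [r for r in records if r.predicted_activity == "AMADH+BADH"]
    if any(r.predicted_location == "non-peroxisomal" for r in badh):
        gb = "high-accumulator"
    elif badh:
        gb = "low/moderate-accumulator"
    else:
        gb = "non-accumulator"
    return PhenotypePrediction(species=species, records=list(records), gb_class=gb)


def extinction_coefficient_280(protein: str, reduced: bool = True) -> float:
    """Molar absorptivity at 280 nm (M⁻¹ cm⁻¹) from sequence composition.

    Sum of Trp and Tyr contributions; with ``reduced=False`` cysteines are
    assumed fully paired into cystines and contribute 125 per disulfide.
    """
    seq = protein.replace(GAP, "").upper()
    bad = sorted({ch for ch in seq if ch not in STANDARD_AA})
    if bad:
        raise ValueError(f"non-standard residues in sequence: {''.join(bad)}")
    eps = seq.count("W") * EPS_TRP + seq.count("Y") * EPS_TYR
    if not reduced:
        eps += (seq.count("C") // 2) * EPS_CYSTINE
    return eps


def _bipartition_sides(tree: dendropy.Tree) -> list[frozenset]:
    """All taxon-label sets on one side of each edge (plus the full set)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sides = {leaves}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(side)
        sides.add(leaves - side)
    return sorted(sides, key=len)


def monophyly_check(tree, tips: Iterable[str]) -> tuple[bool, int]:
    """Do the given tips form a monophyletic group on an unrooted tree?

    ``tree`` may be a dendropy Tree or a Newick string.  The flag is true
    iff some bipartition of the unrooted tree separates exactly the given
    tips.  The size reported is that of the smallest clade containing the
    subset when the tree is read as written (the MRCA clade); because of
    root placement this can exceed the subset size even for an
    unrooted-monophyletic subset.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(data=str(tree), schema="newick",
                                 preserve_underscores=True)
    tipset = frozenset(tips)
    if not tipset:
        raise ValueError("empty tip subset")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = tipset - leaves
    if missing:
        raise ValueError(f"tips absent from tree: {sorted(missing)}")
    mono = any(side == tipset for side in _bipartition_sides(tree))
    # smallest rooted clade (as written) containing all the tips
    clade_size = len(tipset) if mono else len(leaves)
    for node in tree.postorder_node_iter():
        node_leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if tipset <= node_leaves:
            clade_size = len(node_leaves)
            break
    return mono, clade_size


@dataclass
class ClassificationReport:
    """Per-sequence classifications with group and phenotype summaries."""

    records: list[IsoenzymeRecord]
    table: pd.DataFrame
    residue_counts: pd.DataFrame  # per (group, residue type)
    codon_counts: pd.DataFrame  # per (group, codon)
    phenotypes: list[PhenotypePrediction] = field(default_factory=list)
    badh_monophyletic: bool | None = None
    badh_clade_size: int | None = None

    @property
    def phenotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": p.species, "gb_class": p.gb_class,
              "n_isoenzymes": len(p.records)} for p in self.phenotypes],
            columns=["species", "gb_class", "n_isoenzymes"],
        )


def classification_report(alignment: AlignedSequenceSet,
                          ref_position: int = 441,
                          code: GeneticCode = STANDARD_CODE,
                          preset: str = "results-text",
                          tree=None,
                          include_reference: bool = False
                          ) -> ClassificationReport:
    """Classify every sequence of an alignment at the reference position.

    For each entry: the 441-equivalent residue and (when a CDS is present)
    its codon, the PTS1 status of the C-terminus, and the predicted activity
    and location.  A sequence whose alignment ends in gaps where the
    reference still has residues is treated as C-terminally truncated, so
    its PTS1 state is unknowable.  When a tree is given, monophyly of the
    BADH-active tips is assessed.
    """
    column = map_reference_position(alignment, ref_position)
    ref = alignment.reference
    ref_last = max(i for i, ch in enumerate(ref.protein) if ch != GAP)

    records: list[IsoenzymeRecord] = []
    for entry in alignment.entries:
        if entry.id == alignment.reference_id and not include_reference:
            continue
        residue = entry.protein[column - 1].upper()
        type_label = classify_residue_type(residue)
        codon = UNKNOWN
        if entry.cds is not None and residue != GAP:
            codon = extract_codon441(entry, column, code)
        non_gap = [i for i, ch in enumerate(entry.protein) if ch != GAP]
        truncated = bool(non_gap) and non_gap[-1] < ref_last
        if truncated or not non_gap:
            pts1_status, tri = "truncated-unknown", None
        else:
            pts1_status, tri = detect_pts1(entry.ungapped, preset)
        act = predict_activity(type_label)
        records.append(IsoenzymeRecord(
            identifier=entry.id,
            residue441=residue if residue != GAP else UNKNOWN,
            codon441=codon,
            type_label=type_label,
            pts1=pts1_status,
            pts1_tripeptide=tri,
            predicted_activity=act.activity,
            predicted_location=predict_location(pts1_status),
            low_confidence=act.low_confidence,
            group=entry.group,
            species=entry.species,
        ))

    table = pd.DataFrame([{
        "identifier": r.identifier,
        "group": r.group or "",
        "species": r.species or "",
        "residue441": r.residue441,
        "codon441": r.codon441,
        "type": r.type_label,
        "pts1": r.pts1,
        "pts1_tripeptide": r.pts1_tripeptide or "",
        "predicted_activity": r.predicted_activity,
        "predicted_location": r.predicted_location,
        "low_confidence": r.low_confidence,
    } for r in records])

    def _counts(key: str) -> pd.DataFrame:
        if table.empty:
            return pd.DataFrame(columns=["group", key, "count"])
        sub = table[table[key] != UNKNOWN]
        out = (sub.groupby(["group", key], dropna=False).size()
               .rename("count").reset_index())
        return out.sort_values(["group", key], ignore_index=True)

    residue_counts = _counts("residue441")
    codon_counts = _counts("codon441")

    phenotypes = []
    by_species: dict[str, list[IsoenzymeRecord]] = {}
    for r in records:
        if r.species:
            by_species.setdefault(r.species, []).append(r)
    for sp, recs in sorted(by_species.items()):
        phenotypes.append(predict_gb_phenotype(recs, species=sp))

    report = ClassificationReport(records=records, table=table,
                                  residue_counts=residue_counts,
                                  codon_counts=codon_counts,
                                  phenotypes=phenotypes)
    if tree is not None:
        badh_tips = [r.identifier for r in records
                     if r.predicted_activity == "AMADH+BADH"]
        if badh_tips:
            mono, clade = monophyly_check(tree, badh_tips)
            report.badh_monophyletic = mono
            report.badh_clade_size = clade
    return report
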