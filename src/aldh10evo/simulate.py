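"""Seeded generators for every input the analysis pipeline consumes.

Real ALDH10 studies start from database sequence sets and spectroscopic
assay traces; here every stage can instead run on synthetic inputs with
known ground truth.  The generators emulate the statistical structure the
analysis assumes — a family of aligned homologues differing at the
441-equivalent column, initial-velocity curves drawn from the substrate-
inhibition rate law, sigmoidal melt traces, and small trees with controlled
clade composition — and are pure functions of their parameters and a seed.

The template protein is an arbitrary fixed 500-residue sequence with a
marked 441 column and an SKL C-terminus.  It is NOT a real spinach BADH
sequence: conclusions drawn from these fixtures are about the pipeline's
correctness, not about any real enzyme.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AlignedSequenceSet, SequenceEntry, GAP
from .genetic_code import GeneticCode, STANDARD_CODE, codons_for
from .kinetics import KineticDataset, si_velocity
from .stability import MeltCurve, boltzmann_signal

__all__ = [
    "SequenceSpec",
    "REFERENCE_ID",
    "template_protein",
    "gen_sequences",
    "gen_kinetics",
    "gen_melt",
    "gen_tree",
    "BAL_GRID_UM",
    "APAL_GRID_UM",
]

REFERENCE_ID = "REF441"
TEMPLATE_LENGTH = 500
POSITION_441 = 441

#: Default substrate grids (µM).  BAL-like: 8 points over 0.02–2 mM.
BAL_GRID_UM = np.geomspace(20.0, 2000.0, 8)
#: APAL-like: 10 points over 0.5–200 µM (assays stop at 0.2 mM, which is
#: why the inhibition constant is hard to pin down on real data).
APAL_GRID_UM = np.geomspace(0.5, 200.0, 10)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def template_protein(length: int = TEMPLATE_LENGTH) -> str:
    """The fixed synthetic template: random-looking but deterministic,
    Ala at the 441 column, C-terminal SKL."""
    rng = np.random.default_rng(441)  # fixed: the template never varies
    aa = rng.choice(list(_AA20), size=length)
    seq = "".join(aa)
    seq = seq[: POSITION_441 - 1] + "A" + seq[POSITION_441:]
    return seq[:-3] + "SKL"


@dataclass
class SequenceSpec:
    """Composition of a synthetic isoenzyme family.

    ``composition`` gives sequence counts per 441-residue; ``pts1_states``
    the proportions of PTS1-intact, point-mutated and C-terminally
    truncated variants; ``monocot_fraction`` the share of sequences
    labelled monocot (the remainder eudicot).
    """

    composition: dict[str, int] = field(
        default_factory=lambda: {"I": 88, "A": 19, "C": 10, "V": 3, "T": 2})
    pts1_states: dict[str, float] = field(
        default_factory=lambda: {"intact": 0.7, "mutated": 0.2, "truncated": 0.1})
    monocot_fraction: float = 30.0 / 112.0
    template_length: int = TEMPLATE_LENGTH
    codon_weights: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("composition counts must be non-negative")
        total = sum(self.pts1_states.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"pts1_states fractions sum to {total}, expected 1")


# non-matching tripeptides one point mutation away from SKL, under both
# consensus presets
_PTS1_BREAKERS = ["SKP", "DKL", "SNL", "SKG", "EKL"]


def gen_sequences(spec: SequenceSpec | None = None, seed: int = 0,
                  code: GeneticCode = STANDARD_CODE
                  ) -> tuple[AlignedSequenceSet, pd.DataFrame]:
    """Generate an aligned protein family with matching CDS.

    All sequences share the template; they differ at the 441 column
    (residue drawn per the composition, codon drawn per the codon weights
    or uniformly among synonymous codons) and at the C-terminus (intact
    SKL, point-mutated signal, or truncation with trailing alignment gaps).
    Returns the alignment (reference included) and a ground-truth table
    with one row per generated sequence.
    """
    spec = spec or SequenceSpec()
    rng = np.random.default_rng(seed)
    template = template_protein(spec.template_length)
    n_total = sum(spec.composition.values())

    states = list(spec.pts1_states)
    state_p = np.array([spec.pts1_states[s] for s in states], dtype=float)

    entries = [SequenceEntry(id=REFERENCE_ID, protein=template,
                             cds=_reverse_translate(template, rng, code))]
    truth_rows = []
    i = 0
    for residue, count in sorted(spec.composition.items()):
        for _ in range(count):
            i += 1
            ident = f"syn{i:04d}_{residue}"
            pts1_state = str(rng.choice(states, p=state_p))
            group = "monocot" if rng.random() < spec.monocot_fraction else "eudicot"
            protein = template[: POSITION_441 - 1] + residue + template[POSITION_441:]
            if pts1_state == "mutated":
                tri = str(rng.choice(_PTS1_BREAKERS))
                protein = protein[:-3] + tri
            n_trunc = 0
            if pts1_state == "truncated":
                n_trunc = int(rng.integers(5, 31))
                protein = protein[:-n_trunc]
            cds = _reverse_translate(protein, rng, code)
            # force the 441 codon from the requested weights
            codon441 = _draw_codon(residue, spec.codon_weights, rng, code)
            cds = cds[: 3 * (POSITION_441 - 1)] + codon441 + cds[3 * POSITION_441:]
            aligned = protein + GAP * (spec.template_length - len(protein))
            entries.append(SequenceEntry(
                id=ident, protein=aligned, cds=cds, group=group,
                species=f"species_{ident}"))
            truth_rows.append({
                "identifier": ident, "residue441": residue,
                "codon441": codon441, "pts1_state": pts1_state,
                "n_truncated": n_trunc, "group": group,
            })

    truth = pd.DataFrame(truth_rows, columns=[
        "identifier", "residue441", "codon441", "pts1_state",
        "n_truncated", "group"])
    aln = AlignedSequenceSet(entries=entries, reference_id=REFERENCE_ID)
    assert len(aln) == n_total + 1
    return aln, truth


def _reverse_translate(protein: str, rng: np.random.Generator,
                       code: GeneticCode) -> str:
    parts = []
    for aa in protein:
        options = sorted(codons_for(aa, code))
        parts.append(options[rng.integers(len(options))])
    return "".join(parts)


def _draw_codon(residue: str, weights, rng: np.random.Generator,
                code: GeneticCode) -> str:
    options = sorted(codons_for(residue, code))
    if weights and residue in weights:
        w = np.array([weights[residue].get(c, 0.0) for c in options])
        if w.sum() <= 0:
            raise ValueError(f"codon weights for {residue!r} sum to zero")
        return options[rng.choice(len(options), p=w / w.sum())]
    return options[rng.integers(len(options))]


def sequences_to_fasta(alignment: AlignedSequenceSet, aligned: bool = True
                       ) -> tuple[str, str]:
    """Render the alignment as (protein FASTA, CDS FASTA) strings."""
    prot, cds = io.StringIO(), io.StringIO()
    for e in alignment.entries:
        seq = e.protein if aligned else e.ungapped
        prot.write(f">{e.id}\n{seq}\n")
        if e.cds:
            cds.write(f">{e.id}\n{e.cds}\n")
    return prot.getvalue(), cds.getvalue()


def gen_kinetics(kcat: float, Km: float, K_IS: float = np.inf,
                 grid: np.ndarray | None = None, cv: float = 0.0,
                 replicates: int = 1, seed: int = 0,
                 variant: str = "", substrate: str = "") -> KineticDataset:
    """Initial-velocity data from the substrate-inhibition rate law.

    Noise is multiplicative Gaussian (rate × (1 + cv·ε)), matching how
    spectrophotometric assay error scales with signal; cv = 0 returns the
    exact model values.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    S = np.tile(np.asarray(grid if grid is not None else APAL_GRID_UM,
                           dtype=float), replicates)
    v = np.asarray(si_velocity(kcat, Km, K_IS, S), dtype=float)
    if cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + cv * rng.standard_normal(v.shape))
    return KineticDataset(conc=S, rates=v, variant=variant, substrate=substrate)


def gen_melt(tm: float = 50.0, slope: float = 2.0,
             baseline_folded: float = -25.0, baseline_unfolded: float = -5.0,
             sigma: float = 0.0, temperatures: np.ndarray | None = None,
             seed: int = 0, variant: str = "") -> MeltCurve:
    """A Boltzmann melt trace over 20–90 °C with additive Gaussian noise."""
    T = np.asarray(temperatures if temperatures is not None
                   else np.arange(20.0, 91.0, 1.0), dtype=float)
    y = np.asarray(boltzmann_signal(T, tm, slope, baseline_folded,
                                    baseline_unfolded), dtype=float)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + sigma * rng.standard_normal(y.shape)
    return MeltCurve(temperatures=T, signal=y, variant=variant)


def gen_tree(clades: dict[str, dict[str, int]] | None = None, seed: int = 0
             ) -> tuple[str, pd.DataFrame]:
    """A small tree with labelled clades and assigned 441-residue states.

    ``clades`` maps clade label → {residue type: tip count}; each clade is
    a subtree, so monophyly outcomes are known by construction.  Mimics the
    recurring family pattern of one clade of peroxisomal Ile-type enzymes
    and a second, mixed clade.  Returns (newick string, tip state table).
    """
    clades = clades or {
        "clade1": {"I": 6},
        "clade2": {"I": 2, "A": 2, "C": 2},
    }
    n_tips = sum(sum(c.values()) for c in clades.values())
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = np.random.default_rng(seed)

    rows = []
    subtrees = []
    for clade, comp in sorted(clades.items()):
        tips = []
        for residue, count in sorted(comp.items()):
            for j in range(1, count + 1):
                name = f"{clade}_{residue}{j}"
                tips.append(name)
                rows.append({"tip": name, "clade": clade, "residue441": residue})
        order = rng.permutation(len(tips))
        nodes = [f"{tips[k]}:{rng.uniform(0.01, 0.2):.4f}" for k in order]
        while len(nodes) > 1:
            a, b = nodes.pop(), nodes.pop()
            nodes.append(f"({a},{b}):{rng.uniform(0.01, 0.2):.4f}")
        subtrees.append(nodes[0])
    while len(subtrees) > 1:
        a, b = subtrees.pop(), subtrees.pop()
        subtrees.append(f"({a},{b}):{rng.uniform(0.01, 0.2):.4f}")
    newick = subtrees[0].rsplit(":", 1)[0] + ";"
    states = pd.DataFrame(rows, columns=["tip", "clade", "residue441"])
    return newick, states
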