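"""End-to-end analysis pipeline: pathways → classification → kinetics → stability.

A :class:`RunConfig` (plain YAML) names the inputs and thresholds; a run
writes tab-separated report tables plus a log of versions, seeds and
settings.  Identical config + inputs give byte-identical tables.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import AlignedSequenceSet, classification_report
from .genetic_code import STANDARD_CODE, enumerate_pathways
from .kinetics import (KineticDataset, BADH_EFFICIENCY_THRESHOLD,
                       classify_badh_groups, fit_mm, fit_si)
from .stability import MeltCurve, classify_stability, fit_melt

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """One or more pipeline stages failed; carries per-stage messages."""

    def __init__(self, failures: dict[str, str]):
        self.failures = failures
        super().__init__("; ".join(f"[{k}] {v}" for k, v in failures.items()))


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    output_dir: str = "aldh10evo_report"
    alignment_fasta: str | None = None
    cds_fasta: str | None = None
    tree_newick: str | None = None
    kinetics_tsv: str | None = None
    melt_tsv: str | None = None
    reference_id: str = "REF441"
    ref_position: int = 441
    pts1_preset: str = "results-text"
    pathway_pairs: list = field(default_factory=lambda: [["I", "A"], ["I", "C"]])
    kinetic_model: str = "si"  # mm | si
    badh_threshold: float = BADH_EFFICIENCY_THRESHOLD
    delta_tm_threshold: float = 5.0
    stability_reference: str = "wild-type"
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage and write the report bundle.

    Returns a mapping of stage name → written table path.  Raises
    :class:`PipelineError` aggregating all stage failures.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    failures: dict[str, str] = {}
    log_lines = [
        f"aldh10evo {__version__}",
        f"python {sys.version.split()[0]}",
        f"seed {config.seed}",
        f"pts1 preset {config.pts1_preset}",
        f"BADH efficiency threshold {config.badh_threshold} mM^-1 s^-1",
        f"delta-Tm threshold {config.delta_tm_threshold} C",
    ]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                log_lines.append(f"stage {name}: ok ({time.perf_counter() - t0:.2f} s)")
            except Exception as exc:  # aggregated, reported with stage name
                failures[name] = str(exc)
                log_lines.append(f"stage {name}: FAILED ({exc})")
        return deco

    @stage("pathways")
    def _pathways():
        frames = [enumerate_pathways(src, dst, STANDARD_CODE).to_frame()
                  for src, dst in config.pathway_pairs]
        df = pd.concat(frames, ignore_index=True)
        path = outdir / "pathways.tsv"
        _write_tsv(df, path, "minimal codon pathways; codons are DNA triplets")
        outputs["pathways"] = path

    if config.alignment_fasta:
        @stage("classification")
        def _classify():
            aln = AlignedSequenceSet.from_fasta(
                config.alignment_fasta, reference_id=config.reference_id,
                cds_path=config.cds_fasta)
            tree = None
            if config.tree_newick:
                tree = Path(config.tree_newick).read_text()
                import dendropy
                tips = {lf.taxon.label for lf in dendropy.Tree.get(
                    data=tree, schema="newick", preserve_underscores=True
                ).leaf_node_iter()}
                ids = {e.id for e in aln.entries}
                if not tips & ids:
                    log_lines.append(
                        "tree tips share no identifiers with the alignment; "
                        "monophyly check skipped")
                    tree = None
            rep = classification_report(aln, ref_position=config.ref_position,
                                        preset=config.pts1_preset, tree=tree)
            path = outdir / "classification.tsv"
            _write_tsv(rep.table, path,
                       "per-sequence 441-residue type, PTS1 status and predictions")
            outputs["classification"] = path
            path = outdir / "residue_counts.tsv"
            _write_tsv(rep.residue_counts, path, "441-residue counts per group")
            outputs["residue_counts"] = path
            if rep.phenotypes:
                path = outdir / "phenotypes.tsv"
                _write_tsv(rep.phenotype_table, path,
                           "predicted glycine-betaine accumulation class per species")
                outputs["phenotypes"] = path
            if rep.badh_monophyletic is not None:
                log_lines.append(
                    f"BADH-active tips monophyletic: {rep.badh_monophyletic} "
                    f"(smallest containing clade: {rep.badh_clade_size} tips)")

    if config.kinetics_tsv:
        @stage("kinetics")
        def _kinetics():
            df = pd.read_csv(config.kinetics_tsv, sep="\t", comment="#")
            fit = fit_si if config.kinetic_model == "si" else fit_mm
            rows = []
            for (variant, substrate), _ in df.groupby(["variant", "substrate"]):
                ds = KineticDataset.from_dataframe(df, variant, substrate)
                res = fit(ds)
                row = {"variant": variant, "substrate": substrate,
                       "n": res.n_obs}
                for name, value in res.params.items():
                    row[name] = value
                    row[f"{name}_se"] = res.bse[name]
                row["kcat_over_Km_mM_s"] = res.efficiency
                row["K_IS_unreliable"] = res.kis_unreliable
                rows.append(row)
            table = pd.DataFrame(rows)
            path = outdir / "kinetics_fits.tsv"
            _write_tsv(table, path,
                       "kcat (s^-1), Km and K_IS (uM), kcat/Km (mM^-1 s^-1); "
                       "SEs from the linearized covariance")
            outputs["kinetics"] = path
            bal = table[table["substrate"].str.upper() == "BAL"]
            if not bal.empty:
                grouping = classify_badh_groups(
                    dict(zip(bal["variant"], bal["kcat_over_Km_mM_s"])),
                    threshold=config.badh_threshold)
                path = outdir / "badh_groups.tsv"
                _write_tsv(grouping.to_frame(), path,
                           "two-group split by efficiency with betaine aldehyde")
                outputs["badh_groups"] = path

    if config.melt_tsv:
        @stage("stability")
        def _stability():
            df = pd.read_csv(config.melt_tsv, sep="\t", comment="#")
            tms = {}
            rows = []
            for variant in sorted(df["variant"].unique()):
                res = fit_melt(MeltCurve.from_dataframe(df, variant))
                tms[variant] = res.tm_app
                rows.append({"variant": variant, "tm_app_C": res.tm_app,
                             "slope_C": res.slope,
                             "tm_se_C": res.bse["Tm"], "n": res.n_obs})
            table = pd.DataFrame(rows)
            path = outdir / "melt_fits.tsv"
            _write_tsv(table, path, "apparent Tm (C) from Boltzmann fits")
            outputs["melt_fits"] = path
            if config.stability_reference in tms:
                groups = classify_stability(tms, config.stability_reference,
                                            config.delta_tm_threshold)
                path = outdir / "stability_groups.tsv"
                _write_tsv(groups, path,
                           "Tm shift vs reference; threshold "
                           f"{config.delta_tm_threshold} C")
                outputs["stability_groups"] = path

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    if failures:
        raise PipelineError(failures)
    return outputs
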