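"""End-to-end pipeline: QC → diversity → LD/Ne → kinship → families → ROH.

``run_pipeline`` executes every stage on a PLINK-format input and writes a
plain-text report bundle (tab-separated tables, newick trees, a manifest
echoing the full configuration) into the output directory.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataset import GenotypeDataset
from .families import assign_families, cut_lineages, neighbor_joining
from .ldne import NeConfig, ne_trajectory, trajectory_tsv
from .plink import read_plink
from .qc import QCThresholds, apply_qc, diversity_summary
from .relatedness import ibs_distance, vanraden_g
from .roh import (
    PIG_AUTOSOME_LENGTH_KB,
    ROHParams,
    classify_roh,
    detect_roh,
    f_roh,
    roh_summaries,
    segments_table,
)

log = logging.getLogger("herdgen")


@dataclass
class PipelineConfig:
    input_prefix: str
    output_dir: str
    qc: QCThresholds = field(default_factory=QCThresholds)
    roh: ROHParams = field(default_factory=ROHParams)
    ne: NeConfig = field(default_factory=NeConfig)
    k_lineages: int = 8
    relationship_threshold: float = 0.1
    autosome_length_kb: float = PIG_AUTOSOME_LENGTH_KB
    seed: int = 0

    def manifest(self) -> str:
        lines = [f"herdgen_version={__version__}"]
        lines.append(f"input_prefix={self.input_prefix}")
        lines.append(f"output_dir={self.output_dir}")
        lines.append(f"seed={self.seed}")
        lines.append(f"k_lineages={self.k_lineages}")
        lines.append(f"relationship_threshold={self.relationship_threshold}")
        lines.append(f"autosome_length_kb={self.autosome_length_kb}")
        for prefix, obj in (("qc", self.qc), ("roh", self.roh)):
            for name, val in vars(obj).items():
                lines.append(f"{prefix}.{name}={val}")
        lines.append(f"ne.bin_edges_bp={list(map(int, self.ne.bin_edges_bp))}")
        lines.append(f"ne.max_pairs_per_bin={self.ne.max_pairs_per_bin}")
        lines.append(f"ne.cm_per_mb={self.ne.cm_per_mb}")
        lines.append(f"ne.correct_sample_size={self.ne.correct_sample_size}")
        lines.append(f"ne.seed={self.ne.seed}")
        return "\n".join(lines) + "\n"


def _stage(name: str):
    start = time.perf_counter()

    def done(shape_note: str) -> None:
        log.info("%s: %s (%.2f s)", name, shape_note, time.perf_counter() - start)

    return done


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns result objects."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    done = _stage("load")
    ds = read_plink(config.input_prefix)
    done(f"{ds.n_samples} samples x {ds.n_markers} markers")

    done = _stage("qc")
    filtered, report = apply_qc(ds, config.qc)
    (out / "qc_report.tsv").write_text(report.to_tsv())
    done(f"{report.n_retained}/{report.n_input_snps} markers retained")

    done = _stage("diversity")
    div = diversity_summary(filtered)
    (out / "diversity.tsv").write_text(div.to_tsv())
    done(f"P_N={div.P_N:.3f} He={div.He:.4f} Ho={div.Ho:.4f}")

    done = _stage("ld_ne")
    estimates, headline = ne_trajectory(filtered, config.ne)
    (out / "ne_trajectory.tsv").write_text(trajectory_tsv(estimates))
    done(f"headline Ne={headline.ne:.1f} at t={headline.t_generations:.1f}")

    done = _stage("relatedness")
    g = vanraden_g(filtered)
    ibs = ibs_distance(filtered)
    (out / "grm.tsv").write_text(g.to_tsv())
    (out / "ibs_distance.tsv").write_text(ibs.to_tsv())
    done(f"G range [{g.values.min():.2f}, {g.values.max():.2f}]")

    done = _stage("family_structure")
    boars = [
        i
        for i, s in enumerate(filtered.samples)
        if (s.group_label == "boar") or (s.group_label is None and s.sex == "male")
    ]
    if len(boars) >= 2 and config.k_lineages <= len(boars):
        boar_ids = [filtered.samples[i].sample_id for i in boars]
        boar_tree = neighbor_joining(ibs.values[np.ix_(boars, boars)], boar_ids)
        (out / "boar_tree.nwk").write_text(boar_tree.newick() + "\n")
        lineages = cut_lineages(boar_tree, config.k_lineages)
        fam = assign_families(
            g, lineages, threshold=config.relationship_threshold
        )
        groups = {s.sample_id: s.group_label or s.sex for s in filtered.samples}
        (out / "families.tsv").write_text(fam.to_tsv(groups))
        all_tree = neighbor_joining(ibs.values, list(ibs.sample_ids))
        (out / "all_tree.nwk").write_text(all_tree.newick() + "\n")
        done(f"{config.k_lineages} lineages over {len(boars)} boars")
    else:
        fam = None
        log.warning(
            "family_structure skipped: %d boars found, k=%d",
            len(boars),
            config.k_lineages,
        )

    done = _stage("roh_inbreeding")
    auto = filtered.autosomal()
    segments = detect_roh(auto, config.roh)
    segments_table(segments).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    classify_roh(segments).to_csv(out / "roh_classes.tsv", sep="\t", index=False)
    per_chrom, per_indiv, mean_count = roh_summaries(segments, auto)
    per_chrom.to_csv(out / "roh_per_chromosome.tsv", sep="\t")
    per_indiv.to_csv(out / "roh_per_individual.tsv", sep="\t")
    inb = f_roh(
        segments,
        autosome_length_kb=config.autosome_length_kb,
        sample_ids=auto.sample_ids,
    )
    (out / "froh.tsv").write_text(inb.to_tsv())
    done(
        f"{len(segments)} segments, mean {mean_count:.2f}/individual, "
        f"mean F_ROH {inb.population_mean:.3f}"
    )

    (out / "manifest.txt").write_text(config.manifest())
    return {
        "dataset": filtered,
        "qc_report": report,
        "diversity": div,
        "ne_estimates": estimates,
        "ne_headline": headline,
        "grm": g,
        "ibs": ibs,
        "families": fam,
        "roh_segments": segments,
        "roh_mean_count": mean_count,
        "inbreeding": inb,
    }
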