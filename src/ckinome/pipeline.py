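"""End-to-end orchestration: simulate/ingest → infer → classify → analyze.

`run_pipeline` drives every stage over one configuration and writes all
tabular artifacts (TSV with a config-hash header comment, JSON model)
plus a run log.  Outputs contain no timestamps, so a rerun with the same
configuration and seeds is byte-identical.  Each stage failure aborts
with the stage name and cause.

Phylogeny inference is deliberately delegated: the pipeline writes a
representative sequence sample (one randomly chosen member per
cluster–taxon pair, plus any user-supplied special sets) for an external
tree builder and can consume a clade map derived from such a tree, but
never runs tree inference itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import ProfileAlignment, filter_fragments, purge_identity, read_a2m, write_a2m
from .cluster_analysis import (
    comparative_logo,
    de_loop_lengths,
    label_clades,
    loop_stats_frame,
    similarity_matrix,
)
from .gene_structure import GeneStructure, read_exon_table, shared_introns, write_exon_table
from .inference import ConstraintHierarchy, InferenceConfig, consensus_hierarchy, infer_hierarchy
from .scoring import ClassificationResult, classify, select_cutoff
from .synthetic import PresetBundle, default_preset
from .taxonomy import TaxonomyTable, conservation_matrix, domain_frequency, parse_taxdump, write_taxdump

logger = logging.getLogger("ckinome")

#: internal clades reported by default for synthetic runs
DEFAULT_TARGET_TAXA = (3, 4, 5, 6, 7, 8, 9, 12)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """One pipeline run: either a synthetic preset or explicit inputs."""

    out_dir: str | Path
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)
    aln_path: str | Path | None = None
    nodes_path: str | Path | None = None
    names_path: str | Path | None = None
    exons_path: str | Path | None = None
    domains_path: str | Path | None = None
    anchors: dict[str, int] | None = None
    fragment_filter: bool = True
    identity_threshold: float = 0.98
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    max_depth: int = 4
    n_runs: int = 1
    min_support: float = 0.5
    cutoff: float | None = 0.7
    relaxed_cutoff: float = 0.6
    clade_threshold: float = 10.0
    target_taxa: tuple[int, ...] | None = None
    special_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["out_dir"] = None  # location does not alter the science
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineReport:
    paths: dict[str, Path]
    counts: dict[str, int]
    hierarchy: ConstraintHierarchy
    result: ClassificationResult


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ckinome {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def sample_representatives(
    result: ClassificationResult,
    aln: ProfileAlignment,
    tax: TaxonomyTable,
    target_taxa: Sequence[int],
    special_sets: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> list[str]:
    """One random member per occupied (cluster, taxon) pair, plus specials.

    Pairs without members are skipped; the sample is deterministic given
    the seed.  Special sets (e.g. all sequences of a reference organism,
    or an outgroup) are appended verbatim; duplicates are dropped while
    preserving order.
    """
    rng = np.random.default_rng(seed)
    lineages: dict[str, set[int]] = {}
    for rec in aln:
        if rec.organism_id is not None:
            try:
                lineages[rec.id] = set(tax.lineage(rec.organism_id))
            except KeyError:
                continue
    picked: list[str] = []
    for cluster in sorted(result.scores.columns):
        members = result.members(cluster)
        for taxon in target_taxa:
            pool = [m for m in members if taxon in lineages.get(m, ())]
            if pool:
                picked.append(pool[int(rng.integers(len(pool)))])
    for name in sorted(special_sets or {}):
        picked.extend(special_sets[name])
    seen: set[str] = set()
    out = []
    for sid in picked:
        if sid not in seen:
            seen.add(sid)
            out.append(sid)
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute every stage and write the full artifact bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    paths: dict[str, Path] = {}
    counts: dict[str, int] = {}
    log_lines = [
        f"ckinome {__version__}",
        f"config hash {cfg_hash}",
        f"seed {cfg.seed}",
    ]

    # ---- data -------------------------------------------------------------
    stage = "data"
    try:
        genes: list[GeneStructure]
        domains: pd.DataFrame | None
        tax: TaxonomyTable | None
        if cfg.simulate is not None:
            bundle: PresetBundle = default_preset(seed=cfg.seed, **cfg.simulate)
            aln, truth, tax = bundle.aln, bundle.truth, bundle.taxonomy
            genes, domains, anchors = bundle.genes, bundle.domains, bundle.anchors
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            write_a2m(aln, data_dir / "aln.a2m")
            truth.save(data_dir / "truth.json")
            write_taxdump(tax, data_dir / "nodes.dmp", data_dir / "names.dmp")
            write_exon_table(genes, data_dir / "exons.tsv")
            domains.to_csv(data_dir / "domains.tsv", sep="\t", index=False)
            paths["data"] = data_dir
        else:
            if cfg.aln_path is None:
                raise ValueError("aln_path required when simulate is disabled")
            aln = read_a2m(cfg.aln_path)
            anchors = dict(cfg.anchors or {})
            tax = None
            if cfg.nodes_path and cfg.names_path:
                tax = parse_taxdump(cfg.nodes_path, cfg.names_path)
            genes = read_exon_table(cfg.exons_path) if cfg.exons_path else []
            domains = (
                pd.read_csv(cfg.domains_path, sep="\t", comment="#")
                if cfg.domains_path
                else None
            )
        counts["input_records"] = len(aln)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- filtering --------------------------------------------------------
    stage = "filtering"
    try:
        if cfg.fragment_filter and anchors:
            aln = filter_fragments(aln, anchors["beta3-K"], anchors["DFG-D"])
        counts["after_fragment_filter"] = len(aln)
        aln = purge_identity(aln, cfg.identity_threshold)
        counts["after_identity_purge"] = len(aln)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- inference --------------------------------------------------------
    stage = "inference"
    try:
        runs = []
        for r in range(cfg.n_runs):
            run_cfg = dataclasses.replace(cfg.inference, seed=cfg.inference.seed + r)
            runs.append(infer_hierarchy(aln, run_cfg, max_depth=cfg.max_depth))
        if len(runs) > 1:
            hierarchy = consensus_hierarchy(runs, cfg.min_support, aln, cfg.inference)
        else:
            hierarchy = runs[0]
        hierarchy.save(out / "model.json")
        paths["model"] = out / "model.json"
        counts["clusters"] = len(hierarchy.cluster_ids())
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- classification ---------------------------------------------------
    stage = "classification"
    try:
        if cfg.cutoff is None:
            from .scoring import score_all

            pool = score_all(aln, hierarchy).to_numpy().ravel()
            picked = select_cutoff(pool)
            cutoff = picked.value
            log_lines.append(
                f"cutoff selected {cutoff:.3f} fallback={picked.fallback}"
            )
        else:
            cutoff = cfg.cutoff
        result = classify(aln, hierarchy, cutoff)
        scores_df, assign_df = result.to_frames()
        _write_tsv(scores_df, out / "scores.tsv", cfg_hash)
        _write_tsv(assign_df, out / "assignments.tsv", cfg_hash)
        paths["scores"] = out / "scores.tsv"
        paths["assignments"] = out / "assignments.tsv"
        counts["classified"] = sum(1 for p in result.assignments.values() if p)
        counts["unclassified"] = sum(
            1 for p in result.assignments.values() if not p
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- cluster analysis -------------------------------------------------
    stage = "cluster_analysis"
    try:
        sim = similarity_matrix(result, hierarchy, aln)
        _write_tsv(sim, out / "similarity.tsv", cfg_hash, index=True)
        paths["similarity"] = out / "similarity.tsv"
        logo_frames = []
        for node in hierarchy.children(hierarchy.root_id):
            members = result.members(node.id)
            cols = [c.column for c in node.constraints]
            if not members or not cols or len(members) == len(aln):
                continue
            data = comparative_logo(aln, members, cols)
            frame = data.to_frame()
            frame.insert(0, "cluster_id", node.id)
            logo_frames.append(frame)
        if logo_frames:
            _write_tsv(pd.concat(logo_frames), out / "logos.tsv", cfg_hash)
            paths["logos"] = out / "logos.tsv"
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- taxonomy ---------------------------------------------------------
    stage = "taxonomy"
    try:
        if tax is None:
            raise ValueError("conservation analysis needs nodes/names dump files")
        target_taxa = cfg.target_taxa or DEFAULT_TARGET_TAXA
        for label, cut in (("conservation", cutoff), ("conservation_relaxed", cfg.relaxed_cutoff)):
            cons = conservation_matrix(result, aln, tax, list(target_taxa), cut)
            _write_tsv(cons.named(tax), out / f"{label}.tsv", cfg_hash, index=True)
            paths[label] = out / f"{label}.tsv"
        if domains is not None:
            freqs = domain_frequency(domains, result)
            _write_tsv(freqs.full, out / "domain_frequency.tsv", cfg_hash)
            paths["domain_frequency"] = out / "domain_frequency.tsv"
        reps = sample_representatives(
            result, aln, tax, list(target_taxa), cfg.special_sets, seed=cfg.seed
        )
        (out / "representatives.txt").write_text(
            "\n".join([f"# ckinome {__version__} config={cfg_hash}"] + reps) + "\n"
        )
        paths["representatives"] = out / "representatives.txt"
        counts["representatives"] = len(reps)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- introns ----------------------------------------------------------
    stage = "introns"
    try:
        if genes:
            family_map = {
                sid: result.assigned_cluster(sid) for sid in result.assignments
            }
            by_id = {g.protein_id: g for g in genes}
            pairs = [(by_id[rec.id], rec) for rec in aln if rec.id in by_id]
            shared = shared_introns(pairs, family_map)
            _write_tsv(shared, out / "shared_introns.tsv", cfg_hash)
            paths["shared_introns"] = out / "shared_introns.tsv"
            counts["intron_groups"] = len(shared)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- DE loops ----------------------------------------------------------
    stage = "loops"
    try:
        if anchors and "alphaD-end" in anchors:
            family_map = {
                sid: result.assigned_cluster(sid) for sid in result.assignments
            }
            stats = de_loop_lengths(
                aln,
                anchors["alphaD-end"],
                anchors["alphaE-start"],
                family_map,
            )
            stats = label_clades(stats, threshold=cfg.clade_threshold)
            _write_tsv(loop_stats_frame(stats), out / "loops.tsv", cfg_hash)
            paths["loops"] = out / "loops.tsv"
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- run log ----------------------------------------------------------
    log_lines += [f"{k} {v}" for k, v in counts.items()]
    log_lines += [
        f"inference {dataclasses.asdict(cfg.inference)}",
        f"cutoff {cutoff}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = out / "run.log"
    return PipelineReport(paths, counts, hierarchy, result)


__all__ = [
    "DEFAULT_TARGET_TAXA",
    "PipelineConfig",
    "PipelineReport",
    "PipelineStageError",
    "run_pipeline",
    "sample_representatives",
]
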