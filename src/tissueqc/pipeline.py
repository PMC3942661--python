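"""End-to-end orchestration: simulate -> (trim) -> filter -> dedup ->
count -> marker panel -> select -> DE -> interference audit -> class
enrichment, with a per-library report and an optional trimmed arm for
the 5'-bias comparison.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import audit as qaudit
from . import de as qde
from . import enrich as qenrich
from . import panel as qpanel
from . import quant as qquant
from . import readqc as qreadqc
from .core import CountMatrix
from .io import ensure_dir
from .sim import SimulatedExperiment, SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_n: int = 0
    homopolymer_min: int = 50
    mean_phred_min: float = 30.0
    trim5: int = 0
    compare_trim: bool = True
    trim_compare_k: int = 10
    min_mapq: int = 10
    sig_level: float = 0.05
    audit_bins: int = 20
    depth_classes: tuple = (5, 100, 1000, 5000)

    def validate(self) -> None:
        self.simulation.validate()
        if self.trim5 < 0 or self.trim_compare_k <= 0:
            raise ValueError("trim lengths must be non-negative (compare arm > 0)")
        if not 0 < self.sig_level < 1:
            raise ValueError("sig_level must be in (0, 1)")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        schema_errors = []
        sim_raw = raw.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        schema_errors += [f"unknown simulation key {k!r}" for k in sim_raw if k not in known_sim]
        schema_errors += [f"unknown pipeline key {k!r}" for k in raw if k not in known]
        if schema_errors:
            raise ValueError("; ".join(schema_errors))
        for key in ("contamination", "groups", "labels", "cdna_input"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        if "depth_classes" in raw:
            raw["depth_classes"] = tuple(raw["depth_classes"])
        cfg = cls(simulation=SimulationConfig(**sim_raw), **raw)
        cfg.validate()
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@dataclass
class ArmResult:
    """Everything one analysis arm (full or trimmed) produces."""

    trim5: int
    library_stats: pd.DataFrame
    counts: CountMatrix
    fpkm: pd.DataFrame
    dup_diagnostic: qquant.DuplicateDiagnostic
    verdicts: dict
    selected: CountMatrix
    exclusions: pd.DataFrame
    de: pd.DataFrame
    silhouette_all: float
    silhouette_selected: float
    audit: dict
    enrichment: pd.DataFrame
    bias_score: float
    alignments_selected: dict


@_stage("arm")
def run_arm(sim: SimulatedExperiment, config: PipelineConfig, trim5: int) -> ArmResult:
    thresholds = qreadqc.FilterThresholds(
        max_n=config.max_n,
        homopolymer_min=config.homopolymer_min,
        mean_phred_min=config.mean_phred_min,
        trim5=trim5,
    )
    lib_rows = []
    counts_cols = {}
    dedup_alignments = {}
    rates, dup_counts = [], []
    for lib in sim.libraries:
        kept, summary = qreadqc.filter_reads(lib.pairs, thresholds)
        kept_ids = {p.id for p in kept}
        records = [a for a in lib.alignments if a.read_id in kept_ids]
        dd = qquant.remove_duplicates(records)
        res = qquant.count_union(dd.alignments, sim.genes, config.min_mapq)
        counts_cols[lib.name] = res.counts
        dedup_alignments[lib.name] = dd.alignments
        rates.append(dd.duplicate_rate)
        dup_counts.append(dd.n_removed)
        detected = int((res.counts > 0).sum())
        lib_rows.append(
            {
                "library": lib.name,
                "raw_pairs": summary.total,
                "kept_pairs": summary.kept,
                **{f"dropped_{k}": v for k, v in summary.dropped_by_reason.items()},
                "duplicate_rate": dd.duplicate_rate,
                "fragments_counted": res.categories["counted"],
                "ambiguous": res.categories["ambiguous"],
                "no_feature": res.categories["no_feature"],
                "low_quality": res.categories["low_quality"],
                "genes_detected": detected,
                "mean_fragments_per_detected_gene": (
                    float(res.counts[res.counts > 0].mean()) if detected else 0.0
                ),
            }
        )
    library_stats = pd.DataFrame(lib_rows).set_index("library")
    counts = CountMatrix(pd.DataFrame(counts_cols), sim.counts.meta.copy())
    dupdiag = qquant.duplicate_input_diagnostic(
        rates,
        [lib.cdna_input for lib in sim.libraries],
        duplicate_counts=dup_counts,
        libraries=[lib.name for lib in sim.libraries],
    )
    fpkm = qquant.count_matrix_fpkm(counts.counts, sim.genes)

    marker_panel = qpanel.reference_panel_from_profiles(
        sim.profiles, sim.genes, sim.config.phi
    )
    verdicts = qpanel.evaluate_panel(fpkm, marker_panel)
    selected, exclusions = qpanel.select_libraries(verdicts, counts)

    # concordance before/after selection
    groups_all = counts.meta["group"]
    conc_all = qde.concordance(qde.transform_counts(counts.counts))
    sil_all = qde.group_silhouette(conc_all.pca, groups_all)
    groups_sel = selected.meta["group"]
    trans_sel = qde.transform_counts(selected.counts)
    conc_sel = qde.concordance(trans_sel)
    sil_sel = qde.group_silhouette(conc_sel.pca, groups_sel)

    factors = qde.size_factors(selected.counts)
    de = qde.nb_test(selected.counts, groups_sel, factors, sig_level=config.sig_level)

    # interference audit on the selected libraries
    target = next(g for g in sim.genes if g.gene_id == sim.target_gene)
    t_lo, t_hi = sim.targeted_region()
    partition = qaudit.RegionPartition(sim.target_gene, (t_lo, t_hi), (0, t_lo))
    sel_alignments = {lib: dedup_alignments[lib] for lib in selected.libraries}
    group_map = dict(groups_sel)
    interference = qaudit.interference_statistic(
        sel_alignments, group_map, target, partition
    )
    profiles_by_lib = {
        lib: qaudit.coverage_profile(recs, target, config.audit_bins)
        for lib, recs in sel_alignments.items()
    }
    disp_target = de.loc[sim.target_gene, "dispersion"]
    pooled = float(disp_target) if np.isfinite(disp_target) else float(
        np.nanmedian(de["dispersion"])
    )
    restricted = qaudit.region_restricted_de(
        sel_alignments, target, partition, group_map, factors, pooled
    )
    audit_block = {
        "target_gene": sim.target_gene,
        "interference_ratio": interference.ratio,
        "interference_flagged": interference.flagged,
        "targeted_fraction_by_library": interference.fractions,
        "coverage_bins": {k: v for k, v in profiles_by_lib.items()},
        "full_gene": de.loc[sim.target_gene].to_dict(),
        "restricted_5prime": restricted.iloc[0].to_dict(),
    }

    # class composition of the significant genes, against simulated truth
    classes = qenrich.TissueClassSets.from_overlapping(
        *(
            {
                g
                for g, k in zip(sim.profiles.gene_ids, sim.profiles.gene_class)
                if k == cls
            }
            for cls in ("neuronal", "glial", "ubiquitous")
        )
    )
    sig_genes = list(de.index[de["significant"].fillna(False)])
    enrichment = (
        qenrich.classify_de(sig_genes, classes)
        if sig_genes
        else pd.DataFrame(
            columns=["class_size", "de_in_class", "de_total", "percent"]
        )
    )

    # 5' bias diagnostic on the first library's raw reads
    profile = qreadqc.nucleotide_profile(
        sim.libraries[0].pairs, min(40, sim.config.read_length)
    )
    score = qreadqc.bias_score(profile, sim.config.bias_positions)

    return ArmResult(
        trim5, library_stats, counts, fpkm, dupdiag, verdicts, selected,
        exclusions, de, sil_all, sil_sel, audit_block, enrichment, score,
        sel_alignments,
    )


def compare_trim_arms(
    full: ArmResult, trimmed: ArmResult, depth_classes=(5, 100, 1000, 5000)
) -> dict:
    """Trimming comparison block: counted-fragment deltas, per-depth-class
    gains and the DE-list intersection."""
    if list(full.counts.libraries) != list(trimmed.counts.libraries):
        raise ValueError("arms cover different libraries")
    delta = (
        trimmed.library_stats["fragments_counted"]
        - full.library_stats["fragments_counted"]
    )
    factors_full = qde.size_factors(full.counts.counts)
    factors_trim = qde.size_factors(trimmed.counts.counts)
    norm_full = full.counts.counts.div(factors_full, axis=1)
    norm_trim = trimmed.counts.counts.div(factors_trim, axis=1)
    mean_full = norm_full.mean(axis=1)
    gains = {}
    for thr in depth_classes:
        genes = mean_full.index[mean_full > thr]
        if len(genes) == 0:
            gains[f">{thr}"] = None
            continue
        tot_f = norm_full.loc[genes].sum(axis=0)
        tot_t = norm_trim.loc[genes].sum(axis=0)
        gains[f">{thr}"] = float(((tot_t - tot_f) / tot_f).mean())
    sig_full = set(full.de.index[full.de["significant"].fillna(False)])
    sig_trim = set(trimmed.de.index[trimmed.de["significant"].fillna(False)])
    return {
        "counted_fragments_delta": delta,
        "counted_fragments_full": full.library_stats["fragments_counted"],
        "counted_fragments_trimmed": trimmed.library_stats["fragments_counted"],
        "depth_class_gains": gains,
        "de_venn": {
            "both": len(sig_full & sig_trim),
            "full_only": len(sig_full - sig_trim),
            "trimmed_only": len(sig_trim - sig_full),
        },
        "bias_score_raw": full.bias_score,
    }


def _arm_report(arm: ArmResult, sig_level: float) -> dict:
    de = arm.de
    sig = de["significant"].fillna(False)
    up = int((sig & (de["log2_fold_change"] > 0)).sum())
    down = int((sig & (de["log2_fold_change"] < 0)).sum())
    return {
        "trim5": arm.trim5,
        "libraries": arm.library_stats,
        "duplicate_input_correlation": {
            "r_rate": arm.dup_diagnostic.r_rate,
            "r_count": arm.dup_diagnostic.r_count,
            "flagged": arm.dup_diagnostic.flagged,
            "note": arm.dup_diagnostic.note,
        },
        "panel": qpanel.verdicts_frame(arm.verdicts),
        "excluded_libraries": arm.exclusions,
        "selected_libraries": list(arm.selected.libraries),
        "silhouette_all": arm.silhouette_all,
        "silhouette_selected": arm.silhouette_selected,
        "de_summary": {
            "n_tested": int(de["pvalue"].notna().sum()),
            "n_significant": int(sig.sum()),
            "n_up": up,
            "n_down": down,
            "sig_level": sig_level,
        },
        "audit": arm.audit,
        "enrichment": arm.enrichment,
        "bias_score": arm.bias_score,
    }


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Execute all stages; return the run report (JSON-serializable)."""
    config.validate()
    t0 = time.perf_counter()
    sim = simulate_experiment(config.simulation)
    logger.info("simulation finished in %.2fs", time.perf_counter() - t0)
    if outdir:
        sim.write(os.path.join(ensure_dir(outdir), "sim"))

    full = run_arm(sim, config, config.trim5)
    report = {
        "config": dataclasses.asdict(config),
        "seed": config.simulation.seed,
        "report": _arm_report(full, config.sig_level),
    }
    if config.compare_trim:
        trimmed = run_arm(sim, config, config.trim_compare_k)
        report["trimmed_report"] = _arm_report(trimmed, config.sig_level)
        report["trim_comparison"] = compare_trim_arms(
            full, trimmed, config.depth_classes
        )
    report = _jsonable(report)
    if outdir:
        with open(os.path.join(outdir, "run_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        full.counts.counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
        full.fpkm.to_csv(os.path.join(outdir, "fpkm.tsv"), sep="\t")
        full.de.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t")
        qpanel.verdicts_frame(full.verdicts).to_csv(
            os.path.join(outdir, "panel_verdicts.tsv"), sep="\t"
        )
    return report
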