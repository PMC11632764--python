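"""End-to-end orchestration: simulate/enumerate → classify → evaluate →
building-block statistics → accessibility → consolidated report.

The pipeline is a pure function of (inputs, config, seed): the same YAML
config and seed produce byte-identical reports.  Each stage logs one
line with its input/output row counts.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import accessibility as acc
from . import bbstats, library, metrics, screen, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "render_markdown"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-loadable)."""

    out_dir: str = "delbench_run"
    seed: int = 0
    simulate: bool = True
    synth: dict[str, Any] = field(default_factory=dict)

    # input files (used when simulate is off, or to override simulated ones)
    blocks_csv: str | None = None
    counts_csv: str | None = None
    dock_csv: str | None = None
    protein_pdb: str | None = None
    poses_sdf: str | None = None
    evs_csv: str | None = None

    # stage toggles
    run_classify: bool = True
    run_evaluate: bool = True
    run_bbstats: bool = True
    run_accessibility: bool = True

    # thresholds
    hit_mode: str = "fn"  # "fn" or "readcount"
    fn_threshold: float = 1.0
    min_copies: int = 10
    vhl_threshold: float = 0.95
    ef_fractions: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05)
    top_counts: tuple[int, ...] = ()
    top_n_depths: tuple[int, ...] = (100, 1000)
    n_poses: int = 200
    accessibility_A: float = 1e9
    accessibility_n: float = 6.0
    accessibility_cutoff: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("ef_fractions", "top_counts", "top_n_depths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Violations as data; the empty list means the config is runnable."""
    problems: list[str] = []
    if not 0.0 <= cfg.vhl_threshold <= 1.0:
        problems.append(f"vhl_threshold {cfg.vhl_threshold} outside [0, 1]")
    if cfg.fn_threshold < 0:
        problems.append(f"fn_threshold {cfg.fn_threshold} must be >= 0")
    if cfg.min_copies < 0:
        problems.append(f"min_copies {cfg.min_copies} must be >= 0")
    if cfg.hit_mode not in ("fn", "readcount"):
        problems.append(f"hit_mode {cfg.hit_mode!r} must be 'fn' or 'readcount'")
    for f in cfg.ef_fractions:
        if not 0.0 < f <= 1.0:
            problems.append(f"ef fraction {f} outside (0, 1]")
    if not cfg.simulate:
        for name in ("blocks_csv", "counts_csv"):
            path = getattr(cfg, name)
            if path is None:
                problems.append(f"{name} required when simulate is off")
            elif not Path(path).exists():
                problems.append(f"{name}: no such file {path}")
        for name in ("dock_csv", "protein_pdb", "poses_sdf"):
            path = getattr(cfg, name)
            if path is not None and not Path(path).exists():
                problems.append(f"{name}: no such file {path}")
    if cfg.n_poses < 1:
        problems.append("n_poses must be >= 1")
    try:
        synthetic.SynthConfig(**cfg.synth, seed=cfg.seed)
    except (TypeError, ValueError) as exc:
        problems.append(f"synth: {exc}")
    return problems


def _simulate_inputs(cfg: RunConfig, out: Path) -> dict[str, Any]:
    scfg = synthetic.SynthConfig(**cfg.synth, seed=cfg.seed)
    defn, records = synthetic.synth_library(scfg)
    counts, truth = synthetic.synth_screen(scfg, records)
    dock = synthetic.synth_dock(scfg, records, truth.affinity)
    protein, poses, buried = synthetic.synth_pocket(scfg, cfg.n_poses)

    library.write_blocks_csv(defn, out / "blocks.csv")
    library.write_compounds_csv(records, out / "compounds.csv")
    with open(out / "counts.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "count_before", "count_after", "total_before", "total_after"])
        for r in counts:
            w.writerow([r.compound_id, r.count_before, r.count_after, r.total_before, r.total_after])
    metrics.write_dock_csv(dock, out / "dock.csv")
    acc.write_pdb_atoms(protein, out / "rec.pdb")
    acc.write_poses_sdf(poses, out / "poses.sdf")
    acc.write_exit_vectors_csv(
        {p.pose_id: p.exit_vectors for p in poses}, out / "evs.csv"
    )
    with open(out / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "affinity"])
        for rec, a in zip(records, truth.affinity):
            w.writerow([rec.compound_id, repr(float(a))])
    logger.info("simulate: %d compounds, %d poses", len(records), len(poses))
    return {
        "defn": defn,
        "records": records,
        "counts": counts,
        "truth": truth,
        "dock": dock,
        "protein": protein,
        "poses": poses,
        "buried": buried,
    }


def _load_inputs(cfg: RunConfig) -> dict[str, Any]:
    defn = library.read_blocks_csv(cfg.blocks_csv)
    records = list(library.enumerate_library(defn, with_smiles=False))
    counts = screen.read_counts_csv(cfg.counts_csv)
    data: dict[str, Any] = {"defn": defn, "records": records, "counts": counts}
    if cfg.dock_csv:
        data["dock"] = metrics.read_dock_csv(cfg.dock_csv)
    if cfg.protein_pdb and cfg.poses_sdf:
        data["protein"] = acc.read_pdb_atoms(cfg.protein_pdb)
        evs = acc.read_exit_vectors_csv(cfg.evs_csv) if cfg.evs_csv else None
        data["poses"] = acc.read_poses_sdf(cfg.poses_sdf, evs)
    logger.info("load: %d compounds, %d count rows", len(records), len(counts))
    return data


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; return the report."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = _simulate_inputs(cfg, out) if cfg.simulate else _load_inputs(cfg)
    defn: library.LibraryDefinition = data["defn"]
    records = data["records"]

    report: dict[str, Any] = {
        "library": {
            "positions": defn.positions,
            "size": library.library_size(defn),
            "enumerated": len(records),
        }
    }

    screen_records = None
    if cfg.run_classify:
        if cfg.hit_mode == "fn":
            screen_records = screen.classify_hits_fn(data["counts"], cfg.fn_threshold)
        else:
            screen_records = screen.classify_hits_readcount(data["counts"], cfg.min_copies)
        n_hits = sum(r.is_hit for r in screen_records)
        screen.write_screen_csv(screen_records, out / "screen.csv")
        report["screen"] = {
            "mode": cfg.hit_mode,
            "threshold": cfg.fn_threshold if cfg.hit_mode == "fn" else cfg.min_copies,
            "n_records": len(screen_records),
            "n_hits": int(n_hits),
        }
        logger.info("classify: %d records -> %d hits", len(screen_records), n_hits)

    hit_by_id = (
        {r.compound_id: r.is_hit for r in screen_records} if screen_records else {}
    )

    if cfg.run_evaluate:
        if "dock" not in data:
            raise RuntimeError("stage 'evaluate' needs docking records (dock_csv)")
        if screen_records is None:
            raise RuntimeError("stage 'evaluate' needs stage 'classify'")
        dock = data["dock"]
        ranked = metrics.rank_records(dock, key="score")
        labels = [hit_by_id.get(r.compound_id, False) for r in ranked]
        roc_res = metrics.roc(ranked, labels, key="score", restrict_to_keyed=True)
        ef_table = {}
        for frac in cfg.ef_fractions:
            res = metrics.enrichment_factor(ranked, labels, top_fraction=frac)
            ef_table[f"{100 * frac:g}%"] = {
                "selected": res.selected,
                "hits_in_top": res.hits_in_top,
                "ef": res.ef,
            }
        for top in cfg.top_counts:
            res = metrics.enrichment_factor(ranked, labels, top_count=top)
            ef_table[f"top{top}"] = {
                "selected": res.selected,
                "hits_in_top": res.hits_in_top,
                "ef": res.ef,
            }
        eval_section: dict[str, Any] = {
            "n_docked": sum(r.docked for r in dock),
            "n_records": len(dock),
            "auc" if roc_res.complete else "pauc": roc_res.area,
            "roc_complete": roc_res.complete,
            "ef": ef_table,
            "score_summary": metrics.score_distribution_summary(
                [r.score for r in dock if r.score is not None]
            ),
        }
        if any(r.vhl is not None for r in dock):
            predicted = metrics.vhl_filter(
                [r for r in dock if r.vhl is not None], cfg.vhl_threshold
            )
            experimental = {cid for cid, hit in hit_by_id.items() if hit}
            prf = metrics.recall_precision_f1(
                [r.compound_id for r in predicted], experimental
            )
            eval_section["vhl"] = {
                "threshold": cfg.vhl_threshold,
                "n_predicted": len(predicted),
                "recall": prf.recall,
                "precision": prf.precision,
                "f1": prf.f1,
            }
        report["evaluate"] = eval_section
        logger.info(
            "evaluate: area=%.4f complete=%s", roc_res.area, roc_res.complete
        )

    if cfg.run_bbstats:
        if screen_records is None:
            raise RuntimeError("stage 'bbstats' needs stage 'classify'")
        bb = bbstats.bb_matrix_from_records(records)
        exp_hits = np.asarray(
            [hit_by_id.get(r.compound_id, False) for r in records], dtype=bool
        )
        stats_exp = bbstats.compute_bb_stats(bb, exp_hits, defn.positions)
        stats_exp.to_csv(out / "bbstats_experimental.csv", index=False)
        section: dict[str, Any] = {
            "experimental": _bb_summary(stats_exp),
        }
        if "dock" in data:
            ranked = metrics.rank_records(data["dock"], key="score")
            ranked_ids = [r.compound_id for r in ranked if r.docked]
            universe = [r.compound_id for r in records]
            for depth in cfg.top_n_depths:
                if depth > len(ranked_ids):
                    continue
                comp_hits = bbstats.top_n_hitset(ranked_ids, depth, universe)
                stats_comp = bbstats.compute_bb_stats(bb, comp_hits, defn.positions)
                stats_comp.to_csv(out / f"bbstats_top{depth}.csv", index=False)
                _, corr = bbstats.bb_agreement(stats_exp, stats_comp)
                section[f"top{depth}"] = {
                    "summary": _bb_summary(stats_comp),
                    "rank_correlation_vs_experimental": corr,
                }
        report["bbstats"] = section
        logger.info("bbstats: %d blocks", len(stats_exp))

    if cfg.run_accessibility:
        if "poses" not in data or "protein" not in data:
            raise RuntimeError(
                "stage 'accessibility' needs a protein structure and poses"
            )
        results = [
            acc.best_exit_vector(
                pose,
                data["protein"],
                A=cfg.accessibility_A,
                n=cfg.accessibility_n,
                cutoff=cfg.accessibility_cutoff,
            )
            for pose in data["poses"]
        ]
        with open(out / "accessibility.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pose_id", "b_score", "feasible", "chosen_ev"])
            for r in results:
                w.writerow([r.pose_id, repr(r.b_score), int(r.feasible), r.exit_vector_index])
        report["accessibility"] = {
            "n_poses": len(results),
            "feasible_ratio_pct": acc.feasible_ratio(results),
        }
        logger.info(
            "accessibility: %d poses, %.1f%% feasible",
            len(results),
            report["accessibility"]["feasible_ratio_pct"],
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    (out / "report.md").write_text(render_markdown(report))
    return report


def _bb_summary(stats) -> dict[str, Any]:
    top = stats.loc[stats.groupby("position")["p_bind_norm"].idxmax()]
    return {
        "n_blocks": int(len(stats)),
        "top_block_per_position": [
            {
                "position": int(r.position),
                "bb_index": int(r.bb_index),
                "p_bind": None if np.isnan(r.p_bind) else float(r.p_bind),
                "cp": int(r.cp),
                "cp_max": int(r.cp_max),
            }
            for r in top.itertuples()
        ],
    }


def render_markdown(report: dict[str, Any]) -> str:
    """Human-readable companion to report.json."""
    lines = ["# delbench report", ""]
    lib = report["library"]
    lines += [
        "## Library",
        f"- positions: {lib['positions']}",
        f"- size: {lib['size']:,} (enumerated {lib['enumerated']:,})",
        "",
    ]
    if "screen" in report:
        s = report["screen"]
        lines += [
            "## Hit calling",
            f"- mode: {s['mode']} (threshold {s['threshold']})",
            f"- hits: {s['n_hits']:,} / {s['n_records']:,}",
            "",
        ]
    if "evaluate" in report:
        e = report["evaluate"]
        area_key = "auc" if "auc" in e else "pauc"
        lines += [
            "## Virtual-screening evaluation",
            f"- docked: {e['n_docked']:,} / {e['n_records']:,}",
            f"- {area_key.upper()}: {e[area_key]:.4f}"
            + ("" if e["roc_complete"] else " (truncated curve)"),
            "- enrichment factors:",
        ]
        for name, row in e["ef"].items():
            lines.append(
                f"    - {name}: EF={row['ef']:.3f} "
                f"({row['hits_in_top']} hits in top {row['selected']:,})"
            )
        if "vhl" in e:
            v = e["vhl"]
            lines.append(
                f"- VHL >= {v['threshold']}: {v['n_predicted']:,} predicted; "
                f"recall={v['recall']:.3f} precision={v['precision']:.3f} "
                f"F1={v['f1']:.3f}"
            )
        lines.append("")
    if "bbstats" in report:
        lines += ["## Building-block statistics"]
        for name, sec in report["bbstats"].items():
            summary = sec if name == "experimental" else sec["summary"]
            tops = ", ".join(
                f"p{t['position']}:b{t['bb_index']}"
                for t in summary["top_block_per_position"]
            )
            lines.append(f"- {name}: {summary['n_blocks']} blocks; top blocks {tops}")
            if name != "experimental":
                corr = sec["rank_correlation_vs_experimental"]
                lines.append(
                    "    - rank correlation vs experimental: "
                    + ", ".join(f"pos {p}: {c:.3f}" for p, c in corr.items())
                )
        lines.append("")
    if "accessibility" in report:
        a = report["accessibility"]
        lines += [
            "## Exit-vector accessibility",
            f"- poses: {a['n_poses']:,}",
            f"- feasible (B = 0): {a['feasible_ratio_pct']:.1f}%",
            "",
        ]
    return "\n".join(lines)
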