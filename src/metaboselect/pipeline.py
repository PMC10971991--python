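"""End-to-end orchestration: cohort -> stage 1 -> stage 2 -> reports -> map.

A pipeline run mirrors the two-step "hidden layer" of the classifier:
stage 1 picks a small metabolite panel by best-subset LOO-LDA accuracy,
stage 2 expands the panel into monomials (degree <= 3) and searches for
the minimal variable set with maximal LOO accuracy.  Every run writes its
artifacts (cohort CSV, per-stage traces, final report, posterior table,
discriminant map, fitted model) plus a manifest sufficient to reproduce
the run byte-for-byte: floats are serialized at 12 significant digits and
no timestamps enter any output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .cohort import CsvDialect, SampleTable, SyntheticConfig, generate_cohort, load_table, write_table
from .dmap import region_grid
from .evaluation import age_filter, posterior_table
from .lda import fit_lda, loo_evaluate
from .search import stage1_search
from .terms import build_design, expand_terms, stage2_search

log = logging.getLogger("metaboselect")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run."""

    input: Union[str, SyntheticConfig, None] = None  # CSV path, or synthetic recipe
    seed: int = 0
    priors_mode: str = "proportional"
    stage1_max_k: int = 4
    stage1_strategy: str = "forward"
    stage1_budget: int = 100_000
    stage1_patience: int = 2
    stage2_max_degree: int = 3
    stage2_max_vars: int = 8
    stage2_strategy: str = "forward"
    stage2_budget: int = 100_000
    stage2_patience: int = 2
    beam_width: int = 20
    age_min: Optional[float] = None
    age_restrict_class: Optional[str] = None
    map_resolution: int = 400
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            for key in ("n_per_group", "class_names"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            if "marker_spec" in synth:
                synth["marker_spec"] = tuple((int(i), tuple(s)) for i, s in synth["marker_spec"])
            if "correlation_blocks" in synth:
                synth["correlation_blocks"] = tuple((tuple(ix), r) for ix, r in synth["correlation_blocks"])
            if "nonlinear_spec" in synth and synth["nonlinear_spec"] is not None:
                pair, shifts = synth["nonlinear_spec"]
                synth["nonlinear_spec"] = (tuple(pair), tuple(shifts))
            if "age_spec" in synth and synth["age_spec"] is not None:
                synth["age_spec"] = tuple(tuple(a) for a in synth["age_spec"])
            cfg.input = SyntheticConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.input, SyntheticConfig):
            d["input"] = {"synthetic": dataclasses.asdict(self.input)}
        return d


def _round12(obj):
    """Recursively format floats at 12 significant digits for stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_round12(payload), indent=1, allow_nan=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure leaves partial outputs in place alongside a FAILED
    marker naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "tool": "metaboselect",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "ridge_events": [],
    }
    stage = "setup"
    try:
        stage = "cohort"
        if isinstance(config.input, SyntheticConfig):
            synth = dataclasses.replace(config.input, seed=config.seed)
            table = generate_cohort(synth)
            manifest["cohort_source"] = "synthetic"
        elif config.input is not None:
            table = load_table(config.input, CsvDialect())
            manifest["cohort_source"] = str(config.input)
        else:
            raise ValueError("config.input must be a CSV path or a synthetic recipe")
        write_table(table, outdir / "cohort.csv")
        manifest["class_sizes"] = table.class_sizes()

        if config.age_min is not None:
            stage = "age_filter"
            pre = table.class_sizes()
            table = age_filter(table, min_age=config.age_min, restrict_class=config.age_restrict_class)
            manifest["age_filter"] = {
                "min_age": config.age_min,
                "restrict_class": config.age_restrict_class,
                "class_sizes_before": pre,
                "class_sizes_after": table.class_sizes(),
            }
            write_table(table, outdir / "cohort_filtered.csv")

        stage = "stage1"
        s1 = stage1_search(
            table,
            max_k=config.stage1_max_k,
            strategy=config.stage1_strategy,
            budget=config.stage1_budget,
            patience=config.stage1_patience,
            beam_width=config.beam_width,
            priors_mode=config.priors_mode,
        )
        (outdir / "stage1_trace.tsv").write_text(s1.trace_tsv())
        panel = list(s1.selected_feature_names())
        # stage 2 expands terms over the largest panel the search explored:
        # monomials can extract signal from metabolites that added nothing
        # linearly, so the term universe keeps the full explored panel, not
        # just the plateau-minimal one
        panel_full = [s1.feature_names[i] for i in s1.per_size[-1].features]
        manifest["stage1"] = {
            "selected_size": s1.selected_size,
            "panel": panel,
            "panel_explored": panel_full,
            "accuracy": s1.selected().accuracy,
            "evaluations": s1.evaluations,
            "strategy": s1.strategy,
        }
        log.info("stage 1 panel (k=%d, acc=%.3f): %s", s1.selected_size, s1.selected().accuracy, panel)

        stage = "stage2"
        terms = expand_terms(panel_full, max_degree=config.stage2_max_degree)
        s2 = stage2_search(
            table,
            terms,
            max_vars=min(config.stage2_max_vars, len(terms)),
            strategy=config.stage2_strategy,
            budget=config.stage2_budget,
            patience=config.stage2_patience,
            beam_width=config.beam_width,
            priors_mode=config.priors_mode,
        )
        (outdir / "stage2_trace.tsv").write_text(s2.trace_tsv())
        winning = list(s2.selected_feature_names())
        winning_terms = [terms[i] for i in s2.selected().features]
        manifest["stage2"] = {
            "n_terms_universe": len(terms),
            "selected_size": s2.selected_size,
            "variables": winning,
            "accuracy": s2.selected().accuracy,
            "evaluations": s2.evaluations,
            "strategy": s2.strategy,
        }
        log.info("stage 2 variables (k=%d, acc=%.3f): %s", s2.selected_size, s2.selected().accuracy, winning)

        stage = "evaluate"
        design = build_design(table, winning_terms)
        report, records = loo_evaluate(
            design.to_numpy(), priors_mode=config.priors_mode, y=table.groups, class_order=table.class_names
        )
        # subject ids in the design follow the table's order
        for rec, sid in zip(records, table.subject_ids):
            rec.subject_id = str(sid)
        _write_json(outdir / "report.json", report.to_dict())
        (outdir / "report.tsv").write_text(report.to_tsv())
        truth = dict(zip(map(str, table.subject_ids), map(str, table.groups)))
        post_df, post_summary = posterior_table(records, truth, table.class_names)
        post_df.to_csv(outdir / "posteriors.tsv", sep="\t", index=False, float_format="%.12g")
        manifest["final"] = {
            "overall_accuracy": report.overall_accuracy,
            "posterior_summary": post_summary,
        }

        stage = "map"
        model = fit_lda(
            design.to_numpy(),
            priors_mode=config.priors_mode,
            y=table.groups,
            class_order=table.class_names,
            feature_names=tuple(design.columns),
        )
        if model.ridge_used:
            manifest["ridge_events"].append({"stage": "final_fit", "ridge": model.ridge_used})
        model.save(outdir / "model.json")
        if len(table.class_names) >= 3:
            mres = region_grid(model, resolution=config.map_resolution, data=design.to_numpy(), groups=table.groups)
            (outdir / "map.tsv").write_text(mres.to_tsv())
            coords = mres.coordinates
            with open(outdir / "coordinates.tsv", "w") as fh:
                fh.write("subject_id\tgroup\tLD1\tLD2\n")
                for sid, g, (a, b) in zip(table.subject_ids, table.groups, coords):
                    fh.write(f"{sid}\t{g}\t{a:.12g}\t{b:.12g}\n")

        stage = "manifest"
        _write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return outdir
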