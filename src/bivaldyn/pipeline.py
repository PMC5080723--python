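"""End-to-end orchestration with a config file and a reproducible run
manifest.

Stages run in the order simulate (optional) -> normalize -> mark ->
classify -> bivalency -> expression.  Every file output is a pure
function of the config snapshot recorded in the manifest; re-running an
identical config reproduces identical bytes for every deterministic
stage.  Logs go to stderr only.

Config schema (YAML or a plain mapping)::

    seed: 1
    outdir: runs/demo
    stages: [simulate, normalize, mark, classify, bivalency, expression]
    simulate: {n_genes: 500, ...}        # SimulationConfig overrides
    inputs:                              # alternative to simulate
      genes: path/to/genes.tsv
      expression: path/to/expression.tsv
      null_genes: path/to/null_ids.txt   # optional
      peaks:
        H3K4me3: {t0: path.bed, t8: ..., t24: ..., reox8: ...}
        H3K27me3: {t0: ..., ...}
    params: {window_size_bp: 20000, ...} # PipelineParams overrides
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .bivalency_dynamics import mark_states, retention, transitions
from .expression_integration import (
    detection_floor,
    differential_calls,
    expressed_flags,
    median_by_group,
)
from .gene_marking import call_gene_marks, marked_ids, partition_fractions, tss_profile
from .io_genomics import (
    MARKS,
    TIMEPOINTS,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    PipelineParams,
    read_expression,
    read_gene_list,
    read_gene_models,
    read_peaks,
    write_peaks,
)
from .normalization import normalize_k27
from .profile_classifier import classify_genes
from .synthetic_data import SimulationConfig, simulate_all, write_fixtures

STAGES = ("simulate", "normalize", "mark", "classify", "bivalency", "expression")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, Mapping):
        raise PipelineError("config: top level must be a mapping")
    return dict(cfg)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_all(
    config: Mapping | str | Path,
    outdir: str | Path | None = None,
    stages: Sequence[str] | None = None,
) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "bivaldyn_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = tuple(stages or cfg.get("stages") or STAGES)
    for st in stages:
        if st not in STAGES:
            raise PipelineError(f"config: unknown stage {st!r}")
    params = PipelineParams(**cfg.get("params", {}))

    manifest: dict = {
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "stages": list(stages),
        "params": dataclasses.asdict(params),
        "version": __version__,
        "outputs": {},
        "input_checksums": {},
    }

    genes: list[GeneModel]
    peaksets: dict[tuple[str, str], PeakSet]
    expr: ExpressionMatrix | None = None
    null_ids: set[str] = set()

    t_start = time.monotonic()
    if cfg.get("simulate") is not None:
        sim_cfg = SimulationConfig(seed=seed, **cfg["simulate"])
        _log(f"[simulate] n_genes={sim_cfg.n_genes} seed={seed}")
        genes, peaksets, gt, expr = simulate_all(sim_cfg)
        null_ids = gt.null_gene_ids
        if "simulate" in stages:
            paths = write_fixtures(outdir / "fixtures", genes, peaksets, gt, expr)
            manifest["outputs"]["simulate"] = paths
    else:
        inputs = cfg.get("inputs")
        if not inputs:
            raise PipelineError("config: need either 'simulate' or 'inputs'")
        try:
            genes = read_gene_models(inputs["genes"])
            peaksets = {}
            for mark, tp_map in inputs["peaks"].items():
                for tp, path in tp_map.items():
                    peaksets[(mark, tp)] = read_peaks(path, mark, tp)
                    manifest["input_checksums"][f"{mark}:{tp}"] = _sha256(Path(path))
            expr = read_expression(inputs["expression"]) if "expression" in inputs else None
            if "null_genes" in inputs:
                null_ids = read_gene_list(inputs["null_genes"])
            manifest["input_checksums"]["genes"] = _sha256(Path(inputs["genes"]))
            if expr is not None:
                manifest["input_checksums"]["expression"] = _sha256(
                    Path(inputs["expression"])
                )
        except (KeyError, FileNotFoundError) as exc:
            raise PipelineError(f"stage inputs: missing input ({exc})") from exc

    timepoints = [tp for tp in TIMEPOINTS if ("H3K27me3", tp) in peaksets]
    k27_raw = [peaksets[("H3K27me3", tp)] for tp in timepoints]
    k27_scaled: dict[str, PeakSet] = {}
    cutoff = 0.0

    if "normalize" in stages:
        if expr is None:
            raise PipelineError("stage normalize: expression input required")
        _log("[normalize] invariant regions + scale factors + cutoff")
        try:
            result, scaled = normalize_k27(k27_raw, genes, expr, params)
        except Exception as exc:
            raise PipelineError(f"stage normalize: {exc}") from exc
        k27_scaled = {ps.timepoint: ps for ps in scaled}
        cutoff = result.background_cutoff
        ndir = outdir / "normalize"
        ndir.mkdir(exist_ok=True)
        with open(ndir / "invariant_regions.bed", "w") as fh:
            for r in result.invariant_regions.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
        for tp, ps in k27_scaled.items():
            write_peaks(ps, ndir / f"scaled_H3K27me3_{tp}.bed")
        _write_json(
            {
                "scale_factors": result.scale_factors,
                "background_cutoff": result.background_cutoff,
                "achieved_clean_fraction": result.achieved_clean_fraction,
                "n_invariant_regions": len(result.invariant_regions.regions),
                "n_highly_expressed": len(result.highly_expressed_ids),
            },
            ndir / "normalization.json",
        )
        manifest["outputs"]["normalize"] = str(ndir)
    else:
        k27_scaled = {ps.timepoint: ps for ps in k27_raw}

    calls: dict[tuple[str, str], pd.DataFrame] = {}
    if "mark" in stages or "classify" in stages or "bivalency" in stages:
        _log("[mark] per-gene mark calls and TSS profiles")
        for tp in timepoints:
            k4 = peaksets.get(("H3K4me3", tp))
            if k4 is not None:
                calls[("H3K4me3", tp)] = call_gene_marks(genes, k4, 0.0, params.flank_bp)
            calls[("H3K27me3", tp)] = call_gene_marks(
                genes, k27_scaled[tp], cutoff, params.flank_bp
            )
    if "mark" in stages:
        mdir = outdir / "mark"
        mdir.mkdir(exist_ok=True)
        pd.concat(calls.values()).to_csv(mdir / "mark_calls.tsv", sep="\t")
        rows = []
        for tp in timepoints:
            for mark in MARKS:
                ps = k27_scaled[tp] if mark == "H3K27me3" else peaksets.get((mark, tp))
                if ps is None:
                    continue
                prof = tss_profile(
                    ps,
                    genes,
                    params.tss_half_window_bp,
                    params.tss_bin_bp,
                    cutoff if mark == "H3K27me3" else 0.0,
                )
                part = partition_fractions(ps, genes, params.flank_bp)
                for off, inten in zip(prof.offsets, prof.mean_intensity):
                    rows.append(
                        {
                            "mark": mark,
                            "timepoint": tp,
                            "offset": int(off),
                            "mean_intensity": float(inten),
                            "n_genes": prof.n_genes,
                            "genic_fraction": part["genic_fraction"],
                        }
                    )
        pd.DataFrame(rows).to_csv(mdir / "tss_profiles.tsv", sep="\t", index=False)
        manifest["outputs"]["mark"] = str(mdir)

    if "classify" in stages:
        _log("[classify] H3K27me3 profile classes")
        frames = []
        for tp in timepoints:
            mids = marked_ids(calls[("H3K27me3", tp)])
            frames.append(
                classify_genes(genes, k27_scaled[tp], cutoff, params, mids)
            )
        cdir = outdir / "classify"
        cdir.mkdir(exist_ok=True)
        pd.concat(frames).to_csv(cdir / "profile_classes.tsv", sep="\t")
        manifest["outputs"]["classify"] = str(cdir)

    states_df: pd.DataFrame | None = None
    if "bivalency" in stages or "expression" in stages:
        if all(("H3K4me3", tp) in calls for tp in timepoints):
            states_df = pd.DataFrame(
                {
                    tp: mark_states(calls[("H3K4me3", tp)], calls[("H3K27me3", tp)])
                    for tp in timepoints
                }
            )
    if "bivalency" in stages:
        if states_df is None:
            raise PipelineError("stage bivalency: H3K4me3 peak inputs required")
        _log("[bivalency] states, transitions, retention")
        bdir = outdir / "bivalency"
        bdir.mkdir(exist_ok=True)
        states_df.to_csv(bdir / "mark_states.tsv", sep="\t", index_label="gene_id")
        for a, b in zip(timepoints, timepoints[1:]):
            tab = transitions(states_df[a], states_df[b], a, b)
            tab.counts.to_csv(bdir / f"transitions_{a}_{b}.tsv", sep="\t")
        if len(timepoints) >= 3:
            _, counts = retention(states_df)
            _write_json(counts, bdir / "retention.json")
        manifest["outputs"]["bivalency"] = str(bdir)

    if "expression" in stages:
        if expr is None:
            raise PipelineError("stage expression: expression input required")
        _log("[expression] flags, group medians, differential calls")
        edir = outdir / "expression"
        edir.mkdir(exist_ok=True)
        floor = detection_floor(expr, null_ids) if null_ids else None
        flags = expressed_flags(expr, params, floor)
        flags.to_csv(edir / "expression_flags.tsv", sep="\t", index_label="gene_id")
        diff = differential_calls(expr, params)
        diff.to_csv(edir / "differential_calls.tsv", sep="\t", index_label="gene_id")
        report: dict = {"detection_floor": floor}
        if states_df is not None:
            tp0 = timepoints[0]
            groups = {
                state: set(states_df.index[states_df[tp0] == state])
                for state in ("none", "K4only", "K27only", "bivalent")
            }
            medians, tests = median_by_group(expr, groups, tp0)
            report["group_medians"] = medians
            report["group_tests"] = tests.to_dict(orient="records")
        _write_json(report, edir / "expression_report.json")
        manifest["outputs"]["expression"] = str(edir)

    _log(f"[done] {time.monotonic() - t_start:.1f}s")
    _write_json(
        {k: v for k, v in manifest.items() if k != "config"}
        | {"config": json.loads(json.dumps(manifest["config"], default=str))},
        outdir / "manifest.json",
    )
    return manifest
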