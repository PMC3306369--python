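"""End-to-end orchestration: search → consensus → calibrate → diversity,
disparity, trait models and body metrics, with machine-readable outputs.

The pipeline is a pure function of (inputs, config, seed): rerunning
with the same files and seed reproduces the report byte-for-byte.  Each
stage appends one JSON line to ``pipeline.log`` in the output directory
so runs are auditable; a stage whose inputs are absent is skipped with a
logged warning and the remaining stages still run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import body_metrics as bm
from . import chronogram, disparity, diversity, parsimony, trait_models
from . import io_formats as iof

__all__ = ["RunConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """File paths and options for a full pipeline run."""

    matrix_path: str | None = None
    ages_path: str | None = None
    bins_path: str | None = None
    tree_path: str | None = None          # fixed tree: skip the search
    extra_taxa_path: str | None = None    # range-through additions
    disparity_taxa_path: str | None = None  # whitelist, one label per line
    out_dir: str = "paleomacro_out"
    seed: int = 0
    n_replicates: int = 10
    outgroup: str | None = None
    calibration_method: str = "mbl"
    min_duration: float = 1.0
    root_extension: float = 1.0
    measurement_sd: float = 55.0
    n_resamples: int = 1000
    max_trees_held: int | None = None


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.events: list[dict] = []

    def emit(self, stage: str, status: str, **info) -> None:
        self.events.append({"stage": stage, "status": status, **info})

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")


def _read(path: str | None) -> str | None:
    if path is None:
        return None
    return Path(path).read_text()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the supplied inputs allow; return the report dict.

    Outputs written to ``config.out_dir``: report.json, trees.nex,
    timetree.nwk, curve.csv, disparity.csv, fits.json, metrics.csv and
    pipeline.log.  A stage failure raises, naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "pipeline.log")
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed,
                    "config": dataclasses.asdict(config)}

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                try:
                    result = fn(*a, **kw)
                except Exception as exc:
                    log.emit(name, "failed", error=str(exc))
                    log.flush()
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.emit(name, "ok")
                return result
            return run
        return deco

    matrix = records = bins = None
    if config.matrix_path:
        matrix = stage("read_matrix")(iof.read_character_matrix)(
            _read(config.matrix_path))
    if config.ages_path:
        records = stage("read_ages")(iof.read_taxon_table)(
            _read(config.ages_path))
    if config.bins_path:
        bins = stage("read_bins")(iof.read_time_bins)(_read(config.bins_path))

    # --- trees -----------------------------------------------------------
    trees = None
    if config.tree_path:
        trees = [stage("read_tree")(iof.read_tree)(_read(config.tree_path))]
    elif matrix is not None:
        sc = parsimony.SearchConfig(
            n_replicates=config.n_replicates, seed=config.seed,
            outgroup=config.outgroup, max_trees_held=config.max_trees_held)
        trees = stage("search")(parsimony.heuristic_search)(matrix, sc)
        stats = parsimony.ensemble_indices(trees[0], matrix)
        report["tree_stats"] = {
            "n_trees": len(trees), "length": stats.length,
            "ci": stats.ci, "ri": stats.ri, "rc": stats.rc,
        }
        (out / "trees.nex").write_text(parsimony.trees_to_nexus(trees))
    else:
        log.emit("search", "skipped", reason="no matrix or tree supplied")

    consensus = None
    if trees:
        consensus = (trees[0] if len(trees) == 1
                     else stage("consensus")(parsimony.strict_consensus)(trees))

    # --- calibration -----------------------------------------------------
    timetree = None
    if consensus is not None and records is not None:
        timetree = stage("calibrate")(chronogram.calibrate)(
            consensus, records, method=config.calibration_method,
            min_duration=config.min_duration,
            root_extension=config.root_extension)
        (out / "timetree.nwk").write_text(iof.write_tree(timetree.tree))
        report["root_age"] = timetree.root_age
    else:
        log.emit("calibrate", "skipped", reason="needs a tree and ages")

    # --- diversity -------------------------------------------------------
    if timetree is not None and bins is not None:
        extra = []
        if config.extra_taxa_path:
            extra = iof.read_taxon_table(_read(config.extra_taxa_path))
        curve = stage("diversity")(diversity.phylogenetic_diversity)(
            timetree, bins, extra_taxa=extra)
        report["diversity"] = [
            {"bin": c.bin_label, "observed": c.observed,
             "ghost": c.ghost_only, "total": c.total}
            for c in curve.counts
        ]
        with open(out / "curve.csv", "w") as fh:
            fh.write("bin,observed,ghost,total\n")
            for c in curve.counts:
                fh.write(f"{c.bin_label},{c.observed},{c.ghost_only},"
                         f"{c.total}\n")
    else:
        log.emit("diversity", "skipped", reason="needs a timetree and bins")

    # --- disparity -------------------------------------------------------
    if matrix is not None and bins is not None and records is not None:
        whitelist = None
        if config.disparity_taxa_path:
            whitelist = [ln.strip() for ln in
                         _read(config.disparity_taxa_path).splitlines()
                         if ln.strip()]
        dissim = stage("dissimilarity")(disparity.pairwise_dissimilarity)(
            matrix, whitelist)
        dissim = disparity.drop_undefined_taxa(dissim)
        ordination = stage("pcoa")(disparity.pcoa)(dissim)
        assignments = {r.name: r.bin_label for r in records
                       if r.bin_label is not None}
        table = stage("disparity")(disparity.disparity_by_bin)(
            dissim, ordination, assignments, bins,
            n_resamples=config.n_resamples, seed=config.seed)
        report["disparity"] = [
            {"bin": row.bin_label, "n_taxa": row.n_taxa,
             "mpd": row.mpd, "mpd_ci": row.mpd_ci,
             "sov": row.sov, "sov_ci": row.sov_ci}
            for row in table
        ]
        report["pcoa"] = {
            "n_axes": ordination.n_axes,
            "cailliez_constant": ordination.cailliez_constant,
            "percent_first_three": (
                disparity.axis_percentages(ordination,
                                           min(3, ordination.n_axes))),
        }
        with open(out / "disparity.csv", "w") as fh:
            fh.write("bin,n_taxa,mpd,mpd_lo,mpd_hi,sov,sov_lo,sov_hi\n")
            for row in table:
                mpd_ci = row.mpd_ci or (None, None)
                sov_ci = row.sov_ci or (None, None)
                fh.write(",".join(str(x) for x in (
                    row.bin_label, row.n_taxa, row.mpd, *mpd_ci,
                    row.sov, *sov_ci)) + "\n")
    else:
        log.emit("disparity", "skipped",
                 reason="needs a matrix, bins and ages")

    # --- trait models ----------------------------------------------------
    if timetree is not None and records is not None:
        tree_tips = set(timetree.tip_labels())
        values = {r.name: r.trunk_length for r in records
                  if r.trunk_length is not None and r.name in tree_tips}
        if len(values) >= 4:
            data = trait_models.TraitData(values, config.measurement_sd)
            fits_report = {}
            for transform in ("none", "ln"):
                fits = stage(f"traits_{transform}")(trait_models.fit_all)(
                    timetree, data, transform=transform)
                fits_report[transform] = [
                    {"model": f.model, "k": f.k, "lnL": f.lnl,
                     "aicc": f.aicc, "weight": f.akaike_weight,
                     "estimates": f.estimates}
                    for f in fits
                ]
            report["trait_models"] = fits_report
            (out / "fits.json").write_text(
                json.dumps(fits_report, indent=2, sort_keys=True))
        else:
            log.emit("traits", "skipped", reason="fewer than 4 trunk lengths")
    else:
        log.emit("traits", "skipped", reason="needs a timetree and ages")

    # --- body metrics ----------------------------------------------------
    if records is not None:
        props = stage("bodymetrics")(bm.proportion_table)(records)
        trunk_ranges = bm.range_by_bin(
            [(r.bin_label, r.trunk_length) for r in records
             if r.trunk_length is not None])
        report["body_metrics"] = {
            "ratios": {p.taxon: p.ratio for p in props},
            "trunk_range_by_bin": {k: list(v)
                                   for k, v in trunk_ranges.items()},
        }
        with open(out / "metrics.csv", "w") as fh:
            fh.write("taxon,trunk_length,neck_length,ratio,bin\n")
            for p in props:
                fh.write(f"{p.taxon},{p.trunk_length},{p.neck_length},"
                         f"{p.ratio},{p.bin_label}\n")
    else:
        log.emit("bodymetrics", "skipped", reason="needs ages table")

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    log.flush()
    return report
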