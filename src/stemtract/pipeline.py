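"""End-to-end pipeline: simulate (or load), dissect, quantify, report.

One invocation produces a self-contained run directory: the resolved
configuration, per-stage removal/extraction tallies, termination tables,
group statistics and a machine-readable JSON summary. Deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dissection, phantom, stem_metrics, termination_stats
from .dissection import ExtractionRules, PrepParams, StemROI
from .tract_io import modal_dilate

log = logging.getLogger("stemtract")

DEFAULT_FP_REGIONS = {"IFOF": "precentral", "UF": "superior_parietal"}


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "stemtract_run"
    n_subjects: int = 10
    seed: int = 0
    alpha: float = 0.05
    fp_regions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FP_REGIONS))
    broken_fraction: float = 0.2
    min_length_mm: float = 10.0
    operators: tuple = ("GP", "JH")
    make_figures: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _tract_label_names(atlas, region: str):
    names = atlas.table.frame.name.astype(str)
    return set(atlas.table.frame.index[names.str.startswith(region)])


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full phantom-cohort pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        result = _run(config, out)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return result


def _run(config: PipelineConfig, out: Path) -> Path:
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str))
    spec = phantom.PhantomSpec()
    atlas = phantom.build_phantom_atlas(spec)
    dilated = modal_dilate(atlas, 1)
    cohort = phantom.CohortSpec(n_subjects=config.n_subjects,
                                seed=config.seed,
                                broken_fraction=config.broken_fraction)
    prep_params = PrepParams(min_length_mm=config.min_length_mm)
    log.info("simulating %d subjects (seed %d)", config.n_subjects,
             config.seed)
    subjects, meta = phantom.simulate_cohort(atlas, cohort, spec)
    meta.to_csv(out / "subjects.tsv", sep="\t", index=False)

    tracts = sorted(cohort.tracts)
    tallies = []
    termination_tables = {t: [] for t in tracts}
    stem_rows = []
    summaries = {op: [] for op in config.operators}
    for s, (tractogram, truth) in enumerate(subjects):
        traversal = dissection.compute_traversal(tractogram, atlas.affine)
        prep = dissection.prepare_tractogram(tractogram, atlas, dilated,
                                             prep_params, traversal=traversal)
        row = {"subject": s, "stage": "prepare", **prep.tally}
        tallies.append(row)
        log.info("subject %d prepare tally %s", s, prep.tally)
        rng = np.random.default_rng([config.seed, 1000 + s])
        for tract in tracts:
            rules = ExtractionRules(
                exclusion_labels=(_tract_label_names(atlas, "temporal_pole")
                                  if tract == "IFOF" else set()))
            for hemi in ("left", "right"):
                for op_i, op in enumerate(config.operators):
                    mask = phantom.simulate_stem_mask(
                        spec, tract, hemi, rng,
                        operator_shift=0.0 if op_i == 0 else 0.5)
                    roi = StemROI(mask, atlas.affine,
                                  cohort.tracts[tract].orientation,
                                  tract_tag=tract, hemisphere=hemi,
                                  operator=op)
                    summaries[op].append(stem_metrics.stem_summary(
                        roi, atlas.voxel_volume, subject=s))
                    if op_i == 0:
                        ext = dissection.extract_tract(
                            tractogram, roi, rules, atlas, dilated,
                            traversal=traversal)
                        tallies.append({"subject": s,
                                        "stage": f"extract_{tract}_{hemi}",
                                        **ext.tally})
                        termination_tables[tract].append((hemi, ext))
    stem_rows = [{"subject": v.subject, "sex": meta.sex[v.subject],
                  "tract": v.tract, "hemisphere": v.hemisphere,
                  "volume": v.volume_mm3}
                 for v in summaries[config.operators[0]]]

    pd.DataFrame(tallies).to_csv(out / "tallies.tsv", sep="\t", index=False)

    summary = {"n_subjects": config.n_subjects, "seed": config.seed,
               "tracts": {}}
    for tract in tracts:
        # combine the two hemisphere extractions of each subject
        tables = []
        for s in range(config.n_subjects):
            pair = termination_tables[tract][2 * s: 2 * s + 2]
            merged = _merge_extractions([e for _, e in pair])
            tables.append(termination_stats.tally_terminations(
                merged, atlas.table, subject=s, tract=tract))
        counts = termination_stats.cohort_counts(tables)
        counts.to_csv(out / f"counts_{tract}.tsv", sep="\t", index=False)
        ntds = termination_stats.compute_ntds(counts)
        thr = termination_stats.fp_threshold(ntds, config.fp_regions[tract])
        adj = termination_stats.adjust_ntds(ntds, thr)
        presence = termination_stats.presence_percentages(adj)
        ai = termination_stats.asymmetry_table(ntds)
        if config.n_subjects >= 5:
            territories = termination_stats.territory_test(adj, config.alpha)
            asym = termination_stats.asymmetry_test(ai, config.alpha)
        else:
            log.info("%s: cohort below 5 subjects, group tests skipped",
                     tract)
            territories = pd.DataFrame(
                columns=["region", "hemisphere", "p", "degenerate",
                         "significant"]).astype({"significant": bool})
            asym = pd.DataFrame(
                columns=["region", "n", "mean_ai", "p", "tested",
                         "degenerate", "significant"])
            asym = asym.astype({"significant": bool, "tested": bool})
        for name, frame in [("ntds", ntds), ("presence", presence),
                            ("territories", territories),
                            ("asymmetry", asym)]:
            frame.to_csv(out / f"{name}_{tract}.tsv", sep="\t", index=False)
        if config.make_figures:
            from . import plots
            plots.save_report_figures(ntds, asym, out, tract)
        summary["tracts"][tract] = {
            "fp_region": thr.fp_region,
            "threshold": thr.threshold,
            "territories": sorted(
                f"{r.region}:{r.hemisphere}"
                for r in territories.itertuples() if r.significant),
            "significant_asymmetries": sorted(
                asym[asym.significant].region),
        }
        log.info("%s: threshold %.4f, %d territories", tract, thr.threshold,
                 int(territories.significant.sum()))

    vol_df = pd.DataFrame(stem_rows)
    anova = stem_metrics.stem_volume_anova(vol_df)
    anova.to_csv(out / "stem_anova.tsv", sep="\t", index=False)
    reliability = stem_metrics.interoperator_report(
        summaries[config.operators[0]], summaries[config.operators[1]])
    reliability.to_csv(out / "reliability.tsv", sep="\t", index=False)
    summary["stem_anova"] = {
        r.effect: {"F": r.F, "p": r.p} for r in anova.itertuples()}
    summary["reliability_mean_com_dist"] = float(
        reliability.com_dist_mean.mean())
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline complete -> %s", out)
    return out


def _merge_extractions(exts):
    """Pool the two hemisphere extractions of one subject-tract."""
    frames = []
    offset = 0
    streamlines = []
    for e in exts:
        f = e.endpoints.copy()
        f["orig_index"] = f.orig_index + offset
        frames.append(f)
        streamlines += list(e.tractogram.streamlines)
        offset += len(e.tractogram)
    merged = dataclasses.replace(
        exts[0],
        tractogram=dataclasses.replace(exts[0].tractogram,
                                       streamlines=streamlines),
        endpoints=pd.concat(frames, ignore_index=True),
        tally={k: sum(e.tally[k] for e in exts) for k in exts[0].tally},
    )
    return merged
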