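"""End-to-end orchestration of the comparative heat-stress analysis.

Runs the full sequence on an in-memory study (simulated or loaded from
files): dose-response statistics per species, pairwise LT50 ratio tests,
consensus differential expression, HSP panels and strategy calls,
cross-species annotation-name overlap with the Monte-Carlo null, and
orthogroup category statistics.
"""

from __future__ import annotations

import itertools
import logging
import time

import numpy as np
import pandas as pd

from . import expression, orthology, overlap, thermal
from .io import StudyConfig

log = logging.getLogger(__name__)


def _stage(name: str, t0: float, n: int) -> None:
    log.info("%s: %d inputs, %.2fs", name, n, time.perf_counter() - t0)


def analyze_thermal(survival, config: StudyConfig) -> dict:
    """Per-species dose-response fit, UTL, decline width; pairwise ratio tests."""
    t0 = time.perf_counter()
    by_species: dict[str, list] = {}
    for obs in survival:
        by_species.setdefault(obs.species_id, []).append(obs)
    fits, utls, widths = {}, {}, {}
    for sid, obs in by_species.items():
        fits[sid] = thermal.fit_dose_response(obs)
        utls[sid] = thermal.determine_utl(obs, alpha=config.utl_alpha)
        widths[sid] = thermal.decline_width(
            obs, upper=config.survival_upper, lower=config.survival_lower
        )
    ratios = {
        (a, b): thermal.ratio_test(fits[a], fits[b])
        for a, b in itertools.combinations(sorted(fits), 2)
    }
    _stage("thermal", t0, len(survival))
    return {"fits": fits, "utl": utls, "decline_width": widths, "ratio_tests": ratios}


def analyze_expression(counts, catalogs, species_meta, widths, config: StudyConfig) -> dict:
    """Two DE callers, the consensus filter, HSP panels, profiles, strategies."""
    t0 = time.perf_counter()
    out: dict[str, dict] = {}
    for sid, matrix in counts.items():
        factors = expression.tmm_factors(matrix.counts)
        normalized = expression.normalize_tmm(matrix.counts, factors)
        table_nb = expression.de_test(matrix)
        table_t = expression.de_test_logcpm(matrix)
        det = expression.consensus_det(
            table_nb, table_t, fc_cut=config.fc_cut, fdr_cut=config.fdr_cut
        )
        panel = expression.find_hsp_transcripts(catalogs[sid], normalized, det=det)
        profile = expression.classify_profile(
            len(det), len(catalogs[sid]), species_id=sid, cuts=config.profile_cuts
        )
        width = widths[sid].width if sid in widths else None
        strategy = expression.call_strategy(
            profile, species_meta[sid].habitat, panel.differential, width
        )
        out[sid] = {
            "factors": factors,
            "normalized": normalized,
            "tables": (table_nb, table_t),
            "consensus": det,
            "hsp_panel": panel,
            "profile": profile,
            "strategy": strategy,
        }
    _stage("expression", t0, len(counts))
    return out


def analyze_overlap(catalogs, det_sets, config: StudyConfig) -> dict:
    """Pairwise unique-name overlaps against the resampling null.

    Per-pair seeds are derived from the config seed and the sorted pair
    label so results do not depend on pair evaluation order.
    """
    t0 = time.perf_counter()
    name_sets = {
        sid: overlap.unique_meaningful_names(
            catalogs[sid], det_sets[sid].transcripts, species_id=sid
        )
        for sid in det_sets
    }
    tests = {}
    for i, (a, b) in enumerate(itertools.combinations(sorted(det_sets), 2)):
        observed = overlap.observed_overlap(name_sets[a], name_sets[b])
        pair_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
        )
        tests[(a, b)] = overlap.resampling_null(
            catalogs[a],
            catalogs[b],
            n_a=name_sets[a].source_size,
            n_b=name_sets[b].source_size,
            iterations=config.mc_iterations,
            seed=pair_seed,
            species_a=a,
            species_b=b,
            observed=observed,
            alpha=config.overlap_alpha,
        )
    _stage("overlap", t0, len(tests))
    return {"name_sets": name_sets, "tests": tests}


def analyze_orthology(og_table, species_meta, catalogs, det_sets) -> dict:
    """Category assignments, per-species restricted-gene enrichment, summary."""
    t0 = time.perf_counter()
    assignments = orthology.classify_orthogroups(og_table, species_meta)
    orthology.check_category_consistency(assignments, og_table, species_meta)
    statuses, enrichment = {}, {}
    for sid in og_table.species:
        status = orthology.gene_status(
            assignments, og_table, sid, catalog=catalogs[sid].index
        )
        statuses[sid] = status
        det = det_sets[sid].transcripts if sid in det_sets else []
        enrichment[sid] = orthology.restricted_enrichment(status, det, sid)
    summary = orthology.summarize_orthology(
        og_table, {sid: catalogs[sid].index for sid in og_table.species},
        assignments=assignments,
    )
    _stage("orthology", t0, len(og_table))
    return {
        "assignments": assignments,
        "status": statuses,
        "enrichment": enrichment,
        "summary": summary,
    }


def run_study(study, config: StudyConfig | None = None,
              stages=("thermal", "expression", "overlap", "orthology")) -> dict:
    """Run the full analysis on a StudyData; returns the nested results."""
    config = config or StudyConfig(seed=getattr(study, "master_seed", 0))
    results: dict = {"config": config, "seed": config.seed}
    if "thermal" in stages:
        results["thermal"] = analyze_thermal(study.survival, config)
    if "expression" in stages:
        widths = results.get("thermal", {}).get("decline_width", {})
        results["expression"] = analyze_expression(
            study.counts, study.catalogs, study.species_meta, widths, config
        )
    det_sets = {
        sid: res["consensus"] for sid, res in results.get("expression", {}).items()
    }
    if "overlap" in stages and det_sets:
        results["overlap"] = analyze_overlap(study.catalogs, det_sets, config)
    if "orthology" in stages:
        results["orthology"] = analyze_orthology(
            study.orthogroups, study.species_meta, study.catalogs, det_sets
        )
    if "expression" in results:
        sizes = {sid: len(study.catalogs[sid]) for sid in results["expression"]}
        dets = {sid: len(det_sets[sid]) for sid in results["expression"]}
        if len(sizes) >= 3:
            order = sorted(sizes)
            results["size_det_correlation"] = overlap.correlate_size_det(
                [sizes[s] for s in order], [dets[s] for s in order]
            )
    return results


def summarize_results(results: dict) -> pd.DataFrame:
    """One row per species with the headline statistics."""
    rows = {}
    thermal_res = results.get("thermal", {})
    for sid, res in results.get("expression", {}).items():
        fit = thermal_res.get("fits", {}).get(sid)
        utl = thermal_res.get("utl", {}).get(sid)
        width = thermal_res.get("decline_width", {}).get(sid)
        profile = res["profile"]
        rows[sid] = {
            "lt50": fit.lt50 if fit else None,
            "lt50_se": fit.se_lt50 if fit else None,
            "utl": utl.utl if utl else None,
            "decline_width": width.width if width else None,
            "det_count": profile.det_count,
            "transcriptome_size": profile.transcriptome_size,
            "det_fraction_pct": profile.det_fraction,
            "profile": profile.profile,
            "strategy": res["strategy"].strategy,
        }
    return pd.DataFrame(rows).T
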