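"""Replicate orchestration and type-1-error / power tallying.

Type 1 error (association): the rate at a p-value threshold is the mean
over null replicates of (number of testable SNPs with p below the
threshold) / (number of testable SNPs).  Type 1 error (two-point linkage):
the mean count of SNPs with HLOD above the threshold divided by the full
marker count, as literally defined for that analysis.  Power: the
percentage of replicates in which the designated disease SNP beats the
threshold (a replicate whose disease SNP is not testable counts as a miss).

``run_experiment`` wires template generation, simulation, whole- and
split-pedigree association scans, and two-point linkage into tidy tables
with Monte-Carlo standard errors, plus a JSON manifest that replays the run
exactly.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .mqls import MqlsEngine
from .pedigree import Pedigree, kinship
from .simulate import (
    DEFAULT_MAF,
    DEFAULT_PREVALENCE,
    DiseaseModel,
    MarkerMap,
    generate_replicates,
)
from .split import split_kinship, split_pedigree, subjects_of_interest
from .linkage import LinkageModel, twopoint_lod
from .template import TemplateParams, generate_template

__all__ = [
    "P_THRESHOLDS_NULL",
    "P_THRESHOLDS_POWER",
    "HLOD_THRESHOLDS",
    "tally_type1",
    "tally_linkage_type1",
    "tally_power",
    "scan_pvalues",
    "disease_pvalues",
    "build_engine",
    "build_split_engine",
    "run_experiment",
]

log = logging.getLogger("largeped")

P_THRESHOLDS_NULL = (0.05, 0.01, 0.005, 0.001)
P_THRESHOLDS_POWER = (0.05, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)
HLOD_THRESHOLDS = (1.0, 2.0, 3.0)

# RNG stage words for deriving per-analysis master seeds from one seed
_STAGE_NULL = 101
_STAGE_POWER = 211


def _seed32(*words: int) -> int:
    return int(np.random.SeedSequence(list(words)).generate_state(1)[0] % (2**31))


def tally_type1(
    pvalues_by_replicate: list[np.ndarray],
    thresholds=P_THRESHOLDS_NULL,
) -> pd.DataFrame:
    """Average per-replicate fraction of testable SNPs under each p-value
    threshold (percent), with the across-replicate Monte-Carlo SE."""
    if not pvalues_by_replicate:
        raise ValueError("no replicate results to tally")
    rows = []
    for t in thresholds:
        fracs = []
        for p in pvalues_by_replicate:
            p = np.asarray(p, float)
            ok = np.isfinite(p)
            if not ok.any():
                continue
            fracs.append(np.mean(p[ok] < t))
        fracs = np.asarray(fracs)
        rows.append(
            {
                "threshold": t,
                "percent": 100.0 * fracs.mean(),
                "se": 100.0 * fracs.std(ddof=1) / np.sqrt(fracs.size)
                if fracs.size > 1
                else np.nan,
                "n_replicates": int(fracs.size),
            }
        )
    return pd.DataFrame(rows)


def tally_linkage_type1(
    hlods_by_replicate: list[np.ndarray],
    n_markers: int,
    thresholds=HLOD_THRESHOLDS,
) -> pd.DataFrame:
    """Mean count of SNPs over each HLOD threshold divided by ``n_markers``
    (percent)."""
    if not hlods_by_replicate:
        raise ValueError("no replicate results to tally")
    rows = []
    for t in thresholds:
        fracs = np.array(
            [np.sum(np.asarray(h) > t) / n_markers for h in hlods_by_replicate]
        )
        rows.append(
            {
                "threshold": t,
                "percent": 100.0 * fracs.mean(),
                "se": 100.0 * fracs.std(ddof=1) / np.sqrt(fracs.size)
                if fracs.size > 1
                else np.nan,
                "n_replicates": int(fracs.size),
            }
        )
    return pd.DataFrame(rows)


def tally_power(
    disease_stats: np.ndarray,
    thresholds=P_THRESHOLDS_POWER,
    kind: str = "p",
) -> pd.DataFrame:
    """Percent of replicates whose disease-SNP p-value (kind='p', beat =
    below-or-equal) or HLOD (kind='hlod', beat = at-or-above) crosses each
    threshold; NaN (not testable) counts as a miss."""
    stats = np.asarray(disease_stats, float)
    if stats.size == 0:
        raise ValueError("no replicate results to tally")
    n_miss = int(np.isnan(stats).sum())
    if n_miss:
        log.warning("%d replicates with untestable disease SNP counted as misses", n_miss)
    rows = []
    for t in thresholds:
        if kind == "p":
            hits = stats <= t
        elif kind == "hlod":
            hits = stats >= t
        else:
            raise ValueError(f"unknown kind {kind!r}")
        hits = np.where(np.isnan(stats), False, hits)
        pct = 100.0 * hits.mean()
        rows.append(
            {
                "threshold": t,
                "percent": pct,
                "se": 100.0 * np.sqrt(hits.mean() * (1 - hits.mean()) / hits.size),
                "n_replicates": int(stats.size),
            }
        )
    return pd.DataFrame(rows)


def build_engine(
    template: Pedigree, prevalence: float = DEFAULT_PREVALENCE
) -> MqlsEngine:
    """Whole-pedigree association engine: kinship over the genotyped and
    phenotyped members computed on the full structure."""
    geno = [i.id for i in template if i.genotyped]
    phen = [i.id for i in template if i.phenotyped]
    km = kinship(template, sorted(set(geno) | set(phen)))
    return MqlsEngine(km, geno, phen, prevalence)


def build_split_engine(template: Pedigree, bit_limit: int = 24, prevalence: float = DEFAULT_PREVALENCE):
    """Split the template on its own affection labels and return the
    sub-pedigree set plus an engine over the block-diagonal kinship
    (each genotype used once)."""
    subjects = subjects_of_interest(template)
    subs = split_pedigree(template, subjects, bit_limit)
    km = split_kinship(subs)
    covered = set(km.ids)
    geno = [i.id for i in template if i.genotyped and i.id in covered]
    phen = [i.id for i in template if i.phenotyped and i.id in covered]
    return subs, MqlsEngine(km, geno, phen, prevalence)


def scan_pvalues(
    template: Pedigree,
    marker_map: MarkerMap,
    model: DiseaseModel,
    n_reps: int,
    master_seed: int,
    engine: MqlsEngine,
) -> list[np.ndarray]:
    """Per-replicate arrays of p-values (NaN where not testable)."""
    out = []
    for rep in generate_replicates(template, marker_map, model, n_reps, master_seed):
        res = engine.scan_replicate(rep, marker_map.names)
        out.append(np.array([r.p for r in res]))
    return out


def disease_pvalues(
    template: Pedigree,
    marker_map: MarkerMap,
    model: DiseaseModel,
    n_reps: int,
    master_seed: int,
    engine: MqlsEngine,
) -> np.ndarray:
    """Disease-SNP p-value per replicate (NaN = not testable)."""
    if marker_map.disease_locus is None:
        raise ValueError("marker map has no disease locus")
    pvals = scan_pvalues(template, marker_map, model, n_reps, master_seed, engine)
    return np.array([p[marker_map.disease_locus] for p in pvals])


def _model_label(model: DiseaseModel) -> str:
    if model.mode == "null":
        return "null"
    return f"{model.mode}, OR {model.odds_ratio:g}"


def run_experiment(config: dict, out_dir: str | os.PathLike | None = None):
    """Run simulate -> analyze -> tally for a config dictionary.

    Config keys (all optional, defaults in parentheses): ``template`` (the
    default profile), ``n_loci`` (124), ``spacing_cM`` (0.062), ``maf``
    (0.2), ``prevalence`` (106/798), ``n_reps`` (1000), ``master_seed`` (0),
    ``bit_limit`` (24), ``disease_locus`` (middle marker), ``models``
    (null), ``analyses`` (["whole-mqls"]), ``resplit_per_replicate`` (true
    for disease models).  Returns ``(tables, manifest)`` where ``tables``
    is one tidy DataFrame and ``manifest`` replays the run.
    """
    cfg = dict(config)
    tparams = TemplateParams(**cfg.get("template", {}))
    n_loci = int(cfg.get("n_loci", 124))
    disease_locus = int(cfg.get("disease_locus", (n_loci - 1) // 2))
    mmap = MarkerMap.uniform(
        n_loci, float(cfg.get("spacing_cM", 0.062)), disease_locus=disease_locus
    )
    maf = float(cfg.get("maf", DEFAULT_MAF))
    prevalence = float(cfg.get("prevalence", DEFAULT_PREVALENCE))
    n_reps = int(cfg.get("n_reps", 1000))
    seed = int(cfg.get("master_seed", 0))
    bit_limit = int(cfg.get("bit_limit", 24))
    analyses = list(cfg.get("analyses", ["whole-mqls"]))
    model_specs = cfg.get("models", [{"mode": "null"}])

    log.info("generating template (seed %d)", tparams.seed)
    template = generate_template(tparams)
    engine = build_engine(template, prevalence)
    needs_split = any(a != "whole-mqls" for a in analyses)
    subs = split_engine = None
    if needs_split:
        subs, split_engine = build_split_engine(template, bit_limit, prevalence)

    frames = []
    for k, mspec in enumerate(model_specs):
        model = DiseaseModel(
            mode=mspec.get("mode", "null"),
            odds_ratio=float(mspec.get("odds_ratio", 1.0)),
            maf=maf,
            prevalence=prevalence,
        )
        stage = _STAGE_NULL if model.mode == "null" else _STAGE_POWER
        mseed = _seed32(seed, stage, k)
        label = _model_label(model)
        log.info("model %s: %d replicates", label, n_reps)
        for analysis in analyses:
            if analysis == "whole-mqls":
                eng = engine
            elif analysis == "split-mqls":
                eng = split_engine
            elif analysis in ("twopoint-dom", "twopoint-rec"):
                eng = None
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
            if analysis in ("whole-mqls", "split-mqls"):
                if model.mode == "null":
                    pv = scan_pvalues(template, mmap, model, n_reps, mseed, eng)
                    tab = tally_type1(pv)
                else:
                    dp = disease_pvalues(template, mmap, model, n_reps, mseed, eng)
                    tab = tally_power(dp)
            else:
                lmodel = (
                    LinkageModel.dominant()
                    if analysis == "twopoint-dom"
                    else LinkageModel.recessive()
                )
                hlods = []
                for rep in generate_replicates(template, mmap, model, n_reps, mseed):
                    hs = [
                        twopoint_lod(subs, rep, mk, lmodel, maf).hlod
                        for mk in range(n_loci)
                    ]
                    hlods.append(np.array(hs))
                if model.mode == "null":
                    tab = tally_linkage_type1(hlods, n_loci)
                else:
                    tab = tally_power(
                        np.array([h[disease_locus] for h in hlods]),
                        HLOD_THRESHOLDS,
                        kind="hlod",
                    )
            tab.insert(0, "analysis", analysis)
            tab.insert(1, "model", label)
            frames.append(tab)
    table = pd.concat(frames, ignore_index=True)

    manifest = {
        "largeped_version": __version__,
        "config": {
            **cfg,
            "template": asdict(tparams),
            "n_loci": n_loci,
            "disease_locus": disease_locus,
            "maf": maf,
            "prevalence": prevalence,
            "n_reps": n_reps,
            "master_seed": seed,
            "bit_limit": bit_limit,
            "analyses": analyses,
        },
        "template_summary": {
            "members": len(template),
            "founders": len(template.founders),
            "genotyped": sum(1 for i in template if i.genotyped),
            "affected": sum(1 for i in template if i.affection == 2),
            "generations": template.n_generations,
        },
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "tallies.csv"), index=False)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        _write_rendering(table, os.path.join(out_dir, "tallies.txt"))
    return table, manifest


def _write_rendering(table: pd.DataFrame, path: str) -> None:
    """Formatted text rendering: one block per analysis, models as rows and
    thresholds as columns."""
    with open(path, "w") as fh:
        for analysis, part in table.groupby("analysis", sort=False):
            wide = part.pivot_table(
                index="model", columns="threshold", values="percent", sort=False
            )
            fh.write(f"== {analysis} ==\n")
            fh.write(wide.to_string(float_format=lambda v: f"{v:7.2f}"))
            fh.write("\n\n")
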