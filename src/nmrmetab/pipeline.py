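"""End-to-end orchestration: simulate -> preprocess -> model -> biomarkers
-> pathways, with schema-validated configuration and a reproducibility
manifest.

A single global seed deterministically derives per-stage seeds by hashing
the stage name, so disabling one stage never shifts another stage's random
stream. Every effective parameter is echoed into the manifest together
with SHA-256 checksums of each output file; two runs with the same config
and seed produce byte-identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .data import TABLE1, TABLE2, fixture_path
from . import biomarkers as bm
from . import multivariate as mv
from . import pathways as pw
from . import preprocess as pp
from . import synth

log = logging.getLogger("nmrmetab")


class PipelineConfig(BaseModel):
    """Validated stage parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    groups: tuple[str, ...] = ("WKY-N", "SHR-N", "SHR-H")
    n_per_group: int = Field(10, ge=3)
    dilution_sd: float = Field(0.1, ge=0)
    noise_sd: float = Field(0.5, ge=0)
    baseline_amplitude: float = Field(0.5, ge=0)
    biological_cv: float = Field(0.10, ge=0)
    n_points: int = Field(16384, ge=1000)

    exclusion_low: float = 4.33
    exclusion_high: float = 5.50
    bin_width: float = Field(0.015, gt=0)
    pqn_reference: str = "all"
    scaling: Literal["pareto"] = "pareto"

    n_orthogonal: int = Field(1, ge=0)
    cv_repeats: int = Field(7, ge=1)
    n_permutations: int = Field(2000, ge=1)

    half_window: float = Field(0.02, gt=0)
    p_threshold: float = Field(0.05, gt=0, le=1)
    vip_threshold: float = Field(1.0, ge=0)
    impact_threshold: float = Field(0.1, ge=0)

    seed: int = Field(0, ge=0)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_seeds: dict[str, int]
    checksums: dict[str, str]
    started: float
    finished: float

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "checksums": self.checksums,
            "started": self.started,
            "finished": self.finished,
        }
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
        tmp.replace(path)


def validate_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields pure defaults.

    All type and range violations are reported at once with their key
    paths (pydantic aggregates them).
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data = loaded
    data.update(overrides)
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        raise ValueError(f"invalid configuration:\n{err}") from None


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing the stage name (stable, < 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_effect_table() -> synth.EffectTable:
    """Disease and treatment fold changes chained from the two tables."""
    t1 = synth.load_effect_table(fixture_path(TABLE1), "SHR-N_vs_WKY-N")
    t2 = synth.load_effect_table(fixture_path(TABLE2), "SHR-H_vs_SHR-N")
    return synth.EffectTable(pd.concat([t1.frame, t2.frame], ignore_index=True))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages in order, writing outputs and a manifest."""
    started = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in ("synth", "model")}
    outputs: list[Path] = []

    def _run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        log.info("stage %s finished in %.1fs", name, time.time() - t0)
        return result

    # --- synth
    def _synth():
        library = synth.load_resonance_library()
        effects = default_effect_table()
        keep = [c for c in effects.frame["contrast"].unique()
                if all(g in config.groups for g in str(c).split("_vs_"))]
        effects = synth.EffectTable(
            effects.frame[effects.frame["contrast"].isin(keep)].reset_index(drop=True)
        )
        design = synth.CohortDesign(
            groups=config.groups,
            n_per_group=config.n_per_group,
            dilution_sd=config.dilution_sd,
            noise_sd=config.noise_sd,
            baseline_amplitude=config.baseline_amplitude,
            biological_cv=config.biological_cv,
            n_points=config.n_points,
            seed=seeds["synth"],
        )
        sset = synth.simulate_cohort(library, effects, design)
        outputs.extend(synth.write_spectrum_set(sset, out).values())
        return library, sset

    library, sset = _run_stage("synth", _synth)

    # --- preprocess
    def _preprocess():
        trimmed = [pp.exclude_region(s, config.exclusion_low, config.exclusion_high)
                   for s in sset.spectra]
        binned = pp.adaptive_bin(trimmed, config.bin_width)
        normalized, report = pp.pqn_normalize(binned, config.pqn_reference)
        scaled = pp.scale_features(normalized)
        for stage_name, m in (("binned", binned), ("normalized", normalized),
                              ("scaled", scaled)):
            outputs.extend(pp.write_feature_matrix(m, out / f"features_{stage_name}").values())
        report_path = out / "normalization_report.csv"
        report.table.to_csv(report_path, float_format="%.17g")
        outputs.append(report_path)
        return normalized, scaled

    normalized, scaled = _run_stage("preprocess", _preprocess)

    contrasts = [(str(c).split("_vs_")[1], str(c).split("_vs_")[0])
                 for c in sset.truth.frame["contrast"].unique()]

    # --- model (PCA + per-contrast OPLS-DA)
    def _model():
        pca = mv.fit_pca(scaled, n_components=2)
        pca_path = out / "pca_scores.csv"
        pd.DataFrame(pca.scores, index=pca.sample_index,
                     columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
                     ).to_csv(pca_path, float_format="%.17g")
        outputs.append(pca_path)
        summaries = {}
        for ref, case in contrasts:
            tag = f"{case}_vs_{ref}"
            mask = scaled.groups.isin([ref, case]).to_numpy()
            sub = pp.FeatureMatrix(
                scaled.values.iloc[mask],
                scaled.feature_meta,
                scaled.sample_meta.iloc[mask],
                stage="scaled",
            )
            model = mv.fit_oplsda(sub, (ref, case), config.n_orthogonal)
            q2 = mv.cross_validate_q2(sub, (ref, case), config.n_orthogonal,
                                      config.cv_repeats, seeds["model"])
            perm = mv.permutation_test(sub, (ref, case), config.n_orthogonal,
                                       config.n_permutations, seeds["model"],
                                       config.cv_repeats)
            summaries[tag] = {
                "r2x": model.r2x, "r2y": model.r2y, "q2": q2,
                "permutation_p": perm.p_value,
                "n_permutations": perm.n_permutations,
                "explained_pc1": float(pca.explained_variance_fraction[0]),
            }
            loadings = mv.coefficient_loadings(model, sub)
            loadings["vip"] = model.vip
            lpath = out / f"loadings_{tag}.csv"
            loadings.to_csv(lpath, float_format="%.17g")
            outputs.append(lpath)
        mpath = out / "model_summary.json"
        mpath.write_text(json.dumps(summaries, indent=1, sort_keys=True))
        outputs.append(mpath)
        return summaries

    _run_stage("model", _model)

    # --- biomarkers
    def _biomarkers():
        integrals = bm.integrate_metabolites(
            normalized, library, config.half_window,
            (config.exclusion_low, config.exclusion_high),
        )
        tables = {}
        for ref, case in contrasts:
            tag = f"{case}_vs_{ref}"
            mask = integrals.index.isin(
                scaled.sample_meta.index[scaled.groups.isin([ref, case])]
            )
            sub = integrals.loc[mask]
            groups = scaled.groups.reindex(sub.index)
            tests = bm.univariate_tests(sub, groups, (ref, case))
            fc = bm.fold_change(sub, groups, (ref, case))
            bsub = pp.FeatureMatrix(
                scaled.values.loc[sub.index],
                scaled.feature_meta,
                scaled.sample_meta.loc[sub.index],
                stage="scaled",
            )
            model = mv.fit_oplsda(bsub, (ref, case), config.n_orthogonal)
            vip = bm.metabolite_vip(bsub, model.vip, library, config.half_window)
            table = bm.biomarker_table_from_stats(tag, library, tests, fc, vip)
            bm.select_biomarkers(table, config.p_threshold, config.vip_threshold)
            tpath = out / f"biomarkers_{tag}.csv"
            table.frame().to_csv(tpath, index=False, float_format="%.17g")
            outputs.append(tpath)
            tables[tag] = table
        shared = None
        if len(tables) == 2:
            disease, treatment = tables.values()
            shared = bm.shared_reversed(disease, treatment,
                                        config.p_threshold, config.vip_threshold)
            spath = out / "shared_biomarkers.json"
            spath.write_text(json.dumps(
                {"reversed": shared.metabolites,
                 "intersection": shared.intersection,
                 "rule": shared.rule}, indent=1))
            outputs.append(spath)
        return shared

    shared = _run_stage("biomarkers", _biomarkers)

    # --- pathways
    def _pathways():
        marker_names = shared.metabolites if shared else []
        results = pw.analyze_pathways(marker_names)
        screened = pw.screen_pathways(results, config.impact_threshold)
        frame = pd.DataFrame(
            [{"pathway_id": r.pathway_id, "name": r.name,
              "hits": len(r.matched), "p": r.enrichment_p,
              "p_adjusted": r.enrichment_p_adjusted, "impact": r.impact,
              "screened": r.pathway_id in {s.pathway_id for s in screened}}
             for r in results]
        )
        ppath = out / "pathway_results.csv"
        frame.to_csv(ppath, index=False, float_format="%.17g")
        outputs.append(ppath)
        network = pw.build_metabolite_protein_network(marker_names)
        outputs.append(pw.export_edge_list(network, out / "metabolite_protein_edges.tsv"))

    _run_stage("pathways", _pathways)

    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        version=__version__,
        seed=config.seed,
        stage_seeds=seeds,
        checksums={str(p.relative_to(out)): _sha256(p) for p in outputs},
        started=started,
        finished=time.time(),
    )
    manifest.write(out / "manifest.json")
    return manifest


def recover_fold_change(
    effects_fixture: str | Path,
    groups: tuple[str, str],
    metabolite: str,
    seed: int,
    *,
    n_per_group: int = 10,
    dilution_sd: float = 0.1,
    half_window: float = bm.DEFAULT_HALF_WINDOW,
    bin_width: float = pp.DEFAULT_BIN_WIDTH,
) -> float:
    """Simulate one two-group cohort from an effect fixture, preprocess it
    (exclusion, adaptive binning, PQN) and return the estimated fold change
    of one metabolite's integral, case over reference.

    ``groups`` is (reference, case); the fixture's fold changes are applied
    on the ``case_vs_reference`` contrast.
    """
    reference, case = groups
    library = synth.load_resonance_library()
    effects = synth.load_effect_table(effects_fixture, f"{case}_vs_{reference}")
    design = synth.CohortDesign(
        groups=(reference, case),
        n_per_group=n_per_group,
        dilution_sd=dilution_sd,
        seed=seed,
    )
    sset = synth.simulate_cohort(library, effects, design)
    trimmed = [pp.exclude_region(s) for s in sset.spectra]
    binned = pp.adaptive_bin(trimmed, bin_width)
    normalized, _ = pp.pqn_normalize(binned)
    integrals = bm.integrate_metabolites(normalized, library, half_window)
    groups_series = pd.Series(
        [s.group for s in sset.spectra],
        index=pd.Index([s.sample_id for s in sset.spectra], name="sample_id"),
    )
    fc = bm.fold_change(integrals, groups_series, (reference, case))
    return float(fc.loc[metabolite])
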