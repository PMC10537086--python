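"""End-to-end orchestration: simulate/load -> QC -> diversity -> permutation
stats -> engraftment -> similarity shift -> genus shift -> report bundle.

Every stage writes TSV outputs under the run directory; a JSON manifest
records the package version, seed, parameters, stage outputs with SHA-256
checksums, and headline summary numbers, so a run can be reproduced
bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import (
    DEFAULT_QC_FLOOR,
    read_cohort,
    write_cohort,
    write_results,
)
from .diversity import alpha_diversity, beta_diversity
from .engraftment import (
    cohort_engraftment,
    commonly_shared_asvs,
    donor_sharing_summary,
    engrafted_taxonomy_breakdown,
)
from .genus import (
    DEFAULT_PATHOGENIC_GENERA,
    delta_table,
    fit_genus_models,
    tested_genera,
)
from .permstats import pairwise_permanova, permanova, permdisp
from .similarity import (
    DELTA_PREDICTORS,
    delta_model,
    delta_similarity,
    group_delta_summary,
    match_dyads,
)
from .simulate import SimulationConfig, generate_cohort

logger = logging.getLogger("engraft")

#: PERMANOVA covariates: the four host predictors plus age and sex
PERMANOVA_TERMS = list(DELTA_PREDICTORS) + ["age_years", "sex"]


@dataclass
class PipelineConfig:
    """One config to drive the whole analysis.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``input_paths`` (table/taxonomy/metadata/tree files) must be provided.
    ``seed`` controls every stochastic stage.
    """

    outdir: str = "engraft_run"
    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None
    qc_floor: int = DEFAULT_QC_FLOOR
    metrics: tuple[str, ...] = ("bray_curtis", "aitchison")
    pseudocount: float = 0.5
    n_perm: int = 999
    seed: int = 0
    age_tol: float = 1.0
    core_prevalence: float = 0.55
    min_recipient_prev: float = 0.10
    core_genera: list[str] | None = None
    pathogenic_genera: tuple[str, ...] = DEFAULT_PATHOGENIC_GENERA
    similarity_metric: str = "bray_curtis"

    def __post_init__(self):
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of simulation / input_paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "seed" not in sim and "seed" in raw:
                sim["seed"] = raw["seed"]
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_simulate(cfg: PipelineConfig, outdir: Path):
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.simulation.seed or cfg.seed)
        cohort, truth = generate_cohort(sim)
        paths = write_cohort(cohort, outdir / "cohort")
        write_results(truth.to_frame(), outdir / "cohort" / "truth.tsv")
        return cohort, truth, {k: str(v) for k, v in paths.items()}
    paths = cfg.input_paths
    cohort = read_cohort(
        paths["table"], paths["taxonomy"], paths["metadata"], paths.get("tree"),
        qc_floor=cfg.qc_floor,
        proportions=bool(paths.get("proportions", False)),
    )
    return cohort, None, dict(paths)


def run_pipeline(cfg: PipelineConfig, *, resume: bool = False) -> dict:
    """Run every stage and return the manifest (also written to disk).

    With ``resume=True`` a previously simulated cohort is reused, but only
    when the on-disk files' checksums match the previous manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"

    cohort = truth = None
    true_mean_realized: float | None = None
    if resume and manifest_path.exists() and cfg.simulation is not None:
        old = json.loads(manifest_path.read_text())
        inputs = old.get("cohort_files", {})
        ok = inputs and all(
            Path(p).exists() and _sha256(Path(p)) == old["checksums"].get(p)
            for p in inputs.values())
        if ok and old.get("config") == _config_dict(cfg):
            logger.info("resume: cohort checksums match; reusing simulated cohort")
            cohort = read_cohort(inputs["table"], inputs["taxonomy"],
                                 inputs["metadata"], inputs.get("tree"),
                                 qc_floor=cfg.qc_floor)
            truth_path = Path(inputs["table"]).parent / "truth.tsv"
            if truth_path.exists():
                realized = pd.read_csv(truth_path, sep="\t",
                                       float_precision="round_trip")
                true_mean_realized = float(realized["realized_fraction"].mean())
    if cohort is None:
        cohort, truth, cohort_files = _load_or_simulate(cfg, outdir)
    else:
        cohort_files = json.loads(manifest_path.read_text())["cohort_files"]

    outputs: dict[str, str] = {}
    summary: dict[str, float] = {}

    def _write(name: str, frame) -> None:
        path = write_results(frame, outdir / f"{name}.tsv")
        outputs[name] = str(path)

    # -- diversity ---------------------------------------------------------
    alpha = alpha_diversity(cohort)
    _write("alpha_diversity", alpha.reset_index())
    distances = {}
    for metric in cfg.metrics:
        dm = beta_diversity(cohort.table, metric, pseudocount=cfg.pseudocount)
        distances[metric] = dm
        path = outdir / f"distance_{metric}.tsv"
        dm.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")
        outputs[f"distance_{metric}"] = str(path)

    # -- permutation stats on recipient samples ---------------------------
    stats_rows = []
    recip_meta = cohort.metadata
    for phase, role in (("pre", "recipient_pre"), ("post", "recipient_post")):
        ids = cohort.samples_with_role(role)
        for metric, dm in distances.items():
            sub = dm.submatrix(ids)
            res = permanova(sub, recip_meta, PERMANOVA_TERMS, mode="marginal",
                            n_perm=cfg.n_perm, seed=cfg.seed)
            tab = res.to_frame()
            tab.insert(0, "phase", phase)
            tab.insert(1, "metric", metric)
            stats_rows.append(tab)
            if phase == "post" and metric == "aitchison":
                summary["clinical_signs_R2_post_aitchison"] = res.r_squared("clinical_signs")
            try:
                disp = permdisp(sub, recip_meta, "clinical_signs",
                                n_perm=cfg.n_perm, seed=cfg.seed)
                disp_f, disp_p = disp.f_statistic, disp.p_value
            except ValueError as exc:  # e.g. a singleton clinical-sign group
                logger.warning("PERMDISP skipped (%s, %s): %s", phase, metric, exc)
                disp_f = disp_p = float("nan")
            stats_rows.append(pd.DataFrame([{
                "phase": phase, "metric": metric, "term": "PERMDISP clinical_signs",
                "F": disp_f, "p": disp_p}]))
    _write("permanova", pd.concat(stats_rows, ignore_index=True))
    pre_ids = cohort.samples_with_role("recipient_pre")
    pw = pairwise_permanova(distances[cfg.similarity_metric].submatrix(pre_ids),
                            recip_meta, "clinical_signs",
                            n_perm=cfg.n_perm, seed=cfg.seed)
    _write("pairwise_permanova_clinical_signs_pre", pw)

    # -- engraftment -------------------------------------------------------
    eng = cohort_engraftment(cohort)
    _write("engraftment_per_recipient",
           eng.per_recipient.drop(columns=["cat_id"]).reset_index())
    per_donor, kw = donor_sharing_summary(eng)
    _write("engraftment_per_donor", per_donor)
    breakdown = engrafted_taxonomy_breakdown(eng, cohort.taxonomy)
    _write("engrafted_taxonomy_breakdown", breakdown)
    _write("commonly_shared_asvs", commonly_shared_asvs(eng, cohort.taxonomy))
    summary.update({f"engraftment_{k}": v for k, v in eng.summary().items()})
    if kw is not None:
        summary["donor_kruskal_H"], summary["donor_kruskal_p"] = kw
    if truth is not None:
        realized = [truth.realized_fraction(c) for c in sorted(truth.eligible)]
        true_mean_realized = float(pd.Series(realized).mean())
    if true_mean_realized is not None:
        summary["true_mean_realized_rate"] = true_mean_realized

    # -- similarity shift --------------------------------------------------
    recipients = cohort.recipient_meta()
    healthy = cohort.metadata[cohort.metadata["role"] == "healthy"]
    dyads = match_dyads(recipients, healthy, age_tol=cfg.age_tol)
    deltas = delta_similarity(cohort, dyads, metric=cfg.similarity_metric,
                              distance=distances.get(cfg.similarity_metric))
    _write("dyad_deltas", deltas)
    group_rows = []
    for factor in DELTA_PREDICTORS:
        g = group_delta_summary(deltas, recipients, factor)
        g.insert(0, "factor", factor)
        group_rows.append(g)
    _write("delta_group_summary", pd.concat(group_rows, ignore_index=True))
    _write("delta_model", delta_model(deltas, recipients))
    by_sign = group_delta_summary(deltas, recipients, "clinical_signs")
    for _, row in by_sign.iterrows():
        summary[f"delta_similarity_{row['level']}"] = float(row["mean_delta"])

    # -- genus shift -------------------------------------------------------
    genera = tested_genera(cohort, core_prevalence=cfg.core_prevalence,
                           min_recipient_prev=cfg.min_recipient_prev,
                           core=cfg.core_genera,
                           pathogenic=list(cfg.pathogenic_genera))
    gdeltas = delta_table(cohort, genera)
    _write("genus_deltas", gdeltas.reset_index())
    _write("genus_models", fit_genus_models(gdeltas, recipients))

    checksums = {p: _sha256(Path(p)) for p in
                 list(outputs.values()) + list(cohort_files.values())}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "cohort_files": cohort_files,
        "outputs": outputs,
        "checksums": checksums,
        "summary": summary,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, value in list(d.items()):
        if isinstance(value, tuple):
            d[key] = list(value)
    sim = d.get("simulation")
    if sim:
        for key, value in list(sim.items()):
            if isinstance(value, tuple):
                sim[key] = list(value)
    return json.loads(json.dumps(d, default=str))
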