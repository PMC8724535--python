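"""End-to-end orchestration: simulate/load -> QC -> PRS -> pPD -> associations.

Each stage writes a TSV/JSON artifact into the output directory and the
run finishes with a manifest (config hash, LR-table hash, seed, stage row
counts) so that identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, io, ppd, prs, qc
from .simulate import SimulationConfig, SyntheticCohort, inject_qc_failures, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("inputs", "qc", "prs", "ppd", "associate", "sensitivity")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation config or paths to real inputs."""

    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "dosage_tsv"  # or "vcf"
    sumstats_path: str | None = None
    markers_path: str | None = None
    lr_table_path: str | None = None
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    clump_params: prs.ClumpParams = field(default_factory=prs.ClumpParams)
    threshold_set: prs.ThresholdSet = field(default_factory=prs.ThresholdSet)
    inject_failures: dict[str, int] = field(default_factory=dict)
    fully_adjusted_variant: bool = False
    outdir: str = "ppdprs_run"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.genotypes_path is not None
        if self.simulation is None and not has_paths:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.simulation is not None and has_paths:
            raise ValueError("provide either a simulation config or input paths, not both")
        if has_paths and (self.sumstats_path is None or self.markers_path is None):
            raise ValueError("file inputs require genotypes, sumstats and markers paths")

    def content_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        doc = enc(self)
        doc.pop("outdir", None)  # where a run writes does not change what it computes
        blob = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_inputs(config: RunConfig) -> SyntheticCohort:
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        if config.inject_failures:
            cohort = inject_qc_failures(cohort, config.inject_failures, seed=config.seed + 7)
        return cohort
    if config.genotypes_format == "vcf":
        matrix, n_rejected = io.read_vcf(config.genotypes_path)
        if n_rejected:
            logger.warning("rejected %d multi-allelic VCF records", n_rejected)
    elif config.genotypes_format == "dosage_tsv":
        matrix = io.read_dosage_tsv(config.genotypes_path)
    else:
        raise ValueError(f"unknown genotype format {config.genotypes_format!r}")
    sumstats = io.read_sumstats_tsv(config.sumstats_path)
    profiles = io.read_markers_tsv(config.markers_path)
    return SyntheticCohort(
        genotypes=matrix,
        sumstats=sumstats,
        profiles=profiles,
        true_scores=pd.Series(np.nan, index=matrix.individual_ids),
        truth_log={},
        batch_labels=[],
        config=None,
    )


def build_analysis_frame(
    prs_result: prs.PrsResult,
    ppd_results: list[ppd.PpdResult],
    profiles: list[ppd.MarkerProfile],
    mdsc: pd.DataFrame,
) -> pd.DataFrame:
    """Join PRS, pPD results, marker profiles and ancestry covariates by id.

    One row per individual present in all four inputs; ids missing from
    any input raise with the orphan list.  Binary markers are coded
    present=1 / absent=0 / missing=NaN; sex is coded female=1.
    """
    ppd_by_id = {r.individual_id: r for r in ppd_results}
    prof_by_id = {p.individual_id: p for p in profiles}
    ids = [i for i in prs_result.scores.index if i in ppd_by_id and i in prof_by_id and i in mdsc.index]
    orphans = sorted(
        (set(prs_result.scores.index) ^ set(ppd_by_id)) | (set(prs_result.scores.index) ^ set(mdsc.index))
    )
    if not ids:
        raise ValueError(f"no individuals shared across inputs; orphans: {orphans[:10]}")

    state_code = {ppd.PRESENT: 1.0, ppd.ABSENT: 0.0, ppd.MISSING: np.nan}
    rows = []
    for sid in ids:
        r = ppd_by_id[sid]
        p = prof_by_id[sid]
        row = {
            "individual_id": sid,
            "age": p.age,
            "sex": 1.0 if p.sex == "female" else 0.0,
            "MDSC1": mdsc.loc[sid, "MDSC1"],
            "MDSC2": mdsc.loc[sid, "MDSC2"],
            "ppd_prob": r.posttest_prob,
            "pretest_prob": r.pretest_prob,
            "risk_lr": r.risk_lr,
            "prodromal_lr": r.prodromal_lr,
            "total_lr": r.total_lr,
            "ge_30": float(r.ge_30),
            "ge_50": float(r.ge_50),
            "ge_80": float(r.ge_80),
            "dementia": float(p.dementia_flag),
            "mci": float(p.mci_flag),
            "family_history": state_code.get(p.risk_markers.get("family_history_pd", ppd.MISSING), np.nan),
        }
        for name, state in p.prodromal_markers.items():
            row[f"marker_{name}"] = state_code[state]
        for d, v in p.cognitive_z.items():
            row[f"z_{d}"] = v
        for t in prs_result.scores.columns:
            row[f"prs_{t:g}"] = prs_result.scores.loc[sid, t]
            row[f"quartile_{t:g}"] = prs_result.quartiles.loc[sid, t]
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual_id")


def run_sensitivity(
    frame: pd.DataFrame,
    prs_result: prs.PrsResult,
    ppd_results: list[ppd.PpdResult],
    profiles: list[ppd.MarkerProfile],
    table: ppd.LikelihoodRatioTable,
    mdsc: pd.DataFrame,
    headline_threshold: float,
) -> pd.DataFrame:
    """The sensitivity battery around the headline threshold.

    Reruns the cut-off models after excluding dementia (then additionally
    MCI); recomputes pPD probability with the cognitive-deficit marker
    and then the family-history marker removed; splits the cohort by
    family history; and replaces the family-history marker by the PRS
    quartile scheme, comparing the resulting probability distributions.
    """
    t = headline_threshold
    exposure = f"prs_{t:g}"
    rows = []

    def add(results: pd.DataFrame, label: str) -> None:
        sub = results.copy()
        sub["analysis"] = label
        rows.append(sub)

    base_outcomes = [("ge_30", "binary"), ("ge_50", "binary")]

    for label, mask in [
        ("exclude_dementia", frame["dementia"] == 0),
        ("exclude_dementia_mci", (frame["dementia"] == 0) & (frame["mci"] == 0)),
        ("family_history_yes", frame["family_history"] == 1),
        ("family_history_no", frame["family_history"] == 0),
    ]:
        sub = frame.loc[mask]
        out = []
        for outcome, kind in base_outcomes + [("marker_cognitive_deficit", "binary")]:
            spec = assoc.ModelSpec(
                outcome,
                kind,
                exposure,
                ("MDSC1", "MDSC2") if outcome.startswith("ge_") else ("MDSC1", "MDSC2", "age", "sex"),
                subgroup=label,
            )
            try:
                out.append(assoc.fit_logistic(sub, spec).as_row())
            except ValueError as exc:
                logger.info("sensitivity %s / %s skipped: %s", label, outcome, exc)
        if out:
            add(pd.DataFrame(out), label)

    # marker-exclusion recalculations: drop one marker's LR for everyone
    quart = prs_result.quartiles[t].to_dict()
    for drop in ("cognitive_deficit", "family_history_pd"):
        redone, _ = ppd.recompute_excluding(profiles, table, drop)
        reframe = build_analysis_frame(prs_result, redone, profiles, mdsc)
        out = []
        for outcome, kind in base_outcomes:
            spec = assoc.ModelSpec(outcome, kind, exposure, ("MDSC1", "MDSC2"), subgroup=f"drop_{drop}")
            try:
                out.append(assoc.fit_logistic(reframe, spec).as_row())
            except ValueError as exc:
                logger.info("sensitivity drop_%s / %s skipped: %s", drop, outcome, exc)
        if out:
            add(pd.DataFrame(out), f"drop_{drop}")

    # PRS quartile as the genetic risk marker instead of family history
    substituted, _ = ppd.substitute_prs_marker(profiles, table, quart)
    base_prob = pd.Series({r.individual_id: r.posttest_prob for r in ppd_results})
    sub_prob = pd.Series({r.individual_id: r.posttest_prob for r in substituted})
    common = base_prob.index.intersection(sub_prob.index)
    stat, pval = assoc.group_compare(
        np.concatenate([base_prob[common], sub_prob[common]]),
        np.array(["family_history"] * len(common) + ["prs_quartile"] * len(common)),
        "non_normal",
    )
    add(
        pd.DataFrame(
            [
                {
                    "outcome": "ppd_prob",
                    "exposure": "marker_scheme",
                    "covariates": "",
                    "transform": "none",
                    "subgroup": "prs_quartile_substitution",
                    "scale": "median_shift",
                    "estimate": float(sub_prob[common].median() - base_prob[common].median()),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "pvalue": pval,
                    "n": len(common),
                    "converged": True,
                }
            ]
        ),
        "prs_quartile_substitution",
    )
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts under ``config.outdir``, return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }

    table = (
        ppd.LikelihoodRatioTable.from_yaml(config.lr_table_path)
        if config.lr_table_path
        else ppd.LikelihoodRatioTable.default()
    )
    manifest["lr_table_version"] = table.version
    manifest["lr_table_hash"] = table.source_hash

    cohort = load_inputs(config)
    io.write_sumstats_tsv(cohort.sumstats, outdir / "sumstats.tsv")
    io.write_markers_tsv(cohort.profiles, outdir / "markers.tsv")
    io.write_json(cohort.truth_log, outdir / "truth_log.json")
    manifest["stages"]["inputs"] = {
        "n_individuals": cohort.genotypes.n_individuals,
        "n_variants": cohort.genotypes.n_variants,
        "n_sumstats": len(cohort.sumstats),
    }

    clean, report = qc.run_qc(
        cohort.genotypes,
        config.qc_thresholds,
        cohort.batch_labels or None,
    )
    mdsc = report.mdsc
    io.write_json(
        {
            "excluded_samples": report.excluded_samples,
            "excluded_variants": report.excluded_variants,
            "summary_counts": report.summary_counts,
            "notes": report.notes,
        },
        outdir / "qc_report.json",
    )
    mdsc.to_csv(outdir / "mdsc.tsv", sep="\t")
    manifest["stages"]["qc"] = dict(report.summary_counts)

    prs_result = prs.build_prs(clean, cohort.sumstats, config.threshold_set, config.clump_params)
    prs_result.scores.rename(columns=lambda t: f"prs_{t:g}").to_csv(outdir / "prs_scores.tsv", sep="\t")
    manifest["stages"]["prs"] = {f"n_snps_{t:g}": n for t, n in prs_result.n_snps.items()}
    manifest["stages"]["prs"]["harmonization"] = prs_result.harmonization_counts

    kept_ids = set(clean.individual_ids)
    profiles = [p for p in cohort.profiles if p.individual_id in kept_ids]
    ppd_results, n_pd_dlb = ppd.compute_cohort(profiles, table)
    ppd_frame = pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "pretest_prob": r.pretest_prob,
                "risk_lr": r.risk_lr,
                "prodromal_lr": r.prodromal_lr,
                "total_lr": r.total_lr,
                "posttest_prob": r.posttest_prob,
                "ge_30": int(r.ge_30),
                "ge_50": int(r.ge_50),
                "ge_80": int(r.ge_80),
            }
            for r in ppd_results
        ]
    )
    ppd_frame.to_csv(outdir / "ppd_results.tsv", sep="\t", index=False)
    manifest["stages"]["ppd"] = {
        "n_computed": len(ppd_results),
        "n_pd_dlb_excluded": n_pd_dlb,
        "n_ge_30": int(ppd_frame["ge_30"].sum()),
        "n_ge_50": int(ppd_frame["ge_50"].sum()),
        "n_ge_80": int(ppd_frame["ge_80"].sum()),
    }

    frame = build_analysis_frame(prs_result, ppd_results, profiles, mdsc)
    frame.to_csv(outdir / "analysis_frame.tsv", sep="\t", na_rep="NA")
    battery = assoc.run_model_battery(
        frame,
        config.threshold_set.thresholds,
        fully_adjusted_variant=config.fully_adjusted_variant,
    )
    battery.to_csv(outdir / "associations.tsv", sep="\t", index=False, na_rep="NA")
    manifest["stages"]["associate"] = {"n_models": len(battery)}

    headline = 5e-8 if 5e-8 in config.threshold_set.thresholds else config.threshold_set.thresholds[0]
    sens = run_sensitivity(frame, prs_result, ppd_results, profiles, table, mdsc, headline)
    sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False, na_rep="NA")
    manifest["stages"]["sensitivity"] = {"n_models": len(sens), "headline_threshold": headline}

    manifest_blob = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    (outdir / "manifest.json").write_text(manifest_blob + "\n")
    logger.info("pipeline complete: %s", outdir)
    return manifest
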