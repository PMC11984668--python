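"""End-to-end pipeline: QC -> BMIQ -> deconvolution -> imputation ->
clocks -> acceleration -> concordance.

Driven by a :class:`PipelineConfig` (YAML/JSON), which either points at
measured inputs (beta matrices, manifest, control probes, clock
definitions, golden standard, cell references) or embeds a
simulate-block, in which case the synthetic generator provides
everything with known ground truth.  All outputs are tidy TSV tables
plus a JSON run manifest recording seeds and thresholds; given the
same config the outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmiq import normalize_matrix
from .clocks import (
    ClockDefinition,
    compute_acceleration,
    compute_estimates,
)
from .concordance import (
    ConcordanceError,
    compute_icc,
    control_probe_pcs,
    default_n_pcs,
    describe_cohort,
    pairwise_difference_table,
    partial_correlations,
    tissue_correlations,
)
from .containers import (
    BLOOD_TISSUES,
    ORAL_TISSUES,
    BetaMatrix,
    concat_compositions,
    read_manifest_tsv,
    read_matrix_tsv,
    validate_manifest,
    write_manifest_tsv,
    write_matrix_tsv,
)
from .deconvolution import (
    CellReference,
    choose_k,
    estimate_reference_based,
    fit_reference_free,
    select_variable_probes,
)
from .imputation import GoldenStandard, age_group_of, build_golden_standard, impute_missing
from .qc import QCThresholds, apply_qc
from .synthetic import (
    SimConfig,
    generate_clock_definitions,
    generate_cohort,
)

log = logging.getLogger("epiconcord")

STAGES = ("qc", "normalize", "deconvolve", "clocks", "concord")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.record = {"stage": stage, "error": str(cause), "type": type(cause).__name__}


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    bmiq: dict = field(default_factory=dict)
    imputation: dict = field(default_factory=dict)
    deconvolution: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of 'simulate' / 'inputs'"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    """Resolve inputs from the simulate-block or from file paths."""
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        if "n_cell_types" in sim_kwargs:
            sim_kwargs["n_cell_types"] = {
                k: int(v) for k, v in sim_kwargs["n_cell_types"].items()
            }
        sim = SimConfig(**sim_kwargs)
        betas, manifest, controls, truth = generate_cohort(sim)
        clocks = generate_clock_definitions(sim, truth)
        cell_refs = {
            t: CellReference(table=truth.cell_reference[t], tissues=(t,))
            for t in truth.cell_reference
            if t in BLOOD_TISSUES
        }
        return betas, manifest, controls, clocks, None, cell_refs, truth
    paths = config.inputs
    betas = {t: BetaMatrix.from_dir(p) for t, p in paths["beta"].items()}
    manifest = read_manifest_tsv(paths["manifest"])
    controls = read_matrix_tsv(paths["controls"])
    clocks = [ClockDefinition.from_dir(p) for p in paths["clocks"]]
    golden = (
        GoldenStandard.from_tsv(paths["golden"]) if paths.get("golden") else None
    )
    cell_refs = {}
    for tissue, p in paths.get("cell_references", {}).items():
        cell_refs[tissue] = CellReference(
            table=read_matrix_tsv(p), tissues=(tissue,)
        )
    return betas, manifest, controls, clocks, golden, cell_refs, None


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline; returns a result bundle of in-memory tables.

    ``stop_after`` may name a stage from ``STAGES`` to run a prefix of
    the pipeline (used by the CLI subcommands).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    def done(stage: str) -> bool:
        return stop_after is not None and STAGES.index(stop_after) < STAGES.index(stage)

    try:
        betas, manifest, controls, clocks, golden, cell_refs, truth = _load_inputs(
            config
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc
    bundle.update(manifest=manifest, clocks=clocks, truth=truth)

    # ---- QC ---------------------------------------------------------
    try:
        thresholds = QCThresholds(**config.qc)
        log.info("qc: thresholds %s", dataclasses.asdict(thresholds))
        sample_reports, probe_reports = [], []
        clean: dict[str, BetaMatrix] = {}
        for tissue, bm in betas.items():
            sub_manifest = manifest[manifest["tissue"] == tissue]
            filtered, s_rep, p_rep = apply_qc(bm, sub_manifest, thresholds)
            s_rep.insert(0, "tissue", tissue)
            p_rep.insert(0, "tissue", tissue)
            sample_reports.append(s_rep)
            probe_reports.append(p_rep)
            clean[tissue] = filtered
            log.info(
                "qc[%s]: kept %d/%d samples, %d/%d probes",
                tissue, filtered.shape[1], bm.shape[1],
                filtered.shape[0], bm.shape[0],
            )
        sample_report = pd.concat(sample_reports, ignore_index=True)
        probe_report = pd.concat(probe_reports, ignore_index=True)
        kept_samples = [s for bm in clean.values() for s in bm.sample_ids]
        manifest_kept = manifest[manifest["sample_id"].isin(kept_samples)].reset_index(
            drop=True
        )
        controls_kept = controls.loc[:, [c for c in controls.columns if c in kept_samples]]
        sample_report.to_csv(outdir / "sample_exclusions.tsv", sep="\t", index=False)
        probe_report.to_csv(outdir / "probe_exclusions.tsv", sep="\t", index=False)
        write_manifest_tsv(manifest_kept, outdir / "manifest_kept.tsv")
        bundle.update(
            betas=clean,
            manifest_kept=manifest_kept,
            sample_exclusions=sample_report,
            probe_exclusions=probe_report,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", exc) from exc
    if done("normalize"):
        _write_run_manifest(config, outdir)
        return bundle

    # ---- BMIQ -------------------------------------------------------
    try:
        bmiq_opts = dict(config.bmiq)
        normalized: dict[str, BetaMatrix] = {}
        for tissue, bm in clean.items():
            normalized[tissue] = normalize_matrix(bm, **bmiq_opts)
            log.info("bmiq[%s]: normalized %d samples", tissue, bm.shape[1])
            ndir = outdir / "normalized" / tissue
            ndir.mkdir(parents=True, exist_ok=True)
            write_matrix_tsv(normalized[tissue].values, ndir / "values.tsv")
        bundle["normalized"] = normalized
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("bmiq", exc) from exc
    if done("deconvolve"):
        _write_run_manifest(config, outdir)
        return bundle

    # ---- deconvolution ---------------------------------------------
    try:
        dec = dict(config.deconvolution)
        n_var = int(dec.get("n_variable_probes", 1000))
        n_boot = int(dec.get("n_boot", 20))
        trim = float(dec.get("trim", 0.25))
        k_lo, k_hi = dec.get("k_range", (1, 6))
        fixed_k = dec.get("fixed_k", {})
        compositions = {}
        profiles = {}
        for tissue, bm in normalized.items():
            if tissue in cell_refs:
                comp = estimate_reference_based(bm, cell_refs[tissue])
            else:
                n_use = min(n_var, bm.shape[0])
                probes = select_variable_probes(bm, n=n_use)
                sub = bm.values.loc[probes]
                if tissue in fixed_k:
                    k = int(fixed_k[tissue])
                else:
                    profile = choose_k(
                        sub,
                        k_range=range(int(k_lo), int(k_hi) + 1),
                        n_boot=n_boot,
                        trim=trim,
                        seed=config.seed,
                    )
                    profiles[tissue] = profile
                    k = profile.chosen_k
                    prof_df = profile.boot_deviances.copy()
                    prof_df.insert(0, "trimmed_mean", profile.trimmed_mean)
                    prof_df.rename_axis("K").to_csv(
                        outdir / f"deviance_{tissue}.tsv", sep="\t"
                    )
                _, omega, _ = fit_reference_free(sub, k, seed=config.seed)
                from .containers import CellComposition

                comp = CellComposition(
                    proportions=omega.div(omega.sum(axis=1), axis=0),
                    method="reference-free",
                    k=k,
                )
            compositions[tissue] = comp
            log.info("deconvolve[%s]: %s K=%d", tissue, comp.method, comp.k)
        comp_table = concat_compositions(compositions.values())
        comp_table.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        bundle.update(compositions=compositions, deviance_profiles=profiles)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("deconvolve", exc) from exc
    if done("clocks"):
        _write_run_manifest(config, outdir)
        return bundle

    # ---- golden standard + clocks + acceleration -------------------
    try:
        imp = dict(config.imputation)
        age_cut = float(imp.get("age_cut", 18.0))
        max_fraction = float(imp.get("max_fraction", 0.20))
        if golden is None:
            golden = build_golden_standard(normalized, manifest_kept, age_cut=age_cut)
        golden.to_tsv(outdir / "golden_standard.tsv")
        meta = manifest_kept.set_index("sample_id")
        est_frames = []
        imputed_counts: dict[str, int] = {}
        for tissue, bm in normalized.items():
            values = bm.values
            cols = {}
            for sid in values.columns:
                vec = values[sid]
                group = age_group_of(float(meta.loc[sid, "age_years"]), age_cut)
                completed = {}
                for clock in clocks:
                    if clock.kind == "pc":
                        continue
                    filled, rep = impute_missing(
                        vec,
                        clock.required_probes,
                        golden,
                        tissue,
                        group,
                        max_fraction=max_fraction,
                    )
                    completed[clock.name] = filled
                    imputed_counts[clock.name] = imputed_counts.get(
                        clock.name, 0
                    ) + len(rep)
                cols[sid] = (vec, completed)
            # score: linear/composite on completed vectors, pc directly
            rows = []
            for sid, (vec, completed) in cols.items():
                for clock in clocks:
                    use = vec if clock.kind == "pc" else completed[clock.name]
                    est = compute_estimates(
                        [clock], use.to_frame(sid), manifest_kept
                    )
                    rows.append(est)
            est_frames.append(pd.concat(rows, ignore_index=True))
        estimates = pd.concat(est_frames, ignore_index=True)
        estimates = compute_acceleration(estimates, manifest_kept)
        estimates.to_csv(outdir / "clock_estimates.tsv", sep="\t", index=False)
        bundle.update(estimates=estimates, golden=golden, imputed_counts=imputed_counts)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("clocks", exc) from exc
    if done("concord"):
        _write_run_manifest(config, outdir)
        return bundle

    # ---- concordance ------------------------------------------------
    try:
        conc = dict(config.concordance)
        descr = describe_cohort(manifest_kept)
        descr.rename_axis("metric").to_csv(outdir / "descriptives.tsv", sep="\t")
        tissues = sorted(set(manifest_kept["tissue"]))
        pairs = [
            (a, b) for i, a in enumerate(tissues) for b in tissues[i + 1 :]
        ]
        clock_names = [c.name for c in clocks]
        diffs = pairwise_difference_table(
            estimates, manifest_kept, clock_names, pairs
        )
        diffs.to_csv(outdir / "pairwise_differences.tsv", sep="\t", index=False)

        n_pcs = conc.get("n_pcs")
        n_pcs = default_n_pcs(controls_kept) if n_pcs is None else int(n_pcs)
        pcs, evr = control_probe_pcs(controls_kept, n_pcs)
        pcs.rename_axis("sample_id").to_csv(outdir / "control_pcs.tsv", sep="\t")

        corr_tables = {}
        icc_rows = []
        for clock in clocks:
            raw = tissue_correlations(estimates, manifest_kept, clock.name)
            raw.r.rename_axis("tissue").to_csv(
                outdir / f"correlations_{clock.name}_raw.tsv", sep="\t"
            )
            partial = partial_correlations(
                estimates,
                manifest_kept,
                {t: c.proportions for t, c in compositions.items()},
                pcs,
                clock.name,
            )
            partial.r.rename_axis("tissue").to_csv(
                outdir / f"correlations_{clock.name}_partial.tsv", sep="\t"
            )
            corr_tables[clock.name] = {"raw": raw, "partial": partial}
            for subset in _icc_tissue_subsets(manifest_kept):
                try:
                    icc = compute_icc(
                        estimates, manifest_kept, clock.name, tissues=subset
                    )
                except ConcordanceError:
                    continue
                tab = icc.table.copy()
                tab.insert(0, "clock", clock.name)
                tab.insert(1, "tissues", "+".join(subset))
                tab.insert(2, "n_persons", icc.n)
                tab.insert(3, "k_tissues", icc.k)
                icc_rows.append(tab)
        if icc_rows:
            pd.concat(icc_rows, ignore_index=True).to_csv(
                outdir / "icc.tsv", sep="\t", index=False
            )
        bundle.update(
            descriptives=descr,
            pairwise_differences=diffs,
            correlations=corr_tables,
            control_pcs=pcs,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("concord", exc) from exc

    _write_run_manifest(config, outdir)
    summary = {
        "n_samples_kept": int(len(manifest_kept)),
        "n_samples_excluded": int(len(sample_report)),
        "n_probes_excluded": int(len(probe_report)),
        "clocks": clock_names,
        "tissues": tissues,
        "chosen_k": {t: p.chosen_k for t, p in bundle.get("deviance_profiles", {}).items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    bundle["summary"] = summary
    return bundle


def _icc_tissue_subsets(manifest: pd.DataFrame) -> list[list[str]]:
    """Tissue subsets with a chance of listwise-complete persons."""
    subsets = []
    for cohort in ("child", "adult"):
        grp = manifest[manifest["cohort"] == cohort]
        tissues = sorted(set(grp["tissue"]))
        if len(tissues) >= 2:
            subsets.append(tissues)
    shared = sorted(
        set(manifest.loc[manifest["cohort"] == "child", "tissue"])
        & set(manifest.loc[manifest["cohort"] == "adult", "tissue"])
    )
    if len(shared) >= 2 and shared not in subsets:
        subsets.append(shared)
    return subsets


def _write_run_manifest(config: PipelineConfig, outdir: Path) -> None:
    record = {
        "package": "epiconcord",
        "version": __version__,
        "seed": config.seed,
        "qc_thresholds": dataclasses.asdict(QCThresholds(**config.qc)),
        "config": {
            "simulate": config.simulate,
            "inputs": config.inputs,
            "bmiq": config.bmiq,
            "imputation": config.imputation,
            "deconvolution": config.deconvolution,
            "concordance": config.concordance,
        },
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(record, indent=1, sort_keys=True, default=str)
    )
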