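"""End-to-end orchestration: simulate -> preprocess -> DE/signature ->
survival -> TCR -> transport, with seeded reproducibility and a manifest.

A single global seed expands deterministically into per-stage seeds; re-runs
with an unchanged effective configuration skip completed stages unless
forced.  The manifest records the parameter hash, per-stage seeds, status
and output paths (no timestamps, so identical runs are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonotype as clono
from . import io as cio
from . import pseudobulk as pb
from . import signature as sig
from . import survival as surv
from . import transport as tpt
from .datamodel import CohortDataset
from .errors import AnalysisError, ConfigError
from .preprocess import downsample_equal
from .simulate import SimConfig, ground_truth, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "split_by_mos"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "de_signature", "survival", "tcr", "transport")


def split_by_mos(survival: pd.DataFrame, arm: str = "LITT_PEM") -> pd.Series:
    """Survival-group labels from the arm's median overall survival.

    Patients of ``arm`` with OS strictly above the arm median are labelled
    LITT_GT_MOS; the rest of the arm (including any patient exactly at the
    median) LITT_LT_MOS.  Patients of the other arm keep the NLS_PEM label.
    """
    in_arm = survival["arm"] == arm
    if in_arm.sum() < 2:
        raise AnalysisError(f"need >= 2 patients in arm {arm} for the median split")
    os_arm = survival.loc[in_arm, "os_months"].astype(float)
    if os_arm.nunique() == 1:
        raise AnalysisError("all OS values equal; median split undefined")
    med = os_arm.median()
    labels = pd.Series("NLS_PEM", index=survival["patient"].tolist())
    labels[survival.loc[in_arm, "patient"].tolist()] = np.where(
        os_arm > med, "LITT_GT_MOS", "LITT_LT_MOS"
    )
    return labels


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output locations.

    When ``input_bundle`` is None the simulate stage generates the cohort;
    otherwise the bundle directory is loaded and simulate is skipped.
    """

    out_dir: str = "results"
    seed: int = 0
    input_bundle: str | None = None
    stages: tuple[str, ...] = STAGES
    sim: dict = field(default_factory=dict)
    de_cell_type: str = "non_classical_monocyte"
    de_tp_a: str = "PRE"
    de_tp_b: str = "C1"
    de_min_cells: int = 10
    top_k: int = 500
    n_perm: int = 1000
    gmt_path: str | None = None
    pathway_cell_types: tuple[str, ...] = ("CD8_T",)
    pathway_tp_a: str = "C1"
    pathway_tp_b: str = "C2"
    tcr_tp_a: str = "C1"
    tcr_tp_b: str = "C2"
    tcr_source_cluster: str = "CD8_CM"
    transport_cell_type: str = "CD8_T"
    transport_pairs: tuple[tuple[str, str], ...] = (("PRE", "C1"), ("C1", "C2"), ("C2", "C4"))
    transport_n_pc: int = 75
    transport_max_cells: int | None = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "transport_pairs" in raw:
            raw["transport_pairs"] = tuple(tuple(p) for p in raw["transport_pairs"])
        if "pathway_cell_types" in raw:
            raw["pathway_cell_types"] = tuple(raw["pathway_cell_types"])
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _load_dataset(config: PipelineConfig, out: Path) -> CohortDataset:
    if config.input_bundle is not None:
        return cio.load_cohort_dir(config.input_bundle)
    return cio.load_cohort_dir(out / "cohort")


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    A stage is skipped when its outputs exist for the current parameter hash
    and ``force`` is False; a stage failure is recorded and all downstream
    stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    phash = config.parameter_hash()
    previous: dict = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("parameter_hash") != phash:
            previous = {}
    manifest: dict = {"parameter_hash": phash, "seed": config.seed, "stages": {}}
    failed = False
    dataset: CohortDataset | None = None

    runners = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "de_signature": _stage_de_signature,
        "survival": _stage_survival,
        "tcr": _stage_tcr,
        "transport": _stage_transport,
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "disabled"}
            continue
        if failed:
            manifest["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        prev = previous.get("stages", {}).get(stage, {})
        outputs = prev.get("outputs", [])
        if (
            not force
            and prev.get("status") == "complete"
            and outputs
            and all(Path(p).exists() for p in outputs)
        ):
            manifest["stages"][stage] = prev
            logger.info("stage %s: up to date, skipping", stage)
            continue
        seed = config.stage_seed(stage)
        logger.info("stage %s: running (seed %d)", stage, seed)
        try:
            if dataset is None and stage != "simulate":
                dataset = _load_dataset(config, out)
            produced = runners[stage](config, out, seed, dataset, state)
            manifest["stages"][stage] = {
                "status": "complete",
                "seed": seed,
                "outputs": [str(p) for p in produced],
            }
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": f"failed: {exc}", "seed": seed}
            failed = True
    _write_json(manifest_path, manifest)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config, out: Path, seed: int, dataset, state) -> list[Path]:
    if config.input_bundle is not None:
        return [Path(config.input_bundle)]
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", seed)
    sim = SimConfig(**sim_kwargs)
    ds = simulate_cohort(sim)
    paths = cio.save_cohort(ds, out / "cohort")
    truth = ground_truth(sim)
    truth_path = out / "cohort" / "truth.json"
    _write_json(
        truth_path,
        {
            "de_genes": truth.de_genes,
            "hr": truth.hr,
            "activity": truth.activity,
            "transition_matrices": {
                g: [m.tolist() for m in ms] for g, ms in truth.transition_matrices.items()
            },
        },
    )
    gmt_path = out / "cohort" / "pathways.gmt"
    with open(gmt_path, "w", encoding="utf-8") as fh:
        fh.write("DE_PROGRAM\tsynthetic\t" + "\t".join(truth.de_genes) + "\n")
        markers = [g for g in ds.gene_ids[: min(60, len(ds.gene_ids))]]
        fh.write("CELLTYPE_MARKERS\tsynthetic\t" + "\t".join(markers) + "\n")
    return [*paths.values(), truth_path, gmt_path]


def _stage_preprocess(config, out: Path, seed: int, dataset, state) -> list[Path]:
    mask = downsample_equal(dataset, ["survival_group", "timepoint"], seed=seed)
    qc = (
        dataset.cell_meta.groupby(["survival_group", "timepoint"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    qc["n_after_downsample"] = (
        dataset.cell_meta.loc[mask]
        .groupby(["survival_group", "timepoint"], observed=True)
        .size()
        .reindex(qc.set_index(["survival_group", "timepoint"]).index)
        .to_numpy()
    )
    p = out / "qc_cell_counts.tsv"
    qc.to_csv(p, sep="\t", index=False)
    return [p]


def _stage_de_signature(config, out: Path, seed: int, dataset, state) -> list[Path]:
    groups = split_by_mos(dataset.survival)
    litt = sorted(groups.index[groups != "NLS_PEM"])
    long_patients = sorted(groups.index[groups == "LITT_GT_MOS"])
    pbm = pb.aggregate_pseudobulk(
        dataset, config.de_cell_type, (config.de_tp_a, config.de_tp_b),
        min_cells=config.de_min_cells, patients=litt,
    )
    results = pb.fit_nb_lrt(pbm)
    de_path = out / "de_table.tsv"
    results.table.to_csv(de_path, sep="\t")
    signature = pb.top_k_by_fdr(results, k=config.top_k)
    sig_path = out / "signature_genes.txt"
    sig_path.write_text("\n".join(signature) + "\n")
    fc = pb.per_patient_log2fc(
        dataset, list(dataset.gene_ids), config.de_cell_type,
        config.de_tp_a, config.de_tp_b, min_cells=config.de_min_cells, patients=litt,
    )
    z = sig.zscore_from_fc_table(fc, long_patients)
    ranked = sig.rank_genes(z)
    rank_path = out / "ranked_genes.rnk"
    ranked.rename("z").to_csv(rank_path, sep="\t", header=False)
    present = [g for g in signature if g in set(ranked.index)]
    gsea = sig.gsea_permutation(ranked, present, n_perm=config.n_perm, seed=seed)
    gsea_path = out / "gsea.json"
    _write_json(gsea_path, dataclasses.asdict(gsea))
    score = sig.composite_score(fc, signature)
    score_path = out / "signature_scores.tsv"
    pd.DataFrame({"score": score.scores, "group": score.groups}).rename_axis(
        "patient"
    ).to_csv(score_path, sep="\t")
    state["score"] = score
    state["fc"] = fc
    outputs = [de_path, sig_path, rank_path, gsea_path, score_path]
    gmt = config.gmt_path or str(out / "cohort" / "pathways.gmt")
    if Path(gmt).exists():
        pathways = cio.read_gmt(gmt)
        table = sig.signal_change_table(
            dataset, pathways, list(config.pathway_cell_types),
            config.pathway_tp_a, config.pathway_tp_b,
        )
        comp = sig.compare_signal_change(table)
        t_path = out / "pathway_signal_change.tsv"
        c_path = out / "pathway_arm_comparison.tsv"
        table.to_csv(t_path, sep="\t", index=False)
        comp.to_csv(c_path, sep="\t", index=False)
        outputs += [t_path, c_path]
    return outputs


def _stage_survival(config, out: Path, seed: int, dataset, state) -> list[Path]:
    score = state.get("score")
    if score is None:
        scores = pd.read_csv(out / "signature_scores.tsv", sep="\t", index_col="patient")
        groups = scores["group"]
    else:
        groups = score.groups
    cox = surv.cox_age_adjusted(dataset.survival, groups)
    km = surv.km_logrank(dataset.survival, groups)
    cox_path = out / "cox_signature.json"
    _write_json(
        cox_path,
        {
            "hr": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high,
            "wald_p": cox.wald_p, "schoenfeld_p": cox.schoenfeld_p,
            "penalized": cox.penalized,
        },
    )
    km_path = out / "km_by_signature.tsv"
    km.medians.assign(logrank_p=km.logrank_p).to_csv(km_path, sep="\t", index=False)
    return [cox_path, km_path]


def _stage_tcr(config, out: Path, seed: int, dataset, state) -> list[Path]:
    table = clono.diversity_table(dataset)
    div_path = out / "tcr_diversity.tsv"
    table.to_csv(div_path, sep="\t", index=False)
    comp = clono.compare_diversity(table, config.tcr_tp_a, config.tcr_tp_b)
    comp_path = out / "tcr_diversity_tests.tsv"
    comp["between_cohorts"].to_csv(comp_path, sep="\t", index=False)
    fate = clono.clone_fate(
        dataset, config.tcr_source_cluster, config.tcr_tp_a, config.tcr_tp_b
    )
    fate_path = out / "clone_fate.tsv"
    fate.counts.to_csv(fate_path, sep="\t")
    outputs = [div_path, comp_path, fate_path]
    if fate.counts.shape[0] >= 2 and fate.counts.shape[1] >= 2:
        stat, dof, p = clono.chi_square_independence(fate)
        chi_path = out / "clone_fate_chi2.json"
        _write_json(chi_path, {"statistic": stat, "df": dof, "p_value": p})
        outputs.append(chi_path)
    return outputs


def _stage_transport(config, out: Path, seed: int, dataset, state) -> list[Path]:
    summaries = tpt.transition_pipeline(
        dataset,
        config.transport_cell_type,
        [tuple(p) for p in config.transport_pairs],
        n_pc=config.transport_n_pc,
        seed=seed,
        max_cells_per_side=config.transport_max_cells,
    )
    outputs: list[Path] = []
    for cohort, pairs in summaries.items():
        for (tp_a, tp_b), summary in pairs.items():
            stem = f"transport_{cohort}_{tp_a}-{tp_b}"
            fp = out / f"{stem}_fractions.tsv"
            summary.target_fractions.to_csv(fp, sep="\t")
            ap = out / f"{stem}_arrows.tsv"
            summary.cluster_arrows.to_csv(ap, sep="\t", index=False)
            outputs += [fp, ap]
    if not outputs:
        raise AnalysisError("transport stage produced no summaries")
    return outputs
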