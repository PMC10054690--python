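"""End-to-end analysis pipeline: load -> score -> binarize -> group ->
agreement + ROC -> tables.

Produces the three reporting tables of a multi-reader observer study — the
per-group inter-observer table (Fleiss' kappa, unanimity % agreement and
diagonally averaged AUC, each with bootstrap CIs), the intra-observer table
for dual-session readers (Cohen's kappa, % agreement), and pairwise group
comparisons (permutation p-values for agreement metrics, bootstrap z-test
for AUC) — plus per-observer ROC curve exports and a run manifest.

Everything is computed in memory first and written at the end, so a failing
stage leaves no partial output.  The whole bundle is a pure function of the
input files, the configuration and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import roc as roc_mod
from .study_data import (
    GROUP_NAMES,
    GroupCutoffs,
    ScoreMatrix,
    binarize_scores,
    group_members,
    read_annotations,
    read_observers,
    read_reference,
    slice_scores,
)

__all__ = ["AnalysisConfig", "ReportBundle", "PipelineError", "run_analysis"]

logger = logging.getLogger("readerstudy")

SIGNIFICANCE_LEVEL = 0.05


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs, cutoffs, resampling sizes and seed for one analysis run."""

    annotations_path: str | Path
    observers_path: str | Path
    reference_path: str | Path
    cutoffs: GroupCutoffs = GroupCutoffs()
    n_boot: int = agr.DEFAULT_N_BOOT
    n_perm: int = agr.DEFAULT_N_PERM
    ci_level: float = agr.DEFAULT_CI_LEVEL
    seed: int = 0
    out_dir: str | Path | None = None

    def digest(self) -> str:
        doc = {
            "annotations": str(self.annotations_path),
            "observers": str(self.observers_path),
            "reference": str(self.reference_path),
            "cutoffs": asdict(self.cutoffs),
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "ci_level": self.ci_level,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


@dataclass
class ReportBundle:
    """All tables and curves produced by one analysis run."""

    group_agreement: pd.DataFrame
    intra_observer: pd.DataFrame
    comparisons: pd.DataFrame
    observer_curves: dict[str, pd.DataFrame]
    group_curves: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.group_agreement.to_csv(out / "group_agreement.csv", index=False)
        self.intra_observer.to_csv(out / "intra_observer.csv", index=False)
        self.comparisons.to_csv(out / "group_comparisons.csv", index=False)
        curves_dir = out / "roc_curves"
        curves_dir.mkdir(exist_ok=True)
        for obs, df in self.observer_curves.items():
            df.to_csv(curves_dir / f"observer_{obs}.csv", index=False)
        for grp, df in self.group_curves.items():
            df.to_csv(curves_dir / f"group_{grp}.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(name: str):
    """Decorator tagging pipeline stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return inner

    return wrap


@_stage("load")
def _load(config: AnalysisConfig):
    records = read_annotations(config.annotations_path)
    profiles = read_observers(config.observers_path)
    reference = read_reference(config.reference_path)
    logger.info(
        "loaded %d annotations, %d observers, %d slices",
        len(records),
        len(profiles),
        len(reference.slice_labels),
    )
    return records, profiles, reference


@_stage("score")
def _score(records, profiles, reference):
    slices = list(reference.slice_labels.index)
    observers = [p.observer_id for p in profiles]
    scores1 = slice_scores(records, slices, observers, session=1)
    session2_observers = sorted(
        {r.observer_id for r in records if r.session == 2},
        key=observers.index,
    )
    scores2 = None
    if session2_observers:
        full2 = slice_scores(records, slices, observers, session=2)
        scores2 = ScoreMatrix(full2.scores[session2_observers], session=2)
    logger.info(
        "scored %d slices x %d observers (session 2: %d observers)",
        len(slices),
        len(observers),
        len(session2_observers),
    )
    return scores1, scores2


@_stage("agreement")
def _agreement_tables(labels1, members, config, seed_for):
    rows = []
    for group in GROUP_NAMES:
        obs = members[group]
        if len(obs) < 2:
            continue  # empty or singleton groups are absent, not an error
        sub = labels1.labels[obs].to_numpy()
        row = {"group": group, "n_observers": len(obs)}
        for metric in ("fleiss_kappa", "pct_agreement"):
            try:
                est = agr.bootstrap_ci(
                    metric,
                    sub,
                    n_boot=config.n_boot,
                    ci_level=config.ci_level,
                    seed=seed_for(f"boot:{metric}:{group}"),
                )
            except agr.UndefinedKappaError:
                row[metric] = np.nan
                row[f"{metric}_ci_low"] = np.nan
                row[f"{metric}_ci_high"] = np.nan
                continue
            row[metric] = est.value
            row[f"{metric}_ci_low"] = est.ci_low
            row[f"{metric}_ci_high"] = est.ci_high
            if est.n_dropped:
                logger.warning(
                    "%s/%s: %d undefined-kappa resamples dropped",
                    group,
                    metric,
                    est.n_dropped,
                )
        row["fleiss_interpretation"] = (
            agr.kappa_interpretation(row["fleiss_kappa"])
            if np.isfinite(row.get("fleiss_kappa", np.nan))
            else ""
        )
        rows.append(row)
    return rows


@_stage("roc")
def _roc_tables(scores1, reference, members, consensus_ids, config, seed_for, rows):
    observer_curves: dict[str, pd.DataFrame] = {}
    group_curves: dict[str, pd.DataFrame] = {}
    curves_by_obs: dict[str, roc_mod.ROCCurve] = {}
    for obs in scores1.observers:
        if obs in consensus_ids:
            continue  # consensus readers set the reference; no ROC for them
        curve = roc_mod.roc_curve(
            scores1.scores[obs].to_numpy(),
            reference.slice_labels.to_numpy(),
            observer_id=obs,
        )
        curves_by_obs[obs] = curve
        thresholds = [np.nan] + sorted(
            np.unique(scores1.scores[obs].to_numpy()), reverse=True
        )
        observer_curves[obs] = pd.DataFrame(
            {
                "observer_id": obs,
                "threshold": thresholds,
                "fpr": curve.fpr,
                "tpr": curve.tpr,
                "auc": curve.auc,
            }
        )
    auc_by_group: dict[str, roc_mod.GroupAUCSummary] = {}
    for row in rows:
        group = row["group"]
        obs = [o for o in members[group] if o not in consensus_ids]
        if group == "consensus" or len(obs) < 2:
            row["mean_auc"] = np.nan
            row["mean_auc_ci_low"] = np.nan
            row["mean_auc_ci_high"] = np.nan
            continue
        summary = roc_mod.group_auc_summary(
            scores1.scores[obs],
            reference,
            n_boot=config.n_boot,
            seed=seed_for(f"boot:auc:{group}"),
            group=group,
        )
        auc_by_group[group] = summary
        row["mean_auc"] = summary.mean_auc
        row["mean_auc_ci_low"] = summary.ci_low
        row["mean_auc_ci_high"] = summary.ci_high
        avg = roc_mod.diagonal_average([curves_by_obs[o] for o in obs])
        group_curves[group] = pd.DataFrame(
            {"group": group, "fpr": avg.fpr, "tpr": avg.tpr, "auc": avg.auc}
        )
    logger.info(
        "ROC analysis: %d observer curves, %d group summaries",
        len(observer_curves),
        len(auc_by_group),
    )
    return observer_curves, group_curves


@_stage("intra_observer")
def _intra_table(labels1, labels2, config, seed_for):
    rows = []
    if labels2 is None:
        return rows
    for obs in labels2.observers:
        paired = np.column_stack(
            [labels1.labels[obs].to_numpy(), labels2.labels[obs].to_numpy()]
        )
        row = {"observer_id": obs}
        for metric in ("cohen_kappa", "pct_agreement"):
            try:
                est = agr.bootstrap_ci(
                    metric,
                    paired,
                    n_boot=config.n_boot,
                    ci_level=config.ci_level,
                    seed=seed_for(f"boot:intra:{metric}:{obs}"),
                )
            except agr.UndefinedKappaError:
                row[metric] = np.nan
                row[f"{metric}_ci_low"] = np.nan
                row[f"{metric}_ci_high"] = np.nan
                continue
            row[metric] = est.value
            row[f"{metric}_ci_low"] = est.ci_low
            row[f"{metric}_ci_high"] = est.ci_high
        rows.append(row)
    return rows


@_stage("comparisons")
def _comparisons(labels1, scores1, reference, members, consensus_ids, config, seed_for):
    rows = []

    def add(metric, name_a, name_b, result):
        rows.append(
            {
                "metric": metric,
                "group_a": name_a,
                "group_b": name_b,
                "delta": result.delta,
                "p_value": result.p_value,
                "significant": result.p_value < SIGNIFICANCE_LEVEL,
            }
        )

    pairs = [(f"high-{dim}", f"low-{dim}") for dim in ("year", "cine", "adhesion")]
    pairs += [("consensus", g) for g in GROUP_NAMES if g != "consensus"]
    for name_a, name_b in pairs:
        obs_a, obs_b = members[name_a], members[name_b]
        if len(obs_a) < 2 or len(obs_b) < 2 or set(obs_a) & set(obs_b):
            continue
        for metric in ("fleiss_kappa", "pct_agreement"):
            try:
                res = agr.permutation_test(
                    metric,
                    labels1.labels[obs_a].to_numpy(),
                    labels1.labels[obs_b].to_numpy(),
                    n_perm=config.n_perm,
                    seed=seed_for(f"perm:{metric}:{name_a}:{name_b}"),
                    group_a=name_a,
                    group_b=name_b,
                )
            except agr.UndefinedKappaError:
                continue
            add(metric, name_a, name_b, res)
        roc_a = [o for o in obs_a if o not in consensus_ids]
        roc_b = [o for o in obs_b if o not in consensus_ids]
        if len(roc_a) >= 2 and len(roc_b) >= 2:
            res = roc_mod.compare_group_auc(
                scores1.scores[roc_a],
                scores1.scores[roc_b],
                reference,
                n_boot=config.n_boot,
                seed=seed_for(f"boot:auc-cmp:{name_a}:{name_b}"),
                group_a=name_a,
                group_b=name_b,
            )
            add("mean_auc", name_a, name_b, res)
    return rows


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full slice-level analysis and (optionally) write the bundle.

    Stages: load, score, binarize, group, agreement, ROC, intra-observer,
    comparisons, manifest.  Any stage error propagates as
    :class:`PipelineError` naming the stage; output files are only written
    once every stage has succeeded, so failures leave no partial bundle.
    """
    records, profiles, reference = _load(config)
    n_consensus = sum(p.is_consensus for p in profiles)
    if len(profiles) - n_consensus < 2:
        raise PipelineError(
            "stage 'validate': need at least 2 non-consensus observers, got "
            f"{len(profiles) - n_consensus}"
        )
    consensus_ids = {p.observer_id for p in profiles if p.is_consensus}

    # deterministic per-task seeds: hash the task label with the run seed
    def seed_for(label: str) -> int:
        digest = hashlib.sha256(f"{config.seed}:{label}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    scores1, scores2 = _score(records, profiles, reference)
    profile_map = {p.observer_id: p for p in profiles}
    labels1 = binarize_scores(scores1, profile_map)
    labels2 = binarize_scores(scores2, profile_map) if scores2 is not None else None
    members = group_members(profiles, config.cutoffs)

    rows = _agreement_tables(labels1, members, config, seed_for)
    observer_curves, group_curves = _roc_tables(
        scores1, reference, members, consensus_ids, config, seed_for, rows
    )
    intra_rows = _intra_table(labels1, labels2, config, seed_for)
    comparison_rows = _comparisons(
        labels1, scores1, reference, members, consensus_ids, config, seed_for
    )

    from . import __version__

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "readerstudy_version": __version__,
        "n_boot": config.n_boot,
        "n_perm": config.n_perm,
        "ci_level": config.ci_level,
        "cutoffs": asdict(config.cutoffs),
        "n_annotations": len(records),
        "n_observers": len(profiles),
        "n_consensus_observers": n_consensus,
        "n_slices": int(len(reference.slice_labels)),
        "n_positive_slices": reference.n_positive_slices,
        "groups": {g: members[g] for g in GROUP_NAMES if members[g]},
    }

    bundle = ReportBundle(
        group_agreement=pd.DataFrame(rows),
        intra_observer=pd.DataFrame(intra_rows),
        comparisons=pd.DataFrame(comparison_rows),
        observer_curves=observer_curves,
        group_curves=group_curves,
        manifest=manifest,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
        logger.info("report bundle written to %s", config.out_dir)
    return bundle
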