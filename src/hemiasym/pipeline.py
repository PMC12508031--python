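"""End-to-end orchestration: simulate → asymmetry → adjust → aggregate →
rank → coupling → PLS → accuracy → covariate effects, with every table
written next to a provenance record (config, seed, package version)."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import (
    accuracy_correlations,
    extract_accuracy,
    run_accuracy_prediction,
)
from .asymmetry import verify_correspondence
from .coupling import compare_poly_aic, network_coupling, selected_degree, vertexwise_coupling
from .group_stats import grand_mean_scale, one_sample_t_map, residualize_age, split_matched
from .networks import aggregate_cohort_arrays, motor_vs_average, rank_epochs, rank_networks
from .pls import (
    build_feature_matrix,
    cross_cohort_validate,
    fit_pls,
    score_covariate_effects,
    select_components_cv,
)
from .synthetic import Cohort, CohortConfig, generate_cohort
from .vocab import ACCURACY_EPOCHS, MAJOR_NETWORKS

log = logging.getLogger("hemiasym")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run on a synthetic cohort."""

    n_subjects: int = 200
    n_vertices: int = 48
    seed: int = 0
    split_ratio: float = 0.51
    n_components: int = 12
    cv_folds: int = 10
    select_components: bool = False
    adjust_covariates: bool = True
    fisher_z: bool = False
    sigma_subject: float = 0.15
    sigma_vertex: float = 0.10
    sigma_accuracy: float = 0.05
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _adjust(matrix_values: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Age regression then categorical (sex × race) re-centering."""
    adjusted = residualize_age(matrix_values, subjects["age"].to_numpy())
    return grand_mean_scale(adjusted, subjects[["sex", "race"]])


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the full analysis and return a results bundle.

    Deterministic for a fixed config; if ``output_dir`` is set, every
    table is written there along with a JSON provenance report.
    """
    from . import io as hio

    report: dict = {"config": config.to_dict(), "config_digest": config.digest(),
                    "version": __version__}
    stage = "simulate"
    try:
        if cohort is None:
            cohort = generate_cohort(
                CohortConfig(
                    n_subjects=config.n_subjects,
                    n_vertices=config.n_vertices,
                    sigma_subject=config.sigma_subject,
                    sigma_vertex=config.sigma_vertex,
                    sigma_accuracy=config.sigma_accuracy,
                    seed=config.seed,
                )
            )
        subjects = cohort.subjects
        report["n_subjects"] = cohort.n_subjects
        report["n_vertices"] = cohort.n_vertices
        report["accuracy_clip_fraction"] = cohort.accuracy_clip_fraction

        stage = "correspondence"
        corr = verify_correspondence(cohort.pair(cohort.subject_ids[0], cohort.epochs[0]))
        report["correspondence"] = {
            "r": list(corr.correlations), "passed": corr.passed,
        }

        stage = "asymmetry"
        asym = cohort.asymmetry()
        amp = cohort.amplitude()

        stage = "aggregate"
        nem_amp = aggregate_cohort_arrays(
            amp, cohort.partition, cohort.subject_ids, cohort.epochs, "amplitude"
        )
        nem_asym = aggregate_cohort_arrays(
            asym, cohort.partition, cohort.subject_ids, cohort.epochs, "asymmetry"
        )
        if config.adjust_covariates:
            nem_amp.values = _adjust(nem_amp.values, subjects)
            nem_asym.values = _adjust(nem_asym.values, subjects)

        stage = "vertex_stats"
        story_idx = cohort.epochs.index("story")
        tmap = one_sample_t_map(asym[:, story_idx, :])
        report["story_asymmetry_significant_fraction"] = float(tmap.significant.mean())

        stage = "rank"
        net_rank = rank_networks(nem_asym)
        epoch_rank = rank_epochs(nem_asym)
        motor = motor_vs_average(nem_amp)
        report["network_ranking"] = {k: float(v) for k, v in net_rank.items()}
        report["epoch_ranking"] = {k: float(v) for k, v in epoch_rank.items()}

        stage = "coupling"
        vcoup = vertexwise_coupling(amp, asym, fisher_z=config.fisher_z)
        ncoup = network_coupling(nem_amp, nem_asym)
        top = ncoup.r.stack().idxmax()
        report["strongest_network_coupling"] = {
            "network": top[0], "epoch": top[1], "r": float(ncoup.r.loc[top]),
        }
        report["n_undefined_correlations"] = int(ncoup.n_undefined)

        stage = "poly_aic"
        lan_story_amp = nem_amp.cell("LAN", "story")
        lan_story_asym = nem_asym.cell("LAN", "story")
        aic = compare_poly_aic(lan_story_amp, lan_story_asym)
        report["lan_story_aic_selected_degree"] = selected_degree(aic)

        stage = "split"
        split = split_matched(subjects, ratio=config.split_ratio, seed=config.seed)
        report["split"] = {
            "n_discovery": len(split.discovery_ids),
            "n_replication": len(split.replication_ids),
            "balance_p_min": float(split.balance_report["p"].min()),
        }

        stage = "pls_asymmetry"
        X_all = build_feature_matrix(nem_amp)
        Y_all = build_feature_matrix(nem_asym)
        ids_d, ids_r = split.discovery_ids, split.replication_ids
        ncomp = min(config.n_components, len(ids_d) - 1, len(ids_r) - 1)
        if config.select_components:
            ncomp, _ = select_components_cv(
                X_all.loc[ids_d], Y_all.loc[ids_d], k=config.cv_folds,
                max_components=ncomp, seed=config.seed,
            )
        pls_asym = cross_cohort_validate(
            X_all.loc[ids_d], Y_all.loc[ids_d], X_all.loc[ids_r], Y_all.loc[ids_r],
            n_components=ncomp, seed=config.seed,
        )
        model_d = pls_asym["discovery_to_replication"]["model"]
        report["pls_asymmetry"] = {
            "n_components": ncomp,
            "n_predictors": X_all.shape[1],
            "explained_variance_x_pct": float(
                100 * model_d.cumulative_explained_variance_x[-1]
            ),
            "mean_test_r": float(np.mean([
                pls_asym[d]["test"].mean_r for d in pls_asym
            ])),
            "significant_test_cells": int(
                pls_asym["discovery_to_replication"]["test"].mask.sum()
            ),
        }

        stage = "accuracy_correlations"
        acc_assoc = accuracy_correlations(nem_amp, nem_asym, subjects)
        lan_story = {
            m: acc_assoc.cell("LAN", "story", m)["r2"] for m in ("amplitude", "asymmetry")
        }
        report["lan_story_accuracy_r2"] = {k: float(v) for k, v in lan_story.items()}

        stage = "accuracy_prediction"
        features = {}
        accur = {}
        for name, ids in (("discovery", ids_d), ("replication", ids_r)):
            features[name] = {
                "amplitude": X_all.loc[ids],
                "asymmetry": Y_all.loc[ids],
            }
            accur[name] = extract_accuracy(subjects).loc[ids]
        acc_pred = run_accuracy_prediction(
            features, accur, n_components=config.n_components, seed=config.seed
        )
        report["accuracy_prediction"] = {
            m: {
                "mean_test_r": float(acc_pred["summary"].loc[m, "mean_test_r"]),
                "mean_train_r": float(acc_pred["summary"].loc[m, "mean_train_r"]),
            }
            for m in ("amplitude", "asymmetry", "both")
        }

        stage = "covariate_effects"
        model_acc = acc_pred["amplitude"]["discovery_to_replication"]["model"]
        scores = model_acc.transform(features["discovery"]["amplitude"])
        cov = score_covariate_effects(
            scores, subjects.set_index("subject_id").loc[ids_d].reset_index()
        )
        report["covariate_effects"] = {
            "min_p_sex": float(cov["p_sex"].min()),
            "min_p_age": float(cov["p_age"].min()),
        }
    except Exception as err:  # noqa: BLE001 - halt with the stage name
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        out = config.output_dir
        hio.write_subject_table(subjects, os.path.join(out, "subjects.csv"))
        hio.write_matrix(nem_amp, os.path.join(out, "network_amplitude.csv"))
        hio.write_matrix(nem_asym, os.path.join(out, "network_asymmetry.csv"))
        hio.write_matrix(motor, os.path.join(out, "motor_contrast.csv"))
        hio.write_split(split, os.path.join(out, "split.csv"))
        hio.write_stat_map(tmap, os.path.join(out, "story_asymmetry_tmap.csv"))
        ncoup.r.to_csv(os.path.join(out, "network_coupling_r.csv"))
        acc_assoc.table.to_csv(os.path.join(out, "accuracy_correlations.csv"), index=False)
        hio.write_yaml(config.to_dict(), os.path.join(out, "config.yaml"))
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    report["_objects"] = {
        "cohort": cohort,
        "nem_amp": nem_amp,
        "nem_asym": nem_asym,
        "split": split,
        "pls_asymmetry": pls_asym,
        "accuracy_prediction": acc_pred,
        "coupling_vertex": vcoup,
        "coupling_network": ncoup,
        "tmap": tmap,
    }
    return report
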