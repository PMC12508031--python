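"""Brain-behavior accuracy analyses.

Univariate Pearson associations between per-epoch task accuracy and
network-level amplitude or asymmetry, and orchestration of the
multivariate accuracy-prediction experiments (amplitude-only,
asymmetry-only and combined PLS models with cross-cohort validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .networks import NetworkEpochMatrix
from .pls import cross_cohort_validate
from .vocab import ACCURACY_EPOCHS, CONTROL_EPOCHS, MAJOR_NETWORKS, TASK_EPOCHS


@dataclass
class AccuracyAssociation:
    """Per (network, epoch, measure) accuracy correlations.

    ``table`` is tidy with columns network, epoch, measure, epoch_role,
    r, p, r2, plus two significance masks: ``significant_bonferroni``
    (p < α / family size per measure) and ``significant_display``
    (p < 0.001, the display threshold).  Cells with undefined
    correlations (e.g. ceiling-effect accuracy with zero variance) are
    reported as missing, never zero-filled.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    family_size: int = 0
    n_undefined: int = 0

    def cell(self, network: str, epoch: str, measure: str) -> pd.Series:
        t = self.table
        sel = t[(t.network == network) & (t.epoch == epoch) & (t.measure == measure)]
        if sel.empty:
            raise KeyError((network, epoch, measure))
        return sel.iloc[0]


def extract_accuracy(subjects: pd.DataFrame, epochs=ACCURACY_EPOCHS) -> pd.DataFrame:
    """Subjects × epoch accuracy matrix from the covariate table."""
    cols = {e: f"accuracy_{e}" for e in epochs}
    missing = [c for c in cols.values() if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table lacks accuracy columns: {missing}")
    out = subjects[list(cols.values())].copy()
    out.columns = list(cols.keys())
    out.index = pd.Index(subjects["subject_id"], name="subject")
    return out


def accuracy_correlations(
    matrix_a: NetworkEpochMatrix,
    matrix_d: NetworkEpochMatrix,
    subjects: pd.DataFrame,
    networks=MAJOR_NETWORKS,
    alpha: float = 0.05,
    display_p: float = 0.001,
) -> AccuracyAssociation:
    """Correlate per-epoch accuracy with same-epoch network measures.

    For every non-motor epoch and network, Pearson r across subjects
    between that epoch's accuracy and the network's amplitude and
    asymmetry in the same epoch.  Task and control epochs are labeled so
    they can be reported separately.
    """
    acc = extract_accuracy(subjects)
    networks = [k for k in networks if k in matrix_a.networks]
    family = len(networks) * len(acc.columns)
    rows = []
    n_undef = 0
    for measure, matrix in (("amplitude", matrix_a), ("asymmetry", matrix_d)):
        aligned = matrix.values.reindex(index=acc.index)
        for e in acc.columns:
            y = acc[e].to_numpy(float)
            role = "task" if e in TASK_EPOCHS else ("control" if e in CONTROL_EPOCHS else "other")
            for k in networks:
                x = aligned[(k, e)].to_numpy(float)
                if np.std(y) == 0 or np.std(x) == 0:
                    n_undef += 1
                    rows.append(
                        dict(network=k, epoch=e, measure=measure, epoch_role=role,
                             r=np.nan, p=np.nan, r2=np.nan,
                             significant_bonferroni=False, significant_display=False)
                    )
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append(
                    dict(network=k, epoch=e, measure=measure, epoch_role=role,
                         r=r, p=p, r2=r * r,
                         significant_bonferroni=bool(p < alpha / family),
                         significant_display=bool(p < display_p))
                )
    return AccuracyAssociation(
        table=pd.DataFrame(rows), alpha=alpha, family_size=family, n_undefined=n_undef
    )


def run_accuracy_prediction(
    features: dict[str, dict[str, pd.DataFrame]],
    accuracy: dict[str, pd.DataFrame],
    measures=("amplitude", "asymmetry", "both"),
    n_components: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Cross-cohort PLS prediction of task accuracy per brain measure.

    ``features`` maps cohort name ("discovery"/"replication") to a dict
    of measure → subjects × 153 feature frame; ``accuracy`` maps cohort
    name to the subjects × 12 accuracy frame.  For measure "both" the
    amplitude and asymmetry blocks are concatenated column-wise.  Returns
    per-measure cross-cohort heatmap results plus a summary comparing the
    measures' mean held-out test correlations.
    """
    results: dict = {}
    summary_rows = []
    for measure in measures:
        blocks = {}
        for cohort in ("discovery", "replication"):
            if measure == "both":
                amp = features[cohort]["amplitude"]
                asym = features[cohort]["asymmetry"]
                amp = amp.copy()
                asym = asym.copy()
                amp.columns = pd.MultiIndex.from_tuples(
                    [("amp_" + k, e) for k, e in amp.columns]
                )
                asym.columns = pd.MultiIndex.from_tuples(
                    [("asym_" + k, e) for k, e in asym.columns]
                )
                blocks[cohort] = pd.concat([amp, asym], axis=1)
            else:
                blocks[cohort] = features[cohort][measure]
        ncomp = min(
            n_components,
            blocks["discovery"].shape[1],
            min(len(v) for v in blocks.values()) - 1,
        )
        res = cross_cohort_validate(
            blocks["discovery"],
            accuracy["discovery"],
            blocks["replication"],
            accuracy["replication"],
            n_components=ncomp,
            seed=seed,
            alpha=alpha,
        )
        results[measure] = res
        test_rs = [res[d]["test"].mean_r for d in res]
        summary_rows.append(
            {"measure": measure, "mean_test_r": float(np.mean(test_rs)),
             "mean_train_r": float(np.mean([res[d]["train"].mean_r for d in res]))}
        )
    results["summary"] = pd.DataFrame(summary_rows).set_index("measure")
    return results


def boxplot_stats(values: np.ndarray) -> dict:
    """Median, quartiles and 1.5·IQR whiskers of one accuracy sample.

    Whiskers extend to the most extreme data point within 1.5 IQR of the
    quartiles, the usual Tukey convention.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no data")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(v.size - inside.size),
    }
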