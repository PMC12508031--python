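"""Group-level statistics: covariate adjustment, matched cohort splitting,
vertex-wise one-sample tests with FDR correction, and effect sizes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest


@dataclass
class CohortSplit:
    """A discovery/replication partition of subjects with a balance report.

    ``balance_report`` holds one row per matched covariate with the
    between-half test statistic and p-value (two-sample t-tests for age
    and BMI, a two-proportion z-test for sex).
    """

    discovery_ids: list
    replication_ids: list
    balance_report: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.discovery_ids) & set(self.replication_ids)
        if overlap:
            raise ValueError(f"split halves overlap: {sorted(overlap)[:5]}...")


@dataclass
class VertexStatMap:
    """Vertex-wise one-sample test results: t, p, BH-adjusted q, Cohen's d."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d: np.ndarray
    n: int
    n_zero_variance: int = 0

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of vertices with q < 0.05."""
        return self.q < 0.05


def _as_matrix(values) -> tuple[np.ndarray, bool]:
    arr = values.to_numpy(dtype=float) if hasattr(values, "to_numpy") else np.asarray(values, float)
    was_1d = arr.ndim == 1
    if was_1d:
        arr = arr[:, None]
    return arr, was_1d


def residualize_age(values, ages):
    """Regress age out of each column, restoring the original grand mean.

    ``values`` is subjects × variables (DataFrame or array, one row per
    subject); each variable is replaced by the residuals of its
    least-squares fit on age plus that variable's original mean, so the
    output is orthogonal to centered age but keeps its location.
    """
    ages = np.asarray(ages, dtype=float)
    arr, was_1d = _as_matrix(values)
    if arr.shape[0] != ages.size:
        raise ValueError("need exactly one age per subject")
    age_c = ages - ages.mean()
    ss = float(age_c @ age_c)
    if ss == 0:
        raise ValueError("age is constant; the regression slope is undefined")
    col_means = arr.mean(axis=0)
    slopes = age_c @ (arr - col_means) / ss
    resid = arr - col_means - np.outer(age_c, slopes)
    out = resid + col_means
    if was_1d:
        out = out[:, 0]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def grand_mean_scale(values, categories, multiplicative: bool = False):
    """Normalize values across categorical cells to the pooled grand mean.

    ``categories`` is a sequence (or DataFrame of label columns, e.g. sex
    and race) defining one cell per unique label combination.  By default
    each cell is additively shifted so its mean equals the pooled grand
    mean.  Signed contrast values make the literal multiplicative variant
    ill-defined near zero cell means, but it is available with
    ``multiplicative=True`` (cells rescaled by grand_mean / cell_mean).
    """
    if isinstance(categories, pd.DataFrame):
        labels = np.array(
            ["|".join(map(str, row)) for row in categories.to_numpy()], dtype=object
        )
    else:
        labels = np.asarray(categories, dtype=object)
    arr, was_1d = _as_matrix(values)
    if arr.shape[0] != labels.size:
        raise ValueError("need exactly one category label per subject")
    out = arr.copy()
    grand = arr.mean(axis=0)
    for lab in pd.unique(labels):
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"category cell {lab!r} is empty")
        cell_mean = arr[mask].mean(axis=0)
        if multiplicative:
            if np.any(np.abs(cell_mean) < 1e-12):
                raise ValueError(
                    f"multiplicative scaling undefined: cell {lab!r} mean is ~0"
                )
            out[mask] = arr[mask] * (grand / cell_mean)
        else:
            out[mask] = arr[mask] + (grand - cell_mean)
    if was_1d:
        out = out[:, 0]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def split_matched(
    table: pd.DataFrame, ratio: float = 0.51, seed: int = 0
) -> CohortSplit:
    """Split subjects into discovery/replication halves matched on sex.

    The split is stratified by sex at the given ratio (so sex proportions
    are preserved by construction); age and BMI balance follows from
    randomization and is verified in the returned balance report.
    Deterministic for a fixed seed.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    strata = {name: s for name, s in table.groupby("sex", sort=True)}
    for name, stratum in strata.items():
        if len(stratum) < 2:
            raise ValueError(
                f"sex stratum of size {len(stratum)} is too small to split"
            )
    # largest-remainder apportionment of the discovery quota across strata
    target_total = int(round(ratio * len(table)))
    base = {k: int(np.floor(ratio * len(s))) for k, s in strata.items()}
    frac = {k: ratio * len(s) - base[k] for k, s in strata.items()}
    leftover = target_total - sum(base.values())
    for k in sorted(strata, key=lambda k: (-frac[k], k))[:max(leftover, 0)]:
        base[k] += 1
    disc_idx: list[int] = []
    repl_idx: list[int] = []
    for name in sorted(strata):
        stratum = strata[name]
        idx = stratum.index.to_numpy()
        perm = rng.permutation(len(idx))
        n_disc = min(max(base[name], 1), len(idx) - 1)
        disc_idx.extend(idx[perm[:n_disc]])
        repl_idx.extend(idx[perm[n_disc:]])
    disc = table.loc[disc_idx]
    repl = table.loc[repl_idx]

    rows = []
    for cov in ("age", "bmi"):
        if cov in table.columns:
            t, p = stats.ttest_ind(disc[cov], repl[cov])
            rows.append({"covariate": cov, "test": "t", "statistic": t, "p": p})
    n_f = np.array([(disc["sex"] == "F").sum(), (repl["sex"] == "F").sum()])
    n_tot = np.array([len(disc), len(repl)])
    z, p = proportions_ztest(n_f, n_tot)
    rows.append({"covariate": "sex", "test": "proportion_z", "statistic": z, "p": p})
    report = pd.DataFrame(rows)
    return CohortSplit(
        discovery_ids=list(disc["subject_id"]),
        replication_ids=list(repl["subject_id"]),
        balance_report=report,
    )


def fdr_correct(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted, mask)`` where ``adjusted`` are the monotone BH
    adjusted p-values (capped at 1) and ``mask`` flags discoveries at the
    given q level.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, adjusted, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return adjusted, mask


def one_sample_t_map(values: np.ndarray, q_level: float = 0.05) -> VertexStatMap:
    """Vertex-wise one-sample t-test against zero across subjects.

    ``values`` is subjects × vertices.  Per vertex: t = mean/(sd/√n) with
    two-sided p from Student's t on n−1 df, BH-adjusted q across all
    vertices of the map, and Cohen's d = mean/sd.  Zero-variance vertices
    get t = ±inf and p = 0 and are counted in ``n_zero_variance``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be subjects × vertices")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("one-sample t map requires at least 3 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        d = mean / sd
    t[zero_var] = np.sign(mean[zero_var]) * np.inf
    d[zero_var] = np.sign(mean[zero_var]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 0.0
    q, _ = fdr_correct(p, q_level)
    return VertexStatMap(
        t=t, p=p, q=q, d=d, n=n, n_zero_variance=int(zero_var.sum())
    )


def cohens_d_from_r(r: float, n: int | None = None) -> float:
    """Convert a Pearson correlation to Cohen's d: d = 2r/√(1−r²).

    With ``n`` given, applies the small-sample (Hedges) correction factor
    1 − 3/(4(n−2) − 1) to the converted d.
    """
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    d = 2.0 * r / np.sqrt(1.0 - r * r)
    if n is not None:
        if n <= 3:
            raise ValueError("Hedges correction requires n > 3")
        d *= 1.0 - 3.0 / (4.0 * (n - 2) - 1.0)
    return float(d)
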