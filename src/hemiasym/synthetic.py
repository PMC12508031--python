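"""Seeded synthetic cohort generator.

Emulates the statistical structure of a large task-fMRI cohort: per
subject and task epoch, paired left/right vertex maps with
network-structured bilateral amplitude, planted network-specific
lateralization, an amplitude–asymmetry coupling, and behavioural accuracy
linearly linked to amplitude and asymmetry plus age and sex effects.

Generative model
----------------
For subject ``s`` with amplitude factor ``g_s ~ Normal(0, sigma_subject)``,
epoch ``e``, and vertex ``v`` belonging to network ``k``:

    delta = clip(delta_planted[k, e] + beta_coupling[k, e] * g_s, -1, 1)
    L     = mu[k, e] * (1 + delta) * (1 + g_s) + Normal(0, sigma_vertex)
    R     = mu[k, e] * (1 - delta) * (1 + g_s) + Normal(0, sigma_vertex)

The multiplicative (1 ± delta) parameterization makes the planted delta
equal the realized laterality index Δ = (L−R)/(|L|+|R|) exactly in the
noise-free limit, so planted truth is directly checkable downstream.

Accuracy for the 12 non-motor epochs is a linear function of the
subject's realized mean amplitude and mean asymmetry for that epoch, age
(centered) and sex, plus Gaussian noise, clipped to [0, 1]; the clipped
fraction is recorded so it can be monitored (defaults keep it well below
1%).  The motor paradigm carries no accuracy metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .asymmetry import asymmetry_index, bilateral_amplitude
from .types import HemiPair
from .vocab import (
    ACCURACY_EPOCHS,
    EPOCHS,
    MOTOR_EPOCHS,
    NETWORKS,
    validate_epochs,
)

#: Demography defaults emulating a healthy young-adult cohort.
_AGE_MEAN, _AGE_SD, _AGE_RANGE = 28.8, 3.7, (22.0, 37.0)
_FEMALE_FRACTION = 607 / 989
_RACES = ("white", "black", "asian", "other")
_RACE_PROBS = (0.75, 0.13, 0.06, 0.06)


def default_partition(n_vertices: int, networks=NETWORKS) -> np.ndarray:
    """Contiguous, near-equal blocks of vertices per network label.

    The first ``n_vertices % 12`` networks receive one extra vertex.
    Trivial to verify aggregation against by hand.
    """
    networks = list(networks)
    if n_vertices < len(networks):
        raise ValueError(
            f"n_vertices={n_vertices} cannot cover all {len(networks)} networks"
        )
    base, extra = divmod(n_vertices, len(networks))
    sizes = [base + (1 if i < extra else 0) for i in range(len(networks))]
    return np.repeat(np.array(networks, dtype=object), sizes)


def _network_epoch_frame(value: float = 0.0) -> pd.DataFrame:
    return pd.DataFrame(value, index=list(NETWORKS), columns=list(EPOCHS), dtype=float)


def default_mu() -> pd.DataFrame:
    """Default network × epoch mean bilateral amplitude (signal units).

    Baseline 1.0 everywhere, with stronger task-relevant engagement:
    visual networks during visually driven epochs, language network during
    the auditory language epochs, somatomotor during movement, and
    frontoparietal/dorsal-attention during demanding cognitive epochs.
    """
    mu = _network_epoch_frame(1.0)
    visual = ["faces", "shapes", "rel", "match", "social", "random", "0bk", "2bk"]
    mu.loc["VIS1", visual] = 1.6
    mu.loc["VIS2", visual] = 1.5
    mu.loc["LAN", ["story", "math"]] = 1.7
    mu.loc["AUD", ["story", "math"]] = 1.5
    mu.loc[["SMM"], list(MOTOR_EPOCHS)] = 1.8
    mu.loc["FPN", ["rel", "match", "0bk", "2bk", "math"]] = 1.4
    mu.loc["DAN", ["rel", "match", "0bk", "2bk", "social", "random"]] = 1.4
    mu.loc["CON", ["0bk", "2bk", "reward", "punish"]] = 1.3
    mu.loc["DMN", ["story", "social"]] = 1.2
    return mu


def default_delta_planted() -> pd.DataFrame:
    """Default planted laterality: leftward language, contralateral motor."""
    d = _network_epoch_frame(0.0)
    d.loc["LAN", "story"] = 0.25
    d.loc["LAN", "math"] = 0.10
    d.loc["FPN", "2bk"] = 0.08
    d.loc["DAN", ["social", "random"]] = -0.08
    # movements drive the contralateral hemisphere
    d.loc["SMM", "lh"] = -0.20
    d.loc["SMM", "lf"] = -0.15
    d.loc["SMM", "rh"] = 0.20
    d.loc["SMM", "rf"] = 0.15
    return d


def default_beta_coupling() -> pd.DataFrame:
    """Default amplitude→asymmetry coupling, strongest in language cortex."""
    b = _network_epoch_frame(0.0)
    b.loc["LAN", :] = 0.20
    b.loc["FPN", :] = 0.10
    b.loc["DAN", :] = 0.10
    return b


def default_accuracy_coefs() -> pd.DataFrame:
    """Per-epoch accuracy model coefficients for the 12 non-motor epochs.

    Columns: intercept, amp_weight (per signal unit of the subject's mean
    bilateral amplitude), asym_weight (per unit Δ), age_slope (per year,
    age centered), sex_offset (male minus female).
    """
    coefs = pd.DataFrame(
        {
            "intercept": 0.75,
            "amp_weight": 0.08,
            "asym_weight": 0.04,
            "age_slope": -0.003,
            "sex_offset": 0.02,
        },
        index=list(ACCURACY_EPOCHS),
    )
    # demanding epochs sit lower and load more on brain measures
    for e in ("2bk", "rel", "math"):
        coefs.loc[e, "intercept"] = 0.70
        coefs.loc[e, "amp_weight"] = 0.12
        coefs.loc[e, "asym_weight"] = 0.06
    return coefs


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    All network × epoch parameter tables are pandas DataFrames indexed by
    the 12 canonical networks with the 17 epochs as columns.  Noise scales
    are standard deviations; ``sigma_subject`` is the SD of the
    dimensionless per-subject amplitude factor, ``sigma_vertex`` the SD of
    additive per-vertex signal noise (signal units), ``sigma_accuracy``
    the SD of accuracy noise (accuracy fraction units).
    """

    n_subjects: int = 989
    n_vertices: int = 120
    partition: np.ndarray | None = None
    epochs: tuple[str, ...] = EPOCHS
    mu: pd.DataFrame = field(default_factory=default_mu)
    delta_planted: pd.DataFrame = field(default_factory=default_delta_planted)
    beta_coupling: pd.DataFrame = field(default_factory=default_beta_coupling)
    accuracy_coefs: pd.DataFrame = field(default_factory=default_accuracy_coefs)
    sigma_subject: float = 0.15
    sigma_vertex: float = 0.10
    sigma_accuracy: float = 0.05
    coord_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition is None:
            self.partition = default_partition(self.n_vertices)
        self.partition = np.asarray(self.partition, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.partition.shape != (self.n_vertices,):
            raise ValueError(
                f"partition length {self.partition.size} does not match "
                f"n_vertices={self.n_vertices}"
            )
        unknown = set(self.partition) - set(NETWORKS)
        if unknown:
            raise ValueError(f"partition contains unknown network labels: {sorted(unknown)}")
        if self.n_vertices >= len(NETWORKS):
            missing = set(NETWORKS) - set(self.partition)
            if missing:
                raise ValueError(
                    f"all 12 networks must be nonempty; missing: {sorted(missing)}"
                )
        validate_epochs(self.epochs)
        for name in ("sigma_subject", "sigma_vertex", "sigma_accuracy", "coord_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mu", "delta_planted", "beta_coupling"):
            tbl = getattr(self, name)
            if not set(self.partition) <= set(tbl.index) or not set(self.epochs) <= set(
                tbl.columns
            ):
                raise ValueError(f"{name} table must cover all networks and epochs")
        if (self.delta_planted.abs() > 1).any().any():
            raise ValueError("delta_planted entries must lie in [-1, 1]")
        acc_epochs = [e for e in self.epochs if e not in MOTOR_EPOCHS]
        if not set(acc_epochs) <= set(self.accuracy_coefs.index):
            raise ValueError("accuracy_coefs must cover every non-motor epoch")


@dataclass
class Cohort:
    """One generated cohort: covariate table plus all hemisphere map pairs.

    ``left``/``right`` have shape ``(n_subjects, n_epochs, n_vertices)``;
    ``coords_left``/``coords_right`` shape ``(n_vertices, 3)``.
    """

    subjects: pd.DataFrame
    left: np.ndarray
    right: np.ndarray
    coords_left: np.ndarray
    coords_right: np.ndarray
    partition: np.ndarray
    epochs: list[str]
    config: CohortConfig
    accuracy_clip_fraction: float = 0.0

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    @property
    def n_subjects(self) -> int:
        return self.left.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.left.shape[2]

    def pair(self, subject_id: str, epoch: str) -> HemiPair:
        """The HemiPair for one subject × epoch."""
        s = self.subject_ids.index(subject_id)
        e = self.epochs.index(epoch)
        return HemiPair(
            left=self.left[s, e],
            right=self.right[s, e],
            coords_left=self.coords_left,
            coords_right=self.coords_right,
            subject_id=subject_id,
            epoch=epoch,
        )

    def iter_pairs(self) -> Iterator[HemiPair]:
        for sid in self.subject_ids:
            for epoch in self.epochs:
                yield self.pair(sid, epoch)

    def asymmetry(self, eps: float = 1e-12) -> np.ndarray:
        """Vertex-wise Δ for every subject × epoch, shape (S, E, V)."""
        return asymmetry_index(self.left, self.right, eps=eps)

    def amplitude(self) -> np.ndarray:
        """Vertex-wise A for every subject × epoch, shape (S, E, V)."""
        return bilateral_amplitude(self.left, self.right)


def _hemisphere_coords(n_vertices: int, rng: np.random.Generator) -> np.ndarray:
    """Random points on a left-hemisphere-like half ellipsoid (mm units)."""
    u = rng.normal(size=(n_vertices, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[:, 0] = -np.abs(u[:, 0])  # left hemisphere: x < 0
    radii = np.array([65.0, 85.0, 70.0])
    return u * radii


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one seeded synthetic cohort.

    Identical configs (including seed) give bit-identical cohorts.
    Returns a :class:`Cohort` whose ``subjects`` table carries one row per
    subject with covariates and per-epoch accuracy for the non-motor
    epochs (NaN for motor epochs, which have no accuracy metric).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, V = config.n_subjects, config.n_vertices
    epochs = list(config.epochs)
    E = len(epochs)

    # covariates
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, size=S), *_AGE_RANGE)
    sex = np.where(rng.random(S) < _FEMALE_FRACTION, "F", "M")
    race = rng.choice(_RACES, size=S, p=_RACE_PROBS)
    bmi = np.clip(rng.normal(26.4, 5.0, size=S), 16.0, 45.0)
    handedness = np.clip(rng.normal(65.0, 45.0, size=S), -100.0, 100.0)

    # per-vertex parameter tables mapped through the partition
    net_index = pd.Index(config.partition)
    mu_ve = config.mu.reindex(index=net_index, columns=epochs).to_numpy().T  # (E, V)
    d_ve = config.delta_planted.reindex(index=net_index, columns=epochs).to_numpy().T
    b_ve = config.beta_coupling.reindex(index=net_index, columns=epochs).to_numpy().T

    g = rng.normal(0.0, config.sigma_subject, size=S)  # subject amplitude factor
    delta = np.clip(d_ve[None, :, :] + b_ve[None, :, :] * g[:, None, None], -1.0, 1.0)
    base = mu_ve[None, :, :] * (1.0 + g[:, None, None])
    noise_l = rng.normal(0.0, config.sigma_vertex, size=(S, E, V))
    noise_r = rng.normal(0.0, config.sigma_vertex, size=(S, E, V))
    left = base * (1.0 + delta) + noise_l
    right = base * (1.0 - delta) + noise_r

    coords_left = _hemisphere_coords(V, rng)
    coords_right = coords_left * np.array([-1.0, 1.0, 1.0])
    if config.coord_jitter > 0:
        extent = coords_left.max(axis=0) - coords_left.min(axis=0)
        coords_right = coords_right + rng.normal(
            0.0, config.coord_jitter, size=(V, 3)
        ) * extent

    # accuracy from realized subject-level mean amplitude and asymmetry
    amp_mean = bilateral_amplitude(left, right).mean(axis=2)  # (S, E)
    asym_mean = asymmetry_index(left, right).mean(axis=2)  # (S, E)
    is_male = (sex == "M").astype(float)
    age_c = age - _AGE_MEAN

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(S)],
            "age": age,
            "sex": sex,
            "race": race,
            "bmi": bmi,
            "handedness": handedness,
        }
    )
    n_clipped = 0
    n_acc = 0
    for e_name in epochs:
        if e_name in MOTOR_EPOCHS:
            continue
        j = epochs.index(e_name)
        c = config.accuracy_coefs.loc[e_name]
        acc = (
            c["intercept"]
            + c["amp_weight"] * amp_mean[:, j]
            + c["asym_weight"] * asym_mean[:, j]
            + c["age_slope"] * age_c
            + c["sex_offset"] * is_male
            + rng.normal(0.0, config.sigma_accuracy, size=S)
        )
        clipped = np.clip(acc, 0.0, 1.0)
        n_clipped += int(np.count_nonzero(clipped != acc))
        n_acc += S
        subjects[f"accuracy_{e_name}"] = clipped

    return Cohort(
        subjects=subjects,
        left=left,
        right=right,
        coords_left=coords_left,
        coords_right=coords_right,
        partition=config.partition,
        epochs=epochs,
        config=config,
        accuracy_clip_fraction=(n_clipped / n_acc) if n_acc else 0.0,
    )
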