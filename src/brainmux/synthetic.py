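"""Synthetic cohorts: planted-modular band connectomes, scores, band signals.

The generator produces, per subject, M weighted symmetric connectivity
matrices with a planted partition (expected weight ``w_in`` within modules,
``w_out`` between) plus Gaussian weight noise, clipped to [0, 1]. For
AD-profile subjects, weights incident to a chosen set of affected nodes are
scaled by ``1 - delta`` in the alpha2 layer and ``1 + delta`` (capped at 1)
in the theta layer, concentrating those nodes' degree in fewer layers;
HC-profile subjects get no scaling. Cognitive-like scores are affine in a
per-subject network feature plus Gaussian noise.

Every stochastic element is driven by a per-subject seed derived from
``SeedSequence([cohort_seed, group_code, subject_index])``, so cohorts are
reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS
from .spectral import BandConnectome, BandScheme

__all__ = [
    "CohortSpec",
    "Cohort",
    "generate_subject_connectome",
    "generate_cohort",
    "generate_scores",
    "generate_band_signals",
    "THETA_LAYER",
    "ALPHA2_LAYER",
]

#: Layer indices carrying the planted AD imbalance in the default 7-band order.
THETA_LAYER = 1
ALPHA2_LAYER = 3


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``module_sizes`` must sum to ``n_nodes``; ``0 <= w_out < w_in <= 1``;
    ``delta`` in [0, 1) controls the AD-like layer imbalance on
    ``affected_nodes``.
    """

    n_hc: int = 25
    n_ad: int = 25
    n_nodes: int = 40
    n_layers: int = 7
    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    w_in: float = 0.6
    w_out: float = 0.3
    weight_noise_sd: float = 0.05
    affected_nodes: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    delta: float = 0.0
    score_slope: float = 30.0
    score_intercept: float = 10.0
    score_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} but n_nodes={self.n_nodes}"
            )
        if not (0.0 <= self.w_out < self.w_in <= 1.0):
            raise ValueError("require 0 <= w_out < w_in <= 1")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be nonnegative")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if self.delta > 0 and self.n_layers <= ALPHA2_LAYER:
            raise ValueError("delta > 0 requires n_layers >= 4 (theta and alpha2 layers)")
        bad = [i for i in self.affected_nodes if not 0 <= i < self.n_nodes]
        if bad:
            raise ValueError(f"affected_nodes out of range: {bad}")
        if self.n_hc < 1 or self.n_ad < 1:
            raise ValueError("both groups must be nonempty")

    @property
    def module_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass
class Cohort:
    """Generated cohort: per-subject table and band connectomes."""

    table: pd.DataFrame  # columns: id, group, MMSE, FR, TR
    connectomes: dict[str, BandConnectome]
    spec: CohortSpec

    def group_ids(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "id"].tolist()


def _subject_rng(cohort_seed: int, group: str, index: int) -> np.random.Generator:
    group_code = {"HC": 0, "AD": 1}[group]
    return np.random.default_rng(np.random.SeedSequence([cohort_seed, group_code, index]))


def _mean_matrix(spec: CohortSpec) -> np.ndarray:
    labels = spec.module_labels
    same = labels[:, None] == labels[None, :]
    mean = np.where(same, spec.w_in, spec.w_out)
    np.fill_diagonal(mean, 0.0)
    return mean


def generate_subject_connectome(
    spec: CohortSpec, group: str, subject_seed: int | np.random.Generator
) -> BandConnectome:
    """Draw one subject's M-layer weighted connectome.

    ``subject_seed`` may be an integer or an already-split Generator.
    Matrices are symmetric, zero-diagonal, clipped to [0, 1].
    """
    if group not in ("AD", "HC"):
        raise ValueError(f"unknown group {group!r}")
    rng = (
        subject_seed
        if isinstance(subject_seed, np.random.Generator)
        else np.random.default_rng(subject_seed)
    )
    n, M = spec.n_nodes, spec.n_layers
    mean = _mean_matrix(spec)
    iu, ju = np.triu_indices(n, k=1)
    affected = np.zeros(n, dtype=bool)
    affected[list(spec.affected_nodes)] = True
    incident = affected[iu] | affected[ju]

    layers = np.empty((M, n, n))
    for lam in range(M):
        w = mean[iu, ju].copy()
        if spec.weight_noise_sd > 0:
            w = w + rng.normal(0.0, spec.weight_noise_sd, size=w.shape)
        if group == "AD" and spec.delta > 0:
            if lam == ALPHA2_LAYER:
                w[incident] *= 1.0 - spec.delta
            elif lam == THETA_LAYER:
                w[incident] *= 1.0 + spec.delta
        w = np.clip(w, 0.0, 1.0)
        mat = np.zeros((n, n))
        mat[iu, ju] = w
        layers[lam] = mat + mat.T

    scheme = (
        DEFAULT_BANDS
        if M == len(DEFAULT_BANDS)
        else BandScheme([(f"layer{i}", float(i), float(i) + 0.5) for i in range(M)])
    )
    return BandConnectome(matrices=layers, scheme=scheme)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort with placeholder scores.

    Scores are filled by :func:`generate_scores` once a per-subject network
    feature is available; until then they are NaN.
    """
    rows = []
    connectomes: dict[str, BandConnectome] = {}
    for group, count in (("HC", spec.n_hc), ("AD", spec.n_ad)):
        for i in range(count):
            sid = f"{group}{i:03d}"
            rng = _subject_rng(spec.seed, group, i)
            connectomes[sid] = generate_subject_connectome(spec, group, rng)
            rows.append({"id": sid, "group": group, "MMSE": np.nan, "FR": np.nan, "TR": np.nan})
    return Cohort(table=pd.DataFrame(rows), connectomes=connectomes, spec=spec)


def generate_scores(
    cohort: Cohort, feature_per_subject: np.ndarray, spec: CohortSpec | None = None
) -> Cohort:
    """Attach scores affine in ``feature_per_subject`` plus Gaussian noise.

    TR = intercept + slope * feature + N(0, score_noise_sd); MMSE and FR are
    generated analogously with independent noise draws. Deterministic under
    the spec seed.
    """
    spec = spec or cohort.spec
    feature = np.asarray(feature_per_subject, dtype=float)
    if feature.shape[0] != len(cohort.table):
        raise ValueError(
            f"{feature.shape[0]} feature values for {len(cohort.table)} subjects"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, 0]))
    table = cohort.table.copy()
    for col in ("TR", "MMSE", "FR"):
        noise = rng.normal(0.0, spec.score_noise_sd, size=feature.shape) \
            if spec.score_noise_sd > 0 else 0.0
        table[col] = spec.score_intercept + spec.score_slope * feature + noise
    return Cohort(table=table, connectomes=cohort.connectomes, spec=spec)


def generate_band_signals(
    n_rois: int,
    fs: float,
    duration: float,
    coupling: list[tuple[tuple[int, int], str, float]],
    seed: int = 0,
    bands: BandScheme = DEFAULT_BANDS,
) -> "EpochSignals":
    """Zero-mean signals where each coupled ROI pair shares a band-limited
    component of the given strength plus independent broadband noise.

    ``coupling`` entries are ``((roi_a, roi_b), band_name, strength)`` with
    strength in [0, 1]; strength 1 means the pair is driven entirely by the
    shared band component (coherence ~ 1 in that band), strength 0 leaves
    the pair independent.
    """
    from scipy.signal import butter, filtfilt

    from .spectral import EpochSignals

    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    x = rng.standard_normal((n_samples, n_rois))
    for (a, b), band_name, strength in coupling:
        if not 0.0 <= strength <= 1.0:
            raise ValueError(f"coupling strength {strength} outside [0, 1]")
        try:
            band = bands[bands.index(band_name)]
        except KeyError as exc:
            raise ValueError(f"band {band_name!r} not in the band scheme") from exc
        nyq = fs / 2.0
        if band.f_high >= nyq:
            raise ValueError(f"band {band_name!r} exceeds the Nyquist frequency")
        bb, ab = butter(4, [band.f_low / nyq, band.f_high / nyq], btype="band")
        shared = filtfilt(bb, ab, rng.standard_normal(n_samples))
        shared /= shared.std() or 1.0
        for roi in (a, b):
            x[:, roi] = strength * shared + np.sqrt(1.0 - strength**2) * x[:, roi]
    x -= x.mean(axis=0)
    return EpochSignals(data=x, fs=fs, epoch_id="synthetic")
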