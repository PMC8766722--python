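"""Synthetic multimodal ROI-feature cohorts.

Emulates the statistical structure of a small two-group neuroimaging
study — balanced AD/CN groups, a few tens of subjects, per-modality
feature families (morphometry, SUVR, diffusion metrics) in which a
minority of features carry a genuine group difference — without any image
content.  Features follow a Gaussian linear factor model so that every
moment used by the test suite has a closed form:

``x_ij = d * g_i * inf_j + lambda_m * L_i * inf_j
        + sqrt(rho_m) * B_{i,b(j)} + sqrt(1 - lambda_m^2 * inf_j - rho_m) * e_ij``

where ``g_i`` is the 0/1 diagnosis, ``inf_j`` flags informative features,
``L_i`` is a per-subject latent factor shared across modalities (modal
redundancy), ``B`` are per-block nuisance factors, and ``e`` is white
noise.  Coefficients are chosen so every feature has unit within-group
variance, making ``d`` a standardized effect size (Cohen's d).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .tables import AD, FeatureTable

__all__ = [
    "ModalitySpec",
    "CohortConfig",
    "generate_multimodal_cohort",
    "generate_external_cohort",
]


@dataclass(frozen=True)
class ModalitySpec:
    """Generating parameters of one modality's feature family.

    Parameters
    ----------
    name : modality label, e.g. ``"smri"``, ``"pet"``, ``"dti"``
    n_features : number of ROI features
    n_informative : count of features with a planted group effect; these
        are the first ``n_informative`` columns
    effect_size : standardized AD-vs-CN mean shift (Cohen's d) of every
        informative feature
    block_size : features per correlated nuisance block
    block_rho : within-block correlation, in [0, 1)
    latent_loading : loading of informative features on the cross-modality
        latent factor, in [0, 1]; ``latent_loading**2 + block_rho`` must
        stay <= 1 so the unit-variance decomposition exists
    """

    name: str
    n_features: int
    n_informative: int
    effect_size: float = 0.0
    block_size: int = 5
    block_rho: float = 0.0
    latent_loading: float = 0.0

    def __post_init__(self):
        if not self.name:
            raise ConfigError("ModalitySpec.name must be non-empty")
        if self.n_features < 1:
            raise ConfigError("ModalitySpec.n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ConfigError("ModalitySpec.n_informative must lie in [0, n_features]")
        if self.block_size < 1:
            raise ConfigError("ModalitySpec.block_size must be positive")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigError("ModalitySpec.block_rho must lie in [0, 1)")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ConfigError("ModalitySpec.latent_loading must lie in [0, 1]")
        if self.latent_loading**2 + self.block_rho > 1.0 + 1e-12:
            raise ConfigError(
                "ModalitySpec.latent_loading**2 + block_rho exceeds 1; "
                "no unit-variance noise decomposition exists"
            )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"{self.name}_roi{j + 1:03d}" for j in range(self.n_features))

    @property
    def informative_names(self) -> tuple[str, ...]:
        return self.feature_names[: self.n_informative]


def _default_modalities() -> tuple[ModalitySpec, ...]:
    # Feature counts mirror a three-modality ROI study: a large
    # morphometry family, a small amyloid-PET SUVR family, a mid-sized
    # diffusion family.  Effect sizes reflect the field's typical ordering
    # (amyloid > atrophy > diffusion) at a magnitude recoverable from a
    # cohort of a few tens of subjects.
    return (
        ModalitySpec("smri", n_features=142, n_informative=10, effect_size=1.2,
                     block_size=5, block_rho=0.3),
        ModalitySpec("pet", n_features=19, n_informative=3, effect_size=1.5,
                     block_size=5, block_rho=0.3),
        ModalitySpec("dti", n_features=84, n_informative=8, effect_size=1.0,
                     block_size=5, block_rho=0.3),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating parameters.

    ``external_shift`` and ``external_scale`` define the distribution shift
    of the external-validation cohort: external features are
    ``external_shift + external_scale * x`` with ``x`` drawn from the
    internal mechanism on an independent seed stream.  ``subject_dropout``
    drops a random fraction of subjects independently per modality to
    emulate partial multimodal coverage.
    """

    n_per_group: int = 20
    modalities: tuple[ModalitySpec, ...] = field(default_factory=_default_modalities)
    seed: int = 0
    external_shift: float = 0.5
    external_scale: float = 1.2
    subject_dropout: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "modalities", tuple(self.modalities))
        if self.n_per_group < 3:
            raise ConfigError("CohortConfig.n_per_group must be >= 3")
        if not self.modalities:
            raise ConfigError("CohortConfig.modalities must be non-empty")
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise ConfigError("CohortConfig.modalities must have unique names")
        if self.external_scale <= 0:
            raise ConfigError("CohortConfig.external_scale must be positive")
        if not 0.0 <= self.subject_dropout < 1.0:
            raise ConfigError("CohortConfig.subject_dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_cohort(config: CohortConfig, rng: np.random.Generator,
                 id_prefix: str) -> dict[str, FeatureTable]:
    n = 2 * config.n_per_group
    subject_ids = tuple(f"{id_prefix}{i + 1:04d}" for i in range(n))
    labels = np.repeat([0, 1], config.n_per_group)
    latent = rng.standard_normal(n)
    tables: dict[str, FeatureTable] = {}
    for spec in config.modalities:
        p = spec.n_features
        n_blocks = -(-p // spec.block_size)
        block_of = np.arange(p) // spec.block_size
        block_factors = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, p))
        inf = np.zeros(p)
        inf[: spec.n_informative] = 1.0
        lam = spec.latent_loading * inf
        noise_sd = np.sqrt(1.0 - lam**2 - spec.block_rho)
        values = (
            spec.effect_size * np.outer(labels, inf)
            + np.outer(latent, lam)
            + np.sqrt(spec.block_rho) * block_factors[:, block_of]
            + noise_sd * noise
        )
        table = FeatureTable(subject_ids, labels, spec.feature_names, values)
        if config.subject_dropout > 0:
            n_drop = int(round(config.subject_dropout * n))
            n_drop = min(n_drop, n - 2)
            keep = np.sort(rng.permutation(n)[: n - n_drop])
            table = table.take_subjects(keep)
        tables[spec.name] = table
    return tables


def generate_multimodal_cohort(config: CohortConfig) -> dict[str, FeatureTable]:
    """Draw the internal cohort: one FeatureTable per modality.

    All modalities share subject identifiers and labels (full multimodal
    coverage unless ``subject_dropout`` > 0).  Deterministic for a fixed
    ``config.seed``.
    """
    internal_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    return _draw_cohort(config, np.random.default_rng(internal_ss), "S")


def generate_external_cohort(config: CohortConfig) -> dict[str, FeatureTable]:
    """Draw a distribution-shifted external cohort on an independent stream.

    Same feature names and generating mechanism as the internal cohort;
    every feature value x becomes ``external_shift + external_scale * x``.
    """
    _, external_ss = np.random.SeedSequence(config.seed).spawn(2)
    tables = _draw_cohort(config, np.random.default_rng(external_ss), "X")
    shifted = {}
    for name, t in tables.items():
        shifted[name] = FeatureTable(
            t.subject_ids, t.labels, t.feature_names,
            config.external_shift + config.external_scale * t.values,
        )
    return shifted
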