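"""Two-block synthetic data with planted cross-block components.

The generator emulates the structure of a large pediatric neuroimaging
cohort: a brain block of 87 regional gray-matter volumes (68 cortical + 19
subcortical), a behavior block of 4 mutually orthogonal psychopathology
dimensions (general, ADHD, conduct, internalizing), covariate effects for
age, sex, race/ethnicity and scanner manufacturer (optionally intracranial
volume), and a small number of planted rank-1 cross-block components whose
``strength`` equals the population correlation of the latent score pair.

Construction: k shared latent scores per sample are drawn i.i.d. standard
normal; each block receives ``scale * latent * pattern`` plus confound
effects plus independent Gaussian noise. The per-block scale is calibrated
as ``noise_sd * sqrt(strength / (1 - strength))`` so that projecting the
confound-free block onto the planted pattern yields a latent pair with
population correlation exactly ``strength`` (for orthogonal patterns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blocks import ConfoundTable, DataBlock
from .errors import ValidationError

__all__ = [
    "PlantedComponent",
    "NumericConfound",
    "CategoricalConfound",
    "ConfoundModel",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_dataset",
    "default_abcd_like_spec",
    "CORTICAL_REGIONS",
    "SUBCORTICAL_REGIONS",
    "PSYCH_DIMENSIONS",
]

_UNIT_TOL = 1e-8

# Desikan-Killiany cortical parcels (34 per hemisphere)
CORTICAL_REGIONS = tuple(
    f"{hemi}_{name}_vol"
    for hemi in ("lh", "rh")
    for name in (
        "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
        "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
        "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
        "lateralorbitofrontal", "lingual", "medialorbitofrontal",
        "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
        "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
        "posteriorcingulate", "precentral", "precuneus",
        "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
        "superiorparietal", "superiortemporal", "supramarginal",
        "temporalpole", "transversetemporal",
    )
)

# automated-segmentation subcortical volumes (2x9 bilateral + brainstem)
SUBCORTICAL_REGIONS = tuple(
    f"{hemi}_{name}_vol"
    for hemi in ("lh", "rh")
    for name in (
        "accumbens", "amygdala", "caudate", "cerebellumcortex", "hippocampus",
        "pallidum", "putamen", "thalamus", "ventraldc",
    )
) + ("brainstem_vol",)

PSYCH_DIMENSIONS = ("general", "adhd", "conduct", "internalizing")


def _as_unit(v, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if not np.isfinite(nrm) or abs(nrm - 1.0) > _UNIT_TOL:
        raise ValidationError(f"{what} must have unit Euclidean norm (got {nrm:.6g})")
    return v


@dataclass(frozen=True)
class PlantedComponent:
    """One rank-1 cross-block signal: unit patterns plus a strength in [0, 1).

    ``strength`` is the population correlation of the latent score pair
    (the two blocks' projections onto the planted patterns). It factorizes
    as ``brain_latent_r * psych_latent_r``, the correlations of each
    block's latent with the shared factor; ``brain_latent_r`` controls how
    the signal is split between the blocks. The default (None) splits it
    evenly (both sides ``sqrt(strength)``); a larger value concentrates
    signal in the (wide) brain block, which is what makes pattern recovery
    feasible at moderate n without changing the latent-pair correlation.
    """

    brain_pattern: np.ndarray
    psych_pattern: np.ndarray
    strength: float
    brain_latent_r: float | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "brain_pattern", _as_unit(self.brain_pattern, "brain_pattern")
        )
        object.__setattr__(
            self, "psych_pattern", _as_unit(self.psych_pattern, "psych_pattern")
        )
        s = float(self.strength)
        if not np.isfinite(s) or not 0.0 <= s < 1.0:
            raise ValidationError(f"strength must lie in [0, 1), got {s}")
        object.__setattr__(self, "strength", s)
        if self.brain_latent_r is not None:
            qx = float(self.brain_latent_r)
            if not (s <= qx < 1.0):
                raise ValidationError(
                    f"brain_latent_r must lie in [strength, 1), got {qx}"
                )
            object.__setattr__(self, "brain_latent_r", qx)

    @property
    def latent_quality(self) -> tuple[float, float]:
        """(brain, psych) correlations with the shared latent factor."""
        qx = np.sqrt(self.strength) if self.brain_latent_r is None else self.brain_latent_r
        qy = self.strength / qx if qx > 0 else 0.0
        return float(qx), float(qy)


@dataclass(frozen=True)
class NumericConfound:
    """A numeric covariate with per-response-variable slopes."""

    name: str
    mean: float
    sd: float
    brain_slopes: np.ndarray
    psych_slopes: np.ndarray

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"negative sd for covariate {self.name!r}")
        object.__setattr__(
            self, "brain_slopes", np.asarray(self.brain_slopes, dtype=float)
        )
        object.__setattr__(
            self, "psych_slopes", np.asarray(self.psych_slopes, dtype=float)
        )


@dataclass(frozen=True)
class CategoricalConfound:
    """A categorical covariate with sampling frequencies and per-level offsets."""

    name: str
    levels: tuple
    probs: np.ndarray
    brain_offsets: np.ndarray  # (n_levels, n_brain)
    psych_offsets: np.ndarray  # (n_levels, n_psych)

    def __post_init__(self):
        levels = tuple(str(x) for x in self.levels)
        if len(levels) < 2:
            raise ValidationError(
                f"categorical covariate {self.name!r} needs >= 2 levels"
            )
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(levels),) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValidationError(
                f"level probabilities for {self.name!r} must sum to 1"
            )
        bo = np.asarray(self.brain_offsets, dtype=float)
        po = np.asarray(self.psych_offsets, dtype=float)
        if bo.shape[0] != len(levels) or po.shape[0] != len(levels):
            raise ValidationError(
                f"offsets for {self.name!r} must cover all {len(levels)} levels"
            )
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "brain_offsets", bo)
        object.__setattr__(self, "psych_offsets", po)


@dataclass(frozen=True)
class ConfoundModel:
    numeric: tuple = ()
    categorical: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "numeric", tuple(self.numeric))
        object.__setattr__(self, "categorical", tuple(self.categorical))

    @property
    def is_empty(self) -> bool:
        return not self.numeric and not self.categorical


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic dataset."""

    n_samples: int
    components: tuple = ()
    confound_model: ConfoundModel = field(default_factory=ConfoundModel)
    n_brain: int = 87
    n_cortical: int = 68
    n_subcortical: int = 19
    n_psych: int = 4
    noise_sd_brain: float = 1.0
    noise_sd_psych: float = 1.0
    seed: int = 0
    brain_names: tuple | None = None
    psych_names: tuple | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_cortical + self.n_subcortical != self.n_brain:
            raise ValidationError(
                f"n_cortical ({self.n_cortical}) + n_subcortical "
                f"({self.n_subcortical}) != n_brain ({self.n_brain})"
            )
        if self.noise_sd_brain <= 0 or self.noise_sd_psych <= 0:
            raise ValidationError("noise SDs must be positive")
        comps = tuple(self.components)
        for i, c in enumerate(comps):
            if len(c.brain_pattern) != self.n_brain:
                raise ValidationError(
                    f"component {i + 1} brain pattern has length "
                    f"{len(c.brain_pattern)}, expected n_brain={self.n_brain}"
                )
            if len(c.psych_pattern) != self.n_psych:
                raise ValidationError(
                    f"component {i + 1} psych pattern has length "
                    f"{len(c.psych_pattern)}, expected n_psych={self.n_psych}"
                )
        strengths = [c.strength for c in comps]
        if any(s2 >= s1 for s1, s2 in zip(strengths, strengths[1:])):
            raise ValidationError(
                "component strengths must be strictly decreasing"
            )
        for nc in self.confound_model.numeric:
            if nc.brain_slopes.shape != (self.n_brain,) or nc.psych_slopes.shape != (
                self.n_psych,
            ):
                raise ValidationError(
                    f"slope vectors for covariate {nc.name!r} do not match "
                    "the block widths"
                )
        for cc in self.confound_model.categorical:
            if cc.brain_offsets.shape[1] != self.n_brain or cc.psych_offsets.shape[
                1
            ] != self.n_psych:
                raise ValidationError(
                    f"offset tables for covariate {cc.name!r} do not match "
                    "the block widths"
                )
        brain_names = self.brain_names
        if brain_names is None:
            if self.n_brain == 87:
                brain_names = CORTICAL_REGIONS + SUBCORTICAL_REGIONS
            else:
                brain_names = tuple(f"brain_{j + 1:03d}" for j in range(self.n_brain))
        psych_names = self.psych_names
        if psych_names is None:
            if self.n_psych == 4:
                psych_names = PSYCH_DIMENSIONS
            else:
                psych_names = tuple(f"psych_{j + 1}" for j in range(self.n_psych))
        if len(brain_names) != self.n_brain or len(psych_names) != self.n_psych:
            raise ValidationError("variable-name lists do not match block widths")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "brain_names", tuple(brain_names))
        object.__setattr__(self, "psych_names", tuple(psych_names))

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to score recovery against the generator."""

    components: tuple
    confound_model: ConfoundModel
    latent_scores: np.ndarray  # n x k shared latent draws
    x_latent: np.ndarray  # confound-free brain block projected on each pattern
    y_latent: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "components": [
                {
                    "brain_pattern": c.brain_pattern.tolist(),
                    "psych_pattern": c.psych_pattern.tolist(),
                    "strength": c.strength,
                    "brain_latent_r": c.latent_quality[0],
                }
                for c in self.components
            ],
            "confounds": {
                "numeric": [
                    {
                        "name": nc.name,
                        "mean": nc.mean,
                        "sd": nc.sd,
                        "brain_slopes": nc.brain_slopes.tolist(),
                        "psych_slopes": nc.psych_slopes.tolist(),
                    }
                    for nc in self.confound_model.numeric
                ],
                "categorical": [
                    {
                        "name": cc.name,
                        "levels": list(cc.levels),
                        "probs": cc.probs.tolist(),
                        "brain_offsets": cc.brain_offsets.tolist(),
                        "psych_offsets": cc.psych_offsets.tolist(),
                    }
                    for cc in self.confound_model.categorical
                ],
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _signal_scale(latent_r: float, noise_sd: float) -> float:
    # scale a such that corr(block latent, shared factor) = latent_r:
    # a / sqrt(a^2 + sd^2) = latent_r; the latent-pair correlation is then
    # the product of the two blocks' latent_r values, i.e. `strength`
    return noise_sd * latent_r / np.sqrt(1.0 - latent_r**2)


def generate_dataset(spec: SyntheticSpec):
    """Draw one dataset: returns (brain block, psych block, confounds, truth).

    RNG draw order is fixed (latents, covariates, brain noise, psych noise)
    so identical spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.k
    ids = tuple(f"S{i + 1:05d}" for i in range(n))

    Z = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    Xsig = np.zeros((n, spec.n_brain))
    Ysig = np.zeros((n, spec.n_psych))
    for c, comp in enumerate(spec.components):
        qx, qy = comp.latent_quality
        a = _signal_scale(qx, spec.noise_sd_brain)
        b = _signal_scale(qy, spec.noise_sd_psych)
        Xsig += a * np.outer(Z[:, c], comp.brain_pattern)
        Ysig += b * np.outer(Z[:, c], comp.psych_pattern)

    conf_cols: dict = {}
    categorical_names = []
    Xconf = np.zeros((n, spec.n_brain))
    Yconf = np.zeros((n, spec.n_psych))
    for nc in spec.confound_model.numeric:
        vals = nc.mean + nc.sd * rng.standard_normal(n)
        conf_cols[nc.name] = vals
        centered = vals - nc.mean
        Xconf += np.outer(centered, nc.brain_slopes)
        Yconf += np.outer(centered, nc.psych_slopes)
    for cc in spec.confound_model.categorical:
        idx = rng.choice(len(cc.levels), size=n, p=cc.probs)
        conf_cols[cc.name] = [cc.levels[i] for i in idx]
        categorical_names.append(cc.name)
        Xconf += cc.brain_offsets[idx]
        Yconf += cc.psych_offsets[idx]

    Xnoise = spec.noise_sd_brain * rng.standard_normal((n, spec.n_brain))
    Ynoise = spec.noise_sd_psych * rng.standard_normal((n, spec.n_psych))

    X0 = Xsig + Xnoise  # confound-free blocks define the latent pair
    Y0 = Ysig + Ynoise
    brain = DataBlock(ids, spec.brain_names, X0 + Xconf)
    psych = DataBlock(ids, spec.psych_names, Y0 + Yconf)

    confounds = None
    if conf_cols:
        import pandas as pd

        confounds = ConfoundTable(
            ids, pd.DataFrame(conf_cols), tuple(categorical_names)
        )

    if k:
        x_latent = X0 @ np.column_stack([c.brain_pattern for c in spec.components])
        y_latent = Y0 @ np.column_stack([c.psych_pattern for c in spec.components])
    else:
        x_latent = np.zeros((n, 0))
        y_latent = np.zeros((n, 0))
    truth = SyntheticTruth(
        components=spec.components,
        confound_model=spec.confound_model,
        latent_scores=Z,
        x_latent=x_latent,
        y_latent=y_latent,
        seed=spec.seed,
    )
    return brain, psych, confounds, truth


# regions carrying the localized second component (bilateral)
_COMPONENT2_REGIONS = (
    "caudalmiddlefrontal",
    "inferiorparietal",
    "superiortemporal",
    "middletemporal",
    "inferiortemporal",
    "posteriorcingulate",
)


def default_abcd_like_spec(
    n_samples: int,
    seed: int = 0,
    strengths: tuple = (0.16, 0.11),
    include_icv: bool = False,
) -> SyntheticSpec:
    """Spec mirroring the qualitative structure of the motivating cohort.

    Component 1: a globally negative brain pattern paired with a psych
    pattern dominated by the general factor (secondary conduct/ADHD
    contributions). Component 2: a sparse positive pattern over 6 bilateral
    association regions paired with an ADHD-dominated psych pattern.
    Confounds: age (months), sex, race/ethnicity (4 levels), scanner
    manufacturer (3 levels); optionally intracranial volume with a global
    positive slope on all brain variables.
    """
    if n_samples < 50:
        raise ValidationError(f"n_samples must be >= 50, got {n_samples}")
    if len(strengths) != 2 or strengths[0] <= strengths[1]:
        raise ValidationError("expected two strictly decreasing strengths")
    names = CORTICAL_REGIONS + SUBCORTICAL_REGIONS

    brain1 = -np.ones(87) / np.sqrt(87.0)
    psych1 = np.array([0.97, 0.12, 0.12, 0.0])  # general >> conduct/adhd
    psych1 /= np.linalg.norm(psych1)

    brain2 = np.zeros(87)
    hits = [
        j
        for j, nm in enumerate(names)
        if any(region in nm for region in _COMPONENT2_REGIONS)
    ]
    brain2[hits] = 1.0
    brain2 /= np.linalg.norm(brain2)
    psych2 = np.array([0.0, 0.98, 0.0, 0.2])  # adhd >> internalizing
    psych2 /= np.linalg.norm(psych2)

    # most of each latent's signal lives on the (87-variable) brain side so
    # the spatial pattern is recoverable at n ~ 2000; the latent-pair
    # correlations still equal `strengths`
    components = (
        PlantedComponent(brain1, psych1, strengths[0], brain_latent_r=0.97),
        PlantedComponent(brain2, psych2, strengths[1], brain_latent_r=0.97),
    )

    # confound coefficients drawn once from a spec-level stream so the truth
    # tables are reproducible and independent of n_samples
    crng = np.random.default_rng(seed + 1_000_003)
    numeric = [
        NumericConfound(
            name="age_months",
            mean=118.92,
            sd=7.41,
            brain_slopes=0.02 * crng.standard_normal(87),
            psych_slopes=0.01 * crng.standard_normal(4),
        )
    ]
    if include_icv:
        numeric.append(
            NumericConfound(
                name="icv",
                mean=1450.0,
                sd=110.0,
                brain_slopes=np.full(87, 0.003),  # global head-size slope
                psych_slopes=np.zeros(4),
            )
        )
    categorical = (
        CategoricalConfound(
            name="sex",
            levels=("F", "M"),
            probs=np.array([0.478, 0.522]),
            brain_offsets=0.15 * crng.standard_normal((2, 87)),
            psych_offsets=0.08 * crng.standard_normal((2, 4)),
        ),
        CategoricalConfound(
            name="race_ethnicity",
            levels=("black", "hispanic", "other", "white"),
            probs=np.array([0.148, 0.214, 0.125, 0.513]),
            brain_offsets=0.1 * crng.standard_normal((4, 87)),
            psych_offsets=0.05 * crng.standard_normal((4, 4)),
        ),
        CategoricalConfound(
            name="manufacturer",
            levels=("ge", "philips", "siemens"),
            probs=np.array([0.25, 0.15, 0.60]),
            brain_offsets=0.12 * crng.standard_normal((3, 87)),
            psych_offsets=0.04 * crng.standard_normal((3, 4)),
        ),
    )
    return SyntheticSpec(
        n_samples=n_samples,
        components=components,
        confound_model=ConfoundModel(tuple(numeric), categorical),
        seed=seed,
    )
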