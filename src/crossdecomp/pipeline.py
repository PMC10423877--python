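"""End-to-end driver: load or simulate, preprocess, fit, test, compare.

All artifacts written by :func:`run_pipeline` embed the SHA-256 hash of the
canonicalized config plus the seed, so reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cdio
from .blocks import align_samples
from .comparison import ComparisonReport, compare_methods
from .decomposition import METHODS, fit_method
from .errors import ValidationError
from .inference import permutation_test
from .preprocess import preprocess_blocks, vif
from .synthetic import default_abcd_like_spec, generate_dataset

log = logging.getLogger("crossdecomp")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one input source must be given: either all of
    ``x_path``/``y_path`` (files) or ``synthetic_n`` (generator).
    """

    x_path: str | None = None
    y_path: str | None = None
    confounds_path: str | None = None
    synthetic_n: int | None = None
    methods: tuple = METHODS
    k: int = 4
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "crossdecomp_out"
    include_icv: bool = False
    skip_residualization: bool = False
    categorical_confounds: tuple = ()

    def __post_init__(self):
        from_files = self.x_path is not None and self.y_path is not None
        from_synth = self.synthetic_n is not None
        if from_files == from_synth:
            raise ValidationError(
                "config must name exactly one input source: x/y files XOR "
                "a synthetic sample size"
            )
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must lie in (0, 1]")
        methods = tuple(m.upper() for m in self.methods)
        unknown = [m for m in methods if m not in METHODS]
        if unknown:
            raise ValidationError(f"unknown methods {unknown}; choose from {METHODS}")
        object.__setattr__(self, "methods", methods)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["categorical_confounds"] = list(self.categorical_confounds)
        return d

    def sha(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic_n is not None:
        log.info(
            "stage=simulate n=%d seed=%d icv=%s",
            config.synthetic_n,
            config.seed,
            config.include_icv,
        )
        spec = default_abcd_like_spec(
            config.synthetic_n, seed=config.seed, include_icv=config.include_icv
        )
        x, y, confounds, truth = generate_dataset(spec)
        return x, y, confounds, truth
    log.info("stage=load x=%s y=%s", config.x_path, config.y_path)
    x = cdio.read_block(config.x_path)
    y = cdio.read_block(config.y_path)
    confounds = None
    if config.confounds_path:
        confounds = cdio.read_confounds(
            config.confounds_path, categorical=config.categorical_confounds
        )
    return x, y, confounds, None


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison pipeline and write all artifacts.

    Stages: simulate/load -> align on sample IDs -> residualize ->
    standardize -> fit each method -> permutation test -> cross-method
    comparison. Any stage error propagates annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_sha": config.sha(), "seed": config.seed}
    (out / "config.json").write_text(
        json.dumps({"provenance": provenance, "config": config.to_dict()}, indent=1)
        + "\n"
    )

    stage = "input"
    try:
        x, y, confounds, truth = _load_inputs(config)
        if truth is not None:
            truth.to_json(out / "truth.json")
            cdio.write_block(x, out / "brain.csv")
            cdio.write_block(y, out / "psych.csv")
            if confounds is not None:
                cdio.write_confounds(confounds, out / "confounds.csv")

        stage = "align"
        x, y, confounds = align_samples(x, y, confounds)

        stage = "preprocess"
        log.info(
            "stage=preprocess residualize=%s standardize=True",
            confounds is not None and not config.skip_residualization,
        )
        xp, yp = preprocess_blocks(
            x, y, confounds, skip_residualization=config.skip_residualization
        )

        stage = "diagnostics"
        if xp.n > xp.p:  # collinearity profile of the preprocessed brain block
            cdio.write_vif_tsv(xp, vif(xp), out / "vif_brain.tsv", provenance)
        if yp.n > yp.p:
            cdio.write_vif_tsv(yp, vif(yp), out / "vif_psych.tsv", provenance)

        k = min(config.k, xp.p, yp.p)
        fits, reports = [], []
        for method in config.methods:
            stage = f"fit[{method}]"
            log.info("stage=fit method=%s k=%d", method, k)
            fit = fit_method(method, xp, yp, k=k)
            fits.append(fit)
            cdio.write_fit(fit, out / f"fit_{method.lower()}.json", provenance)
            cdio.write_loadings_tsv(
                fit,
                out / f"loadings_brain_{method.lower()}.tsv",
                out / f"loadings_psych_{method.lower()}.tsv",
                provenance,
            )

            stage = f"permtest[{method}]"
            log.info("stage=permtest method=%s B=%d seed=%d", method, config.B, config.seed)
            report = permutation_test(
                xp, yp, method, k=k, B=config.B, seed=config.seed
            )
            reports.append(report)
            cdio.write_permutation_report(
                report, out / f"permutation_{method.lower()}.json", provenance
            )
            cdio.write_permutation_tsv(
                report, out / f"permutation_{method.lower()}.tsv", provenance
            )

        stage = "compare"
        log.info("stage=compare alpha=%g", config.alpha)
        comparison = compare_methods(fits, reports, alpha=config.alpha)
        cdio.write_comparison(comparison, out / "comparison.json", provenance)
        cdio.write_cosine_tsv(comparison, out / "comparison_cosines.tsv", provenance)
    except Exception as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc
    log.info("pipeline complete: %s", out)
    return comparison
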