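"""End-to-end pipeline: design -> responses -> QC -> fit -> preference outputs.

A :class:`PipelineConfig` captures every knob and seed, round-trips through
YAML/JSON losslessly, and :func:`run_pipeline` turns it into a directory of
artifacts (design CSV, response CSV, QC JSON, fit JSON + text table,
utility-table CSV, marginal JSON, log).  Identical configs produce
byte-identical artifacts.

In *analysis-only* mode (``coefficients`` given, simulation/fitting
skipped) the utility table and marginals are produced directly from
supplied published coefficients, so the headline preference tables are
reproducible without any response data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import AttributeScheme, REMOTE_CARE_SCHEME, build_design
from .estimation import (
    MixedLogitSpec,
    expand_to_rows,
    fit_binary_logit,
    fit_mixed_logit,
)
from .preference import (
    CoefficientSet,
    build_utility_table,
    marginal_report,
)
from .qc import RawResponseSet, run_qc
from .simulate import BehaviorMix, PreferenceModel, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run.  All seeds are explicit."""

    # design
    attributes: list[str] = field(
        default_factory=lambda: list(REMOTE_CARE_SCHEME.attributes)
    )
    design_seed: int = 0
    # data source: exactly one of (simulate, responses_csv, coefficients)
    simulate: dict | None = None  # {alpha, betas, sigma_re, nontrader_rate,
    #                                dominant_rates, dropout_rate, n, seed}
    responses_csv: str | None = None
    coefficients: dict | None = None  # {"alpha": ..., "betas": {...}} -> analysis only
    # qc
    exclude_dominant: bool = False
    # estimation
    model: str = "logit"  # "logit" | "mixed"
    n_quadrature: int = 31
    cov_type: str = "observed"
    collapse_pairs: bool = False
    # output
    out_dir: str = "dcepref_out"

    def validate(self) -> None:
        sources = [self.simulate, self.responses_csv, self.coefficients]
        if sum(s is not None for s in sources) != 1:
            raise PipelineError(
                "config: exactly one of simulate / responses_csv / coefficients required"
            )
        if self.model not in ("logit", "mixed"):
            raise PipelineError(f"config: unknown model {self.model!r}")
        if self.coefficients is not None:
            betas = self.coefficients.get("betas", {})
            missing = [a for a in self.attributes if a not in betas]
            if "alpha" not in self.coefficients or missing:
                raise PipelineError(
                    f"config: coefficients must provide alpha and a beta per attribute "
                    f"(missing {missing})"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2))

    @property
    def scheme(self) -> AttributeScheme:
        if tuple(self.attributes) == REMOTE_CARE_SCHEME.attributes:
            return REMOTE_CARE_SCHEME
        return AttributeScheme(tuple(self.attributes))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages; returns paths of written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = [f"config: {json.dumps(config.to_dict(), sort_keys=True)}"]

    def _stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage: {name}")

    try:
        _stage("design")
        scheme = config.scheme
        design = build_design(scheme, order_seed=config.design_seed)
        artifacts["design_csv"] = out / "design.csv"
        design.to_csv(artifacts["design_csv"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"design stage failed: {exc}") from exc

    if config.coefficients is not None:
        coeffs = CoefficientSet(
            scheme=scheme,
            alpha=float(config.coefficients["alpha"]),
            betas={k: float(v) for k, v in config.coefficients["betas"].items()},
        )
    else:
        try:
            if config.simulate is not None:
                _stage("simulate")
                sim = dict(config.simulate)
                model = PreferenceModel(
                    alpha=float(sim["alpha"]),
                    betas=sim["betas"],
                    sigma_re=float(sim.get("sigma_re", 0.0)),
                )
                mix = BehaviorMix(
                    nontrader_rate=float(sim.get("nontrader_rate", 0.0)),
                    dominant_rates=sim.get("dominant_rates", {}),
                    dropout_rate=float(sim.get("dropout_rate", 0.0)),
                )
                cohort = simulate_cohort(
                    design, model, mix, int(sim["n"]), int(sim["seed"])
                )
                artifacts["responses_csv"] = out / "responses.csv"
                cohort.to_csv(artifacts["responses_csv"])
                artifacts["truth_json"] = out / "truth.json"
                cohort.truth_to_json(artifacts["truth_json"])
                raw = RawResponseSet(design, cohort.records())
            else:
                _stage("load responses")
                raw = RawResponseSet.from_csv(config.responses_csv, design)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"data stage failed: {exc}") from exc

        try:
            _stage("qc")
            valid, report = run_qc(raw, exclude_dominant=config.exclude_dominant)
            artifacts["qc_json"] = out / "qc_report.json"
            report.to_json(artifacts["qc_json"])
            log_lines.extend(report.log_lines())
        except Exception as exc:
            raise PipelineError(f"qc stage failed: {exc}") from exc

        try:
            _stage("fit")
            rows = expand_to_rows(valid)
            if config.model == "mixed":
                fit = fit_mixed_logit(
                    rows,
                    MixedLogitSpec(
                        n_quadrature=config.n_quadrature,
                        collapse_pairs=config.collapse_pairs,
                    ),
                )
            else:
                fit = fit_binary_logit(rows, cov_type=config.cov_type)
            artifacts["fit_json"] = out / "fit.json"
            fit.to_json(artifacts["fit_json"])
            artifacts["fit_txt"] = out / "fit.txt"
            Path(artifacts["fit_txt"]).write_text(fit.summary_table() + "\n")
            log_lines.append(f"fit converged: {fit.converged}")
            coeffs = CoefficientSet.from_fit(scheme, fit)
        except Exception as exc:
            raise PipelineError(f"fit stage failed: {exc}") from exc

    try:
        _stage("preference analysis")
        table = build_utility_table(coeffs)
        artifacts["utility_table_csv"] = out / "utility_table.csv"
        table.to_csv(artifacts["utility_table_csv"])
        artifacts["marginals_json"] = out / "marginals.json"
        Path(artifacts["marginals_json"]).write_text(
            json.dumps(marginal_report(coeffs), indent=2)
        )
    except Exception as exc:
        raise PipelineError(f"preference stage failed: {exc}") from exc

    artifacts["log"] = out / "run.log"
    Path(artifacts["log"]).write_text("\n".join(log_lines) + "\n")
    return artifacts
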