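"""YAML configuration mirroring every analysis default.

One file drives the whole pipeline: class grids, kernel settings (backend,
Monte-Carlo sample size K, enumeration cap), parameter bounds, random
search and MCMC settings, cross-validation folds, and — for simulation —
the ground-truth parameters and study design.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from .core import DEFAULT_ACTIONS, AbundanceClassScheme, LHTriplet, SpeciesParameters
from .inference import McmcConfig, ParameterSpace, SearchConfig
from .simulate import StudyDesign, default_design

__all__ = ["AnalysisConfig", "load_config", "default_config"]

#: Default simulation truth: two contrasted life-history strategies spread
#: over the four actions (colonizers under the annual crops, a persister
#: under maize), growth rates straddling 1.
_DEFAULT_TRUTH = {
    "WC": (0.35, 0.50, 3.0),
    "OR": (0.20, 0.45, 1.5),
    "M": (0.10, 0.75, 5.0),
    "SF": (0.25, 0.60, 0.8),
}
_DEFAULT_P0 = (0.30, 0.25, 0.20, 0.15, 0.07, 0.03)


@dataclass
class KernelConfig:
    backend: str = "exact"  # 'exact' (deterministic) or 'mc' (survey-scale procedure)
    K: int = 30_000
    cap: int | None = None  # None -> scheme's seed-bank top cap
    production_mode: str = "poisson"


@dataclass
class AnalysisConfig:
    actions: Tuple[str, ...] = DEFAULT_ACTIONS
    phi_max: float = 200.0
    scheme: AbundanceClassScheme = field(default_factory=AbundanceClassScheme)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    cv_folds: int = 4
    matrix_form: str = "as_printed"
    truth: SpeciesParameters | None = None
    design: StudyDesign | None = None

    def space(self) -> ParameterSpace:
        return ParameterSpace(actions=self.actions, phi_max=self.phi_max)

    def resolved_truth(self) -> SpeciesParameters:
        if self.truth is not None:
            return self.truth
        return SpeciesParameters(
            lht={
                a: LHTriplet(*_DEFAULT_TRUTH[a], phi_max=self.phi_max)
                for a in self.actions
            },
            p0=np.array(_DEFAULT_P0),
        )

    def resolved_design(self) -> StudyDesign:
        return self.design if self.design is not None else default_design()


def _search_from(d: dict) -> SearchConfig:
    return SearchConfig(**d)


def _mcmc_from(d: dict) -> McmcConfig:
    return McmcConfig(**d)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "actions" in raw:
        cfg.actions = tuple(raw["actions"])
    if "phi_max" in raw:
        cfg.phi_max = float(raw["phi_max"])
    if "scheme" in raw:
        cfg.scheme = AbundanceClassScheme.from_dict(raw["scheme"])
    if "kernel" in raw:
        cfg.kernel = KernelConfig(**raw["kernel"])
    if "search" in raw:
        cfg.search = _search_from(raw["search"])
    if "mcmc" in raw:
        cfg.mcmc = _mcmc_from(raw["mcmc"])
    if "cv_folds" in raw:
        cfg.cv_folds = int(raw["cv_folds"])
    if "matrix_form" in raw:
        cfg.matrix_form = str(raw["matrix_form"])
    if "truth" in raw:
        t = raw["truth"]
        cfg.truth = SpeciesParameters(
            lht={
                a: LHTriplet(
                    float(v["sigma"]), float(v["s"]), float(v["phi"]),
                    phi_max=cfg.phi_max,
                )
                for a, v in t["lht"].items()
            },
            p0=np.asarray(t["p0"], dtype=float),
        )
    if "design" in raw:
        d = raw["design"]
        base = default_design()
        cfg.design = StudyDesign(
            n_fields=int(d.get("n_fields", base.n_fields)),
            series_length_pmf={
                int(k): float(v)
                for k, v in d.get(
                    "series_length_pmf", base.series_length_pmf
                ).items()
            },
            action_frequencies={
                str(k): float(v)
                for k, v in d.get(
                    "action_frequencies", base.action_frequencies
                ).items()
            },
            rotation_model=d.get("rotation_model", "iid"),
        )
    return cfg


def default_config() -> Dict:
    """Plain-dict rendering of the defaults (for ``weedhmm config`` export)."""
    cfg = AnalysisConfig()
    truth = cfg.resolved_truth()
    design = cfg.resolved_design()
    return {
        "actions": list(cfg.actions),
        "phi_max": cfg.phi_max,
        "scheme": cfg.scheme.to_dict(),
        "kernel": asdict(cfg.kernel),
        "search": asdict(cfg.search),
        "mcmc": {**asdict(cfg.mcmc), "proposal_scale": float(cfg.mcmc.proposal_scale)},
        "cv_folds": cfg.cv_folds,
        "matrix_form": cfg.matrix_form,
        "truth": {
            "lht": {
                a: {"sigma": t.sigma, "s": t.s, "phi": t.phi}
                for a, t in truth.lht.items()
            },
            "p0": [float(p) for p in truth.p0],
        },
        "design": {
            "n_fields": design.n_fields,
            "series_length_pmf": {
                int(k): float(v) for k, v in design.series_length_pmf.items()
            },
            "action_frequencies": {
                k: float(v) for k, v in design.action_frequencies.items()
            },
            "rotation_model": design.rotation_model,
        },
    }


def dump_config(path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(default_config(), sort_keys=False))
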