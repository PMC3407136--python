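"""Prior configuration for the mixing model.

Defaults follow the vague-prior convention: flat Dirichlet on diets,
Normal(0, 1000) on basal means, Gamma(1e-3, 1e-3) on residual precisions,
hierarchical Normal(mean_j, tau_j^2) on TEFs with a half-Cauchy(25)
hyperprior on tau_j (per-element TEF prior means 0.8 for d13C and 3.4 for
d15N from the enrichment literature).  A uniform TEF prior variant with
literature "mean +/- 2 SD" bounds is available per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = ["ElementTEFPrior", "PriorConfig"]

_DEFAULT_TEF = {
    "d13C": {"mean": 0.8, "bounds": (-2.2, 3.0)},
    "d15N": {"mean": 3.4, "bounds": (1.4, 5.4)},
}


@dataclass(frozen=True)
class ElementTEFPrior:
    """TEF prior for one element.

    family='normal': Delta ~ Normal(mean, tau^2), tau ~ half-Cauchy(sd_scale)
    (or tau pinned to ``fixed_sd`` when given -- a known-TEF analysis).
    family='uniform': Delta ~ Uniform(*bounds).
    """

    family: str = "normal"
    mean: float = 0.0
    sd_scale: float = 25.0
    bounds: tuple[float, float] | None = None
    fixed_sd: float | None = None

    def __post_init__(self):
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown TEF prior family {self.family!r}")
        if self.family == "uniform":
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError("uniform TEF prior needs ordered bounds")
        if self.sd_scale <= 0:
            raise ValueError("sd_scale must be positive")
        if self.fixed_sd is not None and self.fixed_sd <= 0:
            raise ValueError("fixed_sd must be positive")


def _default_tef_prior(element: str) -> ElementTEFPrior:
    d = _DEFAULT_TEF.get(element)
    if d is None:
        return ElementTEFPrior(mean=0.0)
    return ElementTEFPrior(mean=d["mean"], bounds=d["bounds"])


@dataclass(frozen=True)
class PriorConfig:
    """All priors of the model; see the class docstrings for parameterisation."""

    tef: dict[str, ElementTEFPrior] = field(default_factory=dict)
    dirichlet_alpha: float = 1.0
    basal_mean_loc: float = 0.0
    basal_mean_sd: float = 1000.0
    residual_precision_shape: float = 1e-3
    residual_precision_rate: float = 1e-3

    def __post_init__(self):
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet alpha must be positive")
        for v in (
            self.basal_mean_sd,
            self.residual_precision_shape,
            self.residual_precision_rate,
        ):
            if v <= 0:
                raise ValueError("prior scale parameters must be positive")

    def tef_prior(self, element: str) -> ElementTEFPrior:
        return self.tef.get(element, _default_tef_prior(element))

    @classmethod
    def default(cls, elements=("d13C", "d15N"), family: str = "normal") -> "PriorConfig":
        tef = {}
        for e in elements:
            p = _default_tef_prior(e)
            if family == "uniform":
                p = replace(p, family="uniform")
            tef[e] = p
        return cls(tef=tef)

    # -- config-file IO (flat dotted keys) ---------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, object] = {}

        def flatten(prefix: str, obj) -> None:
            for k, v in obj.items():
                key = f"{prefix}{k}"
                if isinstance(v, dict):
                    flatten(key + ".", v)
                else:
                    flat[key] = v

        flatten("", raw)
        elements = sorted(
            {
                k.rsplit(".", 1)[1]
                for k in flat
                if k.startswith(("tef.mean.", "tef.uniform.", "tef.sd_fixed."))
            }
            | set(_DEFAULT_TEF)
        )
        family = str(flat.get("tef.family", "normal"))
        scale = float(flat.get("tef.sd_hyperprior.scale", 25.0))
        tef = {}
        for e in elements:
            base = _default_tef_prior(e)
            bounds = flat.get(f"tef.uniform.{e}", base.bounds)
            fixed = flat.get(f"tef.sd_fixed.{e}")
            tef[e] = ElementTEFPrior(
                family=family,
                mean=float(flat.get(f"tef.mean.{e}", base.mean)),
                sd_scale=scale,
                bounds=None if bounds is None else tuple(float(b) for b in bounds),
                fixed_sd=None if fixed is None else float(fixed),
            )
        return cls(
            tef=tef,
            dirichlet_alpha=float(flat.get("dirichlet.alpha", 1.0)),
            basal_mean_loc=float(flat.get("basal_mean.loc", 0.0)),
            basal_mean_sd=float(flat.get("basal_mean.sd", 1000.0)),
            residual_precision_shape=float(flat.get("residual_precision.shape", 1e-3)),
            residual_precision_rate=float(flat.get("residual_precision.rate", 1e-3)),
        )

    def to_yaml(self, path) -> None:
        doc: dict[str, object] = {
            "dirichlet": {"alpha": self.dirichlet_alpha},
            "basal_mean": {"loc": self.basal_mean_loc, "sd": self.basal_mean_sd},
            "residual_precision": {
                "shape": self.residual_precision_shape,
                "rate": self.residual_precision_rate,
            },
        }
        if self.tef:
            any_prior = next(iter(self.tef.values()))
            tef_doc: dict[str, object] = {
                "family": any_prior.family,
                "sd_hyperprior": {"scale": any_prior.sd_scale},
                "mean": {e: p.mean for e, p in self.tef.items()},
            }
            if any(p.bounds for p in self.tef.values()):
                tef_doc["uniform"] = {
                    e: list(p.bounds) for e, p in self.tef.items() if p.bounds
                }
            if any(p.fixed_sd for p in self.tef.values()):
                tef_doc["sd_fixed"] = {
                    e: p.fixed_sd for e, p in self.tef.items() if p.fixed_sd
                }
            doc["tef"] = tef_doc
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
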