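"""Parameter-file loading and validation.

Built-in parameter sets ship with the package: ``tfv_chain.default`` and
``ftc_chain.default`` hold the published typical values, covariate
coefficients, and variability estimates for the two analyte chains.  User
files use the same YAML schema; unknown keys are rejected so typos fail
loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .params import (ChainConfig, ChainParams, CovariateEffect, DntpParams,
                     IntracellularParams, ParameterError, PlasmaParams,
                     VariabilitySpec)

BUILTIN = {
    "tfv_chain.default": "tfv_chain.yaml",
    "ftc_chain.default": "ftc_chain.yaml",
}


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _build(doc: dict, source: str) -> ChainConfig:
    if not isinstance(doc, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    _check_keys(doc, {"analyte", "dose_ug", "plasma", "intracellular", "dntp",
                      "covariates", "variability"}, source)
    for key in ("analyte", "plasma", "intracellular", "dntp"):
        if key not in doc:
            raise ConfigError(f"{source}: missing required section {key!r}")

    _check_keys(doc["plasma"], {"Ka", "Vc_F", "CL_F", "Vp_F", "Q_F"}, "plasma")
    plasma = PlasmaParams(**{k: float(v) for k, v in doc["plasma"].items()})

    _check_keys(doc["intracellular"], {"Kf", "SC50", "Kel", "R"}, "intracellular")
    ic = IntracellularParams(**{k: float(v) for k, v in doc["intracellular"].items()})

    dntps = []
    for name, fields in doc["dntp"].items():
        _check_keys(fields, {"R0", "EC50", "gamma"}, f"dntp.{name}")
        dntps.append(DntpParams(
            name=name, R0=float(fields["R0"]), EC50=float(fields["EC50"]),
            gamma=(float(fields["gamma"]) if "gamma" in fields else None)))

    from .regimen import STANDARD_DOSE_UG
    dose = float(doc.get("dose_ug", STANDARD_DOSE_UG.get(doc["analyte"], 0.0)))
    chain = ChainParams(analyte=str(doc["analyte"]), dose_ug=dose,
                        plasma=plasma, ic=ic, dntps=dntps)

    effects = []
    for e in doc.get("covariates", []) or []:
        _check_keys(e, {"param", "covariate", "coeff"}, "covariates[]")
        effects.append(CovariateEffect(param=str(e["param"]),
                                       covariate=str(e["covariate"]),
                                       coeff=float(e["coeff"])))

    vdoc = doc.get("variability", {}) or {}
    _check_keys(vdoc, {"omega2", "sigma2", "error_model"}, "variability")
    var = VariabilitySpec(
        omega2={str(k): float(v) for k, v in (vdoc.get("omega2") or {}).items()},
        sigma2={str(k): float(v) for k, v in (vdoc.get("sigma2") or {}).items()},
        error_model={str(k): str(v) for k, v in (vdoc.get("error_model") or {}).items()})

    cfg = ChainConfig(params=chain, covariate_effects=effects, variability=var)
    try:
        cfg.validate()
    except (ParameterError, KeyError) as err:
        raise ConfigError(f"{source}: {err}") from err
    return cfg


def load_params(name_or_path: str | Path) -> ChainConfig:
    """Load a chain configuration from a builtin name or a YAML file."""
    key = str(name_or_path)
    if key in BUILTIN:
        text = resources.files("icpkpd.data").joinpath(BUILTIN[key]).read_text()
        source = key
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ConfigError(
                f"{key!r} is neither a builtin ({sorted(BUILTIN)}) nor a file")
        text = path.read_text()
        source = str(path)
    return _build(yaml.safe_load(text), source)


def default_chains() -> dict[str, ChainConfig]:
    """Both built-in chains keyed by analyte ('TFV', 'FTC')."""
    out = {}
    for name in BUILTIN:
        cfg = load_params(name)
        out[cfg.params.analyte] = cfg
    return out
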