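"""Structured-text (YAML) configuration for parameter sets and trajectories.

Parameter files hold one block per variable x sex, each with the two genotype
strata and the mixing probability ``p1``.  Values in files are on the printed
display scale (``a_mu1`` x1e4, ``b_mu1`` x1e5, ``b_Y`` x1e3); conversion to
the natural scale happens at load time so scale bugs cannot silently leak
into simulation or estimation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .model import GenotypeParams, ModelParams, OptimalTrajectory, TrajectoryPair

__all__ = [
    "load_params_file",
    "load_params",
    "save_params",
    "reference_params",
    "available_reference_sets",
    "save_trajectories",
    "load_trajectories",
]


def _parse_blocks(doc: dict) -> dict:
    if doc.get("scale", "display") != "display":
        raise ValueError("parameter files must declare scale: display")
    out = {}
    for variable, by_sex in doc["parameters"].items():
        for sex, block in by_sex.items():
            out[(variable, sex)] = ModelParams(
                noncarrier=GenotypeParams.from_display(block["noncarrier"]),
                carrier=GenotypeParams.from_display(block["carrier"]),
                p1=float(block["p1"]),
            )
    return out


def load_params_file(path) -> dict:
    """Load every (variable, sex) parameter block from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_blocks(doc)


def load_params(path, variable: str, sex: str) -> ModelParams:
    blocks = load_params_file(path)
    key = (variable, sex)
    if key not in blocks:
        raise KeyError(f"no parameter block for variable={variable!r}, sex={sex!r}")
    return blocks[key]


def save_params(blocks: dict, path) -> None:
    """Write ``{(variable, sex): ModelParams}`` back to display-scale YAML."""
    doc: dict = {"scale": "display", "parameters": {}}
    for (variable, sex), mp in blocks.items():
        doc["parameters"].setdefault(variable, {})[sex] = {
            "p1": float(mp.p1),
            "noncarrier": {k: float(v) for k, v in mp.noncarrier.to_display().items()},
            "carrier": {k: float(v) for k, v in mp.carrier.to_display().items()},
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _reference_blocks() -> dict:
    ref = resources.files("genspm.data").joinpath("reference_params.yaml")
    with resources.as_file(ref) as p:
        return load_params_file(p)


def available_reference_sets() -> list:
    return sorted(_reference_blocks())


def reference_params(variable: str, sex: str) -> ModelParams:
    """Bundled reference parameter set for one variable/sex stratum."""
    blocks = _reference_blocks()
    key = (variable, sex)
    if key not in blocks:
        raise KeyError(
            f"unknown reference stratum {key}; available: {sorted(blocks)}"
        )
    return blocks[key]


# ---------------------------------------------------------------------------
# optimal-trajectory round trip
# ---------------------------------------------------------------------------

def save_trajectories(pair: TrajectoryPair, path) -> None:
    doc = {}
    for name in ("noncarrier", "carrier"):
        f = getattr(pair, name)
        doc[name] = {
            "coeffs": [float(c) for c in f.coeffs],
            "age_domain": [float(a) for a in f.age_domain],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_trajectories(path) -> TrajectoryPair:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def mk(block):
        return OptimalTrajectory(tuple(block["coeffs"]), tuple(block["age_domain"]))

    return TrajectoryPair(mk(doc["noncarrier"]), mk(doc["carrier"]))
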