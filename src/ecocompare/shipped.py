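"""The shipped calibrated size-spectrum configuration.

The packaged files ``calibrated_species.csv``, ``calibrated_theta.csv``
and ``calibrated_resource.yaml`` hold the reference community: 22
dynamic species groups with traits generated from the packaged roster,
feeding-kernel and physiology parameters derived by the standard
procedures, and R_max calibrated so the unfished equilibrium matches the
synthetic source-model virgin biomasses.  Regenerated end to end by the
numbered analysis scripts.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd
import yaml

from .sizespectrum import ResourceParams, SSModel


def _read(name: str):
    return importlib.resources.files("ecocompare.data").joinpath(name)


def load_calibrated_species() -> pd.DataFrame:
    with importlib.resources.as_file(_read("calibrated_species.csv")) as p:
        return pd.read_csv(p)


def load_calibrated_theta() -> pd.DataFrame:
    with importlib.resources.as_file(_read("calibrated_theta.csv")) as p:
        return pd.read_csv(p, index_col=0)


def load_calibrated_resource() -> ResourceParams:
    with importlib.resources.as_file(_read("calibrated_resource.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    return ResourceParams(**raw)


def load_calibrated_model() -> SSModel:
    """Build the shipped calibrated community model."""
    species = load_calibrated_species()
    theta = load_calibrated_theta()
    resource = load_calibrated_resource()
    return SSModel(species, theta, resource=resource)
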