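"""Bundled default inputs.

``data/default_parameters.yaml`` reproduces the published base-case
parameter table verbatim; ``data/life_table_synthetic.csv`` is the
*synthetic* Gompertz life table (the original mortality inputs are cited
but not printed anywhere), with a constant 0.10 CVD case-fatality column.
"""

from __future__ import annotations

from importlib import resources

from .life_tables import LifeTable, load_life_table
from .params import ParameterSet, load_parameters

__all__ = [
    "default_parameters_path",
    "default_life_table_path",
    "load_default_parameters",
    "load_default_life_table",
]


def default_parameters_path():
    return resources.files("noisecea") / "data" / "default_parameters.yaml"


def default_life_table_path():
    return resources.files("noisecea") / "data" / "life_table_synthetic.csv"


def load_default_parameters() -> ParameterSet:
    return load_parameters(default_parameters_path())


def load_default_life_table() -> LifeTable:
    return load_life_table(default_life_table_path())
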